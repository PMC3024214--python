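"""Synthetic structure generation.

Builds idealized polypeptide backbones (N, CA, C, O, and CB except for
glycine) from canonical bond lengths, bond angles and secondary-structure
torsions, so that every geometric operation in the package can be exercised
offline on structures with realistic local geometry. The generator is fully
deterministic given its seed.

Motifs:

* ``helix``  — alpha-helical torsions (phi -57°, psi -47°)
* ``strand`` — antiparallel-beta torsions (phi -139°, psi 135°)
* ``coil``   — torsions drawn per residue from a seeded stream over the
  broadly allowed region of the Ramachandran map, giving irregular,
  mutually dissimilar chains suitable as decoys

Residue types are drawn uniformly from the 20 standard amino acids from the
same seeded stream, so sequence composition is unbiased.
"""

from __future__ import annotations

import math

import numpy as np

from .structure import ONE_TO_THREE, Atom, Residue, Structure

__all__ = ["make_synthetic_structure", "perturb_structure", "random_rotation", "MOTIFS"]

MOTIFS = ("helix", "strand", "coil")

# canonical backbone geometry (Engh/Huber-style ideal values), Å and degrees
_B_N_CA = 1.458
_B_CA_C = 1.525
_B_C_N = 1.329
_B_C_O = 1.231
_B_CA_CB = 1.521
_A_N_CA_C = 111.2
_A_CA_C_N = 116.2
_A_C_N_CA = 121.7
_A_CA_C_O = 120.8
_A_N_CA_CB = 110.4
_OMEGA = 180.0

_TORSIONS = {"helix": (-57.0, -47.0), "strand": (-139.0, 135.0)}

_AA20 = tuple(sorted(ONE_TO_THREE.values()))


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural extension of reference frame (a, b, c) by one atom.

    Returns the point at distance ``bond`` from ``c``, with angle
    ``b-c-new`` and dihedral ``a-b-c-new``.
    """
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(torsion),
        bond * math.sin(angle) * math.sin(torsion),
    ])
    return c + d[0] * bc + d[1] * m + d[2] * n


def make_synthetic_structure(
    n_residues: int,
    motif: str = "helix",
    seed: int = 0,
    structure_id: str | None = None,
) -> Structure:
    """Build an idealized backbone of ``n_residues`` residues.

    Deterministic for a fixed ``(n_residues, motif, seed)``. Consecutive
    CA–CA distances are ~3.8 Å (trans peptide).
    """
    if n_residues < 3:
        raise ValueError("a synthetic structure needs at least 3 residues")
    if motif not in MOTIFS:
        raise ValueError(f"unknown motif {motif!r}; choose from {MOTIFS}")
    rng = np.random.default_rng(seed)
    res_types = [str(rng.choice(_AA20)) for _ in range(n_residues)]
    if motif == "coil":
        phis = rng.uniform(-160.0, -50.0, size=n_residues)
        psis = rng.uniform(-80.0, 170.0, size=n_residues)
    else:
        phi0, psi0 = _TORSIONS[motif]
        phis = np.full(n_residues, phi0)
        psis = np.full(n_residues, psi0)

    # seed the first residue's backbone explicitly
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = math.radians(_A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])

    backbone: list[dict[str, np.ndarray]] = [{"N": n0, "CA": ca0, "C": c0}]
    for i in range(1, n_residues):
        prev = backbone[-1]
        n_i = _place_atom(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psis[i - 1])
        ca_i = _place_atom(prev["CA"], prev["C"], n_i, _B_N_CA, _A_C_N_CA, _OMEGA)
        c_i = _place_atom(prev["C"], n_i, ca_i, _B_CA_C, _A_N_CA_C, phis[i])
        backbone.append({"N": n_i, "CA": ca_i, "C": c_i})

    residues: list[Residue] = []
    for i, bb in enumerate(backbone):
        atoms = [
            Atom("N", "N", bb["N"]),
            Atom("CA", "C", bb["CA"]),
            Atom("C", "C", bb["C"]),
        ]
        # carbonyl oxygen: anti to the next N (or to psi for the last residue)
        o_torsion = psis[i] + 180.0
        atoms.append(Atom("O", "O", _place_atom(bb["N"], bb["CA"], bb["C"],
                                                _B_C_O, _A_CA_C_O, o_torsion)))
        if res_types[i] != "GLY":
            cb = _place_atom(bb["C"], bb["N"], bb["CA"], _B_CA_CB, _A_N_CA_CB, -122.6)
            atoms.append(Atom("CB", "C", cb))
        residues.append(
            Residue(chain_id="A", seq_id=i + 1, res_type=res_types[i], atoms=tuple(atoms))
        )
    sid = structure_id or f"SYN_{motif}_{n_residues}_{seed}"
    return Structure(id=sid, residues=residues)


def perturb_structure(s: Structure, sigma: float, seed: int = 0) -> Structure:
    """Add isotropic Gaussian coordinate noise of standard deviation ``sigma`` Å."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    from dataclasses import replace

    if sigma == 0:
        return Structure(
            id=s.id, residues=list(s.residues), hetero_groups=list(s.hetero_groups),
            title=s.title, site_records=dict(s.site_records),
        )
    rng = np.random.default_rng(seed)

    def jitter(res: Residue) -> Residue:
        atoms = tuple(
            replace(a, coords=a.coords + rng.normal(0.0, sigma, size=3)) for a in res.atoms
        )
        return replace(res, atoms=atoms)

    return Structure(
        id=s.id,
        residues=[jitter(r) for r in s.residues],
        hetero_groups=[jitter(r) for r in s.hetero_groups],
        title=s.title,
        site_records=dict(s.site_records),
    )


def random_rotation(seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """A uniformly random proper rotation and a random translation (for tests)."""
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    rot = Rotation.random(rng=rng).as_matrix()
    trans = rng.uniform(-20.0, 20.0, size=3)
    return rot, trans
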