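"""Reverse 3-residue template generation and matching.

A query structure is decomposed into its full set of 3-residue templates:
every triple of residues in which the closest heavy-atom distance between
each pair is at most ``max_pair_dist`` (default 5.0 Å) and at most
``max_hydrophobic`` (default 1) of the residues are hydrophobic. The
hydrophobic-count rule biases templates towards surface-exposed, polar
constellations of the kind found in functional sites.

Each template is then scanned against target structures: candidate residue
triples of compatible type are pre-filtered on CA–CA distance compatibility
and accepted when the optimal rigid superposition of the designated
matching atoms has an RMSD within tolerance.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .structure import Residue, ResidueId, Structure, residue_min_distance_matrix

__all__ = [
    "Template",
    "RawMatch",
    "SubstitutionPolicy",
    "IDENTITY_POLICY",
    "SIMILARITY_POLICY",
    "HYDROPHOBIC_RESIDUES",
    "generate_templates",
    "match_template",
    "scan",
]

logger = logging.getLogger(__name__)

#: Kyte–Doolittle-positive core used for the surface bias rule
HYDROPHOBIC_RESIDUES = frozenset({"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP"})

#: default per-residue-type matching atoms: CA, CB and one functional atom
_FUNCTIONAL_ATOM = {
    "SER": "OG", "THR": "OG1", "CYS": "SG", "HIS": "NE2", "ASP": "OD1",
    "GLU": "OE1", "ASN": "OD1", "GLN": "OE1", "LYS": "NZ", "ARG": "NH1",
    "TYR": "OH", "TRP": "NE1", "PHE": "CZ", "MET": "SD", "ILE": "CD1",
    "LEU": "CD1", "VAL": "CG1", "PRO": "CG",
}

#: similar-residue groups used by the optional substitution policy
SIMILARITY_GROUPS = (
    {"ASP", "GLU"}, {"LYS", "ARG"}, {"SER", "THR"},
    {"ILE", "LEU", "VAL", "MET"}, {"PHE", "TYR", "TRP"}, {"ASN", "GLN"},
)


@dataclass(frozen=True)
class SubstitutionPolicy:
    """Residue-type compatibility for matching and similarity scoring."""

    name: str
    allow_similar: bool = False

    def group_of(self, res_type: str) -> frozenset[str]:
        for g in SIMILARITY_GROUPS:
            if res_type in g:
                return frozenset(g)
        return frozenset({res_type})

    def compatible(self, template_type: str, candidate_type: str) -> bool:
        if template_type == candidate_type:
            return True
        return self.allow_similar and candidate_type in self.group_of(template_type)

    def classify_pair(self, a: str, b: str) -> str:
        """'identical', 'similar' or 'other' — used by local-similarity scoring."""
        if a == b:
            return "identical"
        if b in self.group_of(a):
            return "similar"
        return "other"


IDENTITY_POLICY = SubstitutionPolicy("identity", allow_similar=False)
SIMILARITY_POLICY = SubstitutionPolicy("similarity", allow_similar=True)


def match_atom_names(res_type: str, residue: Residue | None = None) -> tuple[str, ...]:
    """Atom labels used for geometric matching of one residue.

    When the residue is given, labels absent from it (e.g. side chains not
    modelled in the coordinates) are dropped; CA is always kept.
    """
    if res_type == "GLY":
        return ("CA",)
    names = ["CA", "CB"]
    func = _FUNCTIONAL_ATOM.get(res_type)
    if func:
        names.append(func)
    if residue is not None:
        names = [n for n in names if n == "CA" or residue.atom(n) is not None]
    return tuple(names)


@dataclass(frozen=True)
class Template:
    residues: tuple[tuple[ResidueId, str], ...]  # ordered triple of (id, res_type)
    match_atoms: tuple[tuple[str, ...], ...]  # per-residue atom labels
    pairwise_min_dists: tuple[float, float, float]
    source_id: str
    ca_dists: tuple[float, float, float] = (0.0, 0.0, 0.0)  # CA–CA, for pre-filtering

    @property
    def residue_ids(self) -> tuple[ResidueId, ...]:
        return tuple(rid for rid, _ in self.residues)

    @property
    def residue_types(self) -> tuple[str, ...]:
        return tuple(rt for _, rt in self.residues)


@dataclass(frozen=True)
class RawMatch:
    template: Template
    target_id: str
    matched_residues: tuple[ResidueId, ...]
    template_rmsd: float
    rotation: np.ndarray = field(compare=False, default=None)  # query -> target frame
    translation: np.ndarray = field(compare=False, default=None)

    @property
    def is_self_match(self) -> bool:
        return (
            self.target_id == self.template.source_id
            and self.matched_residues == self.template.residue_ids
        )


def is_hydrophobic(res_type: str, hydrophobic: frozenset[str] = HYDROPHOBIC_RESIDUES) -> bool:
    return res_type in hydrophobic


def generate_templates(
    query: Structure,
    max_pair_dist: float = 5.0,
    max_hydrophobic: int = 1,
    hydrophobic: frozenset[str] = HYDROPHOBIC_RESIDUES,
) -> list[Template]:
    """All 3-residue templates of ``query`` satisfying both selection rules.

    Ordering is deterministic: lexicographic in the (chain, seq, icode)
    identifiers of the triple, and residues within a template follow the
    same order.
    """
    residues = query.residues
    if len(residues) < 3:
        raise ValueError("template generation needs at least 3 polymer residues")
    order = sorted(range(len(residues)), key=lambda i: residues[i].full_id)
    dmat = residue_min_distance_matrix(residues)
    ca = query.ca_coords()
    templates: list[Template] = []
    for ia, ib, ic in itertools.combinations(order, 3):
        trio = (ia, ib, ic)
        d01, d02, d12 = dmat[ia, ib], dmat[ia, ic], dmat[ib, ic]
        if max(d01, d02, d12) > max_pair_dist:
            continue
        n_hyd = sum(is_hydrophobic(residues[i].res_type, hydrophobic) for i in trio)
        if n_hyd > max_hydrophobic:
            continue
        templates.append(
            Template(
                residues=tuple((residues[i].full_id, residues[i].res_type) for i in trio),
                match_atoms=tuple(
                    match_atom_names(residues[i].res_type, residues[i]) for i in trio
                ),
                pairwise_min_dists=(float(d01), float(d02), float(d12)),
                source_id=query.id,
                ca_dists=(
                    float(np.linalg.norm(ca[ia] - ca[ib])),
                    float(np.linalg.norm(ca[ia] - ca[ic])),
                    float(np.linalg.norm(ca[ib] - ca[ic])),
                ),
            )
        )
    templates.sort(key=lambda t: t.residue_ids)
    return templates


def _template_coords(t: Template, query: Structure) -> np.ndarray:
    rows = []
    for (rid, _), names in zip(t.residues, t.match_atoms):
        res = query.residue(rid)
        for name in names:
            atom = res.atom(name)
            if atom is None:
                raise ValueError(f"template residue {rid} lacks atom {name}")
            rows.append(atom.coords)
    return np.asarray(rows)


def _candidate_coords(t: Template, trio: tuple[Residue, ...]) -> np.ndarray | None:
    rows = []
    for names, res in zip(t.match_atoms, trio):
        for name in names:
            atom = res.atom(name)
            if atom is None:
                logger.warning(
                    "candidate residue %s (%s) lacks atom %s; skipped",
                    res.full_id, res.res_type, name,
                )
                return None
            rows.append(atom.coords)
    return np.asarray(rows)


def match_template(
    t: Template,
    target: Structure,
    query: Structure,
    rmsd_tol: float = 2.0,
    policy: SubstitutionPolicy = IDENTITY_POLICY,
    ca_prefilter_tol: float = 2.0,
) -> list[RawMatch]:
    """All residue triples of ``target`` matching template ``t`` within tolerance.

    Candidates are required to be type-compatible under ``policy`` slot by
    slot, to satisfy the CA–CA distance pre-filter, and to superpose onto
    the template's matching atoms with RMSD ≤ ``rmsd_tol``. The search is
    exhaustive over qualifying triples.
    """
    from .scoring import superpose

    if len(target.residues) < 3:
        raise ValueError("target needs at least 3 polymer residues")
    tmpl_coords = _template_coords(t, query)
    ca = target.ca_coords()
    types = t.residue_types
    cands = [
        [i for i, r in enumerate(target.residues) if policy.compatible(tt, r.res_type)]
        for tt in types
    ]
    if not all(cands):
        return []
    d01t, d02t, d12t = t.ca_dists
    camat = cdist(ca, ca)
    matches: list[RawMatch] = []
    for i0 in cands[0]:
        for i1 in cands[1]:
            if i1 == i0 or abs(camat[i0, i1] - d01t) > ca_prefilter_tol:
                continue
            for i2 in cands[2]:
                if i2 in (i0, i1):
                    continue
                if abs(camat[i0, i2] - d02t) > ca_prefilter_tol:
                    continue
                if abs(camat[i1, i2] - d12t) > ca_prefilter_tol:
                    continue
                trio = (target.residues[i0], target.residues[i1], target.residues[i2])
                cand_coords = _candidate_coords(t, trio)
                if cand_coords is None or len(cand_coords) != len(tmpl_coords):
                    continue
                rot, trans, rmsd = superpose(tmpl_coords, cand_coords)
                if rmsd <= rmsd_tol:
                    matches.append(
                        RawMatch(
                            template=t,
                            target_id=target.id,
                            matched_residues=tuple(r.full_id for r in trio),
                            template_rmsd=float(rmsd),
                            rotation=rot,
                            translation=trans,
                        )
                    )
    matches.sort(key=lambda m: (m.matched_residues, m.template_rmsd))
    return matches


def scan(
    query: Structure,
    library: list[Structure],
    max_pair_dist: float = 5.0,
    max_hydrophobic: int = 1,
    rmsd_tol: float = 2.0,
    policy: SubstitutionPolicy = IDENTITY_POLICY,
    ca_prefilter_tol: float = 2.0,
    templates: list[Template] | None = None,
) -> list[RawMatch]:
    """Scan every template of ``query`` against every library structure.

    Matches are deduplicated per (template, target) on the matched residue
    triple, keeping the lowest-RMSD match.
    """
    if not library:
        raise ValueError("library must be non-empty")
    if templates is None:
        templates = generate_templates(query, max_pair_dist, max_hydrophobic)
    out: list[RawMatch] = []
    for t in templates:
        for target in library:
            best: dict[tuple[ResidueId, ...], RawMatch] = {}
            for m in match_template(t, target, query, rmsd_tol, policy, ca_prefilter_tol):
                prev = best.get(m.matched_residues)
                if prev is None or m.template_rmsd < prev.template_rmsd:
                    best[m.matched_residues] = m
            out.extend(best[k] for k in sorted(best))
    return out
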