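"""Coordinate data model and PDB I/O.

The in-memory model is deliberately small: a :class:`Structure` is an ordered
list of polymer :class:`Residue` objects plus a list of non-water hetero
groups (ligands, metals, nucleic-acid residues read from HETATM records).
Author residue numbering is preserved verbatim, since functional-site
residues are conventionally reported in author numbering.

Parsing and writing of the fixed-column PDB format are delegated to gemmi;
this module adds the conventions the rest of the package relies on:

* only the first model of a multi-model file is read (template geometry
  needs a single conformer);
* alternate locations are collapsed to the highest-occupancy conformer,
  ties broken by altloc identifier order;
* waters are dropped; every other HETATM group is kept as a hetero group;
* SITE records, when present, are retained as lists of residue identifiers;
* hydrogens are ignored in all distance computations (heavy-atom
  conventions; most crystal structures lack hydrogens anyway).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "Atom",
    "Residue",
    "ResidueId",
    "Structure",
    "PDBParseError",
    "EmptyStructureError",
    "parse_pdb",
    "write_pdb",
    "min_atom_distance",
    "rigid_transform",
]

#: residue names treated as water and excluded from hetero groups
WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})

#: element symbols excluded from all distance computations
_HYDROGEN = frozenset({"H", "D"})


class PDBParseError(ValueError):
    """Raised for malformed PDB input; carries the offending line number."""


class EmptyStructureError(ValueError):
    """Raised when PDB input contains no ATOM/HETATM records."""


#: (chain_id, seq_id, insertion_code) — the unique residue key within a structure
ResidueId = tuple[str, int, str]


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coords: np.ndarray  # (3,) float64, Å
    occupancy: float = 1.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(f"atom {self.name!r}: coords must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name!r}: empty element symbol")
        object.__setattr__(self, "coords", coords)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in _HYDROGEN


@dataclass(frozen=True)
class Residue:
    chain_id: str
    seq_id: int
    res_type: str
    atoms: tuple[Atom, ...]
    insertion_code: str = ""
    is_polymer: bool = True

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"residue {self.full_id} has no atoms")
        object.__setattr__(self, "atoms", tuple(self.atoms))

    @property
    def full_id(self) -> ResidueId:
        return (self.chain_id, self.seq_id, self.insertion_code)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_coords(self) -> np.ndarray:
        """Coordinates of non-hydrogen atoms, shape (n, 3)."""
        pts = [a.coords for a in self.atoms if not a.is_hydrogen]
        if not pts:  # hydrogen-only residue: fall back to all atoms
            pts = [a.coords for a in self.atoms]
        return np.asarray(pts)

    @property
    def ca(self) -> Atom | None:
        return self.atom("CA")


@dataclass
class Structure:
    id: str
    residues: list[Residue] = field(default_factory=list)
    hetero_groups: list[Residue] = field(default_factory=list)
    title: str = ""
    site_records: dict[str, list[ResidueId]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.residues) + len(self.hetero_groups) < 1:
            raise ValueError("structure must contain at least one residue")
        seen: set[ResidueId] = set()
        for r in self.residues:
            if r.full_id in seen:
                raise ValueError(f"duplicate residue identifier {r.full_id}")
            seen.add(r.full_id)

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, rid: ResidueId) -> Residue:
        for r in self.residues:
            if r.full_id == rid:
                return r
        raise KeyError(rid)

    def ca_coords(self) -> np.ndarray:
        """CA coordinates of all polymer residues, shape (n, 3).

        Residues lacking a CA contribute their first heavy atom so the
        row index always matches the residue index.
        """
        rows = []
        for r in self.residues:
            ca = r.ca
            rows.append(ca.coords if ca is not None else r.heavy_coords()[0])
        return np.asarray(rows)

    def sequence(self) -> str:
        """One-letter amino-acid sequence ('X' for non-standard types)."""
        return "".join(THREE_TO_ONE.get(r.res_type, "X") for r in self.residues)


THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


# ---------------------------------------------------------------------------
# parsing

def _validate_coordinate_fields(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line[:6] not in ("ATOM  ", "HETATM"):
            continue
        for lo, hi in ((30, 38), (38, 46), (46, 54)):
            fieldtxt = line[lo:hi].strip()
            try:
                float(fieldtxt)
            except ValueError:
                raise PDBParseError(
                    f"line {lineno}: malformed coordinate field {fieldtxt!r}"
                ) from None


def _parse_site_records(text: str) -> dict[str, list[ResidueId]]:
    """SITE records: up to four (resname, chain, seqnum[icode]) per line."""
    sites: dict[str, list[ResidueId]] = {}
    for line in text.splitlines():
        if not line.startswith("SITE"):
            continue
        name = line[11:14].strip()
        entries = sites.setdefault(name, [])
        for base in (18, 29, 40, 51):
            resname = line[base : base + 3].strip()
            chain = line[base + 4 : base + 5].strip()
            seqtxt = line[base + 5 : base + 9].strip()
            icode = line[base + 9 : base + 10].strip()
            if not resname or not seqtxt:
                continue
            entries.append((chain, int(seqtxt), icode))
    return sites


def _collapse_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """One atom per atom name: highest occupancy, ties by altloc order."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
        elif (atom.occ, _altloc_rank(prev)) > (prev.occ, _altloc_rank(atom)):
            by_name[atom.name] = atom
    return list(by_name.values())


def _altloc_rank(atom: gemmi.Atom) -> int:
    # smaller altloc char wins a tie; '\0' (no altloc) wins over any letter
    return -ord(atom.altloc) if atom.altloc != "\0" else 0


def parse_pdb(text: str, structure_id: str = "") -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    ATOM records become polymer residues; non-water HETATM records become
    hetero groups. Only the first model is read.
    """
    if not any(line[:6] in ("ATOM  ", "HETATM") for line in text.splitlines()):
        raise EmptyStructureError("input contains no ATOM or HETATM records")
    _validate_coordinate_fields(text)
    st = gemmi.read_pdb_string(text)
    model = st[0]
    residues: list[Residue] = []
    hetero: list[Residue] = []
    for chain in model:
        for gres in chain:
            if gres.is_water() or gres.name in WATER_NAMES:
                continue
            atoms = tuple(
                Atom(
                    name=a.name,
                    element=a.element.name or "X",
                    coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    occupancy=a.occ,
                    is_hetero=gres.het_flag == "H",
                )
                for a in _collapse_altlocs(gres)
            )
            res = Residue(
                chain_id=chain.name,
                seq_id=gres.seqid.num,
                insertion_code=(gres.seqid.icode or "").strip(),
                res_type=gres.name,
                atoms=atoms,
                is_polymer=gres.het_flag != "H",
            )
            (hetero if gres.het_flag == "H" else residues).append(res)
    return Structure(
        id=structure_id or st.name or "",
        residues=residues,
        hetero_groups=hetero,
        title=" ".join(
            ln[10:].strip() for ln in text.splitlines() if ln.startswith("TITLE")
        ),
        site_records=_parse_site_records(text),
    )


# ---------------------------------------------------------------------------
# writing

def write_pdb(s: Structure) -> str:
    """Render a Structure as PDB-format text (3-decimal coordinates)."""
    st = gemmi.Structure()
    st.name = s.id
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for res in list(s.residues) + list(s.hetero_groups):
        chain = chains.get(res.chain_id)
        if chain is None:
            chain = gemmi.Chain(res.chain_id or "A")
            chains[res.chain_id] = chain
        gres = gemmi.Residue()
        gres.name = res.res_type
        gres.seqid = gemmi.SeqId(res.seq_id, res.insertion_code or " ")
        gres.het_flag = "H" if not res.is_polymer else "A"
        for a in res.atoms:
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element)
            ga.pos = gemmi.Position(*a.coords)
            ga.occ = a.occupancy
            gres.add_atom(ga)
        chain.add_residue(gres)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    lines = [ln for ln in st.make_pdb_string().splitlines() if ln[:6] in
             ("ATOM  ", "HETATM", "TER   ", "END   ", "END")]
    site_lines = _format_site_records(s)
    return "\n".join(site_lines + lines) + "\n"


def _format_site_records(s: Structure) -> list[str]:
    lines = []
    lookup = {r.full_id: r.res_type for r in list(s.residues) + list(s.hetero_groups)}
    for name, rids in s.site_records.items():
        for block_no, i in enumerate(range(0, len(rids), 4), start=1):
            chunk = rids[i : i + 4]
            line = f"SITE   {block_no:3d} {name:>3s} {len(rids):2d} "
            for chain, seq, icode in chunk:
                resname = lookup.get((chain, seq, icode), "UNK")
                line += f"{resname:>3s} {chain:1s}{seq:4d}{icode or ' ':1s} "
            lines.append(line.rstrip())
    return lines


# ---------------------------------------------------------------------------
# geometry primitives

def min_atom_distance(r1: Residue, r2: Residue) -> float:
    """Closest heavy-atom distance (Å) between two residues. Symmetric."""
    return float(cdist(r1.heavy_coords(), r2.heavy_coords()).min())


def residue_min_distance_matrix(residues: list[Residue]) -> np.ndarray:
    """Pairwise closest heavy-atom distances for a residue list, shape (n, n).

    Vectorised equivalent of calling :func:`min_atom_distance` on every pair.
    """
    coords = [r.heavy_coords() for r in residues]
    offsets = np.cumsum([0] + [len(c) for c in coords])
    d = cdist(np.vstack(coords), np.vstack(coords))
    n = len(residues)
    out = np.empty((n, n))
    for i in range(n):
        si = slice(offsets[i], offsets[i + 1])
        for j in range(i, n):
            sj = slice(offsets[j], offsets[j + 1])
            out[i, j] = out[j, i] = d[si, sj].min()
    return out


def rigid_transform(s: Structure, rotation: np.ndarray, translation: np.ndarray) -> Structure:
    """Apply ``x -> R x + t`` to every atom; the transform must be a proper rotation."""
    rotation = np.asarray(rotation, dtype=float)
    translation = np.asarray(translation, dtype=float)
    if rotation.shape != (3, 3) or translation.shape != (3,):
        raise ValueError("rotation must be 3x3 and translation a 3-vector")
    if not np.allclose(rotation @ rotation.T, np.eye(3), atol=1e-6) or not math.isclose(
        float(np.linalg.det(rotation)), 1.0, abs_tol=1e-6
    ):
        raise ValueError("rotation must be orthonormal with det = +1")

    def move(res: Residue) -> Residue:
        atoms = tuple(
            replace(a, coords=rotation @ a.coords + translation) for a in res.atoms
        )
        return replace(res, atoms=atoms)

    return Structure(
        id=s.id,
        residues=[move(r) for r in s.residues],
        hetero_groups=[move(r) for r in s.hetero_groups],
        title=s.title,
        site_records=dict(s.site_records),
    )
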