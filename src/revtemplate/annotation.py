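"""Residue-level functional annotation and hit-overlap analysis.

Covers four concerns:

1. Deriving residue-level functional annotations of a structure — PROSITE
   pattern residues, catalytic residues, SITE-record residues, and residues
   in contact with ligands, metals or nucleic acids.
2. Asking whether a template hit lands on annotated residues, and binning
   the outcome by E-value (the annotated / none-annotated / no-annotation
   histogram over confidence classes).
3. Annotation-transfer filter rules (sequence identity ≥ 30%, alignment
   overlap ≥ 80 residues, E < 0.001) and annotation depth rules (EC level
   3–4; GO molecular-function terms at DAG level ≥ 6), plus GO-slim
   mapping.
4. A deterministic "auto-status" classifier encoding the
   known / putative / possible / unknown rules. The published status calls
   were manual; this classifier applies the stated rules mechanically and
   its output should be read as an approximation of curation.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .scoring import TemplateHit, classify_confidence
from .structure import ResidueId, Structure

__all__ = [
    "FunctionalAnnotation",
    "AnnotationRecord",
    "InheritedHit",
    "OntologyGraph",
    "PrositePatternError",
    "match_prosite",
    "contact_residues",
    "hit_annotation_category",
    "select_top_hits",
    "evalue_histogram",
    "transfer_filter",
    "is_deep",
    "map_to_slim",
    "assign_status",
    "STATUS_ORDER",
    "WEAK_GO_TERMS",
]

ANNOTATION_SOURCES = (
    "prosite", "catalytic", "site_record", "ligand_contact",
    "metal_contact", "nucleic_contact",
)

STATUS_ORDER = ("unknown", "possible", "putative", "known")

#: terms too generic to confer 'known' status on their own
WEAK_GO_TERMS = frozenset({"GO:0005506"})

_METALS = frozenset({
    "LI", "NA", "K", "RB", "CS", "MG", "CA", "SR", "BA", "MN", "FE", "CO",
    "NI", "CU", "ZN", "CD", "HG", "MO", "W", "V", "AL",
})
_NUCLEOTIDES = frozenset({"A", "C", "G", "U", "I", "DA", "DC", "DG", "DT", "DU", "DI"})


@dataclass(frozen=True)
class FunctionalAnnotation:
    target_id: str
    residue_ids: frozenset[ResidueId]
    source: str

    def __post_init__(self) -> None:
        if self.source not in ANNOTATION_SOURCES:
            raise ValueError(f"unknown annotation source {self.source!r}")
        if not self.residue_ids:
            raise ValueError("annotation must cover at least one residue")
        object.__setattr__(self, "residue_ids", frozenset(self.residue_ids))


@dataclass(frozen=True)
class AnnotationRecord:
    protein_id: str
    kind: str  # EC | GO_molecular_function | family
    term: str
    depth: int = 0
    evidence: str = "electronic"  # experimental | author | electronic
    family_is_duf: bool = False
    family_specific_function: bool = False


@dataclass(frozen=True)
class InheritedHit:
    subject_id: str
    identity_pct: float
    overlap_len: int
    e_value: float
    annotations: tuple[AnnotationRecord, ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.identity_pct <= 100:
            raise ValueError("identity_pct out of range")
        if self.overlap_len < 0:
            raise ValueError("overlap_len must be non-negative")


# ---------------------------------------------------------------------------
# PROSITE pattern matching

class PrositePatternError(ValueError):
    """Malformed PROSITE pattern; message carries the element position."""


_ELEMENT_RE = re.compile(
    r"(?P<anchor_start><)|(?P<anchor_end>>)|"
    r"(?P<set>\[[A-Z]+\])|(?P<negset>\{[A-Z]+\})|(?P<res>[A-Zx])"
)
_REPEAT_RE = re.compile(r"\((?P<lo>\d+)(?:,(?P<hi>\d+))?\)")


def _parse_prosite(pattern: str) -> tuple[bool, bool, list[tuple[frozenset[str] | None, bool, int, int]]]:
    """Parse into (anchored_start, anchored_end, elements).

    Each element is (allowed_set or None for 'x', negated, min_repeat,
    max_repeat).
    """
    pattern = pattern.rstrip(".")
    anchored_start = anchored_end = False
    elements: list[tuple[frozenset[str] | None, bool, int, int]] = []
    tokens = pattern.split("-")
    for pos, raw in enumerate(tokens):
        token = raw.strip()
        if not token:
            raise PrositePatternError(f"empty element at position {pos}")
        # anchors may be fused to the first/last element: "<M-A", "A-B>"
        if pos == 0 and token.startswith("<") and len(token) > 1:
            anchored_start = True
            token = token[1:]
        if pos == len(tokens) - 1 and token.endswith(">") and len(token) > 1:
            anchored_end = True
            token = token[:-1]
        m = _ELEMENT_RE.match(token)
        if m is None:
            raise PrositePatternError(f"bad element {token!r} at position {pos}")
        rest = token[m.end():]
        lo = hi = 1
        if rest:
            rm = _REPEAT_RE.fullmatch(rest)
            if rm is None:
                raise PrositePatternError(f"bad repeat {rest!r} at position {pos}")
            lo = int(rm.group("lo"))
            hi = int(rm.group("hi")) if rm.group("hi") else lo
            if hi < lo:
                raise PrositePatternError(f"repeat range inverted at position {pos}")
        if m.group("anchor_start"):
            if pos != 0 or rest:
                raise PrositePatternError("'<' only allowed as the first element")
            anchored_start = True
        elif m.group("anchor_end"):
            anchored_end = True
        elif m.group("set"):
            elements.append((frozenset(m.group("set")[1:-1]), False, lo, hi))
        elif m.group("negset"):
            elements.append((frozenset(m.group("negset")[1:-1]), True, lo, hi))
        else:
            res = m.group("res")
            elements.append((None if res == "x" else frozenset(res), False, lo, hi))
    return anchored_start, anchored_end, elements


def _match_here(seq: str, start: int, elements, anchored_end: bool) -> int | None:
    """Backtracking match of elements at ``start``; returns end or None."""

    def step(i: int, el_idx: int) -> int | None:
        if el_idx == len(elements):
            if anchored_end and i != len(seq):
                return None
            return i
        allowed, negated, lo, hi = elements[el_idx]

        def ok(ch: str) -> bool:
            if allowed is None:
                return True
            return (ch not in allowed) if negated else (ch in allowed)

        # greedy with backtracking over the repeat count
        max_take = 0
        while max_take < hi and i + max_take < len(seq) and ok(seq[i + max_take]):
            max_take += 1
        for take in range(max_take, lo - 1, -1):
            res = step(i + take, el_idx + 1)
            if res is not None:
                return res
        return None

    return step(start, 0)


def match_prosite(sequence: str, pattern: str) -> list[tuple[int, int]]:
    """Leftmost non-overlapping matches of a PROSITE pattern.

    Returns half-open 0-based ``(start, end)`` spans in order.
    """
    anchored_start, anchored_end, elements = _parse_prosite(pattern)
    spans: list[tuple[int, int]] = []
    pos = 0
    while pos <= len(sequence):
        end = _match_here(sequence, pos, elements, anchored_end)
        if end is not None:
            spans.append((pos, end))
            pos = max(end, pos + 1)
        else:
            pos += 1
        if anchored_start:
            break
    return spans


# ---------------------------------------------------------------------------
# contact annotations

def _group_kind(res) -> str:
    if res.res_type in _NUCLEOTIDES:
        return "nucleic"
    if len(res.atoms) == 1 and res.atoms[0].element.upper() in _METALS:
        return "metal"
    return "ligand"


def contact_residues(
    s: Structure, group_kind: str, cutoff: float = 4.0
) -> list[FunctionalAnnotation]:
    """Polymer residues with any heavy atom within ``cutoff`` of a group atom.

    One annotation per hetero group of the requested kind (``ligand``,
    ``metal`` or ``nucleic``); no groups of that kind gives an empty list.
    """
    if group_kind not in ("ligand", "metal", "nucleic"):
        raise ValueError(f"unknown group kind {group_kind!r}")
    source = f"{group_kind}_contact"
    out: list[FunctionalAnnotation] = []
    groups = [g for g in s.hetero_groups if _group_kind(g) == group_kind]
    if group_kind == "nucleic":  # nucleic chains may be polymer records too
        groups += [r for r in s.residues if r.res_type in _NUCLEOTIDES]
    amino = [r for r in s.residues if r.res_type not in _NUCLEOTIDES]
    for g in groups:
        gpts = g.heavy_coords()
        rids = {
            r.full_id
            for r in amino
            if cdist(r.heavy_coords(), gpts).min() <= cutoff
        }
        if rids:
            out.append(FunctionalAnnotation(s.id, frozenset(rids), source))
    return out


# ---------------------------------------------------------------------------
# hit / annotation overlap (the E-value histogram logic)

def hit_annotation_category(
    hit: TemplateHit,
    annots: list[FunctionalAnnotation],
    sas_backfill: list[FunctionalAnnotation] = (),
) -> str:
    """'annotated', 'none_annotated' or 'no_annotation' for one hit.

    Backfilled annotations (imported from close sequence relatives of the
    matched structure) count the same as primary ones.
    """
    target = hit.raw_match.target_id
    relevant = [a for a in list(annots) + list(sas_backfill) if a.target_id == target]
    if not relevant:
        return "no_annotation"
    matched = set(hit.raw_match.matched_residues)
    for a in relevant:
        if matched & a.residue_ids:
            return "annotated"
    return "none_annotated"


def select_top_hits(hits: list[TemplateHit], top_k: int = 4) -> list[TemplateHit]:
    """Per query structure, the ``top_k`` lowest-E hits (rank ties by RMSD)."""
    by_query: dict[str, list[TemplateHit]] = {}
    for h in hits:
        by_query.setdefault(h.raw_match.template.source_id, []).append(h)
    out: list[TemplateHit] = []
    for q in sorted(by_query):
        ranked = sorted(
            by_query[q], key=lambda h: (h.e_value, h.raw_match.template_rmsd)
        )
        out.extend(ranked[:top_k])
    return out


def evalue_histogram(
    categorized: list[tuple[TemplateHit, str]],
) -> pd.DataFrame:
    """Counts of hit categories per log10-E-value bin.

    Input is ``(hit, category)`` pairs (categories from
    :func:`hit_annotation_category`); the caller applies top-k selection
    first. Rows are integer log10 bins (bin b holds 10^b ≤ E < 10^(b+1));
    columns ``annotated``, ``none_annotated``, ``no_annotation``,
    ``total``, ``confidence`` (class at the bin's lower edge).
    """
    counts: dict[int, Counter] = {}
    for hit, cat in categorized:
        b = math.floor(math.log10(hit.e_value))
        counts.setdefault(b, Counter())[cat] += 1
    rows = []
    for b in sorted(counts):
        c = counts[b]
        rows.append(
            {
                "log10_bin": b,
                "annotated": c.get("annotated", 0),
                "none_annotated": c.get("none_annotated", 0),
                "no_annotation": c.get("no_annotation", 0),
                "total": sum(c.values()),
                "confidence": classify_confidence(float(10.0 ** b) or 1e-99),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["log10_bin", "annotated", "none_annotated", "no_annotation",
                 "total", "confidence"],
    )


# ---------------------------------------------------------------------------
# transfer filter and depth rules

def transfer_filter(
    hits: list[InheritedHit],
    min_identity: float = 30.0,
    min_overlap: int = 80,
    max_e: float = 0.001,
) -> list[InheritedHit]:
    """Alignment-based annotation transfer: identity ≥ 30%, overlap ≥ 80, E < 0.001."""
    return [
        h
        for h in hits
        if h.identity_pct >= min_identity
        and h.overlap_len >= min_overlap
        and h.e_value < max_e
    ]


@dataclass
class OntologyGraph:
    """'is a' DAG of ontology terms (edges point child -> parent)."""

    graph: nx.DiGraph

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("ontology must be acyclic")

    @classmethod
    def from_edges(cls, edges: list[tuple[str, str]]) -> "OntologyGraph":
        g = nx.DiGraph()
        for child, parent in edges:
            g.add_edge(child, parent)
        return cls(g)

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def roots(self) -> set[str]:
        return {n for n in self.graph.nodes if self.graph.out_degree(n) == 0}

    def level(self, term: str, use_min: bool = False) -> int:
        """Path length from a root to ``term`` (max-depth by default)."""
        if term not in self.graph:
            raise KeyError(f"unknown ontology term {term!r}")
        agg = min if use_min else max
        depth = 0 if self.graph.out_degree(term) == 0 else None
        # longest (or shortest) path to any root, upward DP
        memo: dict[str, int] = {}

        def up(t: str) -> int:
            if t in memo:
                return memo[t]
            parents = list(self.graph.successors(t))
            memo[t] = 0 if not parents else 1 + agg(up(p) for p in parents)
            return memo[t]

        return up(term) if depth is None else 0

    def ancestors(self, term: str) -> set[str]:
        if term not in self.graph:
            raise KeyError(f"unknown ontology term {term!r}")
        return nx.descendants(self.graph, term)  # edges point upward


def ec_specified_levels(term: str) -> int:
    """Number of specified levels of an EC number (trailing dashes excluded)."""
    parts = term.split(".")
    n = 0
    for p in parts:
        if p in ("-", ""):
            break
        n += 1
    return n


def is_deep(record: AnnotationRecord, ontology: OntologyGraph | None = None,
            go_min_level: int = 6, use_min_depth: bool = False) -> bool:
    """Deep annotation rule: EC specified to level 3 or 4, or GO level ≥ 6."""
    if record.kind == "EC":
        return ec_specified_levels(record.term) in (3, 4)
    if record.kind == "GO_molecular_function":
        if ontology is not None:
            return ontology.level(record.term, use_min=use_min_depth) >= go_min_level
        return record.depth >= go_min_level
    return False


def map_to_slim(
    ontology: OntologyGraph, terms: set[str], slim: set[str]
) -> tuple[dict[str, set[str]], Counter]:
    """Map terms to their nearest slim ancestors.

    A term maps to itself if it is a slim member; otherwise to the set of
    slim terms reachable upward with no closer slim term on the path.
    Returns (per-term slim sets, per-slim-term counts over the input).
    """
    unknown_slim = slim - ontology.terms
    if unknown_slim:
        raise ValueError(f"slim terms not in ontology: {sorted(unknown_slim)}")

    @lru_cache(maxsize=None)
    def nearest(term: str) -> frozenset[str]:
        if term in slim:
            return frozenset({term})
        out: set[str] = set()
        for parent in ontology.graph.successors(term):
            out |= nearest(parent)
        return frozenset(out)

    mapping: dict[str, set[str]] = {}
    counts: Counter = Counter()
    for term in sorted(terms):
        if term not in ontology.terms:
            raise KeyError(f"unknown ontology term {term!r}")
        mapping[term] = set(nearest(term))
        counts.update(mapping[term])
    return mapping, counts


# ---------------------------------------------------------------------------
# status rules

def assign_status(
    deep_db: list[AnnotationRecord],
    families: list[AnnotationRecord],
    inherited: list[InheritedHit],
    ontology: OntologyGraph | None = None,
    weak_terms: frozenset[str] = WEAK_GO_TERMS,
) -> str:
    """Auto-status: known / putative / possible / unknown.

    * known    — at least one deep database annotation (weak generic terms
      excluded); family agreement is corroborating but not required.
    * putative — no deep record, but a non-DUF family whose description
      carries a specific molecular function.
    * possible — only inherited annotations that pass the transfer filter.
    * unknown  — nothing above applies.
    """
    deep = [
        r for r in deep_db
        if r.term not in weak_terms and is_deep(r, ontology)
    ]
    if deep:
        return "known"
    informative_families = [
        f for f in families if not f.family_is_duf and f.family_specific_function
    ]
    if informative_families:
        return "putative"
    accepted = transfer_filter(inherited)
    if any(h.annotations for h in accepted):
        return "possible"
    return "unknown"
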