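"""Structural and functional novelty statistics.

Structural novelty: two domains are structurally aligned and superposed,
and the RMSD is length-normalized as

    normRMSD = RMSD * max(L1, L2) / Nmat

where L1, L2 are the domain lengths and Nmat the number of aligned residue
pairs. Short alignments between long domains are thereby penalized. A
domain whose normRMSD to every previously released domain is at least 5 Å
is structurally novel and founds a new structural sub-group (SSG).

The pairwise aligner here is a deliberately simple iterative-superposition
method (seeded by the best-matching 7-residue CA windows, refined by
order-preserving closest-pair assignment); its contract is the
:class:`AlignmentResult`, so a more sophisticated aligner can be swapped in.

Functional novelty: release records (entry, date, annotation-term set,
producing centre) are scanned for the earliest structure carrying each
annotation term, and per-centre "% first" novelty rates are computed, both
per release and per non-redundant structure.

Modelling leverage: entries are processed in release order and credited
with the sequence positions their alignment-coverage intervals cover that
no earlier entry covered. Variant modellability is interval membership of
variant positions.
"""

from __future__ import annotations

import datetime as dt
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .scoring import superpose
from .structure import Structure

__all__ = [
    "AlignmentResult",
    "ReleaseRecord",
    "CoverageInterval",
    "PSI1_PSI2_BOUNDARY",
    "norm_rmsd",
    "simple_align",
    "classify_ssg",
    "cumulative_novelty",
    "first_structures",
    "novelty_percent",
    "novelty_table",
    "coverage_percent",
    "pathway_coverage",
    "novel_leverage",
    "modellable_variants",
]

#: end of the first programme period (structures released before this date)
PSI1_PSI2_BOUNDARY = dt.date(2005, 7, 1)


@dataclass(frozen=True)
class AlignmentResult:
    len_a: int
    len_b: int
    n_matched: int
    rmsd: float
    correspondence: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.n_matched > min(self.len_a, self.len_b):
            raise ValueError("n_matched exceeds the shorter length")
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")

    @property
    def norm_rmsd(self) -> float:
        """normRMSD of this alignment; infinite for an empty alignment."""
        if self.n_matched == 0:
            return float("inf")
        return norm_rmsd(self.rmsd, self.len_a, self.len_b, self.n_matched)


def norm_rmsd(rmsd: float, len_a: int, len_b: int, n_matched: int) -> float:
    """``rmsd * max(len_a, len_b) / n_matched`` (Å)."""
    if n_matched < 1:
        raise ValueError("n_matched must be at least 1")
    if min(len_a, len_b) < n_matched:
        raise ValueError("lengths must be at least n_matched")
    return rmsd * max(len_a, len_b) / n_matched


# ---------------------------------------------------------------------------
# simple iterative structural aligner

def _seed_correspondence(ca_a: np.ndarray, ca_b: np.ndarray, window: int = 7
                         ) -> list[tuple[int, int]] | None:
    """Best-superposing pair of CA windows as the initial correspondence."""
    la, lb = len(ca_a), len(ca_b)
    if la < window or lb < window:
        window = min(la, lb)
    stride = 1 if max(la, lb) <= 60 else 2
    best = None
    for i in range(0, la - window + 1, stride):
        wa = ca_a[i : i + window]
        for j in range(0, lb - window + 1, stride):
            _, _, rmsd = superpose(wa, ca_b[j : j + window])
            if best is None or rmsd < best[0]:
                best = (rmsd, i, j)
    if best is None:
        return None
    _, i, j = best
    return [(i + k, j + k) for k in range(window)]


def _order_preserving_pairs(d: np.ndarray, dist_cut: float) -> list[tuple[int, int]]:
    """Max-cardinality order-preserving matching with distances ≤ dist_cut.

    Dynamic programme over the distance matrix; ties in cardinality are
    broken towards the smaller total distance.
    """
    la, lb = d.shape
    # dp[i][j]: best (count, -sumdist) for prefixes a[:i], b[:j]
    dp = [[(0, 0.0)] * (lb + 1) for _ in range(la + 1)]
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            best = dp[i - 1][j] if dp[i - 1][j] >= dp[i][j - 1] else dp[i][j - 1]
            if d[i - 1, j - 1] <= dist_cut:
                cnt, nsd = dp[i - 1][j - 1]
                cand = (cnt + 1, nsd - float(d[i - 1, j - 1]))
                if cand > best:
                    best = cand
            dp[i][j] = best
    # traceback
    pairs: list[tuple[int, int]] = []
    i, j = la, lb
    while i > 0 and j > 0:
        if (
            d[i - 1, j - 1] <= dist_cut
            and dp[i][j][0] == dp[i - 1][j - 1][0] + 1
            and abs(dp[i][j][1] - (dp[i - 1][j - 1][1] - float(d[i - 1, j - 1]))) < 1e-12
        ):
            pairs.append((i - 1, j - 1))
            i -= 1
            j -= 1
        elif dp[i - 1][j] >= dp[i][j - 1]:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return pairs


def simple_align(
    a: Structure, b: Structure, max_iter: int = 20, dist_cut: float = 6.0
) -> AlignmentResult:
    """Iterative closest-CA structural alignment of two structures.

    Seeds from the best 7-residue window superposition, then alternates
    superposing on the current correspondence and recomputing the optimal
    order-preserving closest-pair correspondence at ``dist_cut``, until the
    correspondence is stable or ``max_iter`` is reached.
    """
    if len(a) < 5 or len(b) < 5:
        raise ValueError("alignment needs at least 5 residues per structure")
    ca_a, ca_b = a.ca_coords(), b.ca_coords()
    corr = _seed_correspondence(ca_a, ca_b)
    if not corr:
        return AlignmentResult(len(a), len(b), 0, 0.0)
    for _ in range(max_iter):
        ia = [p[0] for p in corr]
        ib = [p[1] for p in corr]
        rot, trans, _ = superpose(ca_a[ia], ca_b[ib])
        moved = ca_a @ rot.T + trans
        from scipy.spatial.distance import cdist

        new_corr = _order_preserving_pairs(cdist(moved, ca_b), dist_cut)
        if not new_corr:
            return AlignmentResult(len(a), len(b), 0, 0.0)
        if new_corr == corr:
            break
        corr = new_corr
    ia = [p[0] for p in corr]
    ib = [p[1] for p in corr]
    _, _, rmsd = superpose(ca_a[ia], ca_b[ib])
    return AlignmentResult(
        len_a=len(a), len_b=len(b), n_matched=len(corr), rmsd=float(rmsd),
        correspondence=tuple(corr),
    )


def classify_ssg(
    query_alignments: list[AlignmentResult], threshold: float = 5.0
) -> str:
    """'new_ssg' iff every alignment against the prior library has normRMSD ≥ threshold."""
    if not query_alignments:
        raise ValueError("library of prior alignments must be non-empty")
    best = min(al.norm_rmsd for al in query_alignments)
    return "new_ssg" if best >= threshold else "known_ssg"


def cumulative_novelty(level_counts: list[tuple[str, int]]) -> list[tuple[str, int, int]]:
    """Cumulative novel-domain totals down the classification hierarchy.

    Every domain novel at one level (e.g. fold) is also novel at all finer
    levels (superfamily, SSG), so counts accumulate downward. Returns
    (level, count, cumulative).
    """
    out = []
    running = 0
    for level, count in level_counts:
        running += count
        out.append((level, count, running))
    return out


# ---------------------------------------------------------------------------
# functional novelty (first structures)

@dataclass(frozen=True)
class ReleaseRecord:
    entry_id: str
    release_date: dt.date
    terms: frozenset[str] = frozenset()
    source_center: str = "non-PSI"
    nr_representative: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", frozenset(self.terms))


def first_structures(
    records: list[ReleaseRecord],
) -> dict[str, ReleaseRecord]:
    """Earliest release per annotation term; date ties broken by entry id."""
    firsts: dict[str, ReleaseRecord] = {}
    for rec in records:
        for term in rec.terms:
            prev = firsts.get(term)
            if prev is None or (rec.release_date, rec.entry_id) < (
                prev.release_date, prev.entry_id
            ):
                firsts[term] = rec
    return firsts


def _round_half_up(value: float, digits: int) -> float:
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def novelty_percent(n_first: int, n_total: int) -> float:
    """% of releases that were first structures, round-half-up to 2 decimals."""
    if n_total < 1:
        raise ValueError("n_total must be at least 1")
    if n_first > n_total:
        raise ValueError("n_first cannot exceed n_total")
    return _round_half_up(100.0 * n_first / n_total, 2)


def _in_period(date: dt.date, period: str, boundary: dt.date) -> bool:
    if period == "all":
        return True
    if period == "psi1":
        return date < boundary
    if period == "psi2":
        return date >= boundary
    raise ValueError(f"unknown period {period!r}")


def novelty_table(
    records: list[ReleaseRecord],
    period: str = "all",
    boundary: dt.date = PSI1_PSI2_BOUNDARY,
) -> pd.DataFrame:
    """Per-centre first-structure novelty statistics for a programme period.

    Columns: source, first_structures, structures_total, structures_nr,
    pct_first_total, pct_first_nr. A term's first structure is credited to
    the centre that released it, within the requested period.
    """
    firsts = first_structures(records)
    in_period = [r for r in records if _in_period(r.release_date, period, boundary)]
    sources = sorted({r.source_center for r in records})
    # a structure first for several terms is one first structure
    first_entries: dict[str, set[str]] = {s: set() for s in sources}
    for rec in firsts.values():
        if _in_period(rec.release_date, period, boundary):
            first_entries[rec.source_center].add(rec.entry_id)
    first_counts = {s: len(v) for s, v in first_entries.items()}
    rows = []
    for s in sources:
        mine = [r for r in in_period if r.source_center == s]
        total = len(mine)
        nr = sum(r.nr_representative for r in mine)
        if total == 0:
            continue
        rows.append(
            {
                "source": s,
                "first_structures": first_counts[s],
                "structures_total": total,
                "structures_nr": nr,
                "pct_first_total": novelty_percent(first_counts[s], total),
                "pct_first_nr": novelty_percent(first_counts[s], nr) if nr else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def coverage_percent(n_covered: int, n_total: int, digits: int = 0) -> float:
    """``100 * n_covered / n_total`` rounded half-up to ``digits`` places."""
    if n_total < 1:
        raise ValueError("n_total must be at least 1")
    return _round_half_up(100.0 * n_covered / n_total, digits)


def pathway_coverage(
    ortholog_pathways: dict[str, set[str]], solved: set[str]
) -> tuple[pd.DataFrame, int]:
    """Structural coverage per pathway, plus the multi-pathway ortholog count.

    Returns a frame (pathway, n_orthologs, n_solved, complete) and the
    number of orthologs belonging to more than one pathway (each ortholog
    counted once).
    """
    pathways: dict[str, set[str]] = {}
    for orth, pws in ortholog_pathways.items():
        for pw in pws:
            pathways.setdefault(pw, set()).add(orth)
    rows = []
    for pw in sorted(pathways):
        members = pathways[pw]
        n_solved = len(members & solved)
        rows.append(
            {
                "pathway": pw,
                "n_orthologs": len(members),
                "n_solved": n_solved,
                "complete": n_solved == len(members),
            }
        )
    multi = sum(1 for pws in ortholog_pathways.values() if len(pws) > 1)
    return pd.DataFrame(rows), multi


# ---------------------------------------------------------------------------
# novel modelling leverage

@dataclass(frozen=True)
class CoverageInterval:
    sequence_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    provider_entry: str
    provider_date: dt.date = dt.date(2000, 1, 1)

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid interval {self.start}-{self.end} on {self.sequence_id}"
            )


class _DisjointIntervals:
    """Sorted disjoint 1-based inclusive intervals with incremental union."""

    def __init__(self) -> None:
        self.starts: list[int] = []
        self.ends: list[int] = []

    def add(self, start: int, end: int) -> int:
        """Insert [start, end]; returns the number of newly covered positions."""
        i = bisect_left(self.ends, start - 1)  # first interval that may touch
        j = bisect_right(self.starts, end + 1)  # one past last that may touch
        merged_start, merged_end = start, end
        covered = 0
        for k in range(i, j):
            merged_start = min(merged_start, self.starts[k])
            merged_end = max(merged_end, self.ends[k])
            covered += self.ends[k] - self.starts[k] + 1
        new_len = merged_end - merged_start + 1
        novel = new_len - covered
        del self.starts[i:j]
        del self.ends[i:j]
        self.starts.insert(i, merged_start)
        self.ends.insert(i, merged_end)
        return novel

    def covers(self, pos: int) -> bool:
        i = bisect_right(self.starts, pos) - 1
        return i >= 0 and self.ends[i] >= pos

    def total(self) -> int:
        return sum(e - s + 1 for s, e in zip(self.starts, self.ends))


def novel_leverage(intervals: list[CoverageInterval]) -> dict[str, int]:
    """Per-entry counts of newly covered (sequence, position) pairs.

    Entries are processed in release order (ties by entry id); each entry's
    novel leverage is the number of positions it covers that no earlier
    entry covered. Interval unions are exact.
    """
    by_entry: dict[str, list[CoverageInterval]] = {}
    order: dict[str, dt.date] = {}
    for iv in intervals:
        by_entry.setdefault(iv.provider_entry, []).append(iv)
        prev = order.get(iv.provider_entry)
        order[iv.provider_entry] = iv.provider_date if prev is None else min(prev, iv.provider_date)
    covered: dict[str, _DisjointIntervals] = {}
    out: dict[str, int] = {}
    for entry in sorted(order, key=lambda e: (order[e], e)):
        novel = 0
        for iv in sorted(by_entry[entry], key=lambda v: (v.sequence_id, v.start, v.end)):
            tree = covered.setdefault(iv.sequence_id, _DisjointIntervals())
            novel += tree.add(iv.start, iv.end)
        out[entry] = novel
    return out


def modellable_variants(
    variants: list[tuple[str, int]] | list[tuple[str, int, str]],
    modellable: list[CoverageInterval],
) -> tuple[int, list[bool]]:
    """Which variants fall inside a modellable region of their sequence.

    Variants are de-duplicated on their full tuple (sequence, position and
    any allele field) first; flags are returned for the de-duplicated list
    in first-seen order, along with the modellable count.
    """
    seen: set = set()
    unique: list = []
    for v in variants:
        if v not in seen:
            seen.add(v)
            unique.append(v)
    trees: dict[str, _DisjointIntervals] = {}
    for iv in modellable:
        trees.setdefault(iv.sequence_id, _DisjointIntervals()).add(iv.start, iv.end)
    flags = []
    for v in unique:
        seq, pos = v[0], v[1]
        tree = trees.get(seq)
        flags.append(bool(tree and tree.covers(pos)))
    return sum(flags), flags
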