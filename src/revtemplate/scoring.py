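"""Superposition, local-similarity scoring, E-values and confidence classes.

A raw template match only says that three residues superpose well. What
makes a hit credible is the local similarity of the surrounding region
once the two structures are superposed on the matched residues: conserved
identical and similar residues in equivalent 3-D positions around the
template. This module scores that region, converts scores to expectation
values against an empirical decoy-score distribution, and maps E-values to
the four confidence classes:

* certain   — E < 1e-6
* probable  — 1e-6 ≤ E < 1e-2
* possible  — 1e-2 ≤ E < 1e-1
* long_shot — 1e-1 ≤ E < 10
* none      — E ≥ 10

The score model (weighted identical/similar counts) and the
exponential-tail decoy calibration are this package's own self-consistent
formulation; the class boundaries above are honored exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .structure import Structure
from .templates import IDENTITY_POLICY, RawMatch, SubstitutionPolicy

__all__ = [
    "SimilarityScore",
    "TemplateHit",
    "EvalueCalibration",
    "CONFIDENCE_CLASSES",
    "superpose",
    "local_similarity",
    "calibrate",
    "evalue",
    "classify_confidence",
    "score_matches",
]

#: ordered best-to-worst; "none" means past the long-shot bound
CONFIDENCE_CLASSES = ("certain", "probable", "possible", "long_shot", "none")

IDENTICAL_WEIGHT = 4.0
SIMILAR_WEIGHT = 1.0
EVALUE_FLOOR = 1e-99
TAIL_RATE_CEILING = 1e3


def superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares optimal rigid superposition of ``coords_a`` onto ``coords_b``.

    Returns ``(rotation, translation, rmsd)`` with ``R @ a + t ≈ b``;
    the RMSD is minimal over all proper rigid transforms (Kabsch).
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate sets must both be N x 3 with equal N")
    if len(a) < 3:
        raise ValueError("superposition needs at least 3 points")
    cen_a = a.mean(axis=0)
    cen_b = b.mean(axis=0)
    rot, rssd = Rotation.align_vectors(b - cen_b, a - cen_a)
    rmsd = float(rssd) / math.sqrt(len(a))
    rotation = rot.as_matrix()
    translation = cen_b - rotation @ cen_a
    return rotation, translation, rmsd


@dataclass(frozen=True)
class SimilarityScore:
    n_identical: int
    n_similar: int
    raw_score: float
    region_size: int

    def __post_init__(self) -> None:
        if self.n_identical + self.n_similar > self.region_size:
            raise ValueError("identical + similar pairs exceed region size")
        if self.raw_score < 0:
            raise ValueError("raw_score must be non-negative")


@dataclass(frozen=True)
class TemplateHit:
    raw_match: RawMatch
    score: SimilarityScore
    e_value: float
    confidence: str

    def __post_init__(self) -> None:
        if self.e_value <= 0:
            raise ValueError("e_value must be positive")
        if self.confidence != classify_confidence(self.e_value):
            raise ValueError("confidence inconsistent with e_value")


def local_similarity(
    query: Structure,
    target: Structure,
    match: RawMatch,
    radius: float = 10.0,
    pair_dist: float = 3.0,
    policy: SubstitutionPolicy = IDENTITY_POLICY,
) -> SimilarityScore:
    """Score residue conservation around a template match.

    The match superposition carries the query onto the target. Query
    residues whose (transformed) CA lies within ``radius`` of the template
    centroid form the region; each is paired with its nearest unused target
    residue CA within ``pair_dist`` (greedy nearest-first assignment), and
    pairs are classified identical / similar / other under ``policy``.
    ``raw_score = 4·n_identical + 1·n_similar``.
    """
    rot, trans = match.rotation, match.translation
    q_ca = query.ca_coords() @ rot.T + trans
    tmpl_ca = np.asarray(
        [q_ca[_index_of(query, rid)] for rid in match.template.residue_ids]
    )
    centroid = tmpl_ca.mean(axis=0)
    region = [i for i, p in enumerate(q_ca) if np.linalg.norm(p - centroid) <= radius]
    if not region:
        return SimilarityScore(0, 0, 0.0, 0)
    t_ca = target.ca_coords()
    # greedy nearest-first one-to-one assignment within pair_dist
    pairs = []
    for qi in region:
        d = np.linalg.norm(t_ca - q_ca[qi], axis=1)
        for ti in np.argsort(d):
            if d[ti] > pair_dist:
                break
            pairs.append((float(d[ti]), qi, int(ti)))
            # all candidates within pair_dist are kept; assignment filters below
    pairs.sort()
    used_q: set[int] = set()
    used_t: set[int] = set()
    n_id = n_sim = 0
    for _, qi, ti in pairs:
        if qi in used_q or ti in used_t:
            continue
        used_q.add(qi)
        used_t.add(ti)
        kind = policy.classify_pair(
            query.residues[qi].res_type, target.residues[ti].res_type
        )
        if kind == "identical":
            n_id += 1
        elif kind == "similar":
            n_sim += 1
    raw = IDENTICAL_WEIGHT * n_id + SIMILAR_WEIGHT * n_sim
    return SimilarityScore(n_id, n_sim, raw, len(region))


def _index_of(query: Structure, rid) -> int:
    for i, r in enumerate(query.residues):
        if r.full_id == rid:
            return i
    raise KeyError(rid)


@dataclass(frozen=True)
class EvalueCalibration:
    tail_rate: float
    score_floor: float
    n_decoy_scores: int
    db_size: int

    def __post_init__(self) -> None:
        if self.tail_rate <= 0:
            raise ValueError("tail_rate must be positive")
        if self.n_decoy_scores < 100:
            raise ValueError("calibration needs at least 100 decoy scores")

    def to_json(self) -> str:
        return json.dumps(
            {
                "tail_rate": self.tail_rate,
                "score_floor": self.score_floor,
                "n_decoy_scores": self.n_decoy_scores,
                "db_size": self.db_size,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "EvalueCalibration":
        return cls(**json.loads(text))


def calibrate(
    decoy_scores: list[float] | np.ndarray,
    db_size: int,
    floor_percentile: float = 90.0,
) -> EvalueCalibration:
    """Fit an exponential tail to the upper decoy scores.

    The score floor is the ``floor_percentile`` of the decoy distribution;
    the tail rate is the maximum-likelihood exponential rate of the
    excesses above the floor (memorylessness makes this exact for
    exponential decoys). A degenerate tail (all excesses ~0) pins the rate
    at a fixed ceiling.
    """
    scores = np.asarray(decoy_scores, dtype=float)
    if len(scores) < 100:
        raise ValueError("calibration needs at least 100 decoy scores")
    floor = float(np.percentile(scores, floor_percentile))
    excess = scores[scores > floor] - floor
    if len(excess) == 0 or float(excess.mean()) < 1.0 / TAIL_RATE_CEILING:
        rate = TAIL_RATE_CEILING
    else:
        rate = 1.0 / float(excess.mean())
    return EvalueCalibration(
        tail_rate=rate, score_floor=floor, n_decoy_scores=len(scores), db_size=db_size
    )


def evalue(score: float, cal: EvalueCalibration) -> float:
    """Expected number of decoy hits at or above ``score`` in a scan.

    ``E = db_size · exp(−tail_rate · (score − floor))``, clamped below at
    1e-99. Strictly decreasing in the score (until the clamp).
    """
    e = cal.db_size * math.exp(-cal.tail_rate * (score - cal.score_floor))
    return max(e, EVALUE_FLOOR)


def classify_confidence(e: float) -> str:
    """Map an E-value to its confidence class (boundaries at 1e-6, 1e-2, 1e-1, 10)."""
    if e <= 0:
        raise ValueError("E-value must be positive")
    if e < 1e-6:
        return "certain"
    if e < 1e-2:
        return "probable"
    if e < 1e-1:
        return "possible"
    if e < 10:
        return "long_shot"
    return "none"


def score_matches(
    matches: list[RawMatch],
    query: Structure,
    library: dict[str, Structure],
    cal: EvalueCalibration,
    radius: float = 10.0,
    pair_dist: float = 3.0,
    policy: SubstitutionPolicy = IDENTITY_POLICY,
) -> list[TemplateHit]:
    """Score raw matches, assign E-values and classes, sort by significance."""
    hits = []
    for m in matches:
        target = library[m.target_id]
        score = local_similarity(query, target, m, radius, pair_dist, policy)
        e = evalue(score.raw_score, cal)
        hits.append(TemplateHit(m, score, e, classify_confidence(e)))
    hits.sort(key=lambda h: (h.e_value, h.raw_match.template_rmsd))
    return hits
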