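"""End-to-end pipelines and tabular I/O.

``run_scan_pipeline`` wires the whole template workflow together: generate
the query's reverse templates, scan them against a structure library,
calibrate E-values against decoy scores, score and classify every hit, and
return one table sorted in descending order of significance (ascending
E-value). ``run_fig4_pipeline`` applies the top-4-per-query selection,
categorizes each hit against residue-level annotations, and bins by
E-value to expose how annotation overlap decays with E-value.

Output tables are TSV with ``#``-prefixed provenance comment lines (tool
version, config hash, seed), so repeated runs are byte-comparable.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from .annotation import (
    FunctionalAnnotation,
    evalue_histogram,
    hit_annotation_category,
    select_top_hits,
)
from .config import RunConfig
from .scoring import (
    CONFIDENCE_CLASSES,
    EvalueCalibration,
    calibrate,
    local_similarity,
    score_matches,
)
from .structure import Structure
from .synthetic import make_synthetic_structure
from .templates import IDENTITY_POLICY, generate_templates, scan

__all__ = [
    "ScanResult",
    "run_scan_pipeline",
    "run_fig4_pipeline",
    "decoy_calibration",
    "hits_to_frame",
    "write_tsv",
    "read_tsv",
]


def _rid_str(rid) -> str:
    chain, seq, icode = rid
    return f"{chain}{seq}{icode}"


@dataclass
class ScanResult:
    hits: list  # list[TemplateHit], best first
    table: pd.DataFrame
    calibration: EvalueCalibration
    class_counts: dict[str, int]
    n_templates: int


def decoy_calibration(
    query: Structure,
    library: list[Structure],
    config: RunConfig,
    n_decoys: int = 30,
    min_scores: int = 100,
) -> EvalueCalibration:
    """Calibrate the E-value tail from scans against unrelated decoy coils.

    Decoy structures are seeded from ``config.seed``, so the calibration is
    deterministic for a given configuration.
    """
    rng = np.random.default_rng(config.seed)
    scores: list[float] = []
    templates = generate_templates(query, config.max_pair_dist, config.max_hydrophobic)
    attempt = 0
    while len(scores) < min_scores and attempt < 20:
        decoys = [
            make_synthetic_structure(
                max(len(query), 10),
                "coil",
                seed=int(rng.integers(2**31)),
                structure_id=f"DECOY_{attempt}_{i}",
            )
            for i in range(n_decoys)
        ]
        matches = scan(
            query, decoys, config.max_pair_dist, config.max_hydrophobic,
            config.rmsd_tol, IDENTITY_POLICY, config.ca_prefilter_tol,
            templates=templates,
        )
        decoy_lib = {d.id: d for d in decoys}
        for m in matches:
            s = local_similarity(
                query, decoy_lib[m.target_id], m, config.radius, config.pair_dist
            )
            scores.append(s.raw_score)
        # decoy scans with no matches at all still inform the tail: score 0
        n_missing = n_decoys * max(1, len(templates) // 4) - len(matches)
        scores.extend([0.0] * max(n_missing, 0))
        attempt += 1
    return calibrate(scores, db_size=len(library))


def run_scan_pipeline(
    config: RunConfig,
    query: Structure,
    library: list[Structure],
    cal: EvalueCalibration | None = None,
) -> ScanResult:
    """Scan, score, classify; hits sorted ascending by E-value."""
    if not library:
        raise ValueError("library must be non-empty")
    if cal is None:
        cal = decoy_calibration(query, library, config)
    matches = scan(
        query, library, config.max_pair_dist, config.max_hydrophobic,
        config.rmsd_tol, IDENTITY_POLICY, config.ca_prefilter_tol,
    )
    lib = {s.id: s for s in library}
    hits = score_matches(matches, query, lib, cal, config.radius, config.pair_dist)
    table = hits_to_frame(hits)
    counts = {c: 0 for c in CONFIDENCE_CLASSES}
    for h in hits:
        counts[h.confidence] += 1
    n_templates = len(generate_templates(query, config.max_pair_dist, config.max_hydrophobic))
    return ScanResult(hits, table, cal, counts, n_templates)


def hits_to_frame(hits) -> pd.DataFrame:
    rows = []
    for h in hits:
        m = h.raw_match
        rows.append(
            {
                "query": m.template.source_id,
                "template_residues": "+".join(_rid_str(r) for r in m.template.residue_ids),
                "template_types": "+".join(m.template.residue_types),
                "target": m.target_id,
                "matched_residues": "+".join(_rid_str(r) for r in m.matched_residues),
                "template_rmsd": round(m.template_rmsd, 4),
                "n_identical": h.score.n_identical,
                "n_similar": h.score.n_similar,
                "raw_score": h.score.raw_score,
                "region_size": h.score.region_size,
                "e_value": h.e_value,
                "confidence": h.confidence,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "query", "template_residues", "template_types", "target",
            "matched_residues", "template_rmsd", "n_identical", "n_similar",
            "raw_score", "region_size", "e_value", "confidence",
        ],
    )


def run_fig4_pipeline(
    config: RunConfig,
    hits,
    annotations: list[FunctionalAnnotation],
    sas_backfill: list[FunctionalAnnotation] = (),
) -> pd.DataFrame:
    """Top-k selection, annotation-overlap categorization, E-value binning."""
    top = select_top_hits(hits, config.top_k)
    categorized = [
        (h, hit_annotation_category(h, annotations, sas_backfill)) for h in top
    ]
    return evalue_histogram(categorized)


# ---------------------------------------------------------------------------
# TSV I/O with provenance headers

def write_tsv(df: pd.DataFrame, path, config: RunConfig | None = None) -> None:
    buf = io.StringIO()
    buf.write(f"# revtemplate {__version__}\n")
    if config is not None:
        buf.write(f"# config {config.hash} seed {config.seed}\n")
    df.to_csv(buf, sep="\t", index=False)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
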