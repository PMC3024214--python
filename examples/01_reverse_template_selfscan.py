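"""Scan a query structure's reverse templates against a small library.

Builds a synthetic 30-residue helix, hides it in a library of unrelated
random coils, and runs the full pipeline: template generation, matching,
local-similarity scoring, E-value calibration against decoy scans, and
confidence classification. The query's own triples should come back as the
most significant ('certain') hits.
"""

from revtemplate import RunConfig, make_synthetic_structure, run_scan_pipeline

config = RunConfig(seed=1)
query = make_synthetic_structure(30, "helix", seed=6, structure_id="QUERY")
library = [query] + [
    make_synthetic_structure(30, "coil", seed=400 + i, structure_id=f"LIB{i}")
    for i in range(4)
]

result = run_scan_pipeline(config, query, library)

print(f"templates generated: {result.n_templates}")
print(f"hits: {len(result.hits)}  class counts: {result.class_counts}")
top = result.table.head(3)[["target", "matched_residues", "template_rmsd", "e_value", "confidence"]]
print(top.to_string(index=False))
print(
    "\nThe top hit is the query matching itself (RMSD ~0, minimal E-value,"
    "\nclass 'certain'); coil decoys only produce weak, high-E matches."
)
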