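# Methods

This note records the models, parameter choices and numerical conventions
behind `revtemplate`, and what the synthetic-data tests do and do not show
about real structures.

## Reverse 3-residue templates

A template is an ordered triple of polymer residues of the query such that
the closest heavy-atom distance between every pair is at most
`max_pair_dist` (default **5.0 Å**) and at most `max_hydrophobic`
(default **1**) of the three residues is hydrophobic. Both defaults are the
published selection rules for this method; the hydrophobic-count rule is
the sole surface-bias mechanism implemented — no solvent-accessibility
filter is applied. "Hydrophobic" is taken as {Ala, Val, Leu, Ile, Met, Phe,
Trp}, the Kyte–Doolittle-positive core; the set is configurable because the
method's original description does not pin it down.

Hydrogens are ignored in all distance computations (heavy-atom convention;
most crystal structures lack them). Hetero groups never participate in
templates; they are annotation objects only.

**Matching atoms.** Each template residue contributes CA, CB (CA only for
glycine) and one residue-type-specific functional atom (Ser OG, His NE2,
Asp OD1, …). Atom sets of the production tool this emulates are not
published; this choice captures side-chain orientation at three points per
residue and is configurable. Atoms absent from the coordinates (unmodelled
side chains; the synthetic backbone fixtures carry only N/CA/C/O/CB) are
dropped from the template's match list, so matching degrades gracefully
rather than failing.

**Search.** Candidate triples in a target are pre-filtered on CA–CA
distance compatibility (± 2.0 Å per pair, configurable) before Kabsch
superposition; a match requires superposition RMSD ≤ `rmsd_tol`
(default **2.0 Å**) over the matching atoms. The search is exhaustive over
type-compatible triples — the brute-force oracle tests enforce that no
qualifying triple is missed. Residue-type compatibility is exact 3-letter
identity by default; an optional similarity policy adds the groups
DE / KR / ST / ILVM / FYW / NQ. All tie-breaks are lexicographic in
(chain, residue number, insertion code), making every pipeline
deterministic given its inputs and seed.

## Local-similarity score and E-values

The published scoring and E-value formulation for this method lives in a
separate description that this package does not reproduce; the module
implements a self-consistent substitute and documents it as such:

* after superposing on the matched triple, query residues whose CA falls
  within `radius` (default **10 Å**) of the template centroid form the
  scored region;
* each region residue is paired to its nearest unused target CA within
  `pair_dist` (default **3 Å**), greedy nearest-first, one-to-one;
* `raw_score = 4·n_identical + 1·n_similar`. The 4:1 weights are fixed and
  arbitrary; only the ordering they induce is load-bearing (the
  score-separation test checks true matches outscore decoys, not absolute
  values).

E-values come from an exponential tail fitted to decoy scores:
`score_floor` is the 90th percentile of the decoy distribution (stabilizes
the fit on small decoy sets), `tail_rate` is the maximum-likelihood
exponential rate of the excesses above the floor, and
`E(s) = db_size · exp(−tail_rate · (s − floor))`, clamped below at 1e-99.
Calibration requires ≥ 100 decoy scores; a degenerate tail pins the rate at
a fixed ceiling (1e3). The `db_size` factor is a per-scan correction; no
additional multiple-testing correction across a query's several hundred
templates is applied — a documented assumption.

The confidence classes are exact threshold rules on E:
certain < 1e-6 ≤ probable < 1e-2 ≤ possible < 1e-1 ≤ long shot < 10;
E ≥ 10 is reported as no class.

## Annotations and status rules

Residue-level annotations come from PROSITE pattern matches (a
backtracking matcher over parsed pattern elements, checked against an
independent regex translation), catalytic-residue and SITE-record lists,
and ligand/metal/nucleic-acid contacts at a heavy-atom cutoff of **4.0 Å**
(standard contact convention, configurable). The overlap analysis keeps the
top four hits per query (rank-4 ties broken by template RMSD), categorizes
each as annotated / none-annotated / no-annotation, and bins by
log10(E-value).

Annotation transfer accepts alignments with identity ≥ 30%, overlap ≥ 80
residues and E < 0.001 — all qualifying alignments, not just the best one
(assumption, recorded in output provenance). Profile-search inheritance
records are inputs filtered at E ≤ 0.01; the searches themselves are out of
scope.

"Deep" annotations are EC numbers specified to level 3 or 4 (trailing
dashes excluded) and molecular-function ontology terms at level ≥ 6, where
level is the **maximum** root-to-term path length on the is_a DAG (the
common usage; min-depth is available via a flag). Slim mapping returns each
term's nearest slim ancestors — all of them on diamond topologies.

The status classifier encodes the published rules mechanically — known
(≥ 1 deep database annotation, excluding a configurable weak-term blacklist
seeded with the iron-ion-binding term), putative (no deep record, but a
non-DUF family flagged as functionally specific), possible (only
transfer-accepted inherited annotations), unknown (nothing) — with
precedence known > putative > possible > unknown. The published status
calls were manual; this "auto-status" approximates that curation and is
labelled accordingly. Family agreement is treated as corroborating, not
required, for known status ("preferably agreement" read as optional).
Whether a family description names a specific molecular function is a
per-family input flag; free-text mining is out of scope.

## Structural novelty

`normRMSD = RMSD · max(L1, L2) / Nmat`, with the **5 Å** new-SSG rule. The
package's aligner is a deliberately simple stand-in for the heavy
production aligners used at database scale: it seeds from the
best-superposing pair of 7-residue CA windows, then iterates (superpose on
the current correspondence → recompute the optimal order-preserving
closest-pair correspondence at `dist_cut` = **6.0 Å** by dynamic
programming) until stable, at most 20 iterations. Its contract is the
`AlignmentResult`, so a stronger aligner can be substituted without
touching the statistics. An empty alignment yields infinite normRMSD
(structurally novel by default), which is the conservative direction for
the SSG call. A published alignment-score filter tied to a score scale not
defined here is not reproduced; the aligner exposes the matched fraction
instead, a non-equivalent but monotone-related quantity.

## Release-date statistics

First-structure statistics scan dated release records per annotation term;
date ties break lexicographically by entry id (tie-breaking in the original
analysis is unstated). A structure that is first for several terms counts
once in the "first structures" column. The programme-period boundary is
**2005-07-01** (configurable). Percentages round half-up — 2 decimals for
the novelty tables, 0 where coverage is printed as an integer; half-up is
indistinguishable from truncation on the printed cells and was fixed once.
Non-redundant counts are consumed as input flags (clustering is external);
both total-based and nr-based percentages are computed.

Novel modelling leverage processes entries in release order (ties by entry
id) over 1-based inclusive coverage intervals, maintained as exact
disjoint-interval unions per sequence; per-entry credits provably sum to
the union size. Variants are de-duplicated on their full identity before
the interval-membership test.

## Synthetic data

The fixture generator builds polypeptide backbones (N, CA, C, O, CB except
glycine) from canonical bond lengths/angles and secondary-structure
torsions: helix (−57°, −47°), strand (−139°, 135°), coil (torsions drawn
per residue from a seeded stream over the broadly allowed Ramachandran
region). Residue types are drawn uniformly from the 20 standard amino
acids. Rigid transforms and isotropic Gaussian coordinate noise provide
controlled positives; random coils provide decoys. Consecutive CA–CA
distances are ~3.8 Å, so local geometry is realistic.

What these fixtures do not emulate: packed side chains beyond CB, real
sequence composition and conservation patterns, domain architecture, and
crystallographic artefacts. Passing tests therefore demonstrate the
correctness and discrimination behaviour of the algorithms (oracle
equivalence, invariances, monotonicities, score separation), not the
biological hit rates reported for real structure collections — those
depend on database snapshots far beyond desk scale.

## Problem sizes and tolerances

The test and benchmark sizes were chosen as the smallest that exercise
each property convincingly: brute-force oracle agreement on 50 random
fixtures of 10–40 residues; self-scan significance over 20 seeded trials
against 20 decoys each; calibration recovery at 10,000 decoy scores (±10%
band, well above the ~2% sampling error at that n); leverage conservation
on 100 randomized interval sets (exact); superposition checked against a
numerically refined rotation-space minimum at 1e-3. Geometry comparisons
use 1e-6 Å where exact arithmetic is expected and 1e-3 Å across PDB
round-trips (the format's 3-decimal precision).
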