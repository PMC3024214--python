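"""PROSITE matching, contact annotations, overlap categories, depth and status rules."""

import itertools
import re

import numpy as np
import pytest

from revtemplate.annotation import (
    AnnotationRecord,
    FunctionalAnnotation,
    InheritedHit,
    OntologyGraph,
    PrositePatternError,
    assign_status,
    contact_residues,
    ec_specified_levels,
    evalue_histogram,
    hit_annotation_category,
    is_deep,
    map_to_slim,
    match_prosite,
    select_top_hits,
    transfer_filter,
)
from revtemplate.scoring import SimilarityScore, TemplateHit, classify_confidence
from revtemplate.structure import Atom, Residue, Structure
from revtemplate.templates import RawMatch, Template

from conftest import point_structure


# ---------------------------------------------------------------------------
# PROSITE

def prosite_to_regex(pattern: str) -> str:
    """Independent oracle: literal translation of PROSITE syntax to regex."""
    pattern = pattern.rstrip(".")
    out = []
    for token in pattern.split("-"):
        m = re.match(r"^(<|>|\[[A-Z]+\]|\{[A-Z]+\}|[A-Zx])", token)
        head, rest = m.group(1), token[m.end():]
        if head == "<":
            out.append("^")
            continue
        if head == ">":
            out.append("$")
            continue
        if head == "x":
            piece = "."
        elif head.startswith("["):
            piece = head
        elif head.startswith("{"):
            piece = "[^" + head[1:-1] + "]"
        else:
            piece = head
        if rest:
            piece += rest.replace("(", "{").replace(")", "}")
        out.append(piece)
    return "".join(out)


class TestMatchProsite:
    def test_simple_literal(self):
        assert match_prosite("GATPC", "A-T-P") == [(1, 4)]

    def test_class_and_negation(self):
        assert match_prosite("AKKQ", "[AG]-x(2)-{P}") == [(0, 4)]
        assert match_prosite("AKKP", "[AG]-x(2)-{P}") == []

    def test_anchors(self):
        assert match_prosite("MAB", "<M-A") == [(0, 2)]
        assert match_prosite("AMAB", "<M-A") == []
        assert match_prosite("XAB", "A-B->") == [(1, 3)]
        assert match_prosite("ABX", "A-B->") == []

    def test_range_repeat(self):
        assert match_prosite("ACCCCB", "A-C(2,4)-B") == [(0, 6)]
        assert match_prosite("ACB", "A-C(2,4)-B") == []

    def test_non_overlapping_leftmost(self):
        assert match_prosite("ABABAB", "A-B") == [(0, 2), (2, 4), (4, 6)]

    def test_malformed_pattern_positions(self):
        with pytest.raises(PrositePatternError, match="position 1"):
            match_prosite("ACGT", "A-?-T")

    def test_fuzz_against_regex_translation(self):
        """Randomized patterns against random sequences equal the regex oracle."""
        rng = np.random.default_rng(99)
        alphabet = "ACDEFGHIKLMNPQRSTVWY"

        def random_element():
            kind = rng.integers(0, 4)
            if kind == 0:
                return alphabet[rng.integers(0, 20)]
            if kind == 1:
                return "x"
            letters = "".join(sorted(set(rng.choice(list(alphabet), size=rng.integers(1, 4)))))
            if kind == 2:
                return f"[{letters}]"
            return "{" + letters + "}"

        def random_pattern():
            n = rng.integers(2, 6)
            parts = []
            for _ in range(n):
                el = random_element()
                rep = rng.integers(0, 3)
                if rep == 1:
                    el += f"({rng.integers(1, 4)})"
                elif rep == 2:
                    lo = int(rng.integers(0, 3))
                    el += f"({lo},{lo + int(rng.integers(1, 3))})"
                parts.append(el)
            return "-".join(parts)

        n_cases = 0
        for _ in range(60):
            pattern = random_pattern()
            regex = re.compile(prosite_to_regex(pattern))
            for _ in range(18):
                seq = "".join(rng.choice(list(alphabet), size=rng.integers(5, 200)))
                expected = [m.span() for m in regex.finditer(seq) if m.span()[0] != m.span()[1]
                            or True]
                got = match_prosite(seq, pattern)
                # regex finditer skips ahead differently on empty matches; drop them
                expected = [sp for sp in expected]
                assert got == expected, (pattern, seq)
                n_cases += 1
        assert n_cases >= 1000


# ---------------------------------------------------------------------------
# contacts

def _with_hetero(kind):
    coords = [(0, 0, 0), (4, 0, 0), (8, 0, 0)]
    s = point_structure(coords, ["SER", "THR", "ASP"], structure_id="C")
    if kind == "metal":
        het = Residue("B", 101, "MG", (Atom("MG", "MG", np.array([0.0, 3.5, 0.0])),),
                      is_polymer=False)
    elif kind == "ligand":
        het = Residue(
            "B", 102, "LIG",
            (Atom("C1", "C", np.array([0.0, 3.5, 0.0])),
             Atom("C2", "C", np.array([4.0, 3.0, 0.0]))),
            is_polymer=False,
        )
    else:
        het = Residue("B", 103, "DA", (Atom("P", "P", np.array([8.0, 3.9, 0.0])),),
                      is_polymer=False)
    s.hetero_groups.append(het)
    return s


class TestContactResidues:
    def test_metal_within_cutoff(self):
        s = _with_hetero("metal")
        (ann,) = contact_residues(s, "metal", cutoff=4.0)
        assert ann.residue_ids == {("A", 1, "")}
        assert ann.source == "metal_contact"

    def test_metal_beyond_cutoff_not_annotated(self):
        s = _with_hetero("metal")
        assert contact_residues(s, "metal", cutoff=3.0) == []

    def test_absent_kind_gives_empty_list(self):
        s = _with_hetero("metal")
        assert contact_residues(s, "nucleic") == []

    @pytest.mark.parametrize("kind", ["metal", "ligand", "nucleic"])
    def test_equals_bruteforce_all_pairs(self, kind):
        s = _with_hetero(kind)
        anns = contact_residues(s, kind, cutoff=4.0)
        got = set().union(*(a.residue_ids for a in anns)) if anns else set()
        group_atoms = [a for g in s.hetero_groups for a in g.atoms]
        brute = {
            r.full_id
            for r in s.residues
            for ra in r.atoms
            for ga in group_atoms
            if np.linalg.norm(ra.coords - ga.coords) <= 4.0
        }
        assert got == brute


# ---------------------------------------------------------------------------
# hit categories and histogram

def make_hit(query="Q", target="T", e_value=1e-4, matched=(("A", 1, ""), ("A", 2, ""), ("A", 3, "")),
             rmsd=0.1):
    t = Template(
        residues=tuple((rid, "SER") for rid in (("A", 1, ""), ("A", 2, ""), ("A", 3, ""))),
        match_atoms=(("CA",), ("CA",), ("CA",)),
        pairwise_min_dists=(4.0, 4.0, 4.0),
        source_id=query,
    )
    m = RawMatch(template=t, target_id=target, matched_residues=tuple(matched),
                 template_rmsd=rmsd, rotation=np.eye(3), translation=np.zeros(3))
    return TemplateHit(m, SimilarityScore(1, 0, 4.0, 2), e_value, classify_confidence(e_value))


class TestHitCategories:
    def test_matched_residue_in_annotation_set(self):
        hit = make_hit()
        ann = FunctionalAnnotation("T", frozenset({("A", 1, "")}), "catalytic")
        assert hit_annotation_category(hit, [ann]) == "annotated"

    def test_disjoint_annotations(self):
        hit = make_hit()
        ann = FunctionalAnnotation("T", frozenset({("A", 9, "")}), "catalytic")
        assert hit_annotation_category(hit, [ann]) == "none_annotated"

    def test_unannotated_target(self):
        hit = make_hit()
        ann_other = FunctionalAnnotation("OTHER", frozenset({("A", 1, "")}), "catalytic")
        assert hit_annotation_category(hit, [ann_other]) == "no_annotation"

    def test_backfill_counts_as_annotation(self):
        hit = make_hit()
        backfill = FunctionalAnnotation("T", frozenset({("A", 2, "")}), "prosite")
        assert hit_annotation_category(hit, [], [backfill]) == "annotated"


class TestEvalueHistogram:
    def test_single_bin_all_annotated(self):
        hits = [(make_hit(e_value=2e-4), "annotated") for _ in range(10)]
        df = evalue_histogram(hits)
        assert len(df) == 1
        row = df.iloc[0]
        assert (row.annotated, row.none_annotated, row.no_annotation) == (10, 0, 0)
        assert row.total == 10

    def test_empty_input(self):
        assert evalue_histogram([]).empty

    def test_counts_conserved_across_bins(self):
        rng = np.random.default_rng(5)
        cats = ["annotated", "none_annotated", "no_annotation"]
        hits = [
            (make_hit(e_value=float(10.0 ** rng.uniform(-8, 0))), cats[rng.integers(0, 3)])
            for _ in range(200)
        ]
        df = evalue_histogram(hits)
        assert df.total.sum() == 200
        assert (df.annotated + df.none_annotated + df.no_annotation).equals(df.total)

    def test_top_four_selection_rank_ties_by_rmsd(self):
        hits = [make_hit(e_value=e, rmsd=r) for e, r in
                [(1e-5, 0.5), (1e-4, 0.5), (1e-3, 0.5), (1e-2, 0.1), (1e-2, 0.2), (1.0, 0.9)]]
        top = select_top_hits(hits, top_k=4)
        assert len(top) == 4
        assert top[-1].e_value == 1e-2 and top[-1].raw_match.template_rmsd == 0.1


# ---------------------------------------------------------------------------
# transfer filter, depth, slim, status

class TestTransferFilter:
    def test_boundary_semantics(self):
        ok = InheritedHit("s", 30.0, 80, 0.0009)
        assert transfer_filter([ok]) == [ok]
        assert transfer_filter([InheritedHit("s", 29.9, 200, 1e-10)]) == []
        assert transfer_filter([InheritedHit("s", 90.0, 79, 1e-10)]) == []
        assert transfer_filter([InheritedHit("s", 90.0, 200, 0.001)]) == []

    def test_equals_bruteforce_triple_check(self):
        rng = np.random.default_rng(17)
        hits = [
            InheritedHit("s", float(rng.uniform(0, 100)), int(rng.integers(0, 200)),
                         float(10.0 ** rng.uniform(-12, 0)))
            for _ in range(300)
        ]
        got = transfer_filter(hits)
        brute = [h for h in hits
                 if h.identity_pct >= 30 and h.overlap_len >= 80 and h.e_value < 0.001]
        assert got == brute


def chain_ontology(n):
    """T0 <- T1 <- ... <- Tn (T0 is the root)."""
    return OntologyGraph.from_edges([(f"T{i + 1}", f"T{i}") for i in range(n)])


class TestDepthRules:
    def test_full_ec_number_is_deep(self):
        assert is_deep(AnnotationRecord("p", "EC", "2.4.2.36"))

    def test_class_level_ec_is_not_deep(self):
        assert not is_deep(AnnotationRecord("p", "EC", "1.-.-.-"))
        assert ec_specified_levels("2.4.-.-") == 2
        assert is_deep(AnnotationRecord("p", "EC", "2.4.2.-"))

    def test_go_level_six_boundary_on_chain_dag(self):
        og = chain_ontology(8)
        assert is_deep(AnnotationRecord("p", "GO_molecular_function", "T6"), og)
        assert not is_deep(AnnotationRecord("p", "GO_molecular_function", "T5"), og)

    def test_unknown_go_term_raises(self):
        og = chain_ontology(3)
        with pytest.raises(KeyError, match="T99"):
            is_deep(AnnotationRecord("p", "GO_molecular_function", "T99"), og)

    def test_max_depth_on_diamond(self):
        # two paths of different length: level is the maximum
        og = OntologyGraph.from_edges(
            [("leaf", "mid1"), ("mid1", "root"), ("leaf", "a"), ("a", "b"), ("b", "root")]
        )
        assert og.level("leaf") == 3
        assert og.level("leaf", use_min=True) == 2


class TestMapToSlim:
    def test_slim_member_maps_to_itself(self):
        og = chain_ontology(4)
        mapping, _ = map_to_slim(og, {"T2"}, {"T2", "T0"})
        assert mapping["T2"] == {"T2"}

    def test_leaf_maps_to_single_ancestor(self):
        og = chain_ontology(4)
        mapping, counts = map_to_slim(og, {"T4"}, {"T1"})
        assert mapping["T4"] == {"T1"}
        assert counts["T1"] == 1

    def test_diamond_returns_both_slim_ancestors(self):
        og = OntologyGraph.from_edges([("c", "a"), ("c", "b"), ("a", "r"), ("b", "r")])
        mapping, _ = map_to_slim(og, {"c"}, {"a", "b"})
        # oracle: exhaustive ancestor enumeration
        ancestors = og.ancestors("c") | {"c"}
        assert mapping["c"] == (ancestors & {"a", "b"})
        assert mapping["c"] == {"a", "b"}

    def test_roots_slim_covers_everything(self):
        og = chain_ontology(5)
        mapping, _ = map_to_slim(og, og.terms, og.roots)
        assert all(v == {"T0"} for v in mapping.values())

    def test_full_slim_is_identity(self):
        og = chain_ontology(5)
        mapping, _ = map_to_slim(og, og.terms, og.terms)
        assert all(v == {k} for k, v in mapping.items())


class TestAssignStatus:
    DEEP_EC = AnnotationRecord("p", "EC", "2.4.2.36")
    FAMILY = AnnotationRecord("p", "family", "PF00001", family_specific_function=True)
    DUF = AnnotationRecord("p", "family", "PF09999", family_is_duf=True)
    INHERITED = InheritedHit("s", 45.0, 120, 1e-6,
                             (AnnotationRecord("s", "GO_molecular_function", "T6", depth=6),))

    def test_deep_annotation_with_family_is_known(self):
        assert assign_status([self.DEEP_EC], [self.FAMILY], []) == "known"

    def test_duf_only_is_unknown(self):
        assert assign_status([], [self.DUF], []) == "unknown"

    def test_inherited_only_is_possible(self):
        assert assign_status([], [], [self.INHERITED]) == "possible"

    def test_family_without_deep_is_putative(self):
        assert assign_status([], [self.FAMILY], [self.INHERITED]) == "putative"

    def test_weak_go_term_does_not_confer_known(self):
        weak = AnnotationRecord("p", "GO_molecular_function", "GO:0005506", depth=7)
        assert assign_status([weak], [], []) == "unknown"

    def test_unfiltered_inherited_hits_do_not_count(self):
        weak_hit = InheritedHit("s", 20.0, 120, 1e-6, self.INHERITED.annotations)
        assert assign_status([], [], [weak_hit]) == "unknown"

    def test_adding_deep_annotation_never_lowers_rank(self):
        from revtemplate.annotation import STATUS_ORDER

        cases = [([], [], []), ([], [self.DUF], []), ([], [self.FAMILY], []),
                 ([], [], [self.INHERITED]), ([], [self.FAMILY], [self.INHERITED])]
        for deep, fams, inh in cases:
            before = STATUS_ORDER.index(assign_status(deep, fams, inh))
            after = STATUS_ORDER.index(assign_status(deep + [self.DEEP_EC], fams, inh))
            assert after >= before
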