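"""Gold-standard label construction: filters, propagation, pair logic."""

import itertools

import pytest

from isonet.catalog import GeneCatalog, IsoformRecord
from isonet.exceptions import InputError
from isonet.labels import (
    AnnotationRecord,
    OntologyDAG,
    PPIRecord,
    build_label_sets,
    build_negative_pairs,
    build_positive_pairs,
    filter_evidence,
    filter_ppi,
    filter_terms,
    propagate_not_inverse,
    propagate_true_path,
    resolve_conflicts,
    term_gene_sets,
)
from isonet.pipeline import label_fixture


def make_catalog(spec):
    """spec: {gene: n_isoforms}."""
    records = []
    for gene, n in spec.items():
        for j in range(1, n + 1):
            records.append(
                IsoformRecord(f"{gene}.{j}", gene, "ACGT" * 10, "ACDEFGHIKL" * 3)
            )
    return GeneCatalog(records)


CHAIN = OntologyDAG([("mid", "root"), ("leaf", "mid")])


class TestEvidenceFilter:
    def test_listed_codes_removed(self):
        records = [
            AnnotationRecord("G1", "T1", evidence_code=c)
            for c in ("EXP", "IEA", "NAS", "ND", "IDA")
        ]
        kept = {a.evidence_code for a in filter_evidence(records)}
        assert kept == {"EXP", "IDA"}

    def test_empty_input(self):
        assert filter_evidence([]) == []

    def test_pathway_records_untouched(self):
        records = [
            AnnotationRecord("G1", "P1", evidence_code="IEA", source="pathway")
        ]
        assert filter_evidence(records) == records


class TestPropagation:
    def test_leaf_annotation_reaches_root(self):
        annotated = propagate_true_path(
            CHAIN, [AnnotationRecord("G1", "leaf")]
        )
        assert term_gene_sets(annotated) == {
            "leaf": {"G1"}, "mid": {"G1"}, "root": {"G1"},
        }

    def test_root_annotation_unchanged(self):
        annotated = propagate_true_path(CHAIN, [AnnotationRecord("G1", "root")])
        assert term_gene_sets(annotated) == {"root": {"G1"}}

    def test_idempotent_and_monotone(self):
        records = [AnnotationRecord("G1", "leaf"), AnnotationRecord("G2", "mid")]
        once = propagate_true_path(CHAIN, records)
        twice = propagate_true_path(CHAIN, once)
        assert term_gene_sets(once) == term_gene_sets(twice)
        before = term_gene_sets(records)
        after = term_gene_sets(once)
        for term, genes in before.items():
            assert genes <= after[term]

    def test_not_propagates_to_descendants_only(self):
        records = [AnnotationRecord("G1", "mid", qualifier="NOT")]
        annotated = propagate_not_inverse(CHAIN, records)
        assert term_gene_sets(annotated, "NOT") == {
            "mid": {"G1"}, "leaf": {"G1"},
        }

    def test_not_at_leaf_is_singleton(self):
        records = [AnnotationRecord("G1", "leaf", qualifier="NOT")]
        annotated = propagate_not_inverse(CHAIN, records)
        assert term_gene_sets(annotated, "NOT") == {"leaf": {"G1"}}

    def test_not_idempotent(self):
        records = [AnnotationRecord("G1", "root", qualifier="NOT")]
        once = propagate_not_inverse(CHAIN, records)
        twice = propagate_not_inverse(CHAIN, once)
        assert term_gene_sets(once, "NOT") == term_gene_sets(twice, "NOT")


class TestTermFilter:
    @pytest.mark.parametrize(
        "size,kept", [(9, False), (10, True), (1000, True), (1001, False)]
    )
    def test_size_boundaries(self, size, kept):
        sets = {"T": {f"G{i}" for i in range(size)}}
        assert ("T" in filter_terms(sets)) is kept

    def test_empty_input(self):
        assert filter_terms({}) == {}


class TestPpiFilter:
    def test_apid_evidence_threshold(self):
        dropped = PPIRecord("G1", "G2", "apid", evidence_count=1)
        kept = PPIRecord("G1", "G2", "apid", evidence_count=2)
        assert filter_ppi([dropped]) == set()
        assert filter_ppi([kept]) == {("G1", "G2")}

    def test_mentha_score_threshold(self):
        dropped = PPIRecord("G1", "G2", "mentha", score=0.19)
        kept = PPIRecord("G1", "G2", "mentha", score=0.2)
        assert filter_ppi([dropped]) == set()
        assert filter_ppi([kept]) == {("G1", "G2")}

    def test_iid_orthology_only_dropped(self):
        assert filter_ppi([PPIRecord("G1", "G2", "iid", orthology_only=True)]) == set()
        assert filter_ppi([PPIRecord("G1", "G2", "iid")]) == {("G1", "G2")}

    def test_cross_species_dropped_for_all_sources(self):
        records = [
            PPIRecord("G1", "G2", s, evidence_count=5, taxon_b="human")
            for s in ("intact", "biogrid", "apid", "iid", "mentha")
        ]
        assert filter_ppi(records) == set()

    def test_unknown_source_rejected(self):
        with pytest.raises(InputError, match="mystery"):
            filter_ppi([PPIRecord("G1", "G2", "mystery")])


class TestPositivePairs:
    def test_co_annotated_single_isoform_genes(self):
        catalog = make_catalog({"G1": 1, "G2": 1})
        positives = build_positive_pairs(catalog, {"T1": {"G1", "G2"}})
        assert set(positives) == {("G1.1", "G2.1")}
        assert positives[("G1.1", "G2.1")] == {("ontology", "T1")}

    def test_multi_isoform_gene_contributes_nothing(self):
        catalog = make_catalog({"G1": 1, "G2": 3})
        assert build_positive_pairs(catalog, {"T1": {"G1", "G2"}}) == {}

    def test_four_genes_sharing_one_term_give_six_pairs(self):
        catalog = make_catalog({f"G{i}": 1 for i in range(1, 5)})
        positives = build_positive_pairs(
            catalog, {"T1": {"G1", "G2", "G3", "G4"}}
        )
        assert len(positives) == 6

    def test_ppi_is_an_independent_positive_source(self):
        catalog = make_catalog({"G1": 1, "G2": 1})
        positives = build_positive_pairs(catalog, {}, {}, {("G1", "G2")})
        assert set(positives) == {("G1.1", "G2.1")}


class TestNegativePairs:
    def test_worked_negative_enumeration(self):
        """NOT gene with 2 isoforms against genes with 1+1+3 isoforms: 10."""
        catalog = make_catalog({"G1": 1, "G2": 1, "G3": 2, "G4": 3})
        negatives = build_negative_pairs(
            catalog,
            {"T1": {"G3"}},
            {"T1": {"G1", "G2", "G4"}},
        )
        assert len(negatives) == 10

    def test_no_not_records_no_negatives(self):
        catalog = make_catalog({"G1": 1, "G2": 1})
        assert build_negative_pairs(catalog, {}, {"T1": {"G1", "G2"}}) == {}

    def test_not_gene_never_paired_with_itself(self):
        catalog = make_catalog({"G1": 2, "G2": 1})
        negatives = build_negative_pairs(
            catalog, {"T1": {"G1"}}, {"T1": {"G1", "G2"}}
        )
        genes = {
            tuple(sorted({catalog.gene_of(a), catalog.gene_of(b)}))
            for a, b in negatives
        }
        assert genes == {("G1", "G2")}


class TestConflictResolution:
    def test_pair_in_both_sets_stays_positive(self):
        positives = {("A", "B"): {("ontology", "T1")}}
        negatives = {
            ("A", "B"): {("ontology", "T2")},
            ("A", "C"): {("ontology", "T2")},
        }
        pos, neg = resolve_conflicts(positives, negatives)
        assert [p.key for p in pos] == [("A", "B")]
        assert [n.key for n in neg] == [("A", "C")]

    def test_outputs_disjoint(self):
        positives = {("A", "B"): set(), ("A", "C"): set()}
        negatives = {("A", "B"): set(), ("B", "C"): set()}
        pos, neg = resolve_conflicts(positives, negatives)
        assert {p.key for p in pos} & {n.key for n in neg} == set()


class TestEndToEnd:
    def test_fixture_labels_disjoint_and_cross_gene(self, study):
        labels = study.labels
        pos = {p.key for p in labels.positives}
        neg = {n.key for n in labels.negatives}
        assert pos and neg
        assert pos & neg == set()
        for a, b in itertools.chain(pos, neg):
            assert study.catalog.gene_of(a) != study.catalog.gene_of(b)

    def test_counts_match_brute_force_enumerator(self, study):
        """Scan all C(n,2) pairs against the label rules independently."""
        fixture = study.fixture
        catalog = fixture.catalog
        ann = fixture.annotations
        # independent re-derivation of gene-level sets
        kept = [
            a for a in ann.annotations
            if a.source != "ontology" or a.evidence_code not in {"IEA", "NAS", "ND"}
        ]
        gene_terms = {}
        not_terms = {}
        for a in kept:
            if a.qualifier == "positive":
                closure = {a.term_id} | ann.dag.ancestors(a.term_id)
                gene_terms.setdefault(a.gene_id, set()).update(closure)
            else:
                closure = {a.term_id} | ann.dag.descendants(a.term_id)
                not_terms.setdefault(a.gene_id, set()).update(closure)
        term_counts = {}
        for genes in gene_terms.values():
            for t in genes:
                term_counts[t] = term_counts.get(t, 0) + 1
        retained = {t for t, c in term_counts.items() if 10 <= c <= 1000}
        pathway_genes = {}
        for a in ann.pathways:
            pathway_genes.setdefault(a.term_id, set()).add(a.gene_id)
        ppi_pairs = set()
        for r in ann.ppi:
            ok = r.taxon_a == r.taxon_b == "mouse"
            ok &= not (r.source == "apid" and r.evidence_count < 2)
            ok &= not (r.source == "iid" and r.orthology_only)
            ok &= not (r.source == "mentha" and r.score < 0.2)
            if ok:
                ppi_pairs.add(tuple(sorted((r.gene_a, r.gene_b))))
        single = set(catalog.single_isoform_genes())
        expected_pos = set()
        expected_neg = set()
        isoforms = catalog.isoform_ids
        for a, b in itertools.combinations(isoforms, 2):
            ga, gb = catalog.gene_of(a), catalog.gene_of(b)
            if ga == gb:
                continue
            if ga in single and gb in single:
                shared = (
                    gene_terms.get(ga, set())
                    & gene_terms.get(gb, set())
                    & retained
                )
                shared_pwy = any(
                    ga in g and gb in g for g in pathway_genes.values()
                )
                if shared or shared_pwy or tuple(sorted((ga, gb))) in ppi_pairs:
                    expected_pos.add((a, b))
                    continue
            for ng, pg in ((ga, gb), (gb, ga)):
                conflict = any(
                    t in retained
                    and t in gene_terms.get(pg, set())
                    for t in not_terms.get(ng, set())
                )
                if conflict:
                    expected_neg.add((a, b))
                    break
        expected_neg -= expected_pos
        labels = label_fixture(fixture)
        assert {p.key for p in labels.positives} == expected_pos
        assert {n.key for n in labels.negatives} == expected_neg
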