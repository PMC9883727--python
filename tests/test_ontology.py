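"""Ontology parsing, traversal, propagation, class selection and IC."""

import math

import pytest

from seqgo.containers import AnnotationCorpus
from seqgo.ontology import (
    OboParseError,
    OntologyCycleError,
    PER_SUBONTOLOGY,
    WHOLE_ONTOLOGY,
    compute_ic,
    load_obo,
    propagate,
    select_classes,
    write_obo,
)
from seqgo.synthetic import SyntheticSpec, make_toy_ontology, simulate_proteins, make_motif_map

from conftest import make_go


MINIMAL_OBO = """\
format-version: 1.2

[Term]
id: GO:0000001
name: a
namespace: molecular_function

[Term]
id: GO:0000002
name: b
namespace: molecular_function
is_a: GO:0000001 ! a
"""


class TestLoadObo:
    def test_minimal_file(self, tmp_path):
        path = tmp_path / "go.obo"
        path.write_text(MINIMAL_OBO)
        go = load_obo(str(path))
        assert len(go) == 2
        assert go.edges == {("GO:0000002", "is_a", "GO:0000001")}
        assert go.namespace_of("GO:0000002") == "MFO"

    def test_relationship_edge(self, tmp_path):
        text = MINIMAL_OBO + (
            "\n[Term]\nid: GO:0000003\nname: c\nnamespace: biological_process\n"
            "relationship: part_of GO:0000001\n"
        )
        path = tmp_path / "go.obo"
        path.write_text(text)
        go = load_obo(str(path))
        assert ("GO:0000003", "part_of", "GO:0000001") in go.edges

    def test_cycle_is_an_error(self, tmp_path):
        text = (
            "format-version: 1.2\n\n"
            "[Term]\nid: GO:0000001\nnamespace: molecular_function\nis_a: GO:0000002\n\n"
            "[Term]\nid: GO:0000002\nnamespace: molecular_function\nis_a: GO:0000001\n"
        )
        path = tmp_path / "go.obo"
        path.write_text(text)
        with pytest.raises(OntologyCycleError, match="GO:0000001"):
            load_obo(str(path))

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "go.obo"
        path.write_text("format-version: 1.2\n\n[Term]\nid: GO:0000001\ngarbage\n")
        with pytest.raises(OboParseError, match="line 5"):
            load_obo(str(path))

    def test_obsolete_retained_and_never_traversed(self, tmp_path):
        text = MINIMAL_OBO + (
            "\n[Term]\nid: GO:0000009\nname: gone\nnamespace: molecular_function\n"
            "is_obsolete: true\nreplaced_by: GO:0000001\n"
        )
        path = tmp_path / "go.obo"
        path.write_text(text)
        go = load_obo(str(path))
        assert go.terms["GO:0000009"].obsolete
        assert go.resolve("GO:0000009") == "GO:0000001"
        assert "GO:0000009" not in go.active_terms()

    def test_alt_id_resolves(self, tmp_path):
        text = MINIMAL_OBO.replace(
            "id: GO:0000001\n", "id: GO:0000001\nalt_id: GO:0009999\n"
        )
        path = tmp_path / "go.obo"
        path.write_text(text)
        go = load_obo(str(path))
        assert go.resolve("GO:0009999") == "GO:0000001"

    def test_obo_round_trip(self, tmp_path, cross_ns_go):
        path = tmp_path / "out.obo"
        write_obo(cross_ns_go, str(path))
        reloaded = load_obo(str(path))
        assert reloaded.edges == cross_ns_go.edges
        assert set(reloaded.terms) == set(cross_ns_go.terms)

    def test_agrees_with_obonet(self, tmp_path):
        obonet = pytest.importorskip("obonet")
        spec = SyntheticSpec(n_terms_per_namespace=8, seed=5)
        go = make_toy_ontology(spec)
        path = tmp_path / "toy.obo"
        write_obo(go, str(path))
        graph = obonet.read_obo(str(path))
        assert set(graph.nodes) == set(go.terms)
        obonet_edges = {(c, k, p) for c, p, k in graph.edges(keys=True)}
        assert obonet_edges == go.edges


class TestAncestors:
    def test_chain_two_step_closure(self, chain_go):
        assert chain_go.ancestors("GO:0000003") == {"GO:0000001", "GO:0000002"}

    def test_root_has_no_ancestors(self, chain_go):
        assert chain_go.ancestors("GO:0000001") == frozenset()

    def test_cross_namespace_modes(self, cross_ns_go):
        whole = cross_ns_go.ancestors("GO:0000002", WHOLE_ONTOLOGY)
        per = cross_ns_go.ancestors("GO:0000002", PER_SUBONTOLOGY)
        assert "GO:0000011" in whole and "GO:0000010" in whole
        assert per == {"GO:0000001"}

    def test_per_subontology_subset_of_whole(self):
        spec = SyntheticSpec(n_terms_per_namespace=10, seed=2)
        go = make_toy_ontology(spec)
        for cls in go.active_terms():
            assert go.ancestors(cls, PER_SUBONTOLOGY) <= go.ancestors(cls, WHOLE_ONTOLOGY)

    def test_monotone_along_edges(self):
        spec = SyntheticSpec(n_terms_per_namespace=10, seed=3)
        go = make_toy_ontology(spec)
        for child, rel, parent in go.edges:
            anc = go.ancestors(child)
            assert parent in anc
            assert go.ancestors(parent) <= anc

    def test_unknown_id_raises(self, chain_go):
        with pytest.raises(KeyError):
            chain_go.ancestors("GO:7777777")


class TestPropagate:
    def test_chain_closure(self, chain_go, chain_corpus):
        out = propagate(chain_corpus, chain_go)
        assert out["P1"] == {"GO:0000001", "GO:0000002", "GO:0000003"}
        assert out.propagated
        # input untouched
        assert chain_corpus["P1"] == {"GO:0000003"}

    def test_idempotent_and_extensive(self, chain_go, chain_corpus):
        once = propagate(chain_corpus, chain_go)
        twice = propagate(once, chain_go)
        assert once == twice
        for p in chain_corpus.records:
            assert chain_corpus[p] <= once[p]

    def test_cross_namespace_parent_included(self, cross_ns_go):
        corpus = AnnotationCorpus({"P1": {"GO:0000002"}})
        whole = propagate(corpus, cross_ns_go, WHOLE_ONTOLOGY)
        per = propagate(corpus, cross_ns_go, PER_SUBONTOLOGY)
        assert "GO:0000011" in whole["P1"]
        assert "GO:0000011" not in per["P1"]

    def test_unknown_class_skipped_or_raises(self, chain_go):
        corpus = AnnotationCorpus({"P1": {"GO:0000003", "GO:7777777"}})
        out = propagate(corpus, chain_go)
        assert "GO:7777777" not in out["P1"]
        with pytest.raises(KeyError):
            propagate(corpus, chain_go, on_unknown="error")


class TestSelectClasses:
    def test_requires_propagated(self, chain_corpus):
        with pytest.raises(ValueError):
            select_classes(chain_corpus)

    def test_count_boundary(self, chain_go):
        leaf = "GO:0000003"
        at = AnnotationCorpus({f"P{i}": {leaf} for i in range(50)}, propagated=True)
        below = AnnotationCorpus({f"P{i}": {leaf} for i in range(49)}, propagated=True)
        assert select_classes(at) == [leaf]
        assert select_classes(below) == []

    def test_ancestors_selected_with_leaf(self, chain_go):
        raw = AnnotationCorpus({f"P{i}": {"GO:0000003"} for i in range(60)})
        prop = propagate(raw, chain_go)
        assert select_classes(prop) == ["GO:0000001", "GO:0000002", "GO:0000003"]

    def test_matches_brute_force_recount(self):
        spec = SyntheticSpec(n_proteins=150, n_terms_per_namespace=10, seed=9)
        go = make_toy_ontology(spec)
        motifs = make_motif_map(go, spec)
        _, _, truth = simulate_proteins(go, motifs, spec)
        for min_count in (5, 20, 50):
            counts = {}
            for classes in truth.records.values():
                for c in classes:
                    counts[c] = counts.get(c, 0) + 1
            expected = sorted(c for c, n in counts.items() if n >= min_count)
            assert select_classes(truth, min_count=min_count) == expected


class TestComputeIC:
    def test_child_equal_to_parent_has_zero_ic(self, chain_go):
        raw = AnnotationCorpus({f"P{i}": {"GO:0000002"} for i in range(8)})
        prop = propagate(raw, chain_go)
        ic = compute_ic(prop, chain_go, smoothing=False)
        assert ic["GO:0000002"] == 0.0

    def test_quarter_probability(self, chain_go):
        # 8 proteins at the parent, 2 of which reach the child
        records = {f"P{i}": {"GO:0000002"} for i in range(8)}
        records["P0"] = {"GO:0000003"}
        records["P1"] = {"GO:0000003"}
        prop = propagate(AnnotationCorpus(records), chain_go)
        ic = compute_ic(prop, chain_go, smoothing=False)
        assert ic["GO:0000003"] == pytest.approx(-math.log(0.25), abs=1e-12)

    def test_root_ic_zero(self, chain_go, chain_corpus):
        prop = propagate(chain_corpus, chain_go)
        ic = compute_ic(prop, chain_go)
        assert ic["GO:0000001"] == 0.0

    def test_smoothing_off_zero_denominator_raises(self, chain_go):
        prop = AnnotationCorpus({"P1": {"GO:0000001"}}, propagated=True)
        with pytest.raises(ValueError, match="GO:0000003"):
            compute_ic(prop, chain_go, smoothing=False)

    def test_smoothing_keeps_all_classes_finite(self, chain_go, chain_corpus):
        ic = compute_ic(propagate(chain_corpus, chain_go), chain_go)
        for cls in chain_go.active_terms():
            assert ic[cls] >= 0.0 and math.isfinite(ic[cls])

    def test_counts_antitone_along_isa(self):
        spec = SyntheticSpec(n_proteins=200, n_terms_per_namespace=10, seed=4)
        go = make_toy_ontology(spec)
        motifs = make_motif_map(go, spec)
        _, _, truth = simulate_proteins(go, motifs, spec)
        counts = truth.class_counts()
        for child, rel, parent in go.edges:
            if rel == "is_a":
                assert counts.get(child, 0) <= counts.get(parent, 0)
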