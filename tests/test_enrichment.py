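"""GO DAG parsing, true-path propagation, hypergeometric test, BH."""

import pytest
import scipy.stats as st
from hypothesis import given, strategies as hst

from _oracles import bh_step_up, hypergeom_tail_by_enumeration
from mirlitnet.enrichment import (AnnotationTable, GoDag, bh_adjust, enrich,
                                  hypergeom_term_p, load_annotations,
                                  parse_obo, propagate, write_annotations,
                                  write_obo)
from mirlitnet.errors import (ConfigurationError, ParseError,
                              StatisticsError, StructureError)
from mirlitnet.synthetic import generate_go_fixture


def table(annotations, universe=()):
    return AnnotationTable(
        annotations={g: frozenset(ts) for g, ts in annotations.items()},
        universe=frozenset(universe),
    )


class TestParseObo:
    def test_single_term(self, tmp_path):
        path = tmp_path / "one.obo"
        path.write_text(
            "format-version: 1.2\n\n[Term]\nid: GO:0000001\nname: root\n"
            "namespace: biological_process\n"
        )
        dag = parse_obo(path)
        assert set(dag.terms) == {"GO:0000001"}
        assert dag.roots() == {"GO:0000001"}

    def test_cycle_rejected(self, tmp_path):
        path = tmp_path / "cycle.obo"
        path.write_text(
            "format-version: 1.2\n\n"
            "[Term]\nid: GO:1\nname: a\nis_a: GO:2\n\n"
            "[Term]\nid: GO:2\nname: b\nis_a: GO:1\n"
        )
        with pytest.raises((StructureError, ParseError)):
            parse_obo(path)

    def test_generator_fixture_round_trips(self, tmp_path):
        dag, _ = generate_go_fixture(10, 6, seed=4)
        path = tmp_path / "synthetic.obo"
        write_obo(dag, path)
        back = parse_obo(path)
        assert back.terms == dict(dag.terms)
        assert {t: back.parents.get(t, frozenset()) for t in back.terms} == \
            {t: dag.parents.get(t, frozenset()) for t in dag.terms}


class TestPropagate:
    @pytest.fixture
    def chain_dag(self):
        return GoDag(
            terms={"root": ("r", "bp"), "mid": ("m", "bp"), "leaf": ("l", "bp")},
            parents={"mid": frozenset({"root"}), "leaf": frozenset({"mid"})},
        )

    def test_root_annotation_unchanged(self, chain_dag):
        annot = table({"g1": {"root"}})
        assert propagate(annot, chain_dag).annotations == annot.annotations

    def test_leaf_gains_all_ancestors(self, chain_dag):
        out = propagate(table({"g1": {"leaf"}}), chain_dag)
        assert out.annotations["g1"] == frozenset({"leaf", "mid", "root"})

    def test_idempotent_on_random_fixtures(self, chain_dag):
        for seed in range(5):
            dag, annot = generate_go_fixture(12, 8, seed=seed)
            once = propagate(annot, dag)
            assert propagate(once, dag).annotations == once.annotations


class TestHypergeomTermP:
    @pytest.fixture
    def flat(self):
        """10 genes, one term annotating the first 4 (flat single-root DAG)."""
        genes = [f"g{i}" for i in range(10)]
        annotations = {g: {"T"} if i < 4 else {"root"} for i, g in enumerate(genes)}
        return table(annotations, genes)

    def test_enumerated_example(self, flat):
        # N=10, K=4, n=5, k=4: 6 favourable draws of C(10,5)=252
        p = hypergeom_term_p("T", [f"g{i}" for i in range(4)] + ["g9"], flat)
        assert p == pytest.approx(6 / 252, rel=1e-12)
        assert hypergeom_tail_by_enumeration(10, 4, 5, 4) == pytest.approx(6 / 252)

    def test_query_equals_universe(self, flat):
        assert hypergeom_term_p("T", [f"g{i}" for i in range(10)], flat) == 1.0

    def test_term_annotating_whole_universe(self):
        genes = [f"g{i}" for i in range(6)]
        annot = table({g: {"T"} for g in genes}, genes)
        assert hypergeom_term_p("T", genes[:3], annot) == 1.0

    def test_query_outside_universe_rejected(self, flat):
        with pytest.raises(ConfigurationError):
            hypergeom_term_p("T", ["nope"], flat)

    def test_matches_scipy_survival(self, flat):
        query = [f"g{i}" for i in range(4)] + ["g9", "g8"]
        ours = hypergeom_term_p("T", query, flat)
        assert ours == pytest.approx(st.hypergeom.sf(3, 10, 4, 6), rel=1e-10)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == [pytest.approx(0.03)]

    def test_hand_evaluated_example(self):
        # step-up: every adjusted value collapses to m*p_(m)/m = 0.04
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_rejects_out_of_range(self):
        with pytest.raises(StatisticsError):
            bh_adjust([0.1, 1.5])

    @given(hst.lists(hst.floats(0, 1), min_size=1, max_size=30))
    def test_matches_direct_step_up(self, pvals):
        assert bh_adjust(pvals) == pytest.approx(bh_step_up(pvals), rel=1e-12)

    @given(hst.lists(hst.floats(0, 1), min_size=1, max_size=30),
           hst.randoms(use_true_random=False))
    def test_bounds_and_permutation_invariance(self, pvals, rnd):
        adjusted = bh_adjust(pvals)
        assert all(0 <= q <= 1 for q in adjusted)
        assert all(q >= p for p, q in zip(pvals, adjusted))
        perm = list(range(len(pvals)))
        rnd.shuffle(perm)
        permuted = bh_adjust([pvals[i] for i in perm])
        assert permuted == pytest.approx([adjusted[i] for i in perm])


class TestEnrich:
    def test_planted_term_attains_minimum_p(self):
        genes = [f"GENE{i + 1:03d}" for i in range(30)]
        dag, annot = generate_go_fixture(
            30, 10, enriched_genes=genes[:6], seed=11
        )
        rows = enrich(genes[:6], annot, dag)
        assert rows[0].term_id == "GO:0000010"  # the designated enriched term
        assert rows[0].raw_p == min(r.raw_p for r in rows)
        assert rows[0].query_annotated == 6

    def test_single_gene_query_tests_its_terms_only(self):
        dag, annot = generate_go_fixture(10, 6, seed=2)
        propagated = propagate(annot, dag)
        gene = sorted(annot.annotations)[0]
        rows = enrich([gene], annot, dag)
        assert {r.term_id for r in rows} == set(propagated.annotations[gene])
        assert all(r.query_annotated == 1 for r in rows)

    def test_empty_query_rejected(self):
        dag, annot = generate_go_fixture(10, 4, seed=2)
        with pytest.raises(StatisticsError):
            enrich([], annot, dag)

    def test_row_invariants_and_order(self):
        dag, annot = generate_go_fixture(25, 9, seed=6)
        query = sorted(annot.universe)[:8]
        rows = enrich(query, annot, dag)
        assert [r.raw_p for r in rows] == sorted(r.raw_p for r in rows)
        for r in rows:
            assert 1 <= r.query_annotated <= r.background_annotated
            assert r.adjusted_p >= r.raw_p

    def test_output_schema(self, tmp_path):
        from mirlitnet.enrichment import write_enrichment_tsv

        dag, annot = generate_go_fixture(12, 5, seed=3)
        rows = enrich(sorted(annot.universe)[:4], annot, dag)
        path = tmp_path / "enrichment.tsv"
        write_enrichment_tsv(rows, path)
        header, first = path.read_text().splitlines()[:2]
        assert header.split("\t") == [
            "go_id", "description", "total_genes", "partner_genes",
            "p_value", "corrected_p_value", "significant",
        ]
        # scientific notation with two decimals, e.g. 1.83E-06
        import re

        assert re.fullmatch(r"\d\.\d{2}E[+-]\d{2}", first.split("\t")[4])


class TestAnnotationIO:
    def test_tsv_round_trip(self, tmp_path):
        _, annot = generate_go_fixture(8, 5, seed=9)
        path = tmp_path / "annot.tsv"
        write_annotations(annot, path)
        back = load_annotations(path, universe=annot.universe)
        assert back.annotations == dict(annot.annotations)
        assert back.universe == annot.universe

    def test_malformed_line_rejected(self, tmp_path):
        path = tmp_path / "annot.tsv"
        path.write_text("gene\tterm\nonlyonecolumn\n")
        with pytest.raises(ParseError):
            load_annotations(path)
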