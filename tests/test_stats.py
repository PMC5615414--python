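"""Contingency counting and one-sided Fisher scoring."""

from fractions import Fraction

import pytest
import scipy.stats as st
from hypothesis import given, strategies as hst

from _oracles import fisher_right_tail, point_prob
from conftest import make_annotated
from mirlitnet.errors import StatisticsError
from mirlitnet.stats import (AssociationRecord, ContingencyTable,
                             build_contingency, fisher_one_sided,
                             point_hypergeometric, score_all_pairs, top_k)

tables = hst.tuples(
    hst.integers(0, 15), hst.integers(0, 15),
    hst.integers(0, 15), hst.integers(0, 15),
).filter(lambda t: sum(t) > 0)


class TestPointProbability:
    def test_balanced_table(self):
        assert point_hypergeometric(ContingencyTable(1, 1, 1, 1)) == pytest.approx(
            16 / 24, rel=1e-12
        )

    @pytest.mark.parametrize("a,d", [(3, 0), (0, 5), (10, 0)])
    def test_degenerate_margins_single_table(self, a, d):
        # margins admit exactly one table, so its probability is 1
        assert point_hypergeometric(ContingencyTable(a, 0, 0, d)) == pytest.approx(1.0)

    def test_empty_table_rejected(self):
        with pytest.raises(StatisticsError):
            point_hypergeometric(ContingencyTable(0, 0, 0, 0))

    @given(tables)
    def test_matches_factorial_formula(self, cells):
        t = ContingencyTable(*cells)
        expected = point_prob(*cells)
        assert point_hypergeometric(t, exact=True) == expected

    @given(tables)
    def test_pmf_normalizes_exactly(self, cells):
        t = ContingencyTable(*cells)
        total = sum(
            point_hypergeometric(t.with_a(a), exact=True)
            for a in t.admissible_range()
        )
        assert total == Fraction(1)


class TestFisherOneSided:
    def test_enumerated_example(self):
        # margins (5,15)x(5,15): tail over a'=3,4,5 enumerates to 1126/15504
        p = fisher_one_sided(ContingencyTable(3, 2, 2, 13))
        assert p == pytest.approx(1126 / 15504, rel=1e-12)
        assert fisher_right_tail(3, 2, 2, 13) == Fraction(1126, 15504)

    def test_minimum_a_gives_whole_tail(self):
        t = ContingencyTable(1, 5, 9, 0)  # a already at its admissible minimum
        assert min(t.admissible_range()) == t.a
        assert fisher_one_sided(t) == pytest.approx(1.0)

    def test_single_admissible_table(self):
        assert fisher_one_sided(ContingencyTable(0, 0, 0, 10)) == 1.0

    def test_empty_table_rejected(self):
        with pytest.raises(StatisticsError):
            fisher_one_sided(ContingencyTable(0, 0, 0, 0))

    @given(tables)
    def test_matches_enumeration_and_scipy(self, cells):
        t = ContingencyTable(*cells)
        ours = fisher_one_sided(t)
        oracle = float(fisher_right_tail(*cells))
        assert ours == pytest.approx(oracle, rel=1e-10)
        scipy_p = st.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="greater")[1]
        assert ours == pytest.approx(scipy_p, rel=1e-9)

    def test_log_space_path_matches_scipy(self):
        # n > exact threshold exercises the log-gamma tail
        t = ContingencyTable(30, 270, 120, 1080)
        assert t.n > 500
        scipy_p = st.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="greater")[1]
        assert fisher_one_sided(t) == pytest.approx(scipy_p, rel=1e-9)

    @given(tables)
    def test_p_in_unit_interval(self, cells):
        p = fisher_one_sided(ContingencyTable(*cells))
        assert 0.0 <= p <= 1.0


class TestBuildContingency:
    def test_direct_counting(self):
        corpus = make_annotated([
            ({"miR-1"}, {"LDL"}),
            ({"miR-1"}, set()),
            (set(), {"LDL"}),
            (set(), set()),
            (set(), set()),
        ])
        t = build_contingency(corpus, "miR-1", "LDL")
        assert (t.a, t.b, t.c, t.d, t.n) == (1, 1, 1, 2, 5)

    def test_empty_corpus(self):
        corpus = make_annotated([], mirna_vocab={"miR-1"}, group_vocab={"LDL"})
        t = build_contingency(corpus, "miR-1", "LDL")
        assert (t.a, t.b, t.c, t.d, t.n) == (0, 0, 0, 0, 0)

    def test_unknown_entities_rejected(self):
        corpus = make_annotated([({"miR-1"}, {"LDL"})])
        with pytest.raises(KeyError):
            build_contingency(corpus, "miR-999", "LDL")
        with pytest.raises(KeyError):
            build_contingency(corpus, "miR-1", "Gout")

    def test_matches_ground_truth_counts(self):
        from mirlitnet.lexicon import default_disease_groups, MirnaLexiconEntry
        from mirlitnet.ner import annotate_corpus
        from mirlitnet.synthetic import CorpusConfig, generate_corpus

        cfg = CorpusConfig(n_abstracts=120, seed=7)
        records, truth = generate_corpus(cfg)
        lexicon = [MirnaLexiconEntry(m) for m in cfg.mirna_ids]
        groups = [g for g in default_disease_groups()
                  if g.name in cfg.disease_groups]
        annotated = annotate_corpus(records, lexicon, groups)
        counts = truth.comention_counts()
        for mirna, group in [("miR-33a", "HDL-Cholesterol"), ("miR-122", "LDL")]:
            t = build_contingency(annotated, mirna, group)
            assert t.a == counts.get((mirna, group), 0)
            assert t.n == cfg.n_abstracts


class TestScoreAllPairs:
    def test_strong_cooccurrence_is_significant(self):
        entities = (
            [({"miR-9"}, {"LDL"})] * 8
            + [({"miR-9"}, set())] * 2
            + [(set(), {"LDL"})] * 2
            + [(set(), set())] * 88
        )
        records = score_all_pairs(make_annotated(entities))
        (rec,) = records
        expected = float(fisher_right_tail(8, 2, 2, 88))
        assert rec.paper_count == 8
        assert rec.p_value == pytest.approx(expected, rel=1e-10)
        assert rec.significant

    def test_zero_cooccurrence_not_reported(self):
        records = score_all_pairs(make_annotated([
            ({"miR-9"}, set()),
            (set(), {"LDL"}),
        ]))
        assert records == []

    def test_bh_flag_tightens_calls(self):
        entities = (
            [({"miR-9"}, {"LDL"})] * 3
            + [({"miR-7"}, {"HDL"})] * 2
            + [({"miR-7"}, set()), ({"miR-9"}, set())] * 3
            + [(set(), {"LDL"}), (set(), {"HDL"})] * 3
            + [(set(), set())] * 30
        )
        raw = score_all_pairs(make_annotated(entities))
        bh = score_all_pairs(make_annotated(entities), bh=True)
        assert sum(r.significant for r in bh) <= sum(r.significant for r in raw)


class TestTopK:
    @staticmethod
    def _rec(m, g, count, p):
        return AssociationRecord(m, g, count, p, p <= 0.05)

    def test_rejects_nonpositive_k(self):
        with pytest.raises(StatisticsError):
            top_k([], k=0)

    def test_plain_ascending_sort(self):
        recs = [self._rec(f"miR-{i}", "LDL", 1, p)
                for i, p in enumerate([0.5, 0.01, 0.2])]
        assert [r.p_value for r in top_k(recs, 3)] == [0.01, 0.2, 0.5]

    def test_k_beyond_length_returns_all(self):
        recs = [self._rec("miR-1", "LDL", 1, 0.5)]
        assert len(top_k(recs, 10)) == 1

    def test_tie_break_paper_count_then_name(self):
        recs = [
            self._rec("miR-96", "HDL-Cholesterol", 2, 1e-4),
            self._rec("miR-144", "HDL-Cholesterol", 3, 1e-4),
            self._rec("miR-33a", "HDL-Cholesterol", 7, 1e-4),
            self._rec("miR-185", "HDL-Cholesterol", 2, 1e-4),
        ]
        out = top_k(recs, 4)
        assert [r.mirna_id for r in out] == ["miR-33a", "miR-144", "miR-185", "miR-96"]
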