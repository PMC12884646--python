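"""Entropy Weight Method fusion and percentile redundancy thresholds."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import symscreen as ss
from symscreen.corpus import LayerScoreTable


def _table(x, labels=None):
    x = np.asarray(x, dtype=float)
    labels = labels or tuple((1, i + 2) for i in range(x.shape[0]))
    return LayerScoreTable(tuple(labels), x)


def _ewm_oracle(x, eps=1e-10):
    """Independent step-by-step re-evaluation with math.fsum accumulation."""
    m, n = len(x), len(x[0])
    colsums = [math.fsum(row[j] for row in x) for j in range(n)]
    p = [[(x[i][j] / colsums[j]) or eps for j in range(n)] for i in range(m)]
    k = 1.0 / math.log(m)
    H = [-k * math.fsum(p[i][j] * math.log(p[i][j]) for i in range(m))
         for j in range(n)]
    dsum = math.fsum(1.0 - h for h in H)
    return [(1.0 - h) / dsum for h in H]


class TestEntropyWeights:
    def test_inattention_weights_round_to_published_values(self, table5):
        w = ss.entropy_weights(table5)
        assert tuple(np.round(w.w, 2)) == (0.35, 0.16, 0.49)

    def test_hyperactivity_weights_round_to_published_values(self, table6):
        w = ss.entropy_weights(table6)
        assert tuple(np.round(w.w, 2)) == (0.21, 0.04, 0.75)

    def test_uniform_column_has_unit_entropy_and_zero_weight(self):
        x = np.column_stack([np.full(10, 0.5),
                             np.linspace(0.05, 0.95, 10),
                             np.linspace(0.05, 0.95, 10) ** 3])
        w = ss.entropy_weights(_table(x))
        assert w.H[0] == pytest.approx(1.0)
        assert w.w[0] == pytest.approx(0.0, abs=1e-12)

    def test_weights_sum_to_one_and_entropy_in_unit_interval(self, table5, table6):
        for table in (table5, table6):
            w = ss.entropy_weights(table)
            assert w.w.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all((w.H >= 0) & (w.H <= 1 + 1e-9))
            assert w.k == pytest.approx(1 / np.log(36))

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            ss.entropy_weights(_table([[0.1, 0.2, 0.3]]))

    def test_all_zero_column_rejected(self):
        x = np.column_stack([np.zeros(5), np.linspace(0.1, 0.5, 5),
                             np.linspace(0.2, 0.6, 5)])
        with pytest.raises(ValueError):
            ss.entropy_weights(_table(x))

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(2, 30), st.integers(0, 2**31 - 1))
    def test_agrees_with_high_precision_oracle(self, m, seed):
        x = np.random.default_rng(seed).uniform(0.01, 1.0, size=(m, 3))
        w = ss.entropy_weights(_table(x))
        np.testing.assert_allclose(w.w, _ewm_oracle(x.tolist()), atol=1e-12)

    def test_column_scaling_leaves_weights_unchanged(self, table5):
        w0 = ss.entropy_weights(table5)
        x = table5.x.copy()
        x[:, 1] *= 7.3
        w1 = ss.entropy_weights(_table(x, table5.pair_labels))
        np.testing.assert_allclose(w0.w, w1.w, atol=1e-12)


class TestCombinedScores:
    def test_published_pair_scores_round_to_two_decimals(self, table5, table6):
        w5 = ss.entropy_weights(table5)
        c5 = ss.combined_scores(table5, w5)
        assert round(c5[table5.pair_labels.index((2, 5))], 2) == 0.62
        assert round(c5[table5.pair_labels.index((5, 7))], 2) == 0.58
        w6 = ss.entropy_weights(table6)
        c6 = ss.combined_scores(table6, w6)
        assert round(c6[table6.pair_labels.index((1, 2))], 2) == 0.49

    def test_degenerate_weights_recover_a_single_column(self, table5):
        w = ss.EntropyWeights(k=1.0, H=np.array([0.0, 1.0, 1.0]),
                              d=np.array([1.0, 0.0, 0.0]),
                              w=np.array([1.0, 0.0, 0.0]))
        np.testing.assert_allclose(
            ss.combined_scores(table5, w), table5.column("lexical")
        )

    def test_uniform_weights_average_row(self):
        table = _table([[0.2, 0.4, 0.6], [0.1, 0.1, 0.1]])
        w = ss.EntropyWeights(k=1.0, H=np.zeros(3), d=np.ones(3),
                              w=np.full(3, 1 / 3))
        np.testing.assert_allclose(ss.combined_scores(table, w), [0.4, 0.1])

    def test_convex_combination_bounds(self, table5, table6):
        for table in (table5, table6):
            w = ss.entropy_weights(table)
            c = ss.combined_scores(table, w)
            assert np.all(c >= table.x.min(axis=1) - 1e-12)
            assert np.all(c <= table.x.max(axis=1) + 1e-12)


class TestPercentileCutoff:
    def test_inattention_selection_reproduces_published_pairs(self, table5):
        _, _, thr = ss.redundant_pairs(table5)
        assert round(thr.cutoff, 2) == 0.61
        assert set(thr.selected) == {(2, 5), (5, 7)}

    def test_hyperactivity_selection_reproduces_published_pair(self, table6):
        _, _, thr = ss.redundant_pairs(table6)
        assert set(thr.selected) == {(1, 2)}

    def test_semantic_layer_selections(self, table5, table6):
        thr5 = ss.percentile_cutoff(table5.column("semantic"), 99, 0.03,
                                    labels=table5.pair_labels)
        assert round(thr5.cutoff, 2) == 0.65
        assert set(thr5.selected) == {(1, 4), (2, 5), (4, 5), (5, 7)}
        thr6 = ss.percentile_cutoff(table6.column("semantic"), 99, 0.03,
                                    labels=table6.pair_labels)
        assert round(thr6.cutoff, 2) == 0.47
        assert set(thr6.selected) == {(1, 2)}

    def test_constant_scores_select_everything(self):
        thr = ss.percentile_cutoff([0.4] * 6, 99, 0.03)
        assert thr.cutoff == pytest.approx(0.4)
        assert len(thr.selected) == 6

    @pytest.mark.parametrize("p", [0.0, 100.0, -5.0, 120.0])
    def test_percentile_outside_open_interval_rejected(self, p):
        with pytest.raises(ValueError):
            ss.percentile_cutoff([0.1, 0.2], p, 0.03)

    def test_selection_never_empty(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            scores = rng.random(rng.integers(2, 50))
            thr = ss.percentile_cutoff(scores, 99, 0.0)
            assert len(thr.selected) >= 1
            assert scores.min() <= thr.cutoff <= scores.max()
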