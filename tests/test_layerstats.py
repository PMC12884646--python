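"""Layer validation statistics: Wilcoxon, mutual information, chi-square."""

import itertools

import numpy as np
import pytest
from scipy import stats

import symscreen as ss
from symscreen.layerstats import DegenerateSampleError, layer_comparison_report


def _wilcoxon_oracle(x, y):
    """Rank-based statistic plus exact two-sided p by full sign enumeration."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    wplus = ranks[d > 0].sum()
    wminus = ranks[d < 0].sum()
    dist = np.array(
        [
            sum(r for s, r in zip(signs, ranks) if s)
            for signs in itertools.product([0, 1], repeat=len(d))
        ]
    )
    p = min(2 * min((dist <= wplus).mean(), (dist >= wplus).mean()), 1.0)
    return min(wplus, wminus), p


class TestWilcoxon:
    def test_semantic_vs_lexical_statistic_on_inattention_table(self, table5):
        res = ss.wilcoxon_paired(table5.column("semantic"), table5.column("lexical"))
        assert res.statistic == 141.0
        assert res.p_value == pytest.approx(0.002, abs=1e-3)
        assert res.n == 36

    def test_all_four_domain_layer_statistics(self, table5, table6):
        expected = {
            ("inattention", "lexical"): 141.0,
            ("inattention", "syntactic"): 79.0,
            ("hyperactivity", "lexical"): 88.0,
            ("hyperactivity", "syntactic"): 86.0,
        }
        tables = {"inattention": table5, "hyperactivity": table6}
        for (domain, layer), want in expected.items():
            table = tables[domain]
            res = ss.wilcoxon_paired(table.column("semantic"), table.column(layer))
            assert res.statistic == want
            assert res.p_value < 0.05

    def test_identical_samples_are_degenerate(self):
        x = np.linspace(0.1, 0.9, 12)
        with pytest.raises(DegenerateSampleError):
            ss.wilcoxon_paired(x, x)

    def test_toy_differences_rank_sum(self):
        # differences (1,-2,3,-4,5,6): negative ranks 2 and 4 sum to 6
        y = np.zeros(6)
        x = np.array([1.0, -2.0, 3.0, -4.0, 5.0, 6.0])
        res = ss.wilcoxon_paired(x, y)
        assert res.statistic == 6.0
        stat, p = _wilcoxon_oracle(x, y)
        assert res.statistic == stat
        assert res.p_value == pytest.approx(p)

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_exact_enumeration_for_small_samples(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 9))
        x = np.round(rng.normal(0.5, 0.2, n), 3)
        y = np.round(rng.normal(0.5, 0.2, n), 3)
        d = np.abs(x - y)
        if np.any(d == 0) or len(set(d[d > 0])) < np.count_nonzero(d):
            x = x + np.linspace(0.0011, 0.0017, n)  # break zeros/ties
        res = ss.wilcoxon_paired(x, y)
        stat, p = _wilcoxon_oracle(x, y)
        assert res.statistic == stat
        assert res.p_value == pytest.approx(p)

    def test_zero_differences_dropped_from_n(self):
        x = np.array([0.5, 0.6, 0.7, 0.8, 0.9, 0.3])
        y = x.copy()
        y[0] += 0.1
        y[1] -= 0.2
        y[2] += 0.05
        res = ss.wilcoxon_paired(x, y)
        assert res.n == 3


class TestMutualInfo:
    def test_hyperactivity_syntactic_vs_semantic_is_zero(self, table6):
        mi = ss.mutual_info(table6.column("syntactic"), table6.column("semantic"),
                            seed=0)
        assert mi == pytest.approx(0.0, abs=1e-9)

    def test_self_dependence_is_large(self, table5):
        x = table5.column("semantic")
        assert ss.mutual_info(x, x, seed=0) > 0.5

    def test_independent_uniforms_near_zero(self):
        rng = np.random.default_rng(11)
        x, y = rng.random(200), rng.random(200)
        assert ss.mutual_info(x, y, seed=0) <= 0.05

    def test_monotone_in_dependence_strength(self):
        rng = np.random.default_rng(4)
        x = rng.random(300)
        noise = rng.normal(0, 1, 300)
        estimates = [
            ss.mutual_info(x, x + sd * noise, seed=0) for sd in (1.0, 0.3, 0.05)
        ]
        assert estimates[0] < estimates[1] < estimates[2]

    def test_constant_input_returns_zero(self):
        assert ss.mutual_info(np.full(20, 0.5), np.linspace(0, 1, 20)) == 0.0

    def test_seeded_reproducibility(self, table5):
        a = ss.mutual_info(table5.column("lexical"), table5.column("semantic"), seed=7)
        b = ss.mutual_info(table5.column("lexical"), table5.column("semantic"), seed=7)
        assert a == b


class TestChiSquare:
    def test_published_training_imbalance(self):
        stat, p = ss.chi_square_balance(18, 32)
        assert stat == pytest.approx(3.920, abs=1e-3)
        assert p == pytest.approx(0.048, abs=1e-3)

    def test_balanced_counts_give_zero(self):
        stat, p = ss.chi_square_balance(25, 25)
        assert stat == 0.0
        assert p == 1.0

    def test_hand_computed_value(self):
        stat, _ = ss.chi_square_balance(10, 30)
        assert stat == pytest.approx(10.0)

    @pytest.mark.parametrize("a,b", [(3, 9), (18, 32), (1, 1), (100, 40)])
    def test_closed_form_identity(self, a, b):
        stat, _ = ss.chi_square_balance(a, b)
        assert stat == pytest.approx((a - b) ** 2 / (a + b))

    def test_double_zero_rejected(self):
        with pytest.raises(ValueError):
            ss.chi_square_balance(0, 0)


def test_layer_comparison_report_shape(table5, table6):
    report = layer_comparison_report(
        {"inattention": table5, "hyperactivity_impulsivity": table6}, seed=0
    )
    assert set(report) == {"inattention", "hyperactivity_impulsivity"}
    for rows in report.values():
        assert set(rows) == {"semantic_vs_lexical", "semantic_vs_syntactic"}
        for cell in rows.values():
            assert cell["wilcoxon_p"] <= 1.0
            assert cell["mutual_information"] >= 0.0
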