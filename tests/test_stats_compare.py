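import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nicheshift.stats_compare import (
    chi_squared_counts,
    dunn_posthoc,
    kendall_tau,
    kruskal_wallis,
    occurrence_sensitivity,
)
from oracles import chi_squared_oracle, dunn_z_oracle, kendall_tau_b_oracle, kruskal_wallis_oracle


class TestKruskalWallis:
    def test_matches_rank_formula_oracle(self):
        a, b = np.array([1.0, 2, 3]), np.array([10.0, 20, 30])
        rep = kruskal_wallis(np.r_[a, b], ["g1"] * 3 + ["g2"] * 3)
        assert rep.statistic == pytest.approx(kruskal_wallis_oracle([a, b]), abs=1e-9)
        assert rep.df == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_equivalence_with_ties_small_n(self, seed):
        r = np.random.default_rng(seed)
        a = r.integers(0, 5, size=4).astype(float)
        b = r.integers(0, 5, size=3).astype(float)
        c = r.integers(0, 5, size=3).astype(float)
        if len(np.unique(np.r_[a, b, c])) == 1:
            pytest.skip("degenerate draw: all values tied")
        rep = kruskal_wallis(np.r_[a, b, c], ["a"] * 4 + ["b"] * 3 + ["c"] * 3)
        assert rep.statistic == pytest.approx(
            kruskal_wallis_oracle([a, b, c]), abs=1e-9
        )

    def test_identical_groups_h_zero_p_one(self):
        rep = kruskal_wallis([5.0, 5, 5, 5], ["a", "a", "b", "b"])
        assert rep.statistic == 0.0 and rep.p == 1.0

    def test_null_calibration(self):
        r = np.random.default_rng(0)
        rej = 0
        trials = 500
        for _ in range(trials):
            v = r.normal(size=30)
            rep = kruskal_wallis(v, ["a"] * 15 + ["b"] * 15)
            rej += rep.p < 0.05
        assert 0.02 <= rej / trials <= 0.08

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2 groups"):
            kruskal_wallis([1.0, 2.0], ["a", "a"])


class TestChiSquared:
    def test_perfect_independence_zero(self):
        rep = chi_squared_counts([[10, 10], [10, 10]])
        assert rep.statistic == pytest.approx(0.0)

    def test_matches_margin_oracle(self):
        T = [[30, 10], [10, 30]]
        rep = chi_squared_counts(T)
        x2, df = chi_squared_oracle(np.array(T))
        assert rep.statistic == pytest.approx(x2, abs=1e-9)
        assert rep.df == df

    def test_df_for_2x3(self):
        rep = chi_squared_counts([[5, 6, 7], [8, 9, 10]])
        assert rep.df == 2

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_squared_counts([[0, 0], [5, 5]])


class TestDunn:
    def test_matches_pooled_rank_oracle(self):
        r = np.random.default_rng(1)
        samples = {
            "a": r.integers(0, 8, 6).astype(float),
            "b": r.integers(0, 8, 5).astype(float),
            "c": r.integers(0, 8, 7).astype(float),
        }
        values = np.concatenate(list(samples.values()))
        groups = sum([[g] * len(v) for g, v in samples.items()], [])
        rep = dunn_posthoc(values, groups)
        zs = dunn_z_oracle(samples)
        for _, row in rep.pairwise.iterrows():
            assert row["z"] == pytest.approx(zs[(row["group_a"], row["group_b"])], abs=1e-9)

    def test_shifted_group_detected(self):
        r = np.random.default_rng(2)
        a = r.normal(0, 1, 30)
        b = r.normal(0, 1, 30)
        c = r.normal(8, 1, 30)
        rep = dunn_posthoc(np.r_[a, b, c], ["a"] * 30 + ["b"] * 30 + ["c"] * 30)
        pw = rep.pairwise.set_index(["group_a", "group_b"])
        assert pw.loc[("a", "c"), "p_adj"] < 0.05
        assert pw.loc[("b", "c"), "p_adj"] < 0.05
        assert pw.loc[("a", "b"), "p_adj"] > 0.05

    def test_adjusted_never_below_raw(self):
        r = np.random.default_rng(3)
        v = r.normal(size=24)
        rep = dunn_posthoc(v, ["a", "b", "c"] * 8)
        assert (rep.pairwise["p_adj"] >= rep.pairwise["p"] - 1e-15).all()

    def test_fewer_than_three_groups_rejected(self):
        with pytest.raises(ValueError, match="3 groups"):
            dunn_posthoc([1.0, 2, 3, 4], ["a", "a", "b", "b"])


class TestKendall:
    def test_perfect_concordance(self):
        assert kendall_tau([1, 2, 3, 4], [10, 20, 30, 40]).statistic == pytest.approx(1.0)

    def test_perfect_reversal(self):
        assert kendall_tau([1, 2, 3], [3, 2, 1]).statistic == pytest.approx(-1.0)

    def test_hand_counted_two_thirds(self):
        rep = kendall_tau([1, 2, 3, 4], [1, 3, 2, 4])
        assert rep.statistic == pytest.approx(2 / 3)

    @pytest.mark.parametrize("seed", range(5))
    def test_tau_b_matches_pair_enumeration_with_ties(self, seed):
        r = np.random.default_rng(seed)
        x = r.integers(0, 4, 8).astype(float)
        y = r.integers(0, 4, 8).astype(float)
        if len(np.unique(x)) == 1 or len(np.unique(y)) == 1:
            pytest.skip("degenerate draw")
        rep = kendall_tau(x, y)
        assert rep.statistic == pytest.approx(kendall_tau_b_oracle(x, y), abs=1e-9)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            kendall_tau([1, 1, 1], [1, 2, 3])


class TestOccurrenceSensitivity:
    def _table(self, n, rng, dependent=False):
        n_native = rng.integers(20, 500, size=n)
        D = stats.rankdata(n_native) / n if dependent else rng.uniform(0, 1, n)
        return pd.DataFrame(
            {
                "n_native": n_native,
                "D": D,
                "expansion_class": rng.choice(["low", "high"], n),
            }
        )

    def test_independent_metrics_rarely_flagged(self):
        rng = np.random.default_rng(4)
        clean = 0
        trials = 100
        for _ in range(trials):
            qc = occurrence_sensitivity(self._table(40, rng))
            clean += qc["d_vs_n_native"]["p"] > 0.05
        assert clean / trials >= 0.90

    def test_forced_concordance_detected(self):
        rng = np.random.default_rng(5)
        qc = occurrence_sensitivity(self._table(30, rng, dependent=True))
        assert qc["d_vs_n_native"]["statistic"] == pytest.approx(1.0)

    def test_single_species_not_computable(self):
        t = pd.DataFrame({"n_native": [50], "D": [0.4], "expansion_class": ["low"]})
        qc = occurrence_sensitivity(t)
        assert qc["computable"] is False
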