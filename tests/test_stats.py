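"""Distribution tests, DE caller and modulation summaries against
independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import aneuplex as ax
from aneuplex import ConfigurationError, DataQualityWarning
from conftest import simulate_scenario


def brute_force_ks_d(x, y):
    """Oracle: max |ECDF_x(t) - ECDF_y(t)| scanned point by point."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    best = 0.0
    for t in np.concatenate([x, y]):
        d = abs((x <= t).mean() - (y <= t).mean())
        best = max(best, d)
    return best


class TestKsTwoSample:
    def test_identical_samples_give_zero_d(self):
        res = ax.ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_disjoint_samples_give_d_one(self):
        res = ax.ks_two_sample([1, 2, 3], [4, 5, 6])
        assert res.statistic == 1.0

    def test_d_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            n, m = rng.integers(1, 100, 2)
            x = rng.normal(0, 1, n)
            y = rng.normal(rng.uniform(-1, 1), 1, m)
            if rng.random() < 0.3:  # inject ties
                y = np.round(y, 1)
                x = np.round(x, 1)
            res = ax.ks_two_sample(x, y)
            assert res.statistic == pytest.approx(brute_force_ks_d(x, y), abs=1e-12)

    def test_d_matches_scipy(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 80), rng.normal(0.3, 1.2, 60)
        res = ax.ks_two_sample(x, y)
        ref = sps.ks_2samp(x, y)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)

    def test_p_agrees_with_permutation_estimate(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0.0, 1.0, 60)
        y = rng.normal(0.35, 1.0, 60)
        res = ax.ks_two_sample(x, y)
        pooled = np.concatenate([x, y])
        stat = res.statistic
        hits = 0
        n_perm = 5000
        for _ in range(n_perm):
            rng.shuffle(pooled)
            if brute_force_ks_d(pooled[:60], pooled[60:]) >= stat - 1e-12:
                hits += 1
        p_perm = hits / n_perm
        # asymptotic vs permutation: small-sample bias + Monte-Carlo error
        assert res.p_value == pytest.approx(p_perm, abs=0.05)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ax.ks_two_sample([], [1.0])


class TestBartlett:
    def test_identical_groups_give_zero_statistic(self):
        g = [1.0, 2.0, 3.0, 4.0]
        res = ax.bartlett_test(g, list(g))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_statistic_matches_hand_formula(self):
        groups = [np.array([1.0, 2.0, 3.0, 4.0]), np.array([2.0, 4.0, 6.0, 8.0])]
        k = 2
        n_i = np.array([4, 4])
        big_n = 8
        s2 = np.array([np.var(g, ddof=1) for g in groups])
        sp2 = ((n_i - 1) * s2).sum() / (big_n - k)
        num = (big_n - k) * np.log(sp2) - ((n_i - 1) * np.log(s2)).sum()
        corr = 1 + ((1 / (n_i - 1)).sum() - 1 / (big_n - k)) / (3 * (k - 1))
        expected = num / corr
        res = ax.bartlett_test(*groups)
        assert res.statistic == pytest.approx(expected, rel=1e-12)
        assert res.p_value == pytest.approx(sps.chi2.sf(expected, k - 1), rel=1e-12)

    def test_location_invariance(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 10), rng.normal(0, 3, 12)
        base = ax.bartlett_test(a, b)
        shifted = ax.bartlett_test(a + 100.0, b + 100.0)
        assert shifted.statistic == pytest.approx(base.statistic, rel=1e-9)

    def test_scale_covariance_matches_formula(self):
        # multiplying one group by c changes its variance by c^2; the
        # statistic must track the formula evaluated directly.
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 9), rng.normal(0, 1, 11)
        c = 2.5
        res = ax.bartlett_test(a, b * c)
        ref_stat, _ = sps.bartlett(a, b * c)
        assert res.statistic == pytest.approx(ref_stat, rel=1e-12)
        assert res.statistic > ax.bartlett_test(a, b).statistic

    def test_zero_variance_group_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            ax.bartlett_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            ax.bartlett_test([1.0, 2.0])


class TestBenjaminiHochberg:
    def test_step_up_matches_hand_computation(self):
        # sorted p * n/i: 0.04, 0.04, 0.0533, 0.5 -> monotone from the back.
        # Step-up at FDR 0.05: largest i with p_(i) <= i/n * 0.05 is i=2
        # (0.02 <= 0.025; 0.04 > 0.0375), so exactly two discoveries.
        q = ax.adjust_bh([0.01, 0.02, 0.04, 0.5])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.16 / 3, 0.5], rtol=1e-12)
        assert (q[:2] <= 0.05 + 1e-15).all()
        assert (q[2:] > 0.05).all()

    def test_q_dominates_p_and_is_monotone(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0, 1, 200)
        q = ax.adjust_bh(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestCallDe:
    def test_identical_groups_yield_zero_calls(self):
        # noiseless identical groups across 1000 genes: no false positives
        rng = np.random.default_rng(2)
        vals = rng.lognormal(3, 1, 1000)
        df = pd.DataFrame(
            {f"a{i}": vals for i in range(3)} | {f"c{i}": vals for i in range(3)},
            index=[f"g{i}" for i in range(1000)],
        )
        sheet = pd.DataFrame(
            {"group": ["aneuploid"] * 3 + ["control"] * 3, "replicate": [1, 2, 3] * 2},
            index=pd.Index([f"a{i}" for i in range(3)] + [f"c{i}" for i in range(3)],
                           name="sample_id"),
        )
        calls = ax.call_de(ax.CountMatrix(df, sheet))
        assert (calls["call"] == "ns").all()

    def test_strong_fold_change_called_with_correct_sign(self):
        rng = np.random.default_rng(7)
        base = np.full(50, 100.0)
        rows = {}
        for i in range(4):
            rows[f"a{i}"] = base * (1 + rng.normal(0, 0.01, 50))
            rows[f"c{i}"] = base * (1 + rng.normal(0, 0.01, 50))
        df = pd.DataFrame(rows, index=[f"g{i}" for i in range(50)])
        df.loc["g0", [f"a{i}" for i in range(4)]] *= 8.0   # 8-fold up
        df.loc["g1", [f"a{i}" for i in range(4)]] /= 8.0   # 8-fold down
        sheet = pd.DataFrame(
            {"group": ["aneuploid", "control"] * 4,
             "replicate": [1, 1, 2, 2, 3, 3, 4, 4]},
            index=pd.Index(list(rows), name="sample_id"),
        )
        calls = ax.call_de(ax.CountMatrix(df, sheet))
        assert calls.loc["g0", "call"] == "up"
        assert calls.loc["g1", "call"] == "down"
        # call/sign contract holds everywhere
        assert (calls.loc[calls["call"] == "up", "lfc"] > 0).all()
        assert (calls.loc[calls["call"] == "down", "lfc"] < 0).all()

    def test_single_replicate_warns_and_calls_ns(self):
        df = pd.DataFrame({"a1": [1.0, 100.0], "c1": [100.0, 1.0]}, index=["g0", "g1"])
        sheet = pd.DataFrame(
            {"group": ["aneuploid", "control"], "replicate": [1, 1]},
            index=pd.Index(["a1", "c1"], name="sample_id"),
        )
        with pytest.warns(DataQualityWarning, match="fewer than two replicates"):
            calls = ax.call_de(ax.CountMatrix(df, sheet))
        assert (calls["call"] == "ns").all()


class TestSummarizeModulation:
    def _inputs(self, n_cis=200, n_de_cis=40, n_trans=300, n_su=30, n_sd=15):
        genes = [f"g{i}" for i in range(n_cis + n_trans)]
        partition = pd.Series(
            ["cis:3L"] * n_cis + ["trans"] * n_trans, index=genes, name="partition"
        )
        call = (["up"] * n_de_cis + ["ns"] * (n_cis - n_de_cis)
                + ["up"] * n_su + ["down"] * n_sd + ["ns"] * (n_trans - n_su - n_sd))
        calls = pd.DataFrame({"call": call}, index=genes)
        return calls, partition

    def test_percentages_match_hand_arithmetic(self):
        calls, partition = self._inputs()
        s = ax.summarize_modulation(calls, partition)
        assert s.cis["3L"]["pct_unchanged"] == pytest.approx(80.0)
        assert s.trans["pct_su"] == pytest.approx(10.0)
        assert s.trans["pct_sd"] == pytest.approx(5.0)
        assert s.trans["pct_de"] == pytest.approx(s.trans["pct_su"] + s.trans["pct_sd"])

    def test_no_de_calls_give_100pct_unchanged(self):
        calls, partition = self._inputs(n_de_cis=0, n_su=0, n_sd=0)
        s = ax.summarize_modulation(calls, partition)
        assert s.cis["3L"]["pct_unchanged"] == 100.0
        assert s.trans["pct_su"] == 0.0
        assert s.trans["pct_sd"] == 0.0

    def test_percentages_recompute_from_counts(self):
        calls, partition = self._inputs(n_de_cis=13, n_su=7, n_sd=21)
        s = ax.summarize_modulation(calls, partition)
        c = s.cis["3L"]
        assert c["pct_unchanged"] == pytest.approx(100.0 * (c["n"] - c["n_de"]) / c["n"])
        t = s.trans
        assert t["pct_de"] == pytest.approx(100.0 * (t["n_su"] + t["n_sd"]) / t["n"])

    def test_empty_partition_rejected(self):
        calls, partition = self._inputs()
        with pytest.raises(ConfigurationError):
            ax.summarize_modulation(calls, partition.replace("trans", "cis:3L"))
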