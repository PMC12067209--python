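"""The ratio-distribution pipeline: RPKM, averaging, filtering, binning,
medians, scatter tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import aneuplex as ax
from aneuplex import ConfigurationError
from conftest import simulate_scenario


def _matrix(values: dict, groups: dict) -> ax.CountMatrix:
    df = pd.DataFrame(values, index=[f"g{i}" for i in range(len(next(iter(values.values()))))])
    sheet = pd.DataFrame(
        {"group": [g for g, _ in groups.values()], "replicate": [r for _, r in groups.values()]},
        index=pd.Index(groups.keys(), name="sample_id"),
    )
    return ax.CountMatrix(df, sheet)


class TestNormalizeRpkm:
    def test_formula(self):
        m = _matrix({"a1": [100.0], "c1": [100.0]},
                    {"a1": ("aneuploid", 1), "c1": ("control", 1)})
        lengths = pd.Series([1000.0], index=m.gene_ids)
        libs = pd.Series([1e6, 1e6], index=["a1", "c1"])
        out = ax.normalize_rpkm(m, lengths, libs)
        assert out.values.loc["g0", "a1"] == pytest.approx(100.0)

    def test_doubling_library_halves_values(self):
        m = _matrix({"a1": [10.0, 30.0], "c1": [10.0, 30.0]},
                    {"a1": ("aneuploid", 1), "c1": ("control", 1)})
        lengths = pd.Series([500.0, 800.0], index=m.gene_ids)
        one = ax.normalize_rpkm(m, lengths, pd.Series([1e6, 1e6], index=["a1", "c1"]))
        two = ax.normalize_rpkm(m, lengths, pd.Series([2e6, 2e6], index=["a1", "c1"]))
        np.testing.assert_allclose(two.values, one.values / 2)

    def test_zero_raw_count_stays_zero(self):
        m = _matrix({"a1": [0.0], "c1": [5.0]},
                    {"a1": ("aneuploid", 1), "c1": ("control", 1)})
        out = ax.normalize_rpkm(m, pd.Series([1000.0], index=m.gene_ids),
                                pd.Series([1e6, 1e6], index=["a1", "c1"]))
        assert out.values.loc["g0", "a1"] == 0.0

    def test_zero_library_size_rejected(self):
        m = _matrix({"a1": [1.0], "c1": [1.0]},
                    {"a1": ("aneuploid", 1), "c1": ("control", 1)})
        with pytest.raises(ConfigurationError, match="library sizes"):
            ax.normalize_rpkm(m, pd.Series([1000.0], index=m.gene_ids),
                              pd.Series([0.0, 1e6], index=["a1", "c1"]))


class TestAverageAndFilter:
    def test_replicate_means_match_hand_arithmetic(self):
        m = _matrix(
            {"a1": [1.0, 10.0], "a2": [3.0, 20.0], "a3": [5.0, 30.0], "c1": [2.0, 5.0]},
            {"a1": ("aneuploid", 1), "a2": ("aneuploid", 2), "a3": ("aneuploid", 3),
             "c1": ("control", 1)},
        )
        means = ax.average_replicates(m)
        np.testing.assert_allclose(means["mean_aneuploid"], [3.0, 20.0])
        np.testing.assert_allclose(means["mean_control"], [2.0, 5.0])

    @pytest.mark.parametrize(
        "ma,mc,kept",
        [
            (0.4, 0.5, False),  # sum 0.9 < 1 -> lowly expressed, removed
            (0.5, 0.5, True),   # sum exactly 1 -> retained (strict <1 removes)
            (0.0, 0.0, False),
            (15.0, 10.0, True),
        ],
    )
    def test_low_expression_boundary(self, ma, mc, kept):
        means = pd.DataFrame({"mean_aneuploid": [ma], "mean_control": [mc]}, index=["g"])
        retained = ax.filter_low_expression(means, threshold=1.0)
        assert ("g" in retained) is kept


class TestComputeRatios:
    def test_plain_ratios(self):
        means = pd.DataFrame(
            {"mean_aneuploid": [15.0, 7.0], "mean_control": [10.0, 7.0]}, index=["a", "b"]
        )
        out = ax.compute_ratios(means)
        np.testing.assert_allclose(out["ratio"], [1.5, 1.0])
        assert out["finite"].all()

    def test_zero_control_flagged_not_dropped(self):
        means = pd.DataFrame(
            {"mean_aneuploid": [2.0, 1.0], "mean_control": [0.0, 1.0]}, index=["a", "b"]
        )
        out = ax.compute_ratios(means)
        assert not out.loc["a", "finite"]
        assert np.isinf(out.loc["a", "ratio"])
        # excluded from the median, pooled into the overflow bin
        assert ax.median_ratio(out["ratio"]) == pytest.approx(1.0)
        dist = ax.bin_ratios(out["ratio"].to_numpy(), cap=3.0)
        assert dist.overflow == 1
        assert dist.total == 2


class TestBinning:
    def test_half_open_bin_assignment(self):
        dist = ax.bin_ratios([1.02, 1.05], width=0.05, cap=3.0)
        left_102 = int(np.floor(1.02 / 0.05))
        assert dist.counts[left_102] == 1          # 1.02 in [1.00, 1.05)
        assert dist.counts[left_102 + 1] == 1      # 1.05 in [1.05, 1.10)
        assert dist.edges[left_102] == pytest.approx(1.00)

    def test_cap_pools_overflow(self):
        dist = ax.bin_ratios([0.1, 2.99, 3.0, 17.0, np.inf], width=0.05, cap=3.0)
        assert dist.overflow == 3
        assert dist.total == 5

    @given(st.lists(st.floats(0.0, 10.0), min_size=1, max_size=200))
    @settings(max_examples=60, derandomize=True)
    def test_binning_conserves_counts(self, ratios):
        dist = ax.bin_ratios(ratios, width=0.05, cap=3.0)
        assert dist.total == len(ratios)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            ax.bin_ratios([1.0], width=0.0)

    def test_to_frame_schema(self):
        frame = ax.bin_ratios([0.2, 4.0], partition="trans").to_frame()
        assert list(frame.columns) == ["bin_left", "bin_right", "count", "partition"]
        assert np.isinf(frame["bin_right"].iloc[-1])
        assert frame["count"].sum() == 2


class TestMedian:
    def test_odd_n(self):
        assert ax.median_ratio([1.4, 1.6, 1.5]) == pytest.approx(1.5)

    def test_even_n_mean_of_central_pair(self):
        assert ax.median_ratio([1.0, 2.0]) == pytest.approx(1.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ax.median_ratio([])

    def test_median_invariant_to_bin_width(self):
        rng = np.random.default_rng(0)
        ratios = rng.lognormal(0, 0.3, 500)
        # binning is a display step: the median never passes through it
        m = ax.median_ratio(ratios)
        for width in (0.01, 0.05, 0.25):
            ax.bin_ratios(ratios, width=width)
            assert ax.median_ratio(ratios) == m


class TestEndToEnd:
    def test_noiseless_ratio_table_matches_compositional_closed_form(self):
        genome, genotype, asn, sim = simulate_scenario(
            {"3L": 3}, {"dosage_effect": 1.0}, {"inverse": 1.0}, n_genes=600, seed=23
        )
        table = ax.ratio_table(sim.matrix, genome, genotype)
        expected = asn.expected_ratios.loc[table.index] / sim.size_factor
        np.testing.assert_allclose(table["ratio"], expected, rtol=1e-10)

    def test_size_correction_recovers_true_ratios(self):
        # Multiplying the relative ratios by the true size factor yields
        # each gene's absolute (per-genome) response exactly.
        genome, genotype, asn, sim = simulate_scenario(
            {"3L": 3}, {"compensation": 1.0}, {"inverse": 1.0}, n_genes=600, seed=29
        )
        table = ax.ratio_table(sim.matrix, genome, genotype)
        absolute = table["ratio"] * sim.size_factor
        np.testing.assert_allclose(
            absolute, asn.expected_ratios.loc[table.index], rtol=1e-10
        )
        trans_med = ax.median_ratio(absolute[table["partition"] == "trans"])
        assert trans_med == pytest.approx(2 / 3, rel=1e-10)

    def test_partition_counts_conserved(self):
        genome, genotype, _, sim = simulate_scenario(
            {"3L": 1, "4L": 3}, {"dosage_effect": 1.0}, {"no_change": 1.0},
            n_genes=600, seed=31,
        )
        table = ax.ratio_table(sim.matrix, genome, genotype)
        counts = table["partition"].value_counts()
        assert counts.sum() == len(table)
        assert set(counts.index) == {"cis:3L", "cis:4L", "trans"}


class TestScatterTable:
    def test_log2_fold_change_values(self):
        means = pd.DataFrame(
            {"mean_aneuploid": [20.0, 7.0], "mean_control": [10.0, 7.0]}, index=["a", "b"]
        )
        calls = pd.DataFrame({"call": ["up", "ns"]}, index=["a", "b"])
        out = ax.scatter_table(means, calls)
        assert out.loc["a", "log2_fold_change"] == pytest.approx(1.0)
        assert out.loc["b", "log2_fold_change"] == pytest.approx(0.0)
        assert out.loc["a", "mean_expression"] == pytest.approx(15.0)
        assert out.attrs["reference_ratios"] == (0.5, 0.67, 1.0, 1.5, 2.0)

    def test_class_counts_match_de_caller(self):
        rng = np.random.default_rng(4)
        n = 50
        means = pd.DataFrame(
            {"mean_aneuploid": rng.uniform(1, 10, n), "mean_control": rng.uniform(1, 10, n)},
            index=[f"g{i}" for i in range(n)],
        )
        calls = pd.DataFrame(
            {"call": rng.choice(["up", "down", "ns"], n)}, index=means.index
        )
        out = ax.scatter_table(means, calls)
        assert out["call"].value_counts().to_dict() == calls["call"].value_counts().to_dict()

    def test_nonfinite_rows_flagged(self):
        means = pd.DataFrame(
            {"mean_aneuploid": [2.0], "mean_control": [0.0]}, index=["a"]
        )
        calls = pd.DataFrame({"call": ["ns"]}, index=["a"])
        out = ax.scatter_table(means, calls)
        assert not out["finite"].iloc[0]
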