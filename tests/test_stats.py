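"""Outlier rejection, the methylation statistic, and bootstrap inference."""

import io as std_io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import thompson_tau_oracle
from cometmeth import (
    ConfigurationError,
    DomainError,
    InferenceError,
    MethylationModel,
    ParameterError,
    SimulationParams,
    TreatmentGroups,
    UndefinedRatioError,
    compare_conditions,
    estimate_methylation,
    pct_cpg_methylation,
    simulate_cell_population,
    thompson_tau_filter,
)
from cometmeth.io import write_results
from cometmeth.stats import _tau_crit_table, _tau_filtered_mean, tau_critical


class TestThompsonTau:
    def test_tau_critical_matches_hand_computation(self):
        # n=5, alpha=0.05: t(0.975, 3)=3.1824 -> tau = 1.5712
        assert tau_critical(5, 0.05) == pytest.approx(1.5712, abs=2e-4)

    def test_identical_values_are_never_removed(self):
        kept, removed = thompson_tau_filter([10.0, 10.0, 10.0, 10.0])
        assert list(kept) == [10.0] * 4 and removed == []

    def test_single_gross_outlier_is_removed(self):
        kept, removed = thompson_tau_filter([9.8, 10.0, 10.2, 10.5, 35.0])
        assert removed == [4]
        assert list(kept) == [9.8, 10.0, 10.2, 10.5]

    def test_small_samples_warn_and_pass_through(self):
        with pytest.warns(UserWarning, match="n >= 3"):
            kept, removed = thompson_tau_filter([5.0, 50.0])
        assert list(kept) == [5.0, 50.0] and removed == []

    def test_retained_order_is_preserved(self):
        vals = [10.5, 9.8, 35.0, 10.0, 10.2]
        kept, removed = thompson_tau_filter(vals)
        assert removed == [2]
        assert list(kept) == [10.5, 9.8, 10.0, 10.2]

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ParameterError):
            thompson_tau_filter([1.0, 2.0, 3.0], alpha=1.5)

    def test_matches_brute_force_oracle_on_random_data(self, rng):
        for _ in range(500):
            n = int(rng.integers(3, 51))
            if rng.random() < 0.5:
                vals = rng.normal(50, 10, n)
            else:  # heavy-tailed: plenty of genuine outliers
                vals = rng.standard_cauchy(n) * 5 + 20
            kept, removed = thompson_tau_filter(vals, alpha=0.05)
            oracle_kept, oracle_removed = thompson_tau_oracle(vals)
            assert removed == oracle_removed
            assert np.allclose(kept, oracle_kept)

    def test_fast_sorted_path_matches_reference_filter(self, rng):
        for trial in range(200):
            n = int(rng.integers(3, 80))
            vals = (rng.integers(0, 12, n).astype(float) if trial % 2
                    else rng.normal(30, 8, n))
            kept, _ = thompson_tau_filter(vals)
            sv = np.sort(vals)
            fast = _tau_filtered_mean(
                sv.tolist(), float(sv.sum()), float(np.square(sv).sum()),
                _tau_crit_table(n, 0.05))
            assert fast == pytest.approx(kept.mean(), abs=1e-9)


class TestStatistic:
    @pytest.mark.parametrize("h, m, c, expected", [
        (50.0, 50.0, 0.0, 0.0),
        (40.0, 80.0, 5.0, 45.0),
        (25.0, 60.0, 3.0, 55.0 + 1.0 / 3.0),
        (0.0, 70.0, 0.0, 100.0),
    ])
    def test_hand_computed_values(self, h, m, c, expected):
        assert pct_cpg_methylation(h, m, c) == pytest.approx(expected)

    def test_zero_mspi_mean_is_an_undefined_ratio(self):
        with pytest.raises(UndefinedRatioError):
            pct_cpg_methylation(10.0, 0.0, 2.0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(DomainError):
            pct_cpg_methylation(-1.0, 50.0, 0.0)

    @given(st.floats(0.1, 100), st.floats(0.1, 100))
    @settings(deadline=None, derandomize=True)
    def test_identities(self, a, b):
        assert pct_cpg_methylation(a, a, 0.0) == pytest.approx(0.0)
        assert pct_cpg_methylation(0.0, b, 0.0) == pytest.approx(100.0)

    @given(st.floats(1, 99), st.floats(1, 99), st.floats(0, 50),
           st.floats(0.5, 10))
    @settings(deadline=None, derandomize=True)
    def test_monotone_in_each_enzyme_mean(self, h, m, c, step):
        base = pct_cpg_methylation(h, m, c)
        assert pct_cpg_methylation(h + step, m, c) < base
        assert pct_cpg_methylation(h, m + step, c) > base


class TestEstimate:
    def test_singleton_groups_have_degenerate_interval(self):
        res = estimate_methylation(
            TreatmentGroups(control=[0.0], hpaii=[30.0], mspi=[60.0]),
            n_boot=200, seed=0)
        assert res.pct_methylation == pytest.approx(50.0)
        assert res.conf_int() == (pytest.approx(50.0), pytest.approx(50.0))

    def test_zero_variance_groups_have_zero_width_interval(self):
        res = estimate_methylation(
            TreatmentGroups(control=[2.0] * 5, hpaii=[40.0] * 5,
                            mspi=[80.0] * 5),
            n_boot=500, seed=1)
        assert res.pct_methylation == pytest.approx(48.0)
        assert res.ci_high - res.ci_low == pytest.approx(0.0)

    def test_interval_brackets_bootstrap_median(self, toy_comet_df):
        res = MethylationModel.from_dataframe(toy_comet_df).fit(
            n_boot=500, seed=7)
        med = np.median(res.bootstrap_replicates)
        assert res.ci_low <= med <= res.ci_high

    def test_group_sizes_and_removals_reported(self, toy_comet_df):
        res = MethylationModel.from_dataframe(toy_comet_df).fit(
            n_boot=50, seed=0)
        assert (res.n_control, res.n_hpaii, res.n_mspi) == (4, 4, 4)
        assert res.n_removed_total == 0

    def test_same_seed_reproduces_identical_serialized_results(
            self, toy_comet_df):
        outs = []
        for _ in range(2):
            res = MethylationModel.from_dataframe(toy_comet_df).fit(
                n_boot=300, seed=42)
            buf = std_io.StringIO()
            write_results([res], buf)
            outs.append(buf.getvalue())
        assert outs[0] == outs[1]

    def test_empty_group_rejected(self):
        with pytest.raises(ParameterError, match="mspi"):
            MethylationModel(TreatmentGroups(control=[1.0], hpaii=[2.0],
                                             mspi=[]))

    def test_excess_degenerate_replicates_abort_inference(self):
        groups = TreatmentGroups(control=[0.0, 0.0, 0.0, 0.0],
                                 hpaii=[1.0, 1.0, 2.0, 2.0],
                                 mspi=[0.0, 0.0, 5.0, 5.0])
        with pytest.raises(InferenceError):
            estimate_methylation(groups, n_boot=2000, seed=3)

    def test_ci_covers_truth_in_linear_regime(self):
        # simulated m=0.5 sample: 95% CI should usually cover 50
        hits = 0
        for s in range(20):
            p = SimulationParams.linear_regime(0.5, seed=100 + s)
            df = simulate_cell_population(p, "s")
            res = MethylationModel.from_dataframe(df).fit(
                n_boot=300, seed=s)
            hits += res.ci_low <= 50.0 <= res.ci_high
        assert hits >= 17

    def test_summary_flags_out_of_range_estimates(self):
        res = estimate_methylation(
            TreatmentGroups(control=[60.0] * 4, hpaii=[50.0] * 4,
                            mspi=[55.0] * 4),
            n_boot=100, seed=0)
        assert res.pct_methylation < 0
        assert "NOTE" in res.summary()
        assert "% CpG methylation" in res.summary()


class TestCompareConditions:
    def test_published_point_estimates_reproduce_decreases(self):
        assert compare_conditions(60.2, 34.0).difference == pytest.approx(26.2)
        assert compare_conditions(58.6, 34.6).difference == pytest.approx(24.0)

    def test_identical_data_difference_straddles_zero(self, toy_comet_df):
        model = MethylationModel.from_dataframe(toy_comet_df)
        a = model.fit(n_boot=400, seed=1)
        b = model.fit(n_boot=400, seed=2)
        cmp_ = compare_conditions(a, b)
        assert cmp_.difference == pytest.approx(0.0, abs=1e-9)
        assert cmp_.ci_low < 0.0 < cmp_.ci_high

    def test_fitted_results_yield_difference_interval(self, toy_comet_df):
        model = MethylationModel.from_dataframe(toy_comet_df)
        a = model.fit(n_boot=400, seed=1)
        b = model.fit(n_boot=400, seed=2)
        cmp_ = compare_conditions(a, b)
        assert cmp_.ci_low <= cmp_.difference <= cmp_.ci_high

    def test_mismatched_ci_levels_rejected(self, toy_comet_df):
        model = MethylationModel.from_dataframe(toy_comet_df)
        a = model.fit(n_boot=100, ci_level=0.95, seed=1)
        b = model.fit(n_boot=100, ci_level=0.90, seed=2)
        with pytest.raises(ConfigurationError):
            compare_conditions(a, b)

    def test_mismatched_replicate_streams_rejected(self, toy_comet_df):
        model = MethylationModel.from_dataframe(toy_comet_df)
        a = model.fit(n_boot=100, seed=1)
        b = model.fit(n_boot=200, seed=2)
        with pytest.raises(ConfigurationError):
            compare_conditions(a, b)
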