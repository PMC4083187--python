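"""Forward-simulator behaviour: enzyme model, dose response, determinism."""

import io as std_io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cometmeth import (
    ParameterError,
    SimulationParams,
    expected_tail_intensity,
    simulate_cea_counts,
    simulate_cell_population,
)
from cometmeth.io import write_comet_csv
from cometmeth.stats import pct_cpg_methylation, thompson_tau_filter


def _point_estimate(df):
    """Filtered-means methylation statistic of a simulated sample."""
    means = {}
    for t in ("control", "HpaII", "MspI"):
        vals = df.loc[df["treatment"] == t, "tail_intensity"].to_numpy()
        kept, _ = thompson_tau_filter(vals)
        means[t] = kept.mean()
    return pct_cpg_methylation(means["HpaII"], means["MspI"], means["control"])


class TestSimulationParams:
    @pytest.mark.parametrize("bad, field", [
        (dict(m=1.2), "m"),
        (dict(m=-0.1), "m"),
        (dict(h=2.0), "h"),
        (dict(e=-0.5), "e"),
        (dict(m=0.7, h=0.4), "m + h + e"),
        (dict(S=0), "S"),
        (dict(S=10.5), "S"),
        (dict(kappa=0.0), "kappa"),
        (dict(kappa=-3.0), "kappa"),
        (dict(lambda0=-1.0), "lambda0"),
        (dict(sigma=-0.1), "sigma"),
        (dict(n_cells=0), "n_cells"),
        (dict(n_wells=-2), "n_wells"),
        (dict(d=1.5), "d"),
        (dict(d_hemi_factor=-0.2), "d_hemi_factor"),
    ])
    def test_invalid_parameters_name_offending_field(self, bad, field):
        with pytest.raises(ParameterError, match=field.replace("+", r"\+")):
            SimulationParams(**bad)

    def test_linear_regime_is_noise_free_and_linear(self):
        p = SimulationParams.linear_regime(0.4)
        assert p.lambda0 == 0 and p.sigma == 0 and p.h == 0 and p.e == 0
        assert p.kappa == pytest.approx(100 * p.S * p.d)

    def test_replace_revalidates(self):
        p = SimulationParams()
        with pytest.raises(ParameterError):
            p.replace(m=3.0)


class TestDoseResponse:
    def test_zero_breaks_give_zero_tail(self):
        assert expected_tail_intensity(0, 123.0) == 0.0

    def test_closed_form_at_kappa_breaks(self):
        # 100 * (1 - 1/e)
        assert expected_tail_intensity(50.0, 50.0) == pytest.approx(
            63.21206, abs=1e-4)

    def test_invalid_kappa_rejected(self):
        with pytest.raises(ParameterError):
            expected_tail_intensity(10, 0.0)

    @given(st.floats(0, 20), st.floats(0.01, 5), st.floats(1e-3, 1e6))
    @settings(deadline=None, derandomize=True)
    def test_strictly_increasing_and_bounded(self, b_rel, delta_rel, kappa):
        # break counts expressed in units of kappa, below float saturation
        lo = expected_tail_intensity(b_rel * kappa, kappa)
        hi = expected_tail_intensity((b_rel + delta_rel) * kappa, kappa)
        assert 0.0 <= lo < hi < 100.0


class TestCellPopulation:
    def test_group_structure_matches_assay_design(self):
        # >= 9 wells, 50-100 comets/well, hence >= 400 comets per treatment
        p = SimulationParams(seed=1)
        df = simulate_cell_population(p, "s1")
        assert p.n_wells >= 9 and 50 <= p.n_cells <= 100
        assert len(df) == 3 * p.n_cells * p.n_wells
        counts = df.groupby("treatment").size()
        assert (counts >= 400).all()
        per_well = df.groupby(["treatment", "well"]).size()
        assert (per_well == p.n_cells).all()
        assert set(df["well"]) == set(range(1, p.n_wells + 1))

    def test_unmethylated_sample_has_equivalent_isoschizomer_groups(self):
        # m=0: HpaII and MspI break distributions coincide, statistic ~ 0
        p = SimulationParams.linear_regime(0.0, n_cells=200, seed=11)
        df = simulate_cell_population(p, "s")
        hp = df.loc[df.treatment == "HpaII", "tail_intensity"]
        ms = df.loc[df.treatment == "MspI", "tail_intensity"]
        assert hp.mean() == pytest.approx(ms.mean(), rel=0.02)
        assert abs(_point_estimate(df)) < 2.0

    def test_fully_methylated_sample_blocks_hpaii_completely(self):
        p = SimulationParams(m=1.0, lambda0=0.0, sigma=0.0, seed=3)
        df = simulate_cell_population(p, "s")
        assert (df.loc[df.treatment == "HpaII", "tail_intensity"] == 0).all()
        assert (df.loc[df.treatment == "control", "tail_intensity"] == 0).all()
        assert (df.loc[df.treatment == "MspI", "tail_intensity"] > 0).any()

    def test_tail_intensities_always_in_range(self):
        p = SimulationParams(sigma=30.0, seed=8)  # heavy noise forces clipping
        df = simulate_cell_population(p, "s")
        ti = df["tail_intensity"]
        assert ti.between(0, 100).all()

    def test_statistic_monotone_in_methylated_fraction(self):
        # median point estimate over seeds is non-decreasing in m
        grid = [0.0, 0.25, 0.5, 0.75, 1.0]
        medians = []
        for m in grid:
            vals = [_point_estimate(simulate_cell_population(
                SimulationParams.linear_regime(
                    m, n_cells=30, n_wells=3, seed=s), "s"))
                for s in range(20)]
            medians.append(np.median(vals))
        assert all(a <= b + 1e-9 for a, b in zip(medians, medians[1:]))

    def test_identical_seed_reproduces_identical_csv_bytes(self):
        p = SimulationParams(seed=99)
        bufs = []
        for _ in range(2):
            df = simulate_cell_population(p, "s", "untreated")
            buf = std_io.StringIO()
            write_comet_csv(df, buf)
            bufs.append(buf.getvalue())
        assert bufs[0] == bufs[1]

    def test_different_seeds_differ(self):
        a = simulate_cell_population(SimulationParams(seed=1), "s")
        b = simulate_cell_population(SimulationParams(seed=2), "s")
        assert not a["tail_intensity"].equals(b["tail_intensity"])


class TestCEACounts:
    def test_fully_methylated_gives_zero_hpaii_counts(self):
        p = SimulationParams(m=1.0, lambda0=0, sigma=0)
        s = simulate_cea_counts(p, scale_dpm=100.0, background_dpm=0.0, seed=0)
        assert s.dpm_hpaii == 0.0
        assert s.dpm_mspi > 0.0

    def test_unmethylated_counts_equal_in_expectation(self):
        p = SimulationParams(m=0.0, h=0.0, e=0.0)
        ratios = [simulate_cea_counts(p, 1000.0, seed=s) for s in range(30)]
        r = np.mean([x.dpm_hpaii / x.dpm_mspi for x in ratios])
        assert r == pytest.approx(1.0, abs=0.01)

    def test_poisson_mean_ratio_tracks_unmethylated_fraction(self):
        # m=0.4, d=1: E[HpaII]/E[MspI] = 0.6
        p = SimulationParams(m=0.4, S=1000, d=1.0, kappa=1.0)
        r = np.mean([
            (lambda s: s.dpm_hpaii / s.dpm_mspi)(
                simulate_cea_counts(p, 10.0, seed=i)) for i in range(50)])
        assert r == pytest.approx(0.6, abs=0.01)

    def test_invalid_scale_rejected(self):
        with pytest.raises(ParameterError):
            simulate_cea_counts(SimulationParams(), scale_dpm=-1.0)

    def test_reference_mass_default(self):
        s = simulate_cea_counts(SimulationParams(seed=0), 10.0)
        assert s.dna_mass_mg == 0.5
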