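import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import mannwhitneyu

import beambreak as bb
from beambreak.events import BinnedSeries

from conftest import T0
from test_events import series_of


class TestLabelPhases:
    def test_noon_bin_is_on(self, regime):
        on, straddle = bb.label_phases(np.array([12.0]), regime)
        assert on[0] and not straddle[0]

    def test_lights_off_boundary_bin_is_off(self, regime):
        on, _ = bb.label_phases(np.array([12.0 + regime.photoperiod_h / 2]), regime)
        assert not on[0]

    def test_full_day_on_bin_count_matches_enumeration(self, regime):
        """93 of the 144 10-min bins of a day start inside the 15.5 h
        photoperiod (computed independently from the ramp geometry)."""
        starts = pd.date_range(T0, periods=144, freq="10min")
        on, straddle = bb.label_phases(starts, regime)
        # independent oracle: bin starts strictly inside (noon +/- pp/2)
        hours = np.arange(144) / 6.0
        expected = ((hours > 12 - 15.5 / 2) & (hours < 12 + 15.5 / 2)).sum()
        assert on.sum() == expected == 93
        assert straddle.sum() == 2  # one bin per transition

    def test_straddle_bins_flagged(self, regime):
        # lights-on at 04:15, lights-off at 19:45 under the default regime
        on, straddle = bb.label_phases(
            pd.DatetimeIndex([T0 + pd.Timedelta(hours=4, minutes=10),
                              T0 + pd.Timedelta(hours=19, minutes=40)]), regime)
        assert list(straddle) == [True, True]
        assert list(on) == [False, True]


class TestMannWhitney:
    def test_separated_samples_exact_p(self):
        res = bb.mann_whitney_u([1, 2, 3], [4, 5, 6], mode="exact")
        assert res.u_x == 0.0 and res.u_y == 9.0
        assert res.p_two_sided == pytest.approx(0.1)

    def test_identical_samples_symmetric(self):
        res = bb.mann_whitney_u([1, 2, 2, 5], [1, 2, 2, 5], mode="exact")
        assert res.p_two_sided == 1.0
        assert res.u_x == res.u_y

    @given(st.lists(st.integers(1, 50), min_size=1, max_size=6, unique=True),
           st.lists(st.integers(51, 100), min_size=1, max_size=6, unique=True))
    def test_rank_sum_identity_tie_free(self, x, y):
        res = bb.mann_whitney_u(x, y)
        assert res.u_x + res.u_y == len(x) * len(y)

    @given(st.lists(st.floats(-100, 100, allow_nan=False), min_size=2, max_size=8,
                    unique=True))
    def test_exact_matches_scipy_enumeration(self, pooled):
        half = len(pooled) // 2
        x, y = pooled[:half], pooled[half:]
        if not x or not y:
            return
        res = bb.mann_whitney_u(x, y, mode="exact")
        ref = mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert res.p_two_sided == pytest.approx(ref.pvalue, abs=1e-12)

    @given(st.lists(st.integers(0, 9), min_size=3, max_size=40),
           st.lists(st.integers(0, 9), min_size=3, max_size=40))
    def test_approx_matches_scipy_with_ties(self, x, y):
        res = bb.mann_whitney_u(x, y, mode="approx")
        ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                           use_continuity=True)
        if len(set(x) | set(y)) == 1:
            assert res.p_two_sided == 1.0
        else:
            assert res.p_two_sided == pytest.approx(ref.pvalue, abs=1e-9)

    def test_exact_and_approx_agree_tie_free_n10(self):
        """Normal approximation is within 0.02 of the enumerated p for
        tie-free samples of size 10 vs 10."""
        rng = np.random.default_rng(42)
        for _ in range(3):
            pooled = rng.permutation(np.arange(20.0))
            x, y = pooled[:10], pooled[10:]
            pe = bb.mann_whitney_u(x, y, mode="exact").p_two_sided
            pa = bb.mann_whitney_u(x, y, mode="approx").p_two_sided
            assert abs(pe - pa) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            bb.mann_whitney_u([], [1.0])


class TestPhaseComparison:
    def test_all_zero_series_not_significant(self, regime):
        bs = series_of([0.0] * 144)
        on, straddle = bb.label_phases(bs.bin_starts, regime)
        cmp = bb.phase_comparison(bs, on, straddle)
        assert cmp.p_two_sided == 1.0 and cmp.direction == 0
        assert cmp.stars == "ns"

    def test_phase_without_bins_flagged_not_testable(self, regime):
        bs = series_of([1.0, 2.0, 3.0])  # midnight bins: lights-off only
        on, straddle = bb.label_phases(bs.bin_starts, regime)
        cmp = bb.phase_comparison(bs, on, straddle)
        assert not cmp.testable

    def test_partial_and_straddle_bins_excluded(self, regime):
        vals = [1.0] * 144
        bs = series_of(vals)
        partial = pd.Series(False, index=bs.values.index)
        partial.iloc[0] = True
        bs.partial = partial
        on, straddle = bb.label_phases(bs.bin_starts, regime)
        cmp = bb.phase_comparison(bs, on, straddle)
        assert cmp.n_on + cmp.n_off == 144 - 1 - straddle.sum()


class TestGroupSeries:
    def test_single_individual_sem_missing(self):
        g = bb.group_series([series_of([1.0, 2.0])])
        assert list(g.mean.values) == [1.0, 2.0]
        assert g.sem.isna().all()

    def test_two_individuals_mean_and_sem(self):
        g = bb.group_series([series_of([0.0, 0.0]), series_of([1.0, 1.0])])
        assert np.allclose(g.mean.values, 0.5)
        assert np.allclose(g.sem, 0.5)  # sd = sqrt(0.5), / sqrt(2)

    def test_identical_individuals_zero_sem(self):
        g = bb.group_series([series_of([2.0, 3.0])] * 3)
        assert np.allclose(g.sem, 0.0)

    def test_misaligned_grids_rejected(self):
        a = series_of([1.0, 2.0])
        b = series_of([1.0, 2.0], start=T0 + pd.Timedelta(minutes=10))
        with pytest.raises(ValueError, match="align"):
            bb.group_series([a, b])


class TestGroupPhaseComparison:
    def test_mean_and_pooled_modes_agree_in_direction(self, regime):
        rng = np.random.default_rng(8)
        series = []
        hours = np.arange(144) / 6.0
        dark = ~bb.is_light(regime, hours)
        for _ in range(4):
            vals = rng.poisson(1 + 3 * dark).astype(float)
            series.append(series_of(list(vals)))
        on, straddle = bb.label_phases(series[0].bin_starts, regime)
        mean_cmp = bb.group_phase_comparison(series, on, straddle, mode="mean")
        pooled_cmp = bb.group_phase_comparison(series, on, straddle, mode="pooled")
        assert mean_cmp.direction == pooled_cmp.direction == 1
        assert mean_cmp.p_two_sided < 0.05 and pooled_cmp.p_two_sided < 0.05
        # pooling multiplies the sample size by the number of individuals
        assert pooled_cmp.n_on == 4 * mean_cmp.n_on

    def test_unknown_mode_rejected(self, regime):
        s = [series_of([1.0] * 144)]
        on, straddle = bb.label_phases(s[0].bin_starts, regime)
        with pytest.raises(ValueError):
            bb.group_phase_comparison(s, on, straddle, mode="median")


class TestAverageDay:
    def test_constant_series_flat_profile(self):
        prof = bb.average_day(series_of([0.7] * (144 * 5)))
        assert np.allclose(prof.mean, 0.7)
        assert np.allclose(prof.sem, 0.0)
        assert (prof.n == 5).all()

    def test_periodic_input_reproduces_one_cycle(self, regime):
        starts = pd.date_range(T0, periods=144 * 3, freq="10min")
        hours = ((starts - starts.normalize()).total_seconds() / 3600.0).to_numpy()
        vals = bb.light_intensity(regime, hours)
        prof = bb.average_day(BinnedSeries(values=pd.Series(vals, index=starts),
                                           level="column"))
        assert np.allclose(prof.mean, vals[:144])
        assert np.allclose(prof.sem, 0.0)

    def test_invariant_to_recording_start_day(self, regime):
        hours = (np.arange(144 * 2) / 6.0) % 24.0
        vals = bb.light_intensity(regime, hours)
        a = BinnedSeries(values=pd.Series(vals, index=pd.date_range(
            T0, periods=len(vals), freq="10min")), level="column")
        b = BinnedSeries(values=pd.Series(vals, index=pd.date_range(
            T0 + pd.Timedelta(days=3), periods=len(vals), freq="10min")), level="column")
        assert np.allclose(bb.average_day(a).mean, bb.average_day(b).mean)

    def test_incomplete_day_rejected(self):
        with pytest.raises(ValueError, match="complete day"):
            bb.average_day(series_of([1.0] * 100))

    def test_nocturnal_group_peaks_in_darkness(self, regime):
        """Folding simulated nocturnal individuals into an average day puts
        the activity maximum in a lights-off bin."""
        from beambreak.experiments import (
            DEFAULT_PHOTOTAXIS_GAINS, activity_bin_counts)

        root = np.random.SeedSequence(77)
        series = []
        for i, child in enumerate(root.spawn(5)):
            agent = bb.AgentParams(phototaxis_gain=DEFAULT_PHOTOTAXIS_GAINS[i],
                                   dark_activity_gain=3.0)
            counts = activity_bin_counts(agent, regime, 2, child)
            series.append(BinnedSeries(
                values=pd.Series(counts / counts.max(), index=pd.date_range(
                    T0, periods=counts.size, freq="10min")), level="column"))
        prof = bb.average_day(series)
        peak_hour = prof.minute_of_day[np.argmax(prof.mean)] / 60.0
        assert not bb.is_light(regime, peak_hour)


class TestQCScreen:
    def test_healthy_columns_retained(self, two_column_run):
        config, records = two_column_run
        out = bb.qc_screen(records, config.geometry, config.scan,
                           duration_ms=config.duration_s * 1000)
        assert all(d.keep for d in out.values())

    def test_dead_module_dropped(self, two_column_run):
        config, records = two_column_run
        faulty = {"c01": bb.inject_dead_module(records["c01"], 4)}
        out = bb.qc_screen(faulty, config.geometry, config.scan,
                           duration_ms=config.duration_s * 1000)
        assert not out["c01"].keep
        assert out["c01"].reasons == ("dead module 4",)

    def test_stuck_detector_dropped(self, two_column_run):
        config, records = two_column_run
        duration_ms = int(config.duration_s * 1000)
        stuck = {"c01": bb.inject_stuck_detector(
            records["c01"], module=5, beam=2, duration_ms=duration_ms,
            geometry=config.geometry, scan=config.scan)}
        out = bb.qc_screen(stuck, config.geometry, config.scan,
                           duration_ms=duration_ms)
        assert not out["c01"].keep
        assert "stuck detector module 5" in out["c01"].reasons
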