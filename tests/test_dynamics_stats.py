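"""Detection frequency, BR summaries/histograms, dwells, discovery curves."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tunnelgate.dynamics_stats import (
    BottleneckSeries,
    StatsParams,
    bottleneck_series_from_radius,
    br_histogram,
    br_summary,
    count_distinct_superclusters,
    detection_frequency,
    discovery_curve,
    dwell_histogram,
    first_detection_times,
    open_state_runs,
)


def series(values, dt=0.02, lengths=None):
    return BottleneckSeries(
        supercluster_id=1, replicate_id="r0", condition="A",
        frame_spacing=dt, values=np.asarray(values, float), lengths=lengths,
    )


NAN = np.nan


class TestDetectionFrequency:
    def test_all_frames_detected(self):
        assert detection_frequency(series([1.0] * 100)) == 1.0

    def test_absent_frames_lower_frequency(self):
        assert detection_frequency(series([1.0, NAN, 1.2, 0.9])) == 0.75

    def test_threshold_is_strict(self):
        assert detection_frequency(series([0.7, 0.7001])) == 0.5

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            detection_frequency(series([]))


class TestBrSummary:
    def test_mean_and_max(self):
        s = br_summary(series([1.0, 2.0]))
        assert (s.mean_br, s.max_br) == (1.5, 2.0)

    def test_single_value(self):
        s = br_summary(series([1.3]))
        assert s.mean_br == s.max_br == 1.3

    def test_absences_excluded(self):
        s = br_summary(series([1.0, NAN, 3.0]))
        assert s.mean_br == 2.0

    def test_no_detected_frames_reported_absent(self):
        assert br_summary(series([NAN, NAN])) is None

    def test_mean_length_over_detected_frames(self):
        s = br_summary(series([1.0, NAN], lengths=np.array([6.0, 9.0])))
        assert s.mean_length == 6.0


class TestBrHistogram:
    def test_two_values_two_bins(self):
        p = StatsParams(br_bin_edges=np.arange(0.7, 3.01, 0.1))
        h = br_histogram(series([0.75, 0.85]), p)
        assert h.frequencies[0] == 0.5
        assert h.frequencies[1] == 0.5
        assert h.total == pytest.approx(1.0)

    def test_single_bin_mass(self):
        p = StatsParams(br_bin_edges=np.array([0.7, 0.8, 0.9]))
        h = br_histogram(series([0.75, 0.75, 0.75]), p)
        assert h.frequencies[0] == 1.0

    def test_overflow_collects_tail_and_masses_sum_to_one(self):
        p = StatsParams(br_bin_edges=np.array([0.7, 1.0, 1.5]))
        h = br_histogram(series([0.8, 1.2, 2.5, 9.0]), p)
        assert h.overflow == 0.5
        assert h.total == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_recount(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0.7, 3.5, size=200)
        vals[rng.random(200) < 0.2] = np.nan
        p = StatsParams()
        h = br_histogram(series(vals), p)
        present = vals[~np.isnan(vals)]
        e = p.br_bin_edges
        for i in range(len(e) - 1):
            ref = np.sum((present >= e[i]) & (present < e[i + 1])) / len(present)
            assert h.frequencies[i] == pytest.approx(ref)
        assert h.overflow == pytest.approx(np.sum(present >= e[-1]) / len(present))


class TestOpenStateRuns:
    def test_run_lengths(self):
        runs = open_state_runs(series([1.5, 1.5, 1.0, 1.6]))
        assert [r.duration for r in runs] == pytest.approx([0.04, 0.02])
        # both runs touch a series boundary
        assert [r.censored for r in runs] == [True, True]

    def test_threshold_inclusive(self):
        runs = open_state_runs(series([1.0, 1.4, 1.0]))
        assert len(runs) == 1
        assert runs[0].duration == pytest.approx(0.02)
        assert not runs[0].censored

    def test_all_closed(self):
        assert open_state_runs(series([1.0, 1.2, NAN])) == []

    def test_absent_frames_terminate_runs(self):
        runs = open_state_runs(series([1.0, 1.5, NAN, 1.5, 1.0]))
        assert [r.duration for r in runs] == pytest.approx([0.02, 0.02])

    def test_drop_policy_removes_censored(self):
        p = StatsParams(censoring_policy="drop")
        runs = open_state_runs(series([1.5, 1.0, 1.5, 1.0, 1.5]), p)
        assert len(runs) == 1
        assert not runs[0].censored

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=3.0), min_size=1, max_size=60),
           st.integers(min_value=0, max_value=2**31 - 1))
    def test_total_open_time_conserved(self, values, seed):
        """Sum of run durations (include policy) = dt x open-frame count."""
        rng = np.random.default_rng(seed)
        vals = np.asarray(values)
        vals[rng.random(len(vals)) < 0.3] = np.nan
        p = StatsParams(censoring_policy="include")
        s = series(vals)
        runs = open_state_runs(s, p)
        total = sum(r.duration for r in runs)
        n_open = np.nansum((~np.isnan(vals)) & (vals >= p.open_threshold))
        assert total == pytest.approx(0.02 * n_open, abs=1e-12)


class TestDwellHistogram:
    def test_identical_replicates_zero_sd(self):
        s = series([1.5, 1.0, 1.5, 1.5, 1.0, 1.5])
        runs = open_state_runs(s, StatsParams(censoring_policy="include"))
        hist, sd, sd_over = dwell_histogram([runs, runs])
        assert np.all(sd == 0)
        assert sd_over == 0

    def test_hand_computed_frequencies(self):
        from tunnelgate.dynamics_stats import DwellRun

        p = StatsParams(dwell_bin_edges=np.array([0.02, 0.03, 0.05]))
        runs = [DwellRun(0.02, False), DwellRun(0.02, False), DwellRun(0.04, False)]
        hist, _, _ = dwell_histogram([runs, runs], p)
        np.testing.assert_allclose(hist.frequencies, [2 / 3, 1 / 3])

    def test_zero_run_replicate_contributes_zeros(self):
        from tunnelgate.dynamics_stats import DwellRun

        runs = [DwellRun(0.04, False)]
        hist, sd, _ = dwell_histogram([runs, []])
        assert hist.total == pytest.approx(0.5)

    def test_exponential_dwells_match_analytic_bin_masses(self):
        """Simulated exponential dwells against closed-form bin integrals."""
        from tunnelgate.dynamics_stats import DwellRun
        from tunnelgate.synthetic_data import GatingModel, simulate_gating

        model = GatingModel(k_open=5.0, k_close=5.0, noise_sd=0.0, seed=17)
        _, gt = simulate_gating(model, 150_000, 0.02)
        dwells = gt.open_dwells
        edges = np.geomspace(0.02, 8.0, 13)
        p = StatsParams(dwell_bin_edges=edges)
        reps = np.array_split(dwells, 3)
        hist, sd, _ = dwell_histogram(
            [[DwellRun(d, False) for d in r] for r in reps], p
        )
        # analytic: P(a <= X < b | X >= a0) with X ~ Exp(rate k_close)
        k = model.k_close
        norm = np.exp(-k * edges[0])  # dwells below the first edge are excluded
        # from neither population nor histogram: condition on X >= 0
        n = len(dwells)
        for i in range(len(edges) - 1):
            mass = (np.exp(-k * edges[i]) - np.exp(-k * edges[i + 1]))
            se = np.sqrt(mass * (1 - mass) / n)
            assert abs(hist.frequencies[i] - mass) < 3 * se + 3.0 / n

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            dwell_histogram([[]])


class TestDiscoveryCurve:
    def test_single_replicate_steps_and_saturation(self):
        dc = discovery_curve({"r0": [0.1, 0.5]})
        np.testing.assert_allclose(dc.times, [0.1, 0.5])
        np.testing.assert_allclose(dc.mean_counts, [1, 2])
        assert dc.saturation_times["r0"] == 0.5

    def test_mean_and_envelope(self):
        dc = discovery_curve({"r0": [0.1], "r1": [0.1, 0.2, 0.3]})
        i = np.searchsorted(dc.times, 0.3)
        assert dc.mean_counts[i] == pytest.approx(2.0)
        assert dc.min_counts[i] == 1
        assert dc.max_counts[i] == 3

    def test_replicate_permutation_symmetry(self):
        a = discovery_curve({"r0": [0.1, 0.4], "r1": [0.2]})
        b = discovery_curve({"r1": [0.2], "r0": [0.1, 0.4]})
        np.testing.assert_array_equal(a.times, b.times)
        np.testing.assert_array_equal(a.mean_counts, b.mean_counts)

    def test_monotone_nondecreasing(self, rng):
        times = {f"r{i}": sorted(rng.uniform(0, 10, size=5)) for i in range(4)}
        dc = discovery_curve(times)
        assert np.all(np.diff(dc.mean_counts) >= 0)
        assert np.all(np.diff(dc.min_counts) >= 0)
        assert np.all(np.diff(dc.max_counts) >= 0)

    def test_zero_supercluster_replicate(self):
        dc = discovery_curve({"r0": [0.1], "r1": []})
        assert dc.saturation_times["r1"] is None
        assert dc.min_counts[-1] == 0


class _FakeSC:
    def __init__(self, sc_id, series_map):
        self.supercluster_id = sc_id
        self.series = series_map


class TestSuperclusterCounts:
    def test_first_detection_times(self):
        s1 = series([NAN, 1.2, 1.3])
        s2 = series([1.0, NAN, NAN])
        scs = [
            _FakeSC(1, {("A", "r0"): s1}),
            _FakeSC(2, {("A", "r0"): s2}),
        ]
        assert first_detection_times(scs, "r0") == pytest.approx([0.0, 0.02])

    def test_count_by_condition(self):
        sA = series([1.0])
        sB = BottleneckSeries(1, "r1", "B", 0.02, np.array([1.0]))
        scs = [
            _FakeSC(1, {("A", "r0"): sA, ("B", "r1"): sB}),
            _FakeSC(2, {("B", "r1"): sB}),
            _FakeSC(5, {("A", "r0"): sA}),
        ]
        assert count_distinct_superclusters(scs, "A") == 2
        assert count_distinct_superclusters(scs, "B") == 2
        assert count_distinct_superclusters(scs, "C") == 0

    def test_union_monotonicity(self):
        sA = series([1.0])
        scs = [_FakeSC(1, {("A", "r0"): sA}), _FakeSC(2, {("A", "r0"): sA})]
        union = len(scs)
        assert union >= count_distinct_superclusters(scs, "A")


class TestSeriesFromRadius:
    def test_sub_probe_values_masked(self):
        bs = bottleneck_series_from_radius(
            np.array([1.6, 0.2, 0.9]), frame_spacing=0.02
        )
        np.testing.assert_array_equal(bs.present, [True, False, True])
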