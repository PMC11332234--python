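import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emoseg import (
    BootstrapSpec,
    MagnitudeCurve,
    bootstrap_threshold,
    compute_cea,
    find_consensus_timestamps,
    group_magnitude,
    magnitude_grid,
    merge_events,
    participant_magnitude,
    pelt_meanvar,
)
from emoseg.consensus import cea_trial_matrix, compute_event_windows, default_pelt_penalty
from emoseg.consensus import _segment_cost_factory
from conftest import make_dataset


GRID = magnitude_grid(30.0, 0.1)


class TestParticipantMagnitude:
    def test_unit_peak_and_one_sd_value(self):
        vals = participant_magnitude([5.0], GRID, kernel_sd=0.8)
        assert vals[np.searchsorted(GRID, 5.0)] == pytest.approx(1.0)
        assert vals[np.searchsorted(GRID, 5.8)] == pytest.approx(np.exp(-0.5), abs=1e-12)

    def test_duplicate_pause_is_idempotent(self):
        one = participant_magnitude([5.0], GRID)
        two = participant_magnitude([5.0, 5.0], GRID)
        np.testing.assert_array_equal(one, two)

    def test_overlap_takes_maximum(self):
        # equal bumps at 4 and 6: value at 5 is exp(-1/(2*0.64)) from either side
        vals = participant_magnitude([4.0, 6.0], GRID, kernel_sd=0.8)
        expected = np.exp(-1.0 / (2 * 0.8**2))
        assert vals[np.searchsorted(GRID, 5.0)] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.4578, abs=5e-5)

    def test_empty_pauses_give_zero_vector(self):
        assert not participant_magnitude([], GRID).any()


class TestGroupMagnitude:
    def test_three_synchronized_participants_peak_three(self):
        curve = group_magnitude([[10.0], [10.0], [10.0]], GRID)
        assert curve.values.max() == pytest.approx(3.0)

    def test_single_participant_identity(self):
        curve = group_magnitude([[7.0, 12.0]], GRID)
        np.testing.assert_array_equal(curve.values, participant_magnitude([7.0, 12.0], GRID))

    def test_disjoint_pauses_two_unit_peaks(self):
        curve = group_magnitude([[5.0], [25.0]], GRID)
        assert curve.values[np.searchsorted(GRID, 5.0)] == pytest.approx(1.0)
        assert curve.values[np.searchsorted(GRID, 25.0)] == pytest.approx(1.0)
        assert curve.values.max() < 1.5

    def test_bounded_by_participant_count_and_monotone_in_participants(self, rng):
        pauses = [rng.uniform(0, 30, 4) for _ in range(6)]
        small = group_magnitude(pauses[:5], GRID)
        large = group_magnitude(pauses, GRID)
        assert large.values.max() <= 6.0 + 1e-12
        assert np.all(large.values >= small.values - 1e-12)


class TestFindConsensusTimestamps:
    def test_flat_zero_curve_has_no_events(self):
        curve = MagnitudeCurve("s", GRID, np.zeros(len(GRID)))
        assert len(find_consensus_timestamps(curve, 0.0)) == 0

    def test_single_peak_found_at_its_grid_point(self):
        values = participant_magnitude([12.3], GRID)
        curve = MagnitudeCurve("s", GRID, values)
        (t,) = find_consensus_timestamps(curve, 0.5)
        assert t == pytest.approx(12.3, abs=0.05 + 1e-9)

    def test_subthreshold_peak_excluded(self):
        values = group_magnitude([[5.0], [5.0], [20.0]], GRID).values
        curve = MagnitudeCurve("s", GRID, values)
        stamps = find_consensus_timestamps(curve, 1.5)
        assert len(stamps) == 1 and stamps[0] == pytest.approx(5.0, abs=0.05)

    def test_plateau_reports_midpoint(self):
        values = np.zeros(len(GRID))
        values[100:111] = 2.0  # flat top from 10.0 to 11.0 s
        curve = MagnitudeCurve("s", GRID, values)
        (t,) = find_consensus_timestamps(curve, 1.0)
        assert t == pytest.approx(10.5, abs=1e-9)


class TestMergeEvents:
    @pytest.mark.parametrize(
        "stamps,expected",
        [
            ([10.0, 10.5], [10.25]),
            ([10.0, 10.7, 11.3], [(10.0 + 10.7 + 11.3) / 3]),
            ([10.0, 12.0], [10.0, 12.0]),
            ([], []),
        ],
    )
    def test_examples(self, stamps, expected):
        np.testing.assert_allclose(merge_events(stamps), expected)

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=60, allow_nan=False), max_size=15))
    def test_members_near_cluster_mean_and_remerge_is_noop(self, stamps):
        merged = merge_events(stamps)
        np.testing.assert_allclose(merge_events(merged), merged)
        # every input timestamp lies within window*(cluster size - 1) of its mean
        for t in stamps:
            nearest = merged[np.argmin(np.abs(merged - t))]
            assert abs(t - nearest) <= 0.8 * max(len(stamps) - 1, 1) + 1e-9


def naive_bootstrap_threshold(pause_lists, duration, spec, kernel_sd=0.8, dt=0.1):
    """Independent re-implementation: untruncated kernels, same draw protocol."""
    rng = np.random.default_rng(spec.seed)
    grid = magnitude_grid(duration, dt)
    counts = [len(p) for p in pause_lists]
    pooled = []
    for _ in range(spec.n_iterations):
        total = np.zeros(len(grid))
        for c in counts:
            if c == 0:
                continue
            times = rng.uniform(0.0, duration, c)
            total += np.exp(-((grid[None, :] - times[:, None]) ** 2) / (2 * kernel_sd**2)).max(axis=0)
        pooled.append(total)
    return float(np.quantile(np.concatenate(pooled), spec.critical_probability))


class TestBootstrapThreshold:
    def test_zero_critical_probability_gives_pooled_minimum(self):
        spec = BootstrapSpec(n_iterations=5, critical_probability=0.0, seed=3)
        thr = bootstrap_threshold([[5.0, 9.0]], 30.0, spec)
        assert thr == pytest.approx(0.0, abs=1e-12)

    def test_single_pause_threshold_at_most_one(self):
        spec = BootstrapSpec(n_iterations=20, critical_probability=0.95, seed=3)
        assert bootstrap_threshold([[5.0]], 30.0, spec) <= 1.0

    def test_deterministic_given_seed(self, rng):
        pauses = [rng.uniform(0, 120, 3) for _ in range(20)]
        spec = BootstrapSpec(n_iterations=50, critical_probability=0.95, seed=77)
        assert bootstrap_threshold(pauses, 120.0, spec) == bootstrap_threshold(pauses, 120.0, spec)

    def test_matches_independent_reimplementation(self, rng):
        pauses = [rng.uniform(0, 120, 3) for _ in range(20)]
        spec = BootstrapSpec(n_iterations=50, critical_probability=0.95, seed=77)
        ours = bootstrap_threshold(pauses, 120.0, spec)
        naive = naive_bootstrap_threshold(pauses, 120.0, spec)
        # only the 4-SD kernel truncation separates the two routes
        assert ours == pytest.approx(naive, abs=1e-3)

    def test_max_scheme_is_stricter_than_pooled(self, rng):
        pauses = [rng.uniform(0, 60, 3) for _ in range(10)]
        pooled = bootstrap_threshold(pauses, 60.0, BootstrapSpec(50, 0.95, 7, "pooled"))
        maxed = bootstrap_threshold(pauses, 60.0, BootstrapSpec(50, 0.95, 7, "max"))
        assert maxed >= pooled


def brute_force_changepoints(x, penalty, min_size=2):
    """Exhaustive search over all changepoint sets (tiny n only)."""
    cost = _segment_cost_factory(np.asarray(x, dtype=float))
    n = len(x)
    positions = range(min_size, n - min_size + 1)
    best_cost, best_cps = cost(0, n), []
    for k in range(1, 4):
        for cps in itertools.combinations(positions, k):
            bounds = [0, *cps, n]
            if any(b - a < min_size for a, b in zip(bounds, bounds[1:])):
                continue
            total = sum(cost(a, b) for a, b in zip(bounds, bounds[1:])) + penalty * k
            if total < best_cost - 1e-9:
                best_cost, best_cps = total, list(cps)
    return best_cps


class TestPeltMeanVar:
    def test_three_segment_toy_series_windows(self):
        grid = magnitude_grid(30.0, 0.1)
        values = np.where((grid >= 10.0) & (grid < 20.0), 5.0, 0.0)
        curve = MagnitudeCurve("s", grid, values)
        (event,) = compute_event_windows(curve, [15.0])
        assert event.window_start == pytest.approx(10.0, abs=0.1)
        assert event.window_end == pytest.approx(20.0, abs=0.1)

    def test_matches_exhaustive_search_on_noisy_series(self, rng):
        x = np.concatenate(
            [rng.normal(0, 0.5, 8), rng.normal(4, 2.0, 8), rng.normal(-1, 0.3, 8)]
        )
        pen = default_pelt_penalty(len(x))
        assert pelt_meanvar(x, pen) == brute_force_changepoints(x, pen)

    def test_constant_series_has_no_changepoints(self):
        assert pelt_meanvar(np.ones(50)) == []

    def test_timestamp_before_first_changepoint_uses_stimulus_start(self):
        grid = magnitude_grid(30.0, 0.1)
        values = np.where(grid >= 20.0, 5.0, 0.0)
        curve = MagnitudeCurve("s", grid, values)
        (event,) = compute_event_windows(curve, [5.0])
        assert event.window_start == 0.0
        assert event.window_end == pytest.approx(20.0, abs=0.1)

    def test_two_timestamps_in_one_segment_share_windows(self):
        grid = magnitude_grid(30.0, 0.1)
        values = np.where((grid >= 10.0) & (grid < 20.0), 5.0, 0.0)
        curve = MagnitudeCurve("s", grid, values)
        a, b = compute_event_windows(curve, [13.0, 17.0])
        assert (a.window_start, a.window_end) == (b.window_start, b.window_end)


class TestCea:
    def events(self):
        from emoseg import ConsensusEvent

        return {
            "s1": [
                ConsensusEvent("s1", 5.0, 4.0, 6.0, 3.0),
                ConsensusEvent("s1", 15.0, 14.0, 16.0, 3.0),
            ]
        }

    def test_all_windows_hit_scores_one(self):
        ds = make_dataset({"p1": [5.0, 15.0]})
        assert compute_cea(ds, self.events())["p1"] == 1.0

    def test_no_windows_hit_scores_zero(self):
        ds = make_dataset({"p1": [9.0, 25.0]})
        assert compute_cea(ds, self.events())["p1"] == 0.0

    def test_proportion_pooled_over_events(self):
        ds = make_dataset({"p1": [5.5, 25.0]})
        assert compute_cea(ds, self.events())["p1"] == 0.5

    def test_window_membership_closed_at_endpoints(self):
        ds = make_dataset({"p1": [4.0, 16.0]})
        assert compute_cea(ds, self.events())["p1"] == 1.0

    def test_adding_pauses_never_lowers_cea(self, rng):
        events = self.events()
        base_times = list(rng.uniform(0, 30, 3))
        for extra in rng.uniform(0, 30, 5):
            a = compute_cea(make_dataset({"p1": base_times}), events)["p1"]
            b = compute_cea(make_dataset({"p1": base_times + [float(extra)]}), events)["p1"]
            assert b >= a

    def test_trial_matrix_matches_pooled_cea_for_single_stimulus(self):
        ds = make_dataset({"p1": [5.5, 25.0], "p2": [5.0, 15.0]})
        mat = cea_trial_matrix(ds, self.events())
        pooled = compute_cea(ds, self.events())
        assert mat.loc["p1", "s1"] == pooled["p1"] == 0.5
        assert mat.loc["p2", "s1"] == pooled["p2"] == 1.0
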