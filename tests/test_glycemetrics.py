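"""Glycemic metric panel: worked examples, invariants, and grid oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glulogic import (
    GlucoseSample,
    GlucoseTrace,
    IntervalSeries,
    PenaltyFunction,
    TargetRange,
    TIGHT_RANGE,
    INTERMEDIATE_RANGE,
    censor_trace,
    compute_gpi,
    compute_metrics,
    extended_hyperglycemia_episodes,
    hyperglycemic_index,
    hypoglycemia_incidence,
    mean_daily_max_delta,
    measurements_per_day,
    penalty,
    sampling_interval_stats,
    time_in_target,
    time_to_target,
)
from glulogic.glycemetrics import InvalidSampleError, NoDataError

from conftest import make_trace, random_trace


def grid_time_in_target(trace, target, dt=0.001):
    """Dense-grid numerical oracle for time-in-target, independent of the
    analytic crossing logic."""
    ts, gs = trace.times, trace.values
    grid = np.arange(ts[0], ts[-1], dt)
    g = np.interp(grid, ts, gs)
    return 100.0 * np.mean((g >= target.lower) & (g <= target.upper))


def grid_hgi(trace, target, dt=0.001):
    ts, gs = trace.times, trace.values
    grid = np.arange(ts[0], ts[-1], dt)
    g = np.interp(grid, ts, gs)
    return float(np.mean(np.maximum(0.0, g - target.upper)))


class TestPenalty:
    @pytest.mark.parametrize(
        "G,expected",
        [(95, 0.0), (20, 100.0), (180, 25.0), (110, 0.0), (80, 0.0), (10, 100.0), (400, 100.0)],
    )
    def test_worked_values_tight_range(self, G, expected, tight):
        assert penalty(G, tight) == pytest.approx(expected, abs=1e-9)

    def test_nonpositive_glucose_rejected(self, tight):
        with pytest.raises(InvalidSampleError):
            penalty(0.0, tight)
        with pytest.raises(InvalidSampleError):
            penalty(-5.0, tight)

    @given(G=st.floats(min_value=1.001, max_value=599.999))
    @settings(max_examples=300, deadline=None)
    def test_bounded_and_zero_iff_in_target(self, G):
        for target in (TIGHT_RANGE, INTERMEDIATE_RANGE):
            p = penalty(G, target)
            assert 0.0 <= p <= 100.0
            assert (p == 0.0) == (target.lower <= G <= target.upper)

    def test_monotone_in_deviation(self, tight):
        below = [penalty(g, tight) for g in np.linspace(21, 79.9, 50)]
        above = [penalty(g, tight) for g in np.linspace(110.1, 249, 50)]
        assert all(a > b for a, b in zip(below, below[1:]))  # decreasing toward L
        assert all(b > a for a, b in zip(above, above[1:]))  # increasing from U
        assert penalty(20.0, tight) == penalty(5.0, tight) == 100.0
        assert penalty(250.0, tight) == penalty(500.0, tight) == 100.0

    def test_continuity_at_band_edges(self, tight):
        eps = 1e-7
        assert penalty(tight.lower - eps, tight) < 1e-10
        assert penalty(tight.upper + eps, tight) < 1e-10


class TestGPI:
    def test_worked_three_sample_trace(self, tight):
        trace = make_trace([(0, 95), (1, 20), (2, 180)])
        assert compute_gpi(trace, tight) == pytest.approx((0 + 100 + 25) / 3, abs=1e-9)

    def test_all_in_target_is_zero(self, tight):
        trace = make_trace([(0, 90), (2, 100), (4, 110)])
        assert compute_gpi(trace, tight) == 0.0

    def test_boundary_sample_in_target(self, tight):
        assert compute_gpi(make_trace([(0, 110)]), tight) == 0.0

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_bounded_and_duplication_invariant(self, seed):
        rng = np.random.default_rng(seed)
        trace = random_trace(rng, n=20)
        g = compute_gpi(trace, TIGHT_RANGE)
        assert 0.0 <= g <= 100.0
        doubled = make_trace(
            list(zip(trace.times, trace.values))
            + list(zip(trace.times + trace.times[-1] + 1, trace.values))
        )
        assert compute_gpi(doubled, TIGHT_RANGE) == pytest.approx(g, rel=1e-12)


class TestCensoring:
    def test_short_trace_unchanged(self):
        trace = make_trace([(0, 100), (48, 120)])
        assert censor_trace(trace) == trace

    def test_samples_beyond_horizon_dropped(self):
        trace = make_trace([(0, 100), (330, 120), (340, 130)])
        out = censor_trace(trace)
        assert [s.t for s in out.samples] == [0, 330]

    def test_cosignal_intervals_clipped(self):
        trace = make_trace([(0, 100), (335, 120)], insulin=[(300.0, 400.0, 2.0)])
        out = censor_trace(trace)
        assert out.insulin.intervals == ((300.0, 336.0, 2.0),)

    def test_empty_after_censor_raises(self):
        trace = make_trace([(10, 100)])
        with pytest.raises(NoDataError):
            censor_trace(trace, horizon_h=5.0)


class TestTimeInTarget:
    def test_constant_in_target(self, tight):
        assert time_in_target(make_trace([(0, 100), (24, 100)]), tight) == 100.0

    def test_linear_crossing_half(self, tight):
        # crosses 110 at t=1 on the segment 90 -> 130 over [0, 2]
        assert time_in_target(make_trace([(0, 90), (2, 130)]), tight) == pytest.approx(50.0)

    def test_single_sample_degenerate(self, tight):
        assert time_in_target(make_trace([(0, 100)]), tight) == 100.0
        assert time_in_target(make_trace([(0, 150)]), tight) == 0.0

    def test_zigzag_matches_grid_oracle(self, tight):
        trace = make_trace([(0, 70), (3, 130), (5, 95), (9, 160)])
        assert time_in_target(trace, tight) == pytest.approx(
            grid_time_in_target(trace, tight), abs=0.1
        )

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_in_plus_out_is_total(self, seed):
        rng = np.random.default_rng(seed)
        trace = random_trace(rng, n=20)
        tir = time_in_target(trace, TIGHT_RANGE)
        # complement band coverage: below L and above U
        ts, gs = trace.times, trace.values
        below = time_in_target(trace, TargetRange(1e-6, TIGHT_RANGE.lower))
        above = time_in_target(trace, TargetRange(TIGHT_RANGE.upper, 1e6))
        # interior boundary points have measure zero; the three fractions tile time
        assert tir + below + above == pytest.approx(100.0, rel=1e-9)


class TestTimeToTarget:
    def test_first_sample_in_range(self, tight):
        assert time_to_target(make_trace([(0, 100), (4, 150)]), tight) == 0.0

    def test_boundary_reached_at_endpoint(self, tight):
        assert time_to_target(make_trace([(0, 150), (4, 110)]), tight) == pytest.approx(4.0)

    def test_analytic_crossing(self, tight):
        assert time_to_target(make_trace([(0, 150), (4, 90)]), tight) == pytest.approx(8 / 3)

    def test_never_reached_is_nan(self, tight):
        assert math.isnan(time_to_target(make_trace([(0, 150), (4, 160)]), tight))

    def test_translation_invariant(self, tight):
        a = make_trace([(0, 150), (4, 90)])
        b = make_trace([(10, 150), (14, 90)])
        assert time_to_target(a, tight) == pytest.approx(time_to_target(b, tight))


class TestHyperglycemicIndex:
    def test_constant_above(self, tight):
        assert hyperglycemic_index(make_trace([(0, 190), (10, 190)]), tight) == pytest.approx(80.0)

    def test_never_above_is_zero(self, tight):
        assert hyperglycemic_index(make_trace([(0, 100), (10, 105)]), tight) == 0.0

    def test_piecewise_matches_grid_oracle(self, tight):
        trace = make_trace([(0, 90), (2, 150), (3, 100), (7, 220), (8, 80)])
        assert hyperglycemic_index(trace, tight) == pytest.approx(
            grid_hgi(trace, tight), abs=0.1
        )


class TestDailyMaxDelta:
    def test_two_day_mean(self):
        trace = make_trace([(1, 100), (5, 140), (25, 90), (30, 150)])
        assert mean_daily_max_delta(trace) == pytest.approx(50.0)

    def test_constant_trace_zero(self):
        assert mean_daily_max_delta(make_trace([(0, 100), (5, 100), (40, 100)])) == 0.0

    def test_three_day_brute_force(self):
        rng = np.random.default_rng(3)
        pts = [(t, g) for t, g in zip(np.sort(rng.uniform(0, 70, 30)) + np.arange(30) * 1e-3,
                                      rng.uniform(60, 300, 30))]
        trace = make_trace(pts)
        ts, gs = trace.times, trace.values
        expected = np.mean([
            gs[m].max() - gs[m].min()
            for k in range(3)
            if (m := (ts - ts[0] >= 24 * k) & (ts - ts[0] < 24 * (k + 1))).sum() >= 2
        ])
        assert mean_daily_max_delta(trace) == pytest.approx(expected)

    def test_sparse_windows_skipped(self):
        trace = make_trace([(0, 100), (1, 140), (30, 90)])  # day 2 has one sample
        assert mean_daily_max_delta(trace) == pytest.approx(40.0)


class TestHypoglycemiaAndRuns:
    def test_threshold_flags_and_counts(self):
        h = hypoglycemia_incidence(make_trace([(0, 65), (1, 100)]))
        assert h[70.0] == {"flag": True, "count": 1}
        assert h[40.0] == {"flag": False, "count": 0}

    def test_strict_inequality_at_70(self):
        h = hypoglycemia_incidence(make_trace([(0, 70.0)]))
        assert h[70.0] == {"flag": False, "count": 0}

    def test_repeated_severe_samples_counted(self):
        h = hypoglycemia_incidence(make_trace([(0, 39), (1, 39)]))
        assert h[40.0] == {"flag": True, "count": 2}

    @pytest.mark.parametrize(
        "values,episodes",
        [
            ([185, 190, 200], 1),
            ([185, 170, 190, 200], 0),
            ([200, 200, 200, 150, 190, 190, 190, 190], 2),
            ([180, 180, 180], 0),  # strict > 180
            ([190] * 7, 1),
        ],
    )
    def test_extended_hyperglycemia_runs(self, values, episodes):
        trace = make_trace(enumerate(values))
        assert extended_hyperglycemia_episodes(trace) == episodes


class TestSamplingInterval:
    def test_regular_sampling(self):
        mean, sd = sampling_interval_stats(make_trace([(0, 100), (2, 100), (4, 100), (6, 100)]))
        assert mean == pytest.approx(2.0)
        assert sd == pytest.approx(0.0)

    def test_irregular_mean(self):
        # successive differences 1 h and 4 h
        mean, _ = sampling_interval_stats(make_trace([(0, 100), (1, 100), (5, 100)]))
        assert mean == pytest.approx(2.5)

    def test_implied_measurements_per_day(self):
        assert measurements_per_day(2.0) == pytest.approx(12.0)

    def test_single_sample_raises(self):
        with pytest.raises(NoDataError):
            sampling_interval_stats(make_trace([(0, 100)]))


class TestTranslationInvariance:
    @given(shift=st.floats(min_value=0.0, max_value=200.0))
    @settings(max_examples=25, deadline=None)
    def test_metrics_invariant_under_time_shift(self, shift):
        rng = np.random.default_rng(11)
        base = random_trace(rng, n=25)
        shifted = make_trace(zip(base.times + shift, base.values))
        for fn in (
            lambda tr: compute_gpi(tr, TIGHT_RANGE),
            lambda tr: time_in_target(tr, TIGHT_RANGE),
            lambda tr: hyperglycemic_index(tr, TIGHT_RANGE),
            lambda tr: time_to_target(tr, TIGHT_RANGE),
            lambda tr: mean_daily_max_delta(tr),
            lambda tr: sampling_interval_stats(tr)[0],
        ):
            a, b = fn(base), fn(shifted)
            if math.isnan(a):
                assert math.isnan(b)
            else:
                assert a == pytest.approx(b, rel=1e-9)


class TestFullPanel:
    def test_report_fields_consistent(self, tight):
        trace = make_trace(
            [(0, 150), (2, 120), (4, 100), (8, 95), (12, 105), (26, 130), (28, 60)],
            insulin=[(0.0, 28.0, 2.0)],
        )
        rep = compute_metrics(trace, tight)
        assert rep.n_samples == 7
        assert rep.monitored_time == pytest.approx(28.0)
        assert 0 <= rep.gpi <= 100
        assert rep.hypo[70.0]["flag"] and not rep.hypo[40.0]["flag"]
        assert rep.mean_bg == pytest.approx(np.mean([150, 120, 100, 95, 105, 130, 60]))
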