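"""Per-patient glycemic quality, safety, and workload metrics.

The substrate is an irregularly sampled blood-glucose trace with
co-registered insulin, carbohydrate and steroid signals.  All metrics
operate on the intervention period censored at a configurable horizon
(default 14 days = 336 h).  Glucose is mg/dL throughout; time is hours
since the start of blood glucose control.

The headline metric is the glycemic penalty index (GPI): every glucose
sample receives a 0-100 penalty for deviating hypo- or hyperglycemically
from the configured target range, and the GPI is the plain
(sample-weighted) arithmetic mean of those penalties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "GlucoseSample",
    "GlucoseTrace",
    "IntervalSeries",
    "TargetRange",
    "PenaltyFunction",
    "MetricsReport",
    "InvalidSampleError",
    "NoDataError",
    "penalty",
    "compute_gpi",
    "censor_trace",
    "time_in_target",
    "time_to_target",
    "hyperglycemic_index",
    "mean_daily_max_delta",
    "hypoglycemia_incidence",
    "extended_hyperglycemia_episodes",
    "sampling_interval_stats",
    "measurements_per_day",
    "compute_metrics",
]

#: Censoring horizon, hours (14 days).
DEFAULT_CENSOR_H = 336.0

#: Hypoglycemia thresholds, mg/dL, strict ``<`` comparisons.
HYPO_THRESHOLDS = (70.0, 60.0, 40.0)

#: Extended hyperglycemia: this many consecutive samples strictly > 180 mg/dL.
EXTENDED_HYPER_THRESHOLD = 180.0
EXTENDED_HYPER_RUN = 3


class InvalidSampleError(ValueError):
    """A glucose value outside the physically admissible range."""


class NoDataError(ValueError):
    """A metric was requested on a trace with too few samples."""


@dataclass(frozen=True)
class GlucoseSample:
    """One arterial blood-glucose measurement.

    Parameters
    ----------
    t : float
        Hours since the start of blood glucose control, >= 0.
    G : float
        Blood glucose, mg/dL, in (0, 1000).
    """

    t: float
    G: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.t) or self.t < 0:
            raise InvalidSampleError(f"sample time must be finite and >= 0, got {self.t}")
        if not (0 < self.G < 1000):
            raise InvalidSampleError(f"glucose must be in (0, 1000) mg/dL, got {self.G}")


@dataclass(frozen=True)
class IntervalSeries:
    """Piecewise-constant co-signal: ordered (start_h, end_h, value) intervals.

    Used for insulin infusion rate (IU/h), carbohydrate delivery (g/h) and
    steroid exposure (value 1.0 while on).  Gaps between intervals read as 0.
    """

    intervals: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        prev_end = -math.inf
        for start, end, value in self.intervals:
            if end <= start:
                raise ValueError(f"empty interval [{start}, {end}]")
            if start < prev_end:
                raise ValueError("intervals must be ordered and non-overlapping")
            if value < 0:
                raise ValueError(f"negative co-signal value {value}")
            prev_end = end

    def value_at(self, t: float) -> float:
        for start, end, value in self.intervals:
            if start <= t < end:
                return value
        return 0.0

    def integral(self, a: float, b: float) -> float:
        """Integral of the signal over [a, b] (units: value x hours)."""
        total = 0.0
        for start, end, value in self.intervals:
            lo, hi = max(a, start), min(b, end)
            if hi > lo:
                total += value * (hi - lo)
        return total

    def clipped(self, horizon: float) -> "IntervalSeries":
        out = []
        for start, end, value in self.intervals:
            if start >= horizon:
                continue
            out.append((start, min(end, horizon), value))
        return IntervalSeries(tuple(out))


@dataclass(frozen=True)
class GlucoseTrace:
    """A patient's glucose series plus insulin/nutrition/steroid co-signals."""

    patient_id: str
    samples: tuple[GlucoseSample, ...]
    insulin: IntervalSeries = field(default_factory=IntervalSeries)
    carbs: IntervalSeries = field(default_factory=IntervalSeries)
    steroids: IntervalSeries = field(default_factory=IntervalSeries)

    def __post_init__(self) -> None:
        if len(self.samples) == 0:
            raise NoDataError("a trace needs at least one glucose sample")
        times = [s.t for s in self.samples]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("sample times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.samples])

    @property
    def values(self) -> np.ndarray:
        return np.array([s.G for s in self.samples])

    @property
    def monitored_time(self) -> float:
        """Hours between the first and last sample."""
        return self.samples[-1].t - self.samples[0].t


@dataclass(frozen=True)
class TargetRange:
    """The control band [lower, upper] in mg/dL."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (0 < self.lower < self.upper):
            raise ValueError(f"need 0 < lower < upper, got ({self.lower}, {self.upper})")

    def contains(self, G: float) -> bool:
        return self.lower <= G <= self.upper


#: The two site presets used in practice: tight (Leuven/Hasselt) and
#: intermediate (Amsterdam).
TIGHT_RANGE = TargetRange(80.0, 110.0)
INTERMEDIATE_RANGE = TargetRange(90.0, 145.0)


@dataclass(frozen=True)
class PenaltyFunction:
    """Deviation penalty in [0, 100], zero inside the target range.

    A piecewise power law anchored to the target range: below the lower
    limit the penalty grows as ``((L-G)/(L-hypo_saturation))**hypo_exponent``
    and saturates at 100 at ``hypo_saturation`` (default 20 mg/dL); above
    the upper limit symmetrically with ``hyper_saturation`` (default
    250 mg/dL).  The coefficients are configuration so an alternative
    published curve can be substituted.
    """

    hypo_saturation: float = 20.0
    hyper_saturation: float = 250.0
    hypo_exponent: float = 2.0
    hyper_exponent: float = 2.0

    def __post_init__(self) -> None:
        if self.hypo_exponent < 1 or self.hyper_exponent < 1:
            raise ValueError("penalty exponents must be >= 1")

    def _validate_range(self, target: TargetRange) -> None:
        if not (self.hypo_saturation < target.lower):
            raise ValueError("hypo saturation must lie below the target lower limit")
        if not (self.hyper_saturation > target.upper):
            raise ValueError("hyper saturation must lie above the target upper limit")

    def __call__(self, G, target: TargetRange):
        """Vectorized penalty; accepts scalars or arrays of glucose in mg/dL."""
        self._validate_range(target)
        G_arr = np.asarray(G, dtype=float)
        if np.any(G_arr <= 0):
            raise InvalidSampleError("glucose must be positive")
        L, U = target.lower, target.upper
        hypo = 100.0 * np.minimum(
            1.0, ((L - G_arr) / (L - self.hypo_saturation)) ** self.hypo_exponent
        )
        hyper = 100.0 * np.minimum(
            1.0, ((G_arr - U) / (self.hyper_saturation - U)) ** self.hyper_exponent
        )
        out = np.where(G_arr < L, hypo, np.where(G_arr > U, hyper, 0.0))
        return float(out) if np.isscalar(G) or G_arr.ndim == 0 else out


def penalty(G: float, target: TargetRange, pf: PenaltyFunction | None = None) -> float:
    """Penalty of a single glucose value, 0-100 (0 inside the target range)."""
    pf = pf or PenaltyFunction()
    return pf(float(G), target)


def compute_gpi(
    trace: GlucoseTrace, target: TargetRange, pf: PenaltyFunction | None = None
) -> float:
    """Glycemic penalty index: the sample-weighted mean of per-sample penalties."""
    pf = pf or PenaltyFunction()
    return float(np.mean(pf(trace.values, target)))


def censor_trace(trace: GlucoseTrace, horizon_h: float = DEFAULT_CENSOR_H) -> GlucoseTrace:
    """Truncate a trace and its co-signals at ``horizon_h`` hours."""
    if horizon_h <= 0:
        raise ValueError("censoring horizon must be positive")
    samples = tuple(s for s in trace.samples if s.t <= horizon_h)
    if not samples:
        raise NoDataError(f"no samples at or before {horizon_h} h")
    return replace(
        trace,
        samples=samples,
        insulin=trace.insulin.clipped(horizon_h),
        carbs=trace.carbs.clipped(horizon_h),
        steroids=trace.steroids.clipped(horizon_h),
    )


def _segment_time_in_band(t1, g1, t2, g2, L, U) -> float:
    """Time the linear interpolant on [t1, t2] spends inside [L, U]."""
    dt = t2 - t1
    if g1 == g2:
        return dt if L <= g1 <= U else 0.0
    # Times at which the line enters/leaves the band, found analytically.
    slope = (g2 - g1) / dt
    lo, hi = (g1, g2) if g1 < g2 else (g2, g1)
    enter_g = max(lo, L)
    leave_g = min(hi, U)
    if enter_g > leave_g:
        return 0.0
    return abs(leave_g - enter_g) / abs(slope)


def time_in_target(trace: GlucoseTrace, target: TargetRange) -> float:
    """Percent of monitored time with glucose inside the target range.

    Glucose between samples is linearly interpolated and band crossings are
    located analytically.  With a single sample the monitored time is zero
    and the result degenerates to 100 (in range) or 0.
    """
    ts, gs = trace.times, trace.values
    if len(ts) < 2:
        return 100.0 if target.contains(gs[0]) else 0.0
    total = ts[-1] - ts[0]
    inside = sum(
        _segment_time_in_band(ts[i], gs[i], ts[i + 1], gs[i + 1], target.lower, target.upper)
        for i in range(len(ts) - 1)
    )
    return 100.0 * inside / total


def time_to_target(trace: GlucoseTrace, target: TargetRange) -> float:
    """Hours until the interpolated glucose first lies in the target range.

    Returns 0 when the first sample is already in range, and ``nan`` when
    the band is never reached.
    """
    ts, gs = trace.times, trace.values
    if target.contains(gs[0]):
        return 0.0
    for i in range(len(ts) - 1):
        t1, g1, t2, g2 = ts[i], gs[i], ts[i + 1], gs[i + 1]
        if g1 == g2:
            continue
        slope = (g2 - g1) / (t2 - t1)
        # Earliest boundary crossing into the band on this segment.
        candidates = []
        for bound in (target.lower, target.upper):
            tc = t1 + (bound - g1) / slope
            if t1 <= tc <= t2:
                candidates.append(tc)
        if target.contains(g2) and not candidates:
            candidates.append(t2)
        for tc in sorted(candidates):
            g_at = g1 + slope * (tc - t1)
            if target.lower - 1e-9 <= g_at <= target.upper + 1e-9:
                return float(tc - ts[0])
    return math.nan


def hyperglycemic_index(trace: GlucoseTrace, target: TargetRange) -> float:
    """Time-normalized area of the glucose curve above the upper target limit.

    Integrates ``max(0, G(t) - U)`` over the monitored period (linear
    interpolation, crossings handled exactly) and divides by the monitored
    time.  Units: mg/dL.
    """
    ts, gs = trace.times, trace.values
    if len(ts) < 2:
        raise NoDataError("hyperglycemic index needs >= 2 samples")
    U = target.upper
    area = 0.0
    for i in range(len(ts) - 1):
        t1, g1, t2, g2 = ts[i], gs[i], ts[i + 1], gs[i + 1]
        e1, e2 = g1 - U, g2 - U
        dt = t2 - t1
        if e1 <= 0 and e2 <= 0:
            continue
        if e1 >= 0 and e2 >= 0:
            area += 0.5 * (e1 + e2) * dt
        else:
            # One crossing: triangle on the positive side.
            frac = abs(e1) / (abs(e1) + abs(e2))
            if e1 > 0:
                area += 0.5 * e1 * frac * dt
            else:
                area += 0.5 * e2 * (1 - frac) * dt
    return area / (ts[-1] - ts[0])


def mean_daily_max_delta(trace: GlucoseTrace, window_h: float = 24.0) -> float:
    """Mean over consecutive 24-h windows (from t=0) of max(G) - min(G).

    Windows with fewer than two samples are skipped; ``nan`` when no window
    qualifies.  A marker of glycemic variability.
    """
    ts, gs = trace.times, trace.values
    rel = ts - ts[0]
    n_windows = int(math.floor(rel[-1] / window_h)) + 1
    deltas = []
    for k in range(n_windows):
        mask = (rel >= k * window_h) & (rel < (k + 1) * window_h)
        if mask.sum() >= 2:
            deltas.append(gs[mask].max() - gs[mask].min())
    return float(np.mean(deltas)) if deltas else math.nan


def hypoglycemia_incidence(
    trace: GlucoseTrace, thresholds: Sequence[float] = HYPO_THRESHOLDS
) -> dict[float, dict]:
    """Per-threshold hypoglycemia: any-sample flag and strict-below counts."""
    gs = trace.values
    return {
        float(th): {"flag": bool(np.any(gs < th)), "count": int(np.sum(gs < th))}
        for th in thresholds
    }


def extended_hyperglycemia_episodes(
    trace: GlucoseTrace,
    threshold: float = EXTENDED_HYPER_THRESHOLD,
    run_length: int = EXTENDED_HYPER_RUN,
) -> int:
    """Number of maximal runs of >= ``run_length`` consecutive samples > threshold."""
    episodes = 0
    run = 0
    for g in trace.values:
        if g > threshold:
            run += 1
            if run == run_length:
                episodes += 1
        else:
            run = 0
    return episodes


def sampling_interval_stats(trace: GlucoseTrace) -> tuple[float, float]:
    """Mean and SD (ddof=1) of successive sample-time differences, hours."""
    ts = trace.times
    if len(ts) < 2:
        raise NoDataError("sampling interval needs >= 2 samples")
    diffs = np.diff(ts)
    sd = float(np.std(diffs, ddof=1)) if len(diffs) > 1 else 0.0
    return float(np.mean(diffs)), sd


def measurements_per_day(mean_interval_h: float) -> float:
    """Implied number of blood glucose measurements per day, 24 / mean interval."""
    if mean_interval_h <= 0:
        raise ValueError("mean sampling interval must be positive")
    return 24.0 / mean_interval_h


@dataclass(frozen=True)
class MetricsReport:
    """All per-patient endpoints computed from one censored trace."""

    patient_id: str
    gpi: float
    mean_bg: float
    hgi: float
    tir_pct: float
    time_to_target: float
    mean_daily_max_delta: float
    hypo: dict[float, dict]
    extended_hyper_episodes: int
    mean_sampling_interval: float
    sd_sampling_interval: float
    n_samples: int
    monitored_time: float

    def __post_init__(self) -> None:
        assert 0 <= self.gpi <= 100
        assert 0 <= self.tir_pct <= 100
        assert self.hgi >= 0

    def to_dict(self) -> dict:
        d = {
            "patient_id": self.patient_id,
            "gpi": self.gpi,
            "mean_bg": self.mean_bg,
            "hgi": self.hgi,
            "tir_pct": self.tir_pct,
            "time_to_target": self.time_to_target,
            "mean_daily_max_delta": self.mean_daily_max_delta,
            "extended_hyper_episodes": self.extended_hyper_episodes,
            "mean_sampling_interval": self.mean_sampling_interval,
            "sd_sampling_interval": self.sd_sampling_interval,
            "n_samples": self.n_samples,
            "monitored_time": self.monitored_time,
        }
        for th, rec in self.hypo.items():
            d[f"hypo{int(th)}_flag"] = rec["flag"]
            d[f"hypo{int(th)}_count"] = rec["count"]
        return d


def compute_metrics(
    trace: GlucoseTrace,
    target: TargetRange,
    pf: PenaltyFunction | None = None,
    censor_h: float = DEFAULT_CENSOR_H,
) -> MetricsReport:
    """Censor a trace and compute the full endpoint panel."""
    tr = censor_trace(trace, censor_h)
    n = len(tr.samples)
    if n >= 2:
        mean_dt, sd_dt = sampling_interval_stats(tr)
        hgi = hyperglycemic_index(tr, target)
    else:
        mean_dt = sd_dt = math.nan
        hgi = max(0.0, tr.values[0] - target.upper)
    return MetricsReport(
        patient_id=tr.patient_id,
        gpi=compute_gpi(tr, target, pf),
        mean_bg=float(np.mean(tr.values)),
        hgi=hgi,
        tir_pct=time_in_target(tr, target),
        time_to_target=time_to_target(tr, target),
        mean_daily_max_delta=mean_daily_max_delta(tr),
        hypo=hypoglycemia_incidence(tr),
        extended_hyper_episodes=extended_hyperglycemia_episodes(tr),
        mean_sampling_interval=mean_dt,
        sd_sampling_interval=sd_dt,
        n_samples=n,
        monitored_time=tr.monitored_time,
    )
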