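"""Open-loop advisory insulin-dosing controller.

The controller mirrors the architecture of algorithm-guided blood glucose
control software used in ICUs: a two-phase adaptive patient model plus an
advisory layer.  Phase 1 initializes an insulin-sensitivity prior from
admission covariates (diabetes, admission type, illness severity).
Phase 2 refits the model at every measurement from the observed glucose,
the insulin dose sequence, carbohydrate delivery and steroid exposure,
using recursive least squares with a forgetting factor.

The advisory layer evaluates every candidate infusion rate on a fixed
grid, predicts glucose at the planned next sample via the model's balance
equation, and recommends the rate minimizing the predicted deviation
penalty (ties broken toward the lower, hypoglycemia-averse rate).  It also
chooses the next sampling time and advises dextrose rescue during
hypoglycemia.  Every recommendation is confirmable/overrulable by the
bedside nurse; this module also audits those overrules and protocol
compliance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .glycemetrics import (
    GlucoseTrace,
    InvalidSampleError,
    PenaltyFunction,
    TargetRange,
)

__all__ = [
    "AdmissionProfile",
    "ControllerConfig",
    "ControllerModel",
    "DoseAdvice",
    "OverruleRecord",
    "initialize_model",
    "update_model",
    "advise",
    "classify_overrule",
    "overrule_summary",
    "detect_noncompliance",
    "check_stop_conditions",
    "PatientFlags",
]

AdmissionType = Literal["cardiac_surgery", "other_surgery", "medical", "transplant"]
ADMISSION_TYPES = ("cardiac_surgery", "other_surgery", "medical", "transplant")


@dataclass(frozen=True)
class AdmissionProfile:
    """Phase-1 covariates available at ICU admission."""

    diabetes: bool
    apache2: float
    admission_type: str
    admission_glucose: float
    on_insulin_at_admission: bool = False
    center: str = "A"
    center_target: TargetRange = field(default_factory=lambda: TargetRange(80.0, 110.0))

    def __post_init__(self) -> None:
        if self.apache2 < 0:
            raise ValueError("APACHE-II score must be >= 0")
        if self.admission_glucose <= 0:
            raise InvalidSampleError("admission glucose must be positive")
        if self.admission_type not in ADMISSION_TYPES:
            raise ValueError(f"unknown admission type {self.admission_type!r}")


# Prior insulin-sensitivity gains, (mg/dL per h) per (IU/h), keyed on
# (diabetes, admission_type, apache2 band).  Diabetic priors are lower
# (insulin resistance); higher severity lowers the prior further.  All
# values are configuration, not published coefficients.
_DEFAULT_SENSITIVITY_PRIORS: dict[tuple[bool, str, str], float] = {}
for _adm, _base in (
    ("cardiac_surgery", 2.8),
    ("other_surgery", 2.6),
    ("medical", 2.4),
    ("transplant", 2.2),
):
    for _dia, _dia_mult in ((False, 1.0), (True, 0.7)):
        for _band, _sev_mult in (("low", 1.1), ("mid", 1.0), ("high", 0.85)):
            _DEFAULT_SENSITIVITY_PRIORS[(_dia, _adm, _band)] = _base * _dia_mult * _sev_mult


def _apache_band(score: float) -> str:
    if score < 15:
        return "low"
    if score < 25:
        return "mid"
    return "high"


@dataclass(frozen=True)
class ControllerConfig:
    """Tunable envelope of the controller; all gains and menus live here."""

    sensitivity_priors: dict = field(
        default_factory=lambda: dict(_DEFAULT_SENSITIVITY_PRIORS)
    )
    s_hat_bounds: tuple[float, float] = (1.0, 20.0)
    forgetting: float = 0.9
    carb_coef: float = 2.0  # mg/dL rise per gram of carbohydrate
    steroid_drift_factor: float = 1.3
    rate_grid_step: float = 0.1  # IU/h, matches the minor-overrule granularity
    max_rate: float = 50.0  # IU/h
    sample_menu: tuple[float, ...] = (0.5, 1.0, 2.0, 3.0, 4.0)
    prediction_horizon: float = 4.0  # h, horizon used for the dose search
    aim_fraction: float = 0.5  # in-band setpoint, as a fraction of (U - L) above L
    setpoint_weight: float = 1.0  # weight of the in-band setpoint shaping term
    dextrose_g: float = 10.0
    hypo_rescue_threshold: float = 70.0
    dose_change_alert: float = 2.0  # IU/h change forcing a short resample
    max_dose_step: float = 3.0  # IU/h cap on a single upward dose adjustment
    penalty: PenaltyFunction = field(default_factory=PenaltyFunction)

    def __post_init__(self) -> None:
        if not self.sensitivity_priors:
            raise ValueError("sensitivity prior table must be non-empty")
        if not (0 < self.forgetting <= 1):
            raise ValueError("forgetting factor must lie in (0, 1]")
        lo, hi = self.s_hat_bounds
        if not (0 < lo < hi):
            raise ValueError("sensitivity bounds must be positive and ordered")


@dataclass(frozen=True)
class ControllerModel:
    """Phase-2 adaptive linear glucose balance.

    The discrete balance over one inter-sample interval is

        dG/dt = g_drift * (steroid factor) + carb_coef * carbs - s_hat * u

    where ``u`` is the mean insulin rate over the interval.  ``g_drift``
    (mg/dL/h) and ``s_hat`` ((mg/dL/h) per IU/h) are refit recursively at
    every new sample with forgetting factor ``lambda``; ``P`` is the 2x2
    RLS covariance over (g_drift, s_hat).
    """

    s_hat: float
    g_drift: float
    P: tuple[tuple[float, float], tuple[float, float]]
    forgetting: float
    n_updates: int = 0

    def predict_slope(self, u: float, carbs: float, steroid_on: bool,
                      config: ControllerConfig) -> float:
        drift = self.g_drift * (config.steroid_drift_factor if steroid_on else 1.0)
        return drift + config.carb_coef * carbs - self.s_hat * u


@dataclass(frozen=True)
class DoseAdvice:
    """The controller's output contract for one measurement."""

    insulin_rate: float  # IU/h on the configured grid
    next_sample_in: float  # h, from the sampling menu
    dextrose_g: float = 0.0
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.insulin_rate < 0 or self.dextrose_g < 0:
            raise ValueError("rates and dextrose must be non-negative")


@dataclass(frozen=True)
class OverruleRecord:
    """A nurse deviation from the advised rate; class depends only on |delta|."""

    advised: float
    administered: float
    justified: bool = False

    @property
    def klass(self) -> str:
        return classify_overrule(self.advised, self.administered)


def initialize_model(profile: AdmissionProfile, config: ControllerConfig | None = None
                     ) -> ControllerModel:
    """Phase 1: set the sensitivity prior from the admission covariates."""
    config = config or ControllerConfig()
    key = (profile.diabetes, profile.admission_type, _apache_band(profile.apache2))
    try:
        s0 = config.sensitivity_priors[key]
    except KeyError as exc:
        raise ValueError(f"no sensitivity prior configured for {key}") from exc
    lo, hi = config.s_hat_bounds
    s0 = min(max(s0, lo), hi)
    # Large prior covariance: the data dominate as soon as they arrive.
    return ControllerModel(
        s_hat=s0,
        g_drift=0.0,
        P=((1e4, 0.0), (0.0, 1e4)),
        forgetting=config.forgetting,
    )


def update_model(
    model: ControllerModel,
    trace: GlucoseTrace,
    config: ControllerConfig | None = None,
) -> ControllerModel:
    """Phase 2: one RLS step on the latest inter-sample interval.

    Uses the last two samples of ``trace`` plus the co-registered mean
    insulin rate, carbohydrate rate and steroid exposure over that
    interval.  The regression target is the observed glucose slope; the
    regressors are the (steroid-scaled) drift intercept and the negated
    mean insulin rate.  Zero-length intervals are skipped; ``s_hat`` is
    clipped to its configured bounds.
    """
    config = config or ControllerConfig()
    if len(trace.samples) < 2:
        raise ValueError("model update needs at least two glucose samples")
    s1, s2 = trace.samples[-2], trace.samples[-1]
    dt = s2.t - s1.t
    if dt <= 0:
        return model
    slope = (s2.G - s1.G) / dt
    u_bar = trace.insulin.integral(s1.t, s2.t) / dt
    c_bar = trace.carbs.integral(s1.t, s2.t) / dt
    steroid_on = trace.steroids.integral(s1.t, s2.t) > 0.5 * dt

    # y = theta . x with theta = (g_drift, s_hat); the known carbohydrate
    # term is moved to the left-hand side.
    y = slope - config.carb_coef * c_bar
    x = np.array([config.steroid_drift_factor if steroid_on else 1.0, -u_bar])
    theta = np.array([model.g_drift, model.s_hat])
    P = np.array(model.P)
    lam = model.forgetting

    Px = P @ x
    denom = lam + x @ Px
    gain = Px / denom
    theta = theta + gain * (y - theta @ x)
    P = (P - np.outer(gain, Px)) / lam

    lo, hi = config.s_hat_bounds
    return replace(
        model,
        g_drift=float(theta[0]),
        s_hat=float(min(max(theta[1], lo), hi)),
        P=tuple(map(tuple, P)),
        n_updates=model.n_updates + 1,
    )


def _pick_interval(menu: Sequence[float], hours: float) -> float:
    """Largest menu entry <= hours (smallest entry if none)."""
    eligible = [m for m in menu if m <= hours + 1e-9]
    return max(eligible) if eligible else min(menu)


def advise(
    model: ControllerModel,
    trace: GlucoseTrace,
    target: TargetRange,
    config: ControllerConfig | None = None,
    current_rate: float = 0.0,
    insulin_started: bool | None = None,
) -> DoseAdvice:
    """Advise insulin rate, next sampling time and dextrose for the latest sample.

    Every candidate rate on the grid (step ``rate_grid_step`` from 0 to
    ``max_rate``) is scored by the deviation penalty of the glucose
    predicted at the search horizon; the minimizing rate wins, ties broken
    toward the lower rate.  Insulin is only advised once glycemia has
    exceeded the upper target limit at least once.  Dextrose rescue is
    advised below 70 mg/dL, with insulin off and an urgent resample.
    """
    config = config or ControllerConfig()
    if model is None:
        raise ValueError("controller model is not initialized")
    latest = trace.samples[-1]
    G = latest.G
    if G <= 0:
        raise InvalidSampleError("glucose must be positive")

    warnings: list[str] = []
    if G < config.hypo_rescue_threshold:
        warnings.append("hypoglycemia")
        return DoseAdvice(
            insulin_rate=0.0,
            next_sample_in=min(config.sample_menu),
            dextrose_g=config.dextrose_g,
            warnings=tuple(warnings),
        )

    if insulin_started is None:
        insulin_started = bool(np.any(trace.values > target.upper))
    if not insulin_started:
        # Insulin treatment initiates only after glycemia exceeds the
        # upper target limit; until then no infusion is advised.
        return DoseAdvice(insulin_rate=0.0, next_sample_in=max(config.sample_menu))

    c_now = trace.carbs.value_at(latest.t)
    steroid_on = trace.steroids.value_at(latest.t) > 0.5
    h = config.prediction_horizon
    rates = np.round(
        np.arange(0.0, config.max_rate + config.rate_grid_step / 2, config.rate_grid_step),
        10,
    )
    drift = model.g_drift * (config.steroid_drift_factor if steroid_on else 1.0)
    preds = G + h * (drift + config.carb_coef * c_now - model.s_hat * rates)
    preds = np.maximum(preds, 1.0)
    # Predicted deviation penalty, plus a small quadratic pull toward a
    # mid-band setpoint: the penalty alone is flat across the whole target
    # band, and a pure penalty minimum (ties to the lower rate) would park
    # glucose at the upper limit, where any upward disturbance leaves the
    # band.  The shaping term only orders the zero-penalty plateau; out of
    # band the 0-100 penalty dominates.
    setpoint = target.lower + config.aim_fraction * (target.upper - target.lower)
    width = target.upper - target.lower
    costs = config.penalty(preds, target) + config.setpoint_weight * (
        (preds - setpoint) / width
    ) ** 2
    best = int(np.argmin(costs))  # argmin takes the first minimum: lower rate
    rate = float(rates[best])
    G_pred = float(preds[best])
    # Safety rails: upward dose adjustments are rate-limited, and no
    # insulin runs while glucose sits below the lower target limit,
    # whatever the model believes.
    if rate > current_rate + config.max_dose_step:
        # snap the capped rate down onto the advice grid (hypoglycemia-averse)
        capped = current_rate + config.max_dose_step
        rate = math.floor(capped / config.rate_grid_step + 1e-9) * config.rate_grid_step
        rate = round(rate, 10)
        G_pred = float(np.maximum(G + h * (drift + config.carb_coef * c_now
                                           - model.s_hat * rate), 1.0))
    if G < target.lower:
        rate = 0.0
        G_pred = float(np.maximum(preds[0], 1.0))

    # Sampling-time rules: urgent when (predicted) glucose approaches the
    # lower limit, short after a large dose change, longest only when in
    # target at an unchanged rate (a true fixed point), and an
    # intermediate interval otherwise — the algorithm trades a shorter
    # mean interval (more workload) for tighter control.
    menu = config.sample_menu
    steady = abs(rate - current_rate) < config.rate_grid_step / 2
    if G < target.lower or G_pred < target.lower:
        nxt = min(menu)
    elif abs(rate - current_rate) > config.dose_change_alert:
        nxt = _pick_interval(menu, 1.0)
    elif target.contains(G) and target.contains(G_pred) and steady:
        nxt = max(menu)
    else:
        nxt = _pick_interval(menu, 2.0)

    return DoseAdvice(insulin_rate=rate, next_sample_in=nxt, warnings=tuple(warnings))


def classify_overrule(advised: float, administered: float) -> str:
    """Classify a nurse deviation: none (<=0.1), minor (>0.1 and <1), major (>=1 IU/h)."""
    if advised < 0 or administered < 0:
        raise ValueError("insulin rates must be non-negative")
    d = abs(advised - administered)
    eps = 1e-9  # printed thresholds are exact; guard float representation only
    if d <= 0.1 + eps:
        return "none"
    if d < 1.0 - eps:
        return "minor"
    return "major"


def overrule_summary(records: Sequence[OverruleRecord], n_advice: int) -> dict[str, float]:
    """Percentage of minor and major overrules among advice instances (2 d.p.)."""
    if n_advice <= 0:
        raise ValueError("need at least one advice instance")
    n_minor = sum(1 for r in records if r.klass == "minor")
    n_major = sum(1 for r in records if r.klass == "major")
    if n_minor + n_major > n_advice:
        raise ValueError("more overrules than advice instances")
    return {
        "minor_pct": round(100.0 * n_minor / n_advice, 2),
        "major_pct": round(100.0 * n_major / n_advice, 2),
    }


def detect_noncompliance(use_times: Sequence[float], gap_h: float = 8.0
                         ) -> list[tuple[float, float]]:
    """Gaps of at least ``gap_h`` hours between consecutive software uses.

    Returns the list of (start, end) gap episodes; a patient with one or
    more episodes is protocol non-compliant.
    """
    ts = sorted(use_times)
    return [
        (t1, t2) for t1, t2 in zip(ts, ts[1:]) if t2 - t1 >= gap_h
    ]


@dataclass(frozen=True)
class PatientFlags:
    """Event flags feeding the discontinuation rules."""

    oral_intake: bool = False
    line_removed: bool = False
    discharged: bool = False
    palliative: bool = False
    severe_hypo_count: int = 0
    glucose: float = 100.0
    insulin_rate: float = 0.0


def check_stop_conditions(flags: PatientFlags, config: ControllerConfig | None = None
                          ) -> str | None:
    """Return a stop reason, or None to continue blood glucose control.

    Control stops on oral carbohydrate intake, removal of the
    arterial/central line, discharge, palliative care, recurrent severe
    hypoglycemia (>= 2 episodes < 40 mg/dL), or refractory hyperglycemia
    (> 180 mg/dL while insulin runs at the maximum rate).
    """
    config = config or ControllerConfig()
    if flags.oral_intake:
        return "oral_intake"
    if flags.line_removed:
        return "line_removed"
    if flags.discharged:
        return "discharged"
    if flags.palliative:
        return "palliative"
    if flags.severe_hypo_count >= 2:
        return "recurrent_severe_hypo"
    if flags.glucose > 180.0 and flags.insulin_rate >= config.max_rate:
        return "refractory_hyper"
    return None
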