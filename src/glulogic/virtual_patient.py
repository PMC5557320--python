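"""Stochastic virtual ICU patient and cohort generator.

A deliberately minimal two-compartment glucose-insulin model — enough
structure to exercise an adaptive dosing controller (drifting insulin
sensitivity, steroid and nutrition disturbances) without claiming
physiological fidelity:

    dG/dt = EGP_eff + rho * carbs(t) - (k0 + S_I(t) * I) * G
    dI/dt = u / V_I - kI * I

with G plasma glucose (mg/dL), I effective plasma insulin (IU-eq/L),
u the infusion rate (IU/h), EGP endogenous glucose appearance scaled by
a steroid factor while steroids run, and S_I the insulin sensitivity
following a seeded mean-reverting log random walk.  Analytic steady
states (G -> EGP/k0 untreated) make the integrator testable.

The cohort generator draws admission profiles matching a mixed
surgical/medical ICU population: ~60% cardiac surgery, ~22% diabetes,
APACHE-II ~ Normal(20, 9) truncated at 0, admission glucose lognormal
with median 127 and IQR 108-153 mg/dL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .controller import (
    AdmissionProfile,
    ControllerConfig,
    PatientFlags,
    advise,
    check_stop_conditions,
    initialize_model,
    update_model,
)
from .glycemetrics import (
    GlucoseSample,
    GlucoseTrace,
    IntervalSeries,
    TargetRange,
)
from .nurse import NurseProtocolConfig, advise_nurse

__all__ = [
    "PatientState",
    "DisturbanceSchedule",
    "SimConfig",
    "CohortMix",
    "step_dynamics",
    "measure",
    "generate_cohort",
    "run_closed_loop",
]


@dataclass(frozen=True)
class PatientState:
    """Physiological state and parameters of one virtual patient."""

    G: float  # plasma glucose, mg/dL
    I: float = 0.0  # effective plasma insulin, IU-eq/L
    S_I: float = 0.5  # insulin sensitivity, (dL/IU)-scale gain per h
    EGP: float = 14.0  # endogenous glucose appearance, mg/dL/h
    k0: float = 0.1  # insulin-independent clearance, 1/h
    kI: float = 2.0  # insulin decay, 1/h
    V_I: float = 10.0  # insulin distribution volume, L

    def __post_init__(self) -> None:
        for name in ("G", "S_I", "EGP", "k0", "kI", "V_I"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.I < 0:
            raise ValueError("insulin state must be non-negative")


@dataclass(frozen=True)
class SimConfig:
    """Simulation-wide knobs shared by dynamics and harness."""

    rk4_dt: float = 0.05  # h, internal fixed integration step (upper bound)
    carb_rho: float = 2.0  # mg/dL/h glucose appearance per g/h carbs
    steroid_egp_factor: float = 1.3
    measurement_cv: float = 0.02
    dextrose_mgdl_per_g: float = 2.0  # glucose rise per gram of rescue dextrose
    glucose_floor: float = 1.0
    glucose_ceil: float = 999.0


@dataclass(frozen=True)
class DisturbanceSchedule:
    """Seed-reproducible external disturbances for one patient.

    Carbohydrates and steroids are piecewise-constant signals; the
    insulin-sensitivity multiplier is a mean-reverting log random walk
    sampled on an hourly grid and held constant within each hour.
    """

    carbs: IntervalSeries = field(default_factory=IntervalSeries)
    steroids: IntervalSeries = field(default_factory=IntervalSeries)
    si_times: tuple[float, ...] = (0.0,)
    si_multipliers: tuple[float, ...] = (1.0,)

    def si_multiplier_at(self, t: float) -> float:
        idx = int(np.searchsorted(np.asarray(self.si_times), t, side="right")) - 1
        idx = max(0, min(idx, len(self.si_multipliers) - 1))
        return self.si_multipliers[idx]

    @staticmethod
    def generate(
        rng: np.random.Generator,
        duration_h: float,
        feed_rate: float = 1.75,
        feed_start: float = 8.0,
        steroid_p: float = 0.22,
        si_reversion: float = 0.05,
        si_volatility: float = 0.03,
    ) -> "DisturbanceSchedule":
        carbs = ()
        if feed_rate > 0 and feed_start < duration_h:
            carbs = ((feed_start, duration_h, feed_rate),)
        steroids: tuple = ()
        if rng.random() < steroid_p:
            start = float(rng.uniform(0, duration_h / 2))
            steroids = ((start, min(start + float(rng.uniform(24, 72)), duration_h), 1.0),)
        # Hourly Ornstein-Uhlenbeck walk on log S_I around its admission value.
        n = int(math.ceil(duration_h)) + 1
        x = np.zeros(n)
        for k in range(1, n):
            x[k] = x[k - 1] * (1 - si_reversion) + si_volatility * rng.standard_normal()
        return DisturbanceSchedule(
            carbs=IntervalSeries(carbs),
            steroids=IntervalSeries(steroids),
            si_times=tuple(float(t) for t in range(n)),
            si_multipliers=tuple(np.exp(x)),
        )


def _derivs(G, I, u, S_I_eff, EGP_eff, carb_rate, state: PatientState, cfg: SimConfig):
    dG = EGP_eff + cfg.carb_rho * carb_rate - (state.k0 + S_I_eff * I) * G
    dI = u / state.V_I - state.kI * I
    return dG, dI


def step_dynamics(
    state: PatientState,
    u: float,
    dt: float,
    carb_rate: float = 0.0,
    steroid_on: bool = False,
    si_multiplier: float = 1.0,
    config: SimConfig | None = None,
) -> PatientState:
    """Advance the two-ODE model by ``dt`` hours under constant inputs.

    Fixed-step classical RK4 with an internal step of at most
    ``config.rk4_dt`` (default 0.05 h).  Glucose is clamped to
    (floor, ceil) as a hard safety rail.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if u < 0:
        raise ValueError("insulin rate must be non-negative")
    cfg = config or SimConfig()
    EGP_eff = state.EGP * (cfg.steroid_egp_factor if steroid_on else 1.0)
    S_I_eff = state.S_I * si_multiplier
    n_sub = max(1, int(math.ceil(dt / cfg.rk4_dt)))
    h = dt / n_sub
    G, I = state.G, state.I
    for _ in range(n_sub):
        k1 = _derivs(G, I, u, S_I_eff, EGP_eff, carb_rate, state, cfg)
        k2 = _derivs(G + h / 2 * k1[0], I + h / 2 * k1[1], u, S_I_eff, EGP_eff, carb_rate, state, cfg)
        k3 = _derivs(G + h / 2 * k2[0], I + h / 2 * k2[1], u, S_I_eff, EGP_eff, carb_rate, state, cfg)
        k4 = _derivs(G + h * k3[0], I + h * k3[1], u, S_I_eff, EGP_eff, carb_rate, state, cfg)
        G += h / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        I += h / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
    G = min(max(G, cfg.glucose_floor), cfg.glucose_ceil)
    return replace(state, G=G, I=max(I, 0.0))


def measure(
    state: PatientState, rng: np.random.Generator, cv: float = 0.02
) -> float:
    """One glucose measurement: multiplicative Gaussian noise, floored at 1 mg/dL."""
    if cv < 0:
        raise ValueError("coefficient of variation must be >= 0")
    g = state.G * (1.0 + cv * rng.standard_normal()) if cv > 0 else state.G
    return max(g, 1.0)


@dataclass(frozen=True)
class CohortMix:
    """Admission mix of the generated cohort (defaults match a mixed ICU)."""

    cardiac: float = 0.60
    other_surgery: float = 0.19
    medical: float = 0.18
    transplant: float = 0.03
    diabetes: float = 0.216
    apache_mean: float = 20.0
    apache_sd: float = 9.0
    glucose_log_median: float = 127.0
    glucose_log_sigma: float = 0.2582  # matches IQR 108-153 around median 127
    on_insulin_p: float = 0.215
    centers: tuple[tuple[str, float, float, float], ...] = (
        # (name, probability, target lower, target upper)
        ("Leuven", 0.55, 80.0, 110.0),
        ("Hasselt", 0.30, 80.0, 110.0),
        ("Amsterdam", 0.15, 90.0, 145.0),
    )

    def __post_init__(self) -> None:
        probs = (self.cardiac, self.other_surgery, self.medical, self.transplant,
                 self.diabetes, self.on_insulin_p) + tuple(p for _, p, _, _ in self.centers)
        if any(not (0 <= p <= 1) for p in probs):
            raise ValueError("mix probabilities must lie in [0, 1]")


def generate_cohort(
    n: int,
    mix: CohortMix | None = None,
    seed: int | None = None,
    duration_h: float = 72.0,
) -> list[tuple[AdmissionProfile, PatientState, DisturbanceSchedule]]:
    """Draw ``n`` virtual patients with admission profiles matching the mix.

    Deterministic for a fixed seed.  Patient physiology is drawn so that
    untreated simulated patients settle hyperglycemic (roughly
    140-250 mg/dL), mirroring an insulin-requiring ICU population;
    diabetic patients receive a lower insulin sensitivity.
    """
    if n <= 0:
        raise ValueError("cohort size must be positive")
    mix = mix or CohortMix()
    rng = np.random.default_rng(seed)
    adm_types = ("cardiac_surgery", "other_surgery", "medical", "transplant")
    adm_p = np.array([mix.cardiac, mix.other_surgery, mix.medical, mix.transplant])
    adm_p = adm_p / adm_p.sum()
    center_names = [c[0] for c in mix.centers]
    center_p = np.array([c[1] for c in mix.centers])
    center_p = center_p / center_p.sum()
    center_targets = {c[0]: TargetRange(c[2], c[3]) for c in mix.centers}

    cohort = []
    for _ in range(n):
        adm_type = str(rng.choice(adm_types, p=adm_p))
        diabetes = bool(rng.random() < mix.diabetes)
        apache = float(max(0.0, rng.normal(mix.apache_mean, mix.apache_sd)))
        adm_glucose = float(
            np.exp(np.log(mix.glucose_log_median) + mix.glucose_log_sigma * rng.standard_normal())
        )
        adm_glucose = min(max(adm_glucose, 40.0), 600.0)
        center = str(rng.choice(center_names, p=center_p))
        profile = AdmissionProfile(
            diabetes=diabetes,
            apache2=apache,
            admission_type=adm_type,
            admission_glucose=adm_glucose,
            on_insulin_at_admission=bool(rng.random() < mix.on_insulin_p),
            center=center,
            center_target=center_targets[center],
        )
        s_i = float(np.exp(np.log(0.5) + 0.25 * rng.standard_normal()))
        if diabetes:
            s_i *= 0.7
        state = PatientState(
            G=adm_glucose,
            S_I=s_i,
            EGP=float(rng.uniform(14.0, 24.0)),
        )
        schedule = DisturbanceSchedule.generate(rng, duration_h)
        cohort.append((profile, state, schedule))
    return cohort


def _simulate_interval(
    state: PatientState,
    t0: float,
    t1: float,
    u: float,
    schedule: DisturbanceSchedule,
    cfg: SimConfig,
) -> PatientState:
    """Integrate across an inter-sample interval, honoring disturbance breakpoints."""
    breaks = {t0, t1}
    for series in (schedule.carbs, schedule.steroids):
        for s, e, _ in series.intervals:
            for b in (s, e):
                if t0 < b < t1:
                    breaks.add(b)
    for b in schedule.si_times:
        if t0 < b < t1:
            breaks.add(b)
    pts = sorted(breaks)
    for a, b in zip(pts, pts[1:]):
        mid = 0.5 * (a + b)
        state = step_dynamics(
            state,
            u,
            b - a,
            carb_rate=schedule.carbs.value_at(mid),
            steroid_on=schedule.steroids.value_at(mid) > 0.5,
            si_multiplier=schedule.si_multiplier_at(mid),
            config=cfg,
        )
    return state


def run_closed_loop(
    profile: AdmissionProfile,
    state: PatientState,
    schedule: DisturbanceSchedule,
    policy: str = "controller",
    duration_h: float = 72.0,
    seed: int | None = None,
    sim_config: SimConfig | None = None,
    controller_config: ControllerConfig | None = None,
    nurse_config: NurseProtocolConfig | None = None,
    patient_id: str = "p0",
) -> tuple[GlucoseTrace, list[dict], str | None]:
    """Simulate one patient under a dosing policy.

    Alternates measure -> advise -> administer -> integrate until
    ``duration_h`` or a stop condition.  Returns the audited glucose
    trace (with the administered insulin as a co-signal), the advice log
    (one dict per measurement), and the stop reason if any.
    """
    if duration_h <= 0:
        raise ValueError("duration must be positive")
    if policy not in ("controller", "nurse"):
        raise ValueError(f"unknown policy {policy!r}")
    cfg = sim_config or SimConfig()
    rng = np.random.default_rng(seed)
    target = profile.center_target

    samples: list[GlucoseSample] = []
    insulin_iv: list[tuple[float, float, float]] = []
    log: list[dict] = []
    model = initialize_model(profile, controller_config) if policy == "controller" else None
    t = 0.0
    rate = 0.0
    insulin_started = profile.on_insulin_at_admission
    severe_hypo = 0
    stop_reason: str | None = None

    while t <= duration_h + 1e-9:
        g_meas = measure(state, rng, cfg.measurement_cv)
        samples.append(GlucoseSample(t=t, G=g_meas))
        trace_now = GlucoseTrace(
            patient_id=patient_id,
            samples=tuple(samples),
            insulin=IntervalSeries(tuple(insulin_iv)),
            carbs=schedule.carbs.clipped(t + 1e-6),
            steroids=schedule.steroids.clipped(t + 1e-6),
        )
        if g_meas > target.upper:
            insulin_started = True
        if g_meas < 40.0:
            severe_hypo += 1

        if policy == "controller":
            if len(samples) >= 2:
                model = update_model(model, trace_now, controller_config)
            advice = advise(
                model, trace_now, target, controller_config,
                current_rate=rate, insulin_started=insulin_started,
            )
        else:
            advice = advise_nurse(
                trace_now, target, nurse_config, rng,
                current_rate=rate, insulin_started=insulin_started,
            )

        flags = PatientFlags(
            severe_hypo_count=severe_hypo,
            glucose=g_meas,
            insulin_rate=rate,
        )
        stop_reason = check_stop_conditions(flags, controller_config)
        log.append({
            "patient_id": patient_id,
            "t_h": t,
            "glucose_mgdl": g_meas,
            "advised_IU_h": advice.insulin_rate,
            "administered_IU_h": advice.insulin_rate,
            "next_sample_h": advice.next_sample_in,
            "dextrose_g": advice.dextrose_g,
            "warnings": ";".join(advice.warnings),
        })
        if stop_reason is not None:
            break

        rate = advice.insulin_rate
        if advice.dextrose_g > 0:
            state = replace(
                state,
                G=min(state.G + cfg.dextrose_mgdl_per_g * advice.dextrose_g,
                      cfg.glucose_ceil),
            )
        t_next = min(t + advice.next_sample_in, duration_h)
        if t_next <= t + 1e-9:
            break
        if rate > 0:
            insulin_iv.append((t, t_next, rate))
        state = _simulate_interval(state, t, t_next, rate, schedule, cfg)
        t = t_next

    end_t = samples[-1].t if samples else duration_h
    trace = GlucoseTrace(
        patient_id=patient_id,
        samples=tuple(samples),
        insulin=IntervalSeries(tuple(insulin_iv)),
        carbs=schedule.carbs.clipped(max(end_t, 1e-6)),
        steroids=schedule.steroids.clipped(max(end_t, 1e-6)),
    )
    return trace, log, stop_reason
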