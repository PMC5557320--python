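# Methods

This note documents the models, defaults and design decisions behind
`glulogic`, and what the test suite does and does not establish.

## Glycemic metrics

All metrics operate on an irregularly sampled glucose trace (mg/dL,
hours) censored at 336 h (14 days, configurable). Between samples the
trace is linearly interpolated; band and threshold crossings are located
analytically, so time-in-target and the hyperglycemic index are exact for
the interpolant rather than grid approximations. A dense-grid numerical
integrator (Δt = 0.001 h) serves as an independent oracle in the tests.

The penalty function behind the glycemic penalty index is a piecewise
power law anchored to the configured target range: zero inside [L, U],
rising as the squared normalized deviation outside, saturating at 100 at
20 mg/dL (hypoglycemic side) and 250 mg/dL (hyperglycemic side). The
published index this emulates is defined by an externally calibrated
curve that is not reproduced here; the implemented form satisfies the
same contract (0–100, zero exactly in target, monotone in deviation,
penalizing both zones) and every coefficient — saturation points and
exponents — is configuration, so a user holding the original calibration
can substitute it. GPI is the *sample-weighted* mean of per-sample
penalties (not time-weighted), which makes it invariant under duplicating
the sample vector but sensitive to sampling frequency; that matches how
the index is defined clinically.

Conventions fixed where the source material is silent:

- hypoglycemia and hyperglycemia thresholds are strict (<70, <60, <40;
  >180 mg/dL);
- the 24-h windows for the daily maximum glucose excursion start at the
  first sample of the trace (keeping every metric invariant under time
  translation) and windows with fewer than two samples are skipped;
- the sampling-interval summary is the mean and SD of successive
  sample-time differences;
- with a single sample, time-in-target degenerates to 100%/0% by
  membership, and the sampling interval is undefined (NaN).

## Advisory controller

The controller is an open-loop advisory system in the architecture of
clinically deployed algorithm-guided BGC software: phase 1 sets an
insulin-sensitivity prior from admission covariates (diabetes, admission
type, APACHE-II band; diabetic and sicker patients get lower priors);
phase 2 refits a linear glucose balance

    dG/dt = g_drift · (steroid factor) + carb_coef · carbs − s_hat · u

by recursive least squares with forgetting factor λ = 0.9 at every new
measurement, with `s_hat` clipped to configurable bounds (default
1–20 (mg/dL/h)/(IU/h)). The carbohydrate coefficient is treated as a
known covariate and moved to the regression's left-hand side; steroids
scale the drift regressor. With λ = 1 and a diffuse prior the estimate
coincides with batch least squares, which the tests verify against a
`numpy.linalg.lstsq` oracle. The exact equations of the original clinical
software are proprietary and are not claimed here; this module reproduces
the stated architecture, and all gains are configuration.

The dose search scores every candidate rate on a 0.1 IU/h grid (0 to
50 IU/h) by the deviation penalty of the glucose predicted at a 4-h
horizon, ties broken toward the lower (hypoglycemia-averse) rate. Two
additions proved necessary in closed loop:

- **In-band setpoint shaping.** The penalty is identically zero across
  the whole target band, so a pure penalty minimum with a lower-rate
  tie-break always selects the least insulin whose prediction touches
  the *upper* limit — the controller then parks glucose at U and any
  upward disturbance leaves the band. A small quadratic term
  `((G_pred − G_set)/(U−L))²` with `G_set` at mid-band (aim_fraction 0.5,
  weight 1) orders the zero-penalty plateau without affecting the
  out-of-band optimum, where the 0–100 penalty dominates.
- **Safety rails.** Upward dose adjustments are capped at 3 IU/h per
  advice (snapped down onto the grid), and insulin is forced off while
  glucose sits below L. Without these, rare estimator transients after a
  hypoglycemia rescue (the sensitivity estimate collapsing to its lower
  bound while the drift estimate is inflated by the rebound) could advise
  maximum-rate insulin into a patient still carrying plasma insulin.

Resampling comes from the menu {0.5, 1, 2, 3, 4} h: 0.5 h when current or
predicted glucose is below L (or after a rescue), 1 h after a dose change
above 2 IU/h, 4 h only at a true fixed point (in target, unchanged rate),
otherwise 2 h. These rules give the simulated controller arm a mean
interval near 2.3 h versus ~2.8 h for the nurse comparator — the
algorithm deliberately trades sampling workload for tighter control.
Dextrose rescue (default 10 g) is advised below 70 mg/dL, and insulin is
only initiated once glycemia has exceeded U at least once.

Overrule auditing classifies |advised − administered| as none (≤0.1),
minor (>0.1 and <1) or major (≥1 IU/h); protocol non-compliance is a gap
of ≥8 h between software uses. Stop conditions: oral carbohydrate intake,
line removal, discharge, palliative care, two severe hypoglycemia
episodes, or glucose >180 mg/dL at the maximum rate.

## Nurse comparator

A sliding-scale protocol expressed relative to the target range (bands:
<70, below L, in target, U to U+35, to U+70, above), with rate
adjustments {stop, −1, 0, +0.5, +1, +2} IU/h, an up-titration halved when
glucose is already falling, and sampling intervals of 4 h in target, 2 h
out, 1 h after hypoglycemia. The single behavioral dial is **leniency**
(default 0.25): the probability of deferring an up-titration while
glucose sits between U and U+35 — modeling the tendency, under broader
targets, to tolerate values near the upper limit. On a fixed 100-patient
cohort, mean simulated glucose rises monotonically over the leniency grid
{0, 0.25, 0.5}.

## Virtual patient

A deliberately minimal two-ODE model:

    dG/dt = EGP_eff + ρ·carbs(t) − (k0 + S_I(t)·I)·G
    dI/dt = u/V_I − kI·I

Defaults: EGP 14–24 mg/dL/h (drawn per patient so the untreated steady
state EGP/k0 lies at 140–240 mg/dL — an insulin-requiring population),
k0 = 0.1 /h, kI = 2 /h, V_I = 10 L, ρ = 2 (mg/dL/h per g/h), steroid
factor 1.3 on EGP. S_I ~ lognormal around 0.5 (diabetics ×0.7) and drifts
as an hourly mean-reverting log random walk (reversion 0.05 /h,
volatility 0.03), emulating critical-illness sensitivity swings.
Integration is fixed-step RK4 at ≤0.05 h, validated against a step-halved
oracle (≤0.01 mg/dL over 72 h). Measurements carry multiplicative
Gaussian noise (CV 2% by default, the scale of arterial blood-gas
analyzers).

The cohort generator matches a mixed surgical/medical ICU: 60% cardiac
surgery / 19% other surgery / 18% medical / 3% transplant, 21.6%
diabetes, APACHE-II ~ N(20, 9²) truncated at 0, admission glucose
lognormal calibrated to median 127 and IQR 108–153 mg/dL, three centers
(55/30/15%) carrying the 80–110 and 90–145 mg/dL target presets, 72-h
default stay. Feeding starts at 8 h at 1.75 g/h (≈42 g/day).

What this simulator does **not** capture: meal absorption kinetics,
hepatic/renal insulin compartments, diurnal rhythm, sensor drift or
inter-device bias, and the long-tailed severity mix of a real ICU. The
in-silico protocol contrast is therefore a *direction* check — the
simulated effect sizes (e.g., controller-arm GPI near 0–1 versus ~2 for
the nurse arm) are much larger than clinical ones, because the virtual
patients are easier to control than real ones. Passing tests show the
machinery is internally consistent and the protocols behave as designed,
not that clinical effect sizes are reproduced.

## Trial engine

Stratified permuted-block randomization: blocks of 10 (5+5) per center ×
(cardiac vs other) stratum; cardiac enrolment is refused once it would
exceed 60% of the target enrolment. Sample sizes use the normal
approximation: two means `n = 2((z_{1−α/2}+z_{1−β})σ/Δ)²` and two
proportions in the Fleiss form (pooled variance under the null, unpooled
under the alternative, no continuity correction) — these are the forms
that reproduce the registered 458/707/769 exactly, so z rather than t
quantiles are adopted throughout. Confidence intervals are percentile
bootstrap (B = 2000 by default). Continuous endpoints are compared with
the Wilcoxon rank-sum test (Student's t for mean glucose and the sampling
interval), proportions with chi-square, switching to Fisher's exact test
when any expected cell is below 5; no multiplicity correction, matching
the original analysis plan. Per-sample hypoglycemia proportions pool
counts across each arm's samples. Subgroup tables are filtered reruns of
the same comparison.

## Problem sizes and determinism

The default in-silico trial is 400 patients × 72 h (a few seconds on one
CPU); the test suite's heavier checks use 100–200 simulated patients or
100 seeds per property. Every stochastic component — cohort, disturbance
paths, measurement noise, randomization, bootstrap — derives from a
single integer seed via `numpy` `SeedSequence` spawning, so identical
seeds give bit-identical traces, and trace CSVs round-trip exactly
(`%.17g` writing, round-trip float parsing).
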