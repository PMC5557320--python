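"""Trial design machinery: randomization, power, and arm comparison.

Implements the statistical design of a two-arm ICU glycemic-control
trial: stratified permuted-block randomization (blocks of 10 per
center x admission-type stratum, with a cap on cardiac-surgery
enrolment), the pre-registered sample-size calculations for two means
and two proportions, bootstrap percentile confidence intervals, and a
per-arm endpoint comparison table with Wilcoxon rank-sum, t and
chi-square / Fisher exact tests (no multiplicity correction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .glycemetrics import GlucoseTrace, MetricsReport

__all__ = [
    "TrialDesign",
    "PowerSpec",
    "randomize",
    "sample_size_two_means",
    "sample_size_two_props",
    "bootstrap_ci",
    "compare_arms",
    "daily_exposure_summary",
]

ARMS = ("Nurse-C", "LOGIC-C")


@dataclass(frozen=True)
class TrialDesign:
    """Randomization scheme and censoring for the in-silico trial."""

    arms: tuple[str, str] = ARMS
    block_size: int = 10
    cardiac_cap: float = 0.60
    censor_h: float = 336.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.block_size % 2 != 0:
            raise ValueError("block size must be even for 1:1 within-block balance")
        if not (0 < self.cardiac_cap <= 1):
            raise ValueError("cardiac cap must lie in (0, 1]")


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of a two-sided sample-size calculation (equal allocation)."""

    alpha: float = 0.05
    power: float = 0.90
    mu1: float | None = None
    mu2: float | None = None
    sigma: float | None = None
    p1: float | None = None
    p2: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1) or not (0 < self.power < 1):
            raise ValueError("alpha and power must lie in (0, 1)")


def _stratum(profile) -> tuple[str, str]:
    cardiac = "cardiac" if profile.admission_type == "cardiac_surgery" else "other"
    return (profile.center, cardiac)


def randomize(
    profiles: Sequence,
    design: TrialDesign | None = None,
    seed: int | None = None,
) -> tuple[list[str | None], list[int]]:
    """Stratified permuted-block 1:1 assignment with a cardiac enrolment cap.

    Within each center x (cardiac vs other) stratum, consecutive patients
    fill random permutations of ``block_size/2`` labels per arm.  Once
    enrolling another cardiac-surgery patient would push the cardiac
    fraction above ``cardiac_cap`` of the total target enrolment, cardiac
    patients are refused (assignment ``None``).

    Returns (assignments aligned with ``profiles``, indices of enrolled
    patients).  Deterministic per seed.
    """
    design = design or TrialDesign()
    if seed is None:
        seed = design.seed
    rng = np.random.default_rng(seed)
    n_target = len(profiles)
    max_cardiac = int(math.floor(design.cardiac_cap * n_target))

    blocks: dict[tuple[str, str], list[str]] = {}
    assignments: list[str | None] = []
    enrolled: list[int] = []
    n_cardiac = 0
    half = design.block_size // 2
    for i, profile in enumerate(profiles):
        stratum = _stratum(profile)
        cardiac = stratum[1] == "cardiac"
        if cardiac and n_cardiac >= max_cardiac:
            assignments.append(None)
            continue
        if not blocks.get(stratum):
            block = [design.arms[0]] * half + [design.arms[1]] * half
            blocks[stratum] = list(rng.permutation(block))
        assignments.append(blocks[stratum].pop(0))
        enrolled.append(i)
        if cardiac:
            n_cardiac += 1
    return assignments, enrolled


def sample_size_two_means(spec: PowerSpec) -> int:
    """Patients per arm to detect mu1 vs mu2 with common sigma (z approximation).

    n = ceil( 2 * ((z_{1-a/2} + z_{1-b}) * sigma / delta)^2 )
    """
    if spec.mu1 is None or spec.mu2 is None or spec.sigma is None:
        raise ValueError("two-mean calculation needs mu1, mu2 and sigma")
    delta = spec.mu1 - spec.mu2
    if delta == 0:
        raise ValueError("effect size must be non-zero")
    if spec.sigma <= 0:
        raise ValueError("sigma must be positive")
    za = stats.norm.ppf(1 - spec.alpha / 2)
    zb = stats.norm.ppf(spec.power)
    return max(1, math.ceil(2 * ((za + zb) * spec.sigma / abs(delta)) ** 2))


def sample_size_two_props(spec: PowerSpec) -> int:
    """Patients per arm to detect p1 vs p2 (Fleiss form, no continuity correction).

    Pooled variance under the null, unpooled under the alternative:

    n = ceil( ( z_{1-a/2} sqrt(2 pbar qbar) + z_{1-b} sqrt(p1 q1 + p2 q2) )^2
              / (p1 - p2)^2 )
    """
    if spec.p1 is None or spec.p2 is None:
        raise ValueError("two-proportion calculation needs p1 and p2")
    p1, p2 = spec.p1, spec.p2
    if not (0 < p1 < 1 and 0 < p2 < 1):
        raise ValueError("proportions must lie in (0, 1)")
    if p1 == p2:
        raise ValueError("proportions must differ")
    za = stats.norm.ppf(1 - spec.alpha / 2)
    zb = stats.norm.ppf(spec.power)
    pbar = (p1 + p2) / 2
    num = za * math.sqrt(2 * pbar * (1 - pbar)) + zb * math.sqrt(
        p1 * (1 - p1) + p2 * (1 - p2)
    )
    return max(1, math.ceil((num / (p1 - p2)) ** 2))


def bootstrap_ci(
    values: Sequence[float],
    statistic: Callable[[np.ndarray], float] = np.median,
    B: int = 2000,
    seed: int | None = None,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval of a statistic."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("bootstrap needs at least 2 values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(x), size=(B, len(x)))
    boot = np.array([statistic(x[row]) for row in idx])
    lo, hi = np.percentile(boot, [100 * (1 - level) / 2, 100 * (1 + level) / 2])
    return float(lo), float(hi)


# Endpoints summarized as median (IQR) with Wilcoxon rank-sum tests vs the
# single mean (SD) endpoint tested with Student's t.
_MEDIAN_FIELDS = (
    "gpi",
    "hgi",
    "tir_pct",
    "time_to_target",
    "mean_daily_max_delta",
    "monitored_time",
)
_MEAN_FIELDS = ("mean_bg", "mean_sampling_interval")


def _prop_test(k1: int, n1: int, k2: int, n2: int) -> float:
    """Chi-square test of a 2x2 table; Fisher exact when any expected cell < 5."""
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
    if table.min() < 0 or n1 == 0 or n2 == 0:
        return math.nan
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    if table.sum() == 0 or (col == 0).any():
        return math.nan
    expected = row * col / table.sum()
    if expected.min() < 5:
        return float(stats.fisher_exact(table)[1])
    return float(stats.chi2_contingency(table, correction=False)[1])


def compare_arms(
    reports: Sequence[MetricsReport],
    assignments: Sequence[str],
    design: TrialDesign | None = None,
    seed: int | None = None,
    B: int = 2000,
) -> pd.DataFrame:
    """Per-arm endpoint comparison in the shape of a trial summary table.

    Continuous endpoints are reported as median (IQR) with bootstrap
    percentile 95% CIs of the median and Wilcoxon rank-sum p-values
    (mean/SD and Student's t for mean blood glucose and the sampling
    interval); hypoglycemia and extended hyperglycemia are reported per
    patient as n (%) with chi-square / Fisher p-values, and per sample by
    pooling counts across each arm.  P-values are two-sided and carry no
    multiplicity correction.
    """
    design = design or TrialDesign()
    if len(reports) != len(assignments):
        raise ValueError("reports and assignments must align")
    arm_reports: dict[str, list[MetricsReport]] = {a: [] for a in design.arms}
    for rep, arm in zip(reports, assignments):
        if arm is None:
            continue
        arm_reports[arm].append(rep)
    for arm, reps in arm_reports.items():
        if not reps:
            raise ValueError(f"arm {arm!r} is empty")

    a0, a1 = design.arms
    rows = []
    rng = np.random.default_rng(seed)

    def _values(arm: str, field_name: str) -> np.ndarray:
        vals = np.array([getattr(r, field_name) for r in arm_reports[arm]], dtype=float)
        return vals[~np.isnan(vals)]

    for field_name in _MEDIAN_FIELDS + _MEAN_FIELDS:
        x0, x1 = _values(a0, field_name), _values(a1, field_name)
        if len(x0) < 2 or len(x1) < 2:
            continue
        if field_name in _MEAN_FIELDS:
            stat = np.mean
            p = float(stats.ttest_ind(x0, x1, equal_var=False).pvalue)
            summ0 = f"{np.mean(x0):.1f} ({np.std(x0, ddof=1):.1f})"
            summ1 = f"{np.mean(x1):.1f} ({np.std(x1, ddof=1):.1f})"
        else:
            stat = np.median
            p = float(stats.mannwhitneyu(x0, x1, alternative="two-sided").pvalue)
            q0 = np.percentile(x0, [25, 50, 75])
            q1 = np.percentile(x1, [25, 50, 75])
            summ0 = f"{q0[1]:.1f} ({q0[0]:.1f}-{q0[2]:.1f})"
            summ1 = f"{q1[1]:.1f} ({q1[0]:.1f}-{q1[2]:.1f})"
        ci0 = bootstrap_ci(x0, stat, B=B, seed=int(rng.integers(2**31)))
        ci1 = bootstrap_ci(x1, stat, B=B, seed=int(rng.integers(2**31)))
        rows.append({
            "endpoint": field_name,
            f"{a0}": summ0, f"{a0}_ci": ci0,
            f"{a1}": summ1, f"{a1}_ci": ci1,
            f"{a0}_value": float(stat(x0)), f"{a1}_value": float(stat(x1)),
            "p_value": p,
        })

    # Hypoglycemia per patient (flags) and per sample (pooled counts), plus
    # extended hyperglycemia per patient.
    for th in (70, 60, 40):
        n0, n1 = len(arm_reports[a0]), len(arm_reports[a1])
        k0 = sum(r.hypo[float(th)]["flag"] for r in arm_reports[a0])
        k1 = sum(r.hypo[float(th)]["flag"] for r in arm_reports[a1])
        rows.append({
            "endpoint": f"hypo{th}_patients",
            f"{a0}": f"{k0} ({100 * k0 / n0:.1f})",
            f"{a1}": f"{k1} ({100 * k1 / n1:.1f})",
            f"{a0}_value": 100 * k0 / n0, f"{a1}_value": 100 * k1 / n1,
            "p_value": _prop_test(k0, n0, k1, n1),
        })
        s0 = sum(r.n_samples for r in arm_reports[a0])
        s1 = sum(r.n_samples for r in arm_reports[a1])
        c0 = sum(r.hypo[float(th)]["count"] for r in arm_reports[a0])
        c1 = sum(r.hypo[float(th)]["count"] for r in arm_reports[a1])
        rows.append({
            "endpoint": f"hypo{th}_samples",
            f"{a0}": f"{c0} ({100 * c0 / s0:.2f})",
            f"{a1}": f"{c1} ({100 * c1 / s1:.2f})",
            f"{a0}_value": 100 * c0 / s0, f"{a1}_value": 100 * c1 / s1,
            "p_value": _prop_test(c0, s0, c1, s1),
        })
    n0, n1 = len(arm_reports[a0]), len(arm_reports[a1])
    e0 = sum(r.extended_hyper_episodes > 0 for r in arm_reports[a0])
    e1 = sum(r.extended_hyper_episodes > 0 for r in arm_reports[a1])
    rows.append({
        "endpoint": "extended_hyper_patients",
        f"{a0}": f"{e0} ({100 * e0 / n0:.1f})",
        f"{a1}": f"{e1} ({100 * e1 / n1:.1f})",
        f"{a0}_value": 100 * e0 / n0, f"{a1}_value": 100 * e1 / n1,
        "p_value": _prop_test(e0, n0, e1, n1),
    })

    return pd.DataFrame(rows)


def compare_subgroup(
    reports: Sequence[MetricsReport],
    assignments: Sequence[str],
    mask: Sequence[bool],
    **kwargs,
) -> pd.DataFrame:
    """Filtered rerun of :func:`compare_arms` on a preplanned subgroup."""
    reps = [r for r, m in zip(reports, mask) if m]
    arms = [a for a, m in zip(assignments, mask) if m]
    return compare_arms(reps, arms, **kwargs)


def daily_exposure_summary(traces: Sequence[GlucoseTrace]) -> pd.DataFrame:
    """Per-patient daily insulin (IU/day) and carbohydrate (g/day) exposure.

    Time-integral of each co-signal over the monitored period divided by
    the monitored time in days.
    """
    rows = []
    for tr in traces:
        t0, t1 = tr.samples[0].t, tr.samples[-1].t
        days = max((t1 - t0) / 24.0, 1e-12)
        rows.append({
            "patient_id": tr.patient_id,
            "insulin_IU_day": tr.insulin.integral(t0, t1) / days,
            "carbs_g_day": tr.carbs.integral(t0, t1) / days,
        })
    return pd.DataFrame(rows)
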