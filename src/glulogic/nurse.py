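"""Rule-based nurse comparator for in-silico arm-vs-arm trials.

Emulates nurse-directed blood glucose control with a sliding-scale dose
table and band-based sampling intervals.  The single behavioral dial is
*leniency*: the probability that the nurse defers a recommended dose
increase while glucose sits moderately above the upper target limit —
the tendency, under broader targets, to tolerate values near the upper
limit rather than up-titrate.

The sliding scale is expressed relative to the target range so that the
same table serves both the tight (80-110 mg/dL) and intermediate
(90-145 mg/dL) site presets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .controller import DoseAdvice
from .glycemetrics import GlucoseTrace, TargetRange

__all__ = ["NurseProtocolConfig", "advise_nurse"]


@dataclass(frozen=True)
class NurseProtocolConfig:
    """Sliding scale, sampling rules, and the leniency dial.

    ``sliding_scale`` maps glucose bands to rate adjustments (IU/h); bands
    are offsets relative to the target limits L and U so they partition
    (0, inf) for any range.  ``sampling_rules`` maps the same bands to
    resampling intervals (h).  ``leniency`` in [0, 1] is the probability
    of deferring an up-titration when L <= G < U + leniency_window.
    """

    # (band key, rate adjustment IU/h); bands evaluated top-down.
    sliding_scale: tuple[tuple[str, float], ...] = (
        ("below_70", -99.0),       # stop insulin
        ("below_L", -1.0),
        ("in_target", 0.0),
        ("above_U", 0.5),
        ("above_U35", 1.0),
        ("above_U70", 2.0),
    )
    sampling_rules: tuple[tuple[str, float], ...] = (
        ("below_70", 1.0),
        ("below_L", 2.0),
        ("in_target", 4.0),
        ("above_U", 2.0),
        ("above_U35", 2.0),
        ("above_U70", 2.0),
    )
    leniency: float = 0.25
    leniency_window: float = 35.0  # mg/dL above U where deferral applies
    max_rate: float = 50.0
    dextrose_g: float = 10.0

    def __post_init__(self) -> None:
        if not (0 <= self.leniency <= 1):
            raise ValueError("leniency must lie in [0, 1]")
        if any(iv <= 0 for _, iv in self.sampling_rules):
            raise ValueError("sampling intervals must be positive")
        needed = {"below_70", "below_L", "in_target", "above_U", "above_U35", "above_U70"}
        if needed - {k for k, _ in self.sliding_scale}:
            raise ValueError("sliding scale must cover all glucose bands")


def _band(G: float, target: TargetRange) -> str:
    if G < 70.0:
        return "below_70"
    if G < target.lower:
        return "below_L"
    if G <= target.upper:
        return "in_target"
    if G <= target.upper + 35.0:
        return "above_U"
    if G <= target.upper + 70.0:
        return "above_U35"
    return "above_U70"


def advise_nurse(
    trace: GlucoseTrace,
    target: TargetRange,
    config: NurseProtocolConfig | None = None,
    rng: np.random.Generator | None = None,
    current_rate: float = 0.0,
    insulin_started: bool | None = None,
) -> DoseAdvice:
    """Nurse dose decision for the latest sample of ``trace``.

    Deterministic table lookup on the latest glucose band, adjusted by the
    slope sign (a falling glucose halves an up-titration); the stochastic
    leniency dial defers up-titration in the band just above the upper
    limit with the configured probability.
    """
    config = config or NurseProtocolConfig()
    rng = rng if rng is not None else np.random.default_rng()
    latest = trace.samples[-1]
    G = latest.G
    band = _band(G, target)
    scale = dict(config.sliding_scale)
    intervals = dict(config.sampling_rules)
    if band not in scale:
        raise ValueError(f"unconfigured glucose band {band!r}")

    if insulin_started is None:
        insulin_started = bool(np.any(trace.values > target.upper))

    if band == "below_70":
        return DoseAdvice(
            insulin_rate=0.0,
            next_sample_in=intervals[band],
            dextrose_g=config.dextrose_g,
            warnings=("hypoglycemia",),
        )

    adjust = scale[band]
    # Slope sign: when glucose is already falling, halve an up-titration.
    if adjust > 0 and len(trace.samples) >= 2 and trace.samples[-2].G > G:
        adjust *= 0.5
    # Leniency: defer a recommended increase while G is above U but below
    # the leniency window.
    if (
        adjust > 0
        and target.upper < G < target.upper + config.leniency_window
        and config.leniency > 0
        and rng.random() < config.leniency
    ):
        adjust = 0.0
    if not insulin_started:
        adjust = min(adjust, 0.0)

    rate = min(max(current_rate + adjust, 0.0), config.max_rate)
    return DoseAdvice(insulin_rate=round(rate, 1), next_sample_in=intervals[band])
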