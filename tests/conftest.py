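import numpy as np
import pytest

from glulogic import (
    GlucoseSample,
    GlucoseTrace,
    IntervalSeries,
    TargetRange,
)


def make_trace(points, patient_id="p", insulin=(), carbs=(), steroids=()):
    """Build a trace from (t, G) pairs and optional co-signal interval tuples."""
    return GlucoseTrace(
        patient_id=patient_id,
        samples=tuple(GlucoseSample(t=float(t), G=float(g)) for t, g in points),
        insulin=IntervalSeries(tuple(insulin)),
        carbs=IntervalSeries(tuple(carbs)),
        steroids=IntervalSeries(tuple(steroids)),
    )


@pytest.fixture
def tight():
    return TargetRange(80.0, 110.0)


@pytest.fixture
def intermediate():
    return TargetRange(90.0, 145.0)


def random_trace(rng, n=50, t_max=100.0, lo=40.0, hi=400.0):
    """Random irregular trace for oracle comparisons."""
    ts = np.sort(rng.uniform(0, t_max, size=n))
    ts += np.arange(n) * 1e-3  # enforce strict monotonicity
    gs = rng.uniform(lo, hi, size=n)
    return make_trace(zip(ts, gs))
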