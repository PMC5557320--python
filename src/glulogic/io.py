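"""CSV/JSON formats for traces, co-signals, metrics and configs.

Trace CSV schema: ``patient_id, t_hours, glucose_mgdl`` (comma-separated,
UTF-8, mandatory header, ``#``-prefixed comment lines carry seed/config
provenance).  Co-signal CSV schema: ``patient_id, start_h, end_h,
channel, value`` with channel one of ``insulin_IU_h``, ``carbs_g_h``,
``steroid``.  Glucose is mg/dL only; any other unit in a header is an
explicit error, not a silent conversion.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .glycemetrics import (
    GlucoseSample,
    GlucoseTrace,
    IntervalSeries,
    MetricsReport,
)

__all__ = [
    "TraceParseError",
    "read_trace_csv",
    "read_traces_csv",
    "write_trace_csv",
    "metrics_to_frame",
    "config_hash",
]

TRACE_COLUMNS = ("patient_id", "t_hours", "glucose_mgdl")
COSIGNAL_COLUMNS = ("patient_id", "start_h", "end_h", "channel", "value")
_CHANNELS = ("insulin_IU_h", "carbs_g_h", "steroid")


class TraceParseError(ValueError):
    """A trace or co-signal file violates the schema."""


def _read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def read_traces_csv(
    path: str | Path, cosignal_path: str | Path | None = None
) -> dict[str, GlucoseTrace]:
    """Parse a trace CSV (plus optional co-signal CSV) into traces by patient."""
    df = _read_csv(path)
    for col in df.columns:
        if "mmol" in col.lower():
            raise TraceParseError(
                f"unsupported unit in column {col!r}: glucose must be mg/dL"
            )
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise TraceParseError(f"missing columns {sorted(missing)} in {path}")

    cosignals: dict[str, dict[str, list]] = {}
    if cosignal_path is not None:
        cdf = _read_csv(cosignal_path)
        missing = set(COSIGNAL_COLUMNS) - set(cdf.columns)
        if missing:
            raise TraceParseError(f"missing columns {sorted(missing)} in {cosignal_path}")
        for row in cdf.itertuples():
            if row.channel not in _CHANNELS:
                raise TraceParseError(f"unknown co-signal channel {row.channel!r}")
            cosignals.setdefault(str(row.patient_id), {}).setdefault(
                row.channel, []
            ).append((float(row.start_h), float(row.end_h), float(row.value)))

    traces: dict[str, GlucoseTrace] = {}
    for pid, group in df.groupby("patient_id", sort=False):
        times = group["t_hours"].to_numpy(dtype=float)
        for i in range(1, len(times)):
            if times[i] <= times[i - 1]:
                raise TraceParseError(
                    f"non-monotone sample times for patient {pid!r} at row "
                    f"{group.index[i]} (t={times[i]} after t={times[i - 1]})"
                )
        try:
            samples = tuple(
                GlucoseSample(t=float(t), G=float(g))
                for t, g in zip(times, group["glucose_mgdl"])
            )
        except ValueError as exc:
            raise TraceParseError(f"invalid sample for patient {pid!r}: {exc}") from exc
        cs = cosignals.get(str(pid), {})
        traces[str(pid)] = GlucoseTrace(
            patient_id=str(pid),
            samples=samples,
            insulin=IntervalSeries(tuple(sorted(cs.get("insulin_IU_h", ())))),
            carbs=IntervalSeries(tuple(sorted(cs.get("carbs_g_h", ())))),
            steroids=IntervalSeries(tuple(sorted(cs.get("steroid", ())))),
        )
    if not traces:
        raise TraceParseError(f"no samples found in {path}")
    return traces


def read_trace_csv(
    path: str | Path, cosignal_path: str | Path | None = None
) -> GlucoseTrace:
    """Parse a single-patient trace CSV; errors if several patients are present."""
    traces = read_traces_csv(path, cosignal_path)
    if len(traces) != 1:
        raise TraceParseError(
            f"expected one patient in {path}, found {sorted(traces)}"
        )
    return next(iter(traces.values()))


def write_trace_csv(
    traces: GlucoseTrace | Iterable[GlucoseTrace],
    path: str | Path,
    cosignal_path: str | Path | None = None,
    header_comment: str | None = None,
) -> None:
    """Write traces (and optionally co-signals) in the canonical schema."""
    if isinstance(traces, GlucoseTrace):
        traces = [traces]
    traces = list(traces)
    rows = [
        {"patient_id": tr.patient_id, "t_hours": s.t, "glucose_mgdl": s.G}
        for tr in traces
        for s in tr.samples
    ]
    _write_with_comment(pd.DataFrame(rows, columns=list(TRACE_COLUMNS)), path, header_comment)
    if cosignal_path is not None:
        crows = []
        for tr in traces:
            for channel, series in (
                ("insulin_IU_h", tr.insulin),
                ("carbs_g_h", tr.carbs),
                ("steroid", tr.steroids),
            ):
                for start, end, value in series.intervals:
                    crows.append({
                        "patient_id": tr.patient_id, "start_h": start,
                        "end_h": end, "channel": channel, "value": value,
                    })
        _write_with_comment(
            pd.DataFrame(crows, columns=list(COSIGNAL_COLUMNS)), cosignal_path,
            header_comment,
        )


def _write_with_comment(df: pd.DataFrame, path: str | Path, comment: str | None) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def metrics_to_frame(reports: Sequence[MetricsReport]) -> pd.DataFrame:
    """Tidy one-row-per-patient metrics table."""
    return pd.DataFrame([r.to_dict() for r in reports])


def config_hash(config: dict) -> str:
    """Stable short hash of a resolved configuration dict (for provenance)."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
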