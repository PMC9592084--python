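"""File formats: histogram TSV, trace CSV (+JSON sidecar), JSON results.

All formats are plain text and round-trip losslessly: floats are
written with 17 significant digits, counts as integers.  Units are
seconds for time, ns for lifetimes, photon counts for intensities.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .tcspc import TCSPCHistogram
from .traces import ROITrace

__all__ = [
    "write_histogram",
    "read_histogram",
    "write_traces_csv",
    "read_traces_csv",
    "write_json",
    "read_json",
]

_FLOAT_FMT = "%.17g"


def write_histogram(hist: TCSPCHistogram, path: str | Path) -> None:
    """Write one histogram as tab-separated ``bin_start_ns  counts`` with
    ``#``-prefixed header lines carrying channel, frame time and laser
    period."""
    path = Path(path)
    lines = [
        f"# channel: {hist.channel}",
        f"# laser_period_ns: {_FLOAT_FMT % hist.laser_period_ns}",
        f"# frame_time_s: "
        + ("" if hist.frame_time_s is None else _FLOAT_FMT % hist.frame_time_s),
        "# columns: bin_start_ns\tcounts",
    ]
    for start, c in zip(hist.bin_edges[:-1], hist.counts):
        lines.append(f"{_FLOAT_FMT % start}\t{int(c)}")
    path.write_text("\n".join(lines) + "\n")


def read_histogram(path: str | Path) -> TCSPCHistogram:
    path = Path(path)
    channel = "green"
    laser_period = None
    frame_time: float | None = None
    starts: list[float] = []
    counts: list[int] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("channel:"):
                channel = body.split(":", 1)[1].strip()
            elif body.startswith("laser_period_ns:"):
                laser_period = float(body.split(":", 1)[1])
            elif body.startswith("frame_time_s:"):
                val = body.split(":", 1)[1].strip()
                frame_time = float(val) if val else None
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
        try:
            starts.append(float(parts[0]))
            count = int(parts[1])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
        if count < 0:
            raise ValueError(f"{path}:{lineno}: negative count {count}")
        counts.append(count)
    if laser_period is None:
        raise ValueError(f"{path}: missing '# laser_period_ns:' header")
    if len(starts) < 2:
        raise ValueError(f"{path}: too few bins")
    width = starts[1] - starts[0]
    edges = np.array(starts + [starts[-1] + width])
    return TCSPCHistogram(
        bin_edges=edges,
        counts=np.array(counts),
        channel=channel,
        laser_period_ns=laser_period,
        frame_time_s=frame_time,
    )


def write_traces_csv(
    traces: list[ROITrace],
    path: str | Path,
    sidecar: dict | None = None,
) -> None:
    """Write traces as ``roi_id,sensor,time_s,value,units`` rows; stimulus
    metadata goes in a JSON sidecar next to the CSV."""
    path = Path(path)
    rows = []
    meta: dict[str, dict] = {}
    for tr in traces:
        for t, v in zip(tr.times_s, tr.values):
            rows.append(
                {
                    "roi_id": tr.roi_id,
                    "sensor": tr.sensor,
                    "time_s": t,
                    "value": v,
                    "units": tr.units,
                }
            )
        if tr.stim_time_s is not None:
            meta[f"{tr.roi_id}/{tr.sensor}"] = {"stim_time_s": tr.stim_time_s}
    df = pd.DataFrame(rows, columns=["roi_id", "sensor", "time_s", "value", "units"])
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    if sidecar is not None or meta:
        side = dict(sidecar or {})
        side.setdefault("stimuli", meta)
        write_json(side, path.with_suffix(".json"))


def read_traces_csv(path: str | Path) -> list[ROITrace]:
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed CSV: {exc}") from exc
    required = {"roi_id", "sensor", "time_s", "value", "units"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: missing columns {sorted(required - set(df.columns))}"
        )
    stimuli = {}
    sidecar_path = path.with_suffix(".json")
    if sidecar_path.exists():
        stimuli = read_json(sidecar_path).get("stimuli", {})
    traces = []
    for (roi, sensor), grp in df.groupby(["roi_id", "sensor"], sort=False):
        units = grp["units"].iloc[0]
        stim = stimuli.get(f"{roi}/{sensor}", {}).get("stim_time_s")
        traces.append(
            ROITrace(
                roi_id=str(roi),
                sensor=str(sensor),
                times_s=grp["time_s"].to_numpy(),
                values=grp["value"].to_numpy(),
                units=str(units),
                stim_time_s=stim,
            )
        )
    return traces


def _json_default(o):
    if isinstance(o, np.bool_):
        return bool(o)
    if isinstance(o, np.integer):
        return int(o)
    if isinstance(o, np.floating):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o).__name__}")


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n"
    )


def read_json(path: str | Path) -> dict:
    path = Path(path)
    try:
        return json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}:{exc.lineno}: invalid JSON: {exc.msg}") from exc
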