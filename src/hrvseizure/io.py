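"""Plain-text readers and writers for RR series, ECG records and reports.

Formats:
  RR series      CSV ``time_s,rr_ms[,label|flag]`` (one row per interval,
                 ``time_s`` = interval end time)
  ECG record     CSV ``time_s,mv``, or one-sample-per-line text with the
                 sampling rate supplied out of band
  annotations    CSV ``onset_s``
  reports/models JSON
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError
from .records import ECGRecord, RRSeries


def write_rr_csv(
    path: str | Path,
    rr: RRSeries,
    labels: np.ndarray | None = None,
    header_comment: str | None = None,
) -> None:
    """Write an RR series; third column holds labels if given, else flags."""
    third = labels if labels is not None else rr.flags
    df = pd.DataFrame(
        {"time_s": rr.interval_times, "rr_ms": rr.rr, "label": third}
    )
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False, float_format="%.6f")


def read_rr_csv(path: str | Path) -> tuple[RRSeries, np.ndarray | None]:
    """Read ``time_s,rr_ms[,label]``; beat times are reconstructed so that
    each interval ends at its stated time."""
    df = pd.read_csv(path, comment="#")
    if "time_s" not in df or "rr_ms" not in df:
        raise ParameterError("RR CSV must have time_s and rr_ms columns")
    times = df["time_s"].to_numpy(dtype=float)
    rr = df["rr_ms"].to_numpy(dtype=float)
    beat_times = np.concatenate([[times[0] - rr[0] / 1000.0], times])
    labels = df["label"].to_numpy(dtype=object) if "label" in df else None
    return RRSeries(beat_times, rr), labels


def write_ecg_csv(path: str | Path, ecg: ECGRecord) -> None:
    pd.DataFrame({"time_s": ecg.times, "mv": ecg.samples}).to_csv(
        path, index=False, float_format="%.6f"
    )


def read_ecg_csv(path: str | Path) -> ECGRecord:
    df = pd.read_csv(path, comment="#")
    if "time_s" not in df or "mv" not in df:
        raise ParameterError("ECG CSV must have time_s and mv columns")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ParameterError("ECG CSV must contain at least 2 samples")
    fs = 1.0 / float(np.median(np.diff(t)))
    return ECGRecord(df["mv"].to_numpy(dtype=float), fs, start_time=float(t[0]))


def read_ecg_text(path: str | Path, sampling_rate: float) -> ECGRecord:
    """One voltage sample (mV) per line, at a known sampling rate."""
    samples = np.loadtxt(path, dtype=float, ndmin=1)
    return ECGRecord(samples, sampling_rate)


def write_annotations_csv(path: str | Path, onsets: list[float]) -> None:
    pd.DataFrame({"onset_s": onsets}).to_csv(path, index=False)


def read_annotations_csv(path: str | Path) -> list[float]:
    df = pd.read_csv(path, comment="#")
    if "onset_s" not in df:
        raise ParameterError("annotation CSV must have an onset_s column")
    return [float(v) for v in df["onset_s"]]


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
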