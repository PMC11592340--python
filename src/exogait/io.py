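"""CSV readers/writers for the long-format trace tables.

The on-disk format is one long table with columns ``subject_id,
condition, channel, time_s, value`` (channel is a muscle name or
``GRF``), plus an optional JSON sidecar with the generator's ground
truth.  Values round-trip bit-exactly for finite floats because Python's
shortest-repr float formatting is used on write.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import CONDITIONS, MUSCLES, EMGDataset, SubjectRecord
from .trace import ForceTrace

REQUIRED_COLUMNS = ("subject_id", "condition", "channel", "time_s", "value")


class TraceFormatError(ValueError):
    pass


def read_trace_csv(path: str | Path) -> dict[tuple[int, str, str], ForceTrace]:
    """Read a long-format trace table into per-(subject, condition,
    channel) time series.

    Malformed rows raise with the offending line number.
    """
    path = Path(path)
    if not path.exists():
        raise TraceFormatError(f"{path}: no such file")
    if path.stat().st_size == 0:
        raise TraceFormatError(f"{path}: empty input file")
    try:
        # round_trip parsing keeps finite floats bit-exact through the
        # write/read cycle
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as e:
        raise TraceFormatError(f"{path}: empty input file") from e
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TraceFormatError(
            f"{path}: missing header column(s) {missing}; "
            f"expected {list(REQUIRED_COLUMNS)}")
    for col in ("time_s", "value"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(np.where(bad)[0][0]) + 2  # header + 1-based
            raise TraceFormatError(
                f"{path}:{line}: non-numeric {col!r} value {df[col][bad].iloc[0]!r}")
        df[col] = pd.to_numeric(df[col])
    out: dict[tuple[int, str, str], ForceTrace] = {}
    for (sid, cond, chan), g in df.groupby(
            ["subject_id", "condition", "channel"], sort=False):
        units = "N" if chan == "GRF" else "a.u."
        out[(int(sid), str(cond), str(chan))] = ForceTrace(
            g["value"].to_numpy(), g["time_s"].to_numpy(),
            domain="time", units=units, label=str(chan))
    return out


def write_trace_csv(dataset: EMGDataset, path: str | Path) -> None:
    dataset.to_frame().to_csv(path, index=False)


def dataset_from_traces(
    traces: dict[tuple[int, str, str], ForceTrace],
    ground_truth: dict | None = None,
) -> EMGDataset:
    """Rebuild an :class:`EMGDataset` from keyed traces (reader output)."""
    records: list[SubjectRecord] = []
    subjects = sorted({k[0] for k in traces})
    for sid in subjects:
        for cond in CONDITIONS:
            try:
                grf = traces[(sid, cond, "GRF")]
            except KeyError as e:
                raise TraceFormatError(
                    f"subject {sid} condition {cond}: no GRF channel") from e
            envs = {}
            for m in MUSCLES:
                if (sid, cond, m) not in traces:
                    raise TraceFormatError(
                        f"subject {sid} condition {cond}: missing muscle {m}")
                envs[m] = traces[(sid, cond, m)]
            rate = 1.0 / grf.dt
            records.append(SubjectRecord(sid, cond, envs, grf, rate))
    return EMGDataset(records=records, ground_truth=ground_truth or {})


def read_dataset(directory: str | Path) -> EMGDataset:
    """Read a generated dataset directory (CSV + optional sidecar)."""
    directory = Path(directory)
    traces = read_trace_csv(directory / "emg_dataset.csv")
    gt_path = directory / "ground_truth.json"
    gt = json.loads(gt_path.read_text()) if gt_path.exists() else {}
    return dataset_from_traces(traces, gt)
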