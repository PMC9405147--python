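"""CSV readers/writers for every stage boundary.

Raw streams use one file per animal with header ``t,st,activity,roll,y_accel``,
ISO-8601 timestamps and empty fields for missing values; herd metadata is one
CSV per run.  Readers validate monotone timestamps and sensor ranges and name
the offending record in their diagnostics; timestamp gaps are legal and come
back as all-missing rows on the complete 3-min grid, ready for forward-fill.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import AnimalMeta, CADENCE, CHANNELS, SENSOR_RANGES

_FORMATS = {"st": "%.2f", "activity": "%.1f", "roll": "%.2f", "y_accel": "%.0f"}
_TIME_FMT = "%Y-%m-%dT%H:%M:%S"


def write_stream_csv(stream: pd.DataFrame, path: str | Path) -> None:
    """Write one animal's raw stream; missing values become empty fields."""
    lines = ["t," + ",".join(CHANNELS)]
    for t, row in zip(stream.index, stream.itertuples(index=False)):
        fields = [t.strftime(_TIME_FMT)]
        for ch in CHANNELS:
            v = getattr(row, ch)
            fields.append("" if pd.isna(v) else _FORMATS[ch] % v)
        lines.append(",".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def read_stream_csv(path: str | Path) -> pd.DataFrame:
    """Read a raw stream, validating cadence and sensor ranges.

    Returns the stream on the complete 3-min grid between the first and last
    timestamp; rows absent from the file appear as all-NaN records.
    """
    path = Path(path)
    df = pd.read_csv(path)
    expected_cols = ["t", *CHANNELS]
    if list(df.columns) != expected_cols:
        raise ValueError(f"{path}: expected columns {expected_cols}, got {list(df.columns)}")
    if df.empty:
        raise ValueError(f"{path}: no records")
    try:
        ts = pd.to_datetime(df["t"], format=_TIME_FMT)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: malformed timestamp ({exc})") from exc
    deltas = ts.diff().dropna()
    bad = deltas[deltas <= pd.Timedelta(0)]
    if len(bad):
        raise ValueError(f"{path}: non-monotone timestamp at record {bad.index[0]}")
    off_grid = deltas[(deltas % CADENCE) != pd.Timedelta(0)]
    if len(off_grid):
        raise ValueError(f"{path}: timestamp off the 3-min grid at record {off_grid.index[0]}")
    for ch in CHANNELS:
        low, high, _ = SENSOR_RANGES[ch]
        vals = pd.to_numeric(df[ch], errors="coerce")
        bad_parse = df.index[df[ch].notna() & vals.isna()]
        if len(bad_parse):
            raise ValueError(f"{path}: malformed {ch} value at record {bad_parse[0]}")
        out = df.index[(vals < low) | (vals > high)]
        if len(out):
            raise ValueError(
                f"{path}: {ch} value {vals[out[0]]} outside [{low}, {high}] at record {out[0]}")
        df[ch] = vals
    stream = df.drop(columns="t").set_index(pd.Index(ts, name="t"))
    full = pd.date_range(ts.iloc[0], ts.iloc[-1], freq=CADENCE)
    return stream.reindex(pd.Index(full, name="t"))


def write_herd_csv(metas: list[AnimalMeta], path: str | Path) -> None:
    lines = ["animal_id,housing,expected_calving,actual_calving,stream_start,stream_end"]
    for m in metas:
        lines.append(",".join([
            m.animal_id, m.housing,
            m.expected_calving.strftime(_TIME_FMT),
            m.actual_calving.strftime(_TIME_FMT),
            m.stream_start.strftime(_TIME_FMT),
            m.stream_end.strftime(_TIME_FMT),
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_herd_csv(path: str | Path) -> list[AnimalMeta]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"herd metadata file not found: {path}")
    df = pd.read_csv(path)
    metas = []
    for row in df.itertuples(index=False):
        metas.append(AnimalMeta(
            animal_id=str(row.animal_id),
            housing=row.housing,
            expected_calving=pd.Timestamp(row.expected_calving),
            actual_calving=pd.Timestamp(row.actual_calving),
            stream_start=pd.Timestamp(row.stream_start),
            stream_end=pd.Timestamp(row.stream_end),
        ))
    return metas


def write_hourly_csv(hourly: pd.DataFrame, path: str | Path) -> None:
    hourly.to_csv(path, index_label="hour", float_format="%.6g")


def write_derived_csv(derived: pd.DataFrame, path: str | Path) -> None:
    derived.to_csv(path, index_label="hour", float_format="%.10g")


def write_features_csv(features: pd.DataFrame, path: str | Path) -> None:
    features.to_csv(path, index=False, float_format="%.10g")


def write_predictions_csv(preds: pd.DataFrame, path: str | Path) -> None:
    preds.to_csv(path, index=False)
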