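"""Raw 3-min streams to hourly aggregates.

The hourly quantities are: maximum skin temperature, mean activity
intensity, mean tail-raising index, lying minutes, and the number of
standing/lying posture changes.  Posture is inferred per 3-min record from
the roll angle; missing values are forward-filled at the record level before
aggregation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic import CADENCE, CHANNELS, SLOTS_PER_HOUR

HOURLY_COLUMNS = ("st_max", "act_mean", "tail_mean", "lying_min", "posture_changes")


def classify_posture(roll: float | np.ndarray | pd.Series,
                     threshold: float = 1.0) -> np.ndarray:
    """Standing (0) vs lying (1) from the roll angle.

    Lying iff |roll| strictly exceeds the threshold; a roll exactly at the
    threshold is standing.  Missing roll propagates as NaN.
    """
    roll = np.asarray(roll, dtype=float)
    out = np.where(np.abs(roll) > threshold, 1.0, 0.0)
    return np.where(np.isnan(roll), np.nan, out)


def forward_fill(stream: pd.DataFrame, animal_id: str = "?") -> pd.DataFrame:
    """Fill each channel's missing records with its last observed value.

    Records before a channel's first observation stay missing; the hours
    containing them are excluded downstream (warm-up).  A channel with no
    observations at all is unusable and raises.
    """
    for ch in CHANNELS:
        if stream[ch].notna().sum() == 0:
            raise ValueError(f"channel {ch!r} entirely missing for animal {animal_id}")
    return stream.ffill()


def aggregate_hourly(stream: pd.DataFrame, roll_threshold: float = 1.0) -> pd.DataFrame:
    """Aggregate a forward-filled 3-min stream into clock-hour bins.

    Bins are left-closed right-open [h:00, h+1:00).  Per hour: st_max is the
    slot maximum, act_mean/tail_mean are slot means, lying_min is 3 minutes
    per lying slot, and posture_changes counts record-to-record posture
    switches attributed to the hour of the later record (so a switch across
    an hour boundary belongs to the later hour).  Hours that are not fully
    covered by 20 valid records — the partial hours at either end of the
    stream and any hour still containing missing values — are dropped.
    """
    df = stream.copy()
    df["posture"] = classify_posture(df["roll"], roll_threshold)
    change = df["posture"].diff().abs()
    # the very first record has no predecessor: no change attributable
    change.iloc[0] = 0.0
    df["change"] = change

    hours = df.index.floor("h")
    grouped = df.groupby(hours)
    out = pd.DataFrame({
        "st_max": grouped["st"].max(),
        "act_mean": grouped["activity"].mean(),
        "tail_mean": grouped["y_accel"].mean(),
        "lying_min": grouped["posture"].sum() * (CADENCE.seconds / 60.0),
        "posture_changes": grouped["change"].sum(),
    })
    out.index.name = "hour"

    n_records = grouped.size()
    n_valid = df[list(CHANNELS)].notna().all(axis=1).groupby(hours).sum()
    complete = (n_records == SLOTS_PER_HOUR) & (n_valid == SLOTS_PER_HOUR)
    return out[complete.reindex(out.index, fill_value=False)]
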