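"""Feature extraction for the calving classifiers.

Each signal contributes eight trailing-window features — the minimum and
maximum over a short and a long window, and the differences between the
current value and each extremum — computed from current and past hours only
(no look-ahead).  The smoothed rST and the activity / lying / posture-change
ratios use 12 h / 24 h windows for the 24-h model and 6 h / 12 h for the 6-h
model; the tail-raising ratio uses shorter 6 h / 12 h (24-h model) and
3 h / 6 h (6-h model) windows, matching its later onset.  That yields 40
sensor features, to which the signed number of days until the expected
calving date ("Days", positive before the expected date) is added: 41
predictors in total.
"""

from __future__ import annotations

import pandas as pd

from .synthetic import AnimalMeta
from .signals import DERIVED_COLUMNS

#: derived-signal column -> display label used in feature names
SIGNAL_LABELS = {
    "rst_smooth": "rST",
    "r_act": "rAct",
    "r_lying": "rLying",
    "r_post": "rPost",
    "r_tail": "rTail",
}

#: horizon -> {signal: (short window h, long window h)}
WINDOWS = {
    "24h": {"rst_smooth": (12, 24), "r_act": (12, 24), "r_lying": (12, 24),
            "r_post": (12, 24), "r_tail": (6, 12)},
    "6h": {"rst_smooth": (6, 12), "r_act": (6, 12), "r_lying": (6, 12),
           "r_post": (6, 12), "r_tail": (3, 6)},
}

#: positive-label window starts H hours before calving
LABEL_HOURS = {"24h": 24, "6h": 6}

DAYS_FEATURE = "Days"
META_COLUMNS = ("animal_id", "hour")


def feature_names(horizon: str) -> list[str]:
    """The 41 predictor names for one horizon, in stable order."""
    names = []
    for col in DERIVED_COLUMNS:
        label = SIGNAL_LABELS[col]
        for w in WINDOWS[horizon][col]:
            names += [f"min{w}h_{label}", f"max{w}h_{label}",
                      f"diffmin{w}h_{label}", f"diffmax{w}h_{label}"]
    names.append(DAYS_FEATURE)
    return names


def sensor_feature_names(horizon: str) -> list[str]:
    return [n for n in feature_names(horizon) if n != DAYS_FEATURE]


def extract_features(derived: pd.DataFrame, meta: AnimalMeta,
                     horizon: str) -> pd.DataFrame:
    """Build the per-hour feature matrix for one animal and one horizon.

    Rows are kept only where the derived signals are valid over every window
    involved, so each feature is a pure function of current and past hours.
    """
    if horizon not in WINDOWS:
        raise ValueError(f"horizon must be one of {tuple(WINDOWS)}, got {horizon!r}")
    masked = derived[list(DERIVED_COLUMNS)].where(derived["valid"], other=float("nan"))
    out = pd.DataFrame(index=derived.index)
    for col in DERIVED_COLUMNS:
        label = SIGNAL_LABELS[col]
        cur = masked[col]
        for w in WINDOWS[horizon][col]:
            wmin = cur.rolling(w, min_periods=w).min()
            wmax = cur.rolling(w, min_periods=w).max()
            out[f"min{w}h_{label}"] = wmin
            out[f"max{w}h_{label}"] = wmax
            out[f"diffmin{w}h_{label}"] = cur - wmin
            out[f"diffmax{w}h_{label}"] = cur - wmax
    out[DAYS_FEATURE] = (meta.expected_calving - out.index) / pd.Timedelta(days=1)
    out = out.dropna()
    out.insert(0, "animal_id", meta.animal_id)
    out.insert(1, "hour", out.index)
    return out.reset_index(drop=True)


def label_rows(matrix: pd.DataFrame, meta: AnimalMeta, horizon: str) -> pd.DataFrame:
    """Attach the binary label: positive from H hours before to 6 h after calving.

    The window is closed on both ends at hour resolution; H is 24 or 6
    according to the horizon.
    """
    h = LABEL_HOURS[horizon]
    lo = meta.actual_calving - pd.Timedelta(hours=h)
    hi = meta.actual_calving + pd.Timedelta(hours=6)
    out = matrix.copy()
    out["label"] = ((out["hour"] >= lo) & (out["hour"] <= hi)).astype(int)
    return out
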