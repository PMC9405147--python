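"""Derived hourly signals: circadian-residual skin temperature and the four
trailing-window ratio signals.

* rST — residual skin temperature: the hourly maximum ST minus the mean ST
  at the same clock hour over the previous three days; removes the circadian
  rhythm.  Smoothed with an EWMA (alpha = 0.1 by default).
* rAct, rLying — sums over the last 24 h divided by sums over the prior
  25-48 h (activity intensity, lying minutes).
* rPost — mean posture changes over the last 6 h / mean over the prior
  7-30 h (posture changes rise over a short pre-calving window).
* rTail — mean tail-raising index over the last 3 h / mean over the prior
  4-27 h.  The index is signed; the sign is preserved, and ratios whose
  denominator is within ``eps`` of zero are marked invalid.

"Last K h" at hour h means hours [h-K+1, h], inclusive of the current hour;
the prior window abuts it with no gap.  Nothing is defined during the 72-h
warm-up that the three-day temperature baseline requires.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DERIVED_COLUMNS = ("rst_smooth", "r_act", "r_lying", "r_post", "r_tail")

#: (signal, source hourly column, kind, recent hours, prior hours)
_RATIO_DEFS = (
    ("r_act", "act_mean", "sum", 24, 24),
    ("r_lying", "lying_min", "sum", 24, 24),
    ("r_post", "posture_changes", "mean", 6, 24),
    ("r_tail", "tail_mean", "mean", 3, 24),
)


def residual_st(st_max: pd.Series) -> pd.Series:
    """rST(h) = st_max(h) - mean(st_max(h-24), st_max(h-48), st_max(h-72)).

    Hours lacking the full three-day same-hour history are NaN (warm-up,
    not an error).  The input must sit on a contiguous hourly grid.
    """
    _check_hourly(st_max.index)
    baseline = (st_max.shift(24) + st_max.shift(48) + st_max.shift(72)) / 3.0
    return st_max - baseline


def ewma(series: pd.Series | np.ndarray, alpha: float) -> pd.Series | np.ndarray:
    """EWMA_0 = X_0;  EWMA_t = alpha * X_t + (1 - alpha) * EWMA_{t-1}.

    Applied over the valid (non-NaN) values in time order; leading NaNs are
    preserved, and the recursion starts at the first valid value.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    values = np.asarray(series, dtype=float)
    if values.size == 0 or np.all(np.isnan(values)):
        raise ValueError("ewma requires at least one valid value")
    out = np.full_like(values, np.nan)
    prev = np.nan
    for i, x in enumerate(values):
        if np.isnan(x):
            continue
        prev = x if np.isnan(prev) else alpha * x + (1.0 - alpha) * prev
        out[i] = prev
    if isinstance(series, pd.Series):
        return pd.Series(out, index=series.index, name=series.name)
    return out


def window_ratio(series: pd.Series, kind: str, recent: int, prior: int,
                 eps: float = 1e-6) -> pd.Series:
    """Trailing-window ratio recent/(abutting prior window) per hour.

    kind='sum' divides window totals, kind='mean' divides window averages.
    Hours whose windows are not fully populated, or whose prior-window
    aggregate is within ``eps`` of zero, come back NaN.
    """
    _check_hourly(series.index)
    if kind not in ("sum", "mean"):
        raise ValueError(f"kind must be 'sum' or 'mean', got {kind!r}")
    roll_recent = series.rolling(recent, min_periods=recent)
    roll_prior = series.shift(recent).rolling(prior, min_periods=prior)
    num = roll_recent.sum() if kind == "sum" else roll_recent.mean()
    den = roll_prior.sum() if kind == "sum" else roll_prior.mean()
    out = num / den.where(den.abs() >= eps)
    return out


def derive(hourly: pd.DataFrame, alpha: float = 0.1, eps: float = 1e-6) -> pd.DataFrame:
    """Compute all derived signals from an hourly aggregate table.

    The hourly table may have gaps (incomplete hours dropped upstream); it
    is reindexed to a contiguous hourly grid and any window touching a gap
    is invalid.  Returns columns rst_smooth, r_act, r_lying, r_post, r_tail
    and a boolean ``valid`` flag (all five finite).
    """
    if hourly.empty:
        raise ValueError("empty hourly series")
    full = pd.date_range(hourly.index[0], hourly.index[-1], freq="h")
    h = hourly.reindex(pd.Index(full, name="hour"))

    rst = residual_st(h["st_max"])
    out = pd.DataFrame(index=h.index)
    out["rst_smooth"] = ewma(rst, alpha) if rst.notna().any() else rst
    for name, col, kind, recent, prior in _RATIO_DEFS:
        out[name] = window_ratio(h[col], kind, recent, prior, eps)
    out["valid"] = out[list(DERIVED_COLUMNS)].notna().all(axis=1)
    return out


def _check_hourly(index: pd.Index) -> None:
    if len(index) > 1:
        steps = pd.Index(index).to_series().diff().dropna()
        if not (steps == pd.Timedelta(hours=1)).all():
            raise ValueError("series must be on a contiguous hourly grid")
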