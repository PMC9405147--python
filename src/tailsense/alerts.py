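"""Hourly predictions to calving alerts and event-level evaluation.

A 24-h alert is raised once three consecutive hourly positives have been
seen, timestamped at the third hour (the earliest moment the rule is
satisfied); alerts falling within 12 h of an already retained alert are
assumed related and merged into it (earliest time kept).  A 6-h alert
requires a 6-h-model positive that coincides with a 24-h-model positive at
the same hour; consecutive such hours form one alert at their first hour.

At evaluation time an alert is a true positive iff calving occurs within
its horizon — in (alert_time, alert_time + H] with H = 24 or 6 — a calving
with no true-positive alert is one false negative, and every other
pre-calving alert is one false positive.  Alerts raised at or after calving
predict nothing and are excluded from scoring.  Sensitivity counts each
calving once even when several alerts hit it; the intervals from every
true-positive alert to calving are reported as mean +- standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import AnimalMeta

HORIZON_HOURS = {"24h": 24, "6h": 6}
MIN_RUN_24H = 3
MERGE_WINDOW_H = 12


@dataclass(frozen=True)
class Alert:
    animal_id: str
    horizon: str
    time: pd.Timestamp
    #: the positive hours the alert was raised from
    hours: tuple[pd.Timestamp, ...]


@dataclass
class AlertEvaluation:
    """Event-level confusion counts and metrics for one housing x horizon."""

    horizon: str
    tp: int
    fn: int
    fp: int
    intervals_h: list[float] = field(default_factory=list)

    @property
    def sensitivity(self) -> float | None:
        return None if self.tp + self.fn == 0 else 100.0 * self.tp / (self.tp + self.fn)

    @property
    def precision(self) -> float | None:
        return None if self.tp + self.fp == 0 else 100.0 * self.tp / (self.tp + self.fp)

    @property
    def mean_interval_h(self) -> float | None:
        return None if not self.intervals_h else float(np.mean(self.intervals_h))

    @property
    def se_interval_h(self) -> float | None:
        if len(self.intervals_h) < 2:
            return None
        return float(np.std(self.intervals_h, ddof=1) / np.sqrt(len(self.intervals_h)))

    @classmethod
    def from_counts(cls, tp: int, fn: int, fp: int, horizon: str = "24h") -> "AlertEvaluation":
        return cls(horizon=horizon, tp=tp, fn=fn, fp=fp)


def _runs(hours: pd.Series) -> list[list[pd.Timestamp]]:
    """Group a sorted sequence of positive hours into hourly-consecutive runs."""
    runs: list[list[pd.Timestamp]] = []
    for h in hours:
        if runs and h - runs[-1][-1] == pd.Timedelta(hours=1):
            runs[-1].append(h)
        else:
            runs.append([h])
    return runs


def merge_alerts(alerts: list[Alert]) -> list[Alert]:
    """Drop alerts within 12 h after an already retained alert (idempotent)."""
    kept: list[Alert] = []
    for a in sorted(alerts, key=lambda a: a.time):
        if kept and a.time - kept[-1].time <= pd.Timedelta(hours=MERGE_WINDOW_H):
            prev = kept[-1]
            kept[-1] = Alert(prev.animal_id, prev.horizon, prev.time,
                             prev.hours + a.hours)
        else:
            kept.append(a)
    return kept


def detect_24h_alerts(pred: pd.DataFrame) -> list[Alert]:
    """24-h alerts from one animal's hourly predictions (animal_id, hour, pred).

    Each run of >= 3 consecutive positive hours raises one alert at the
    run's third hour; alerts are then merged under the 12-h rule.
    """
    pos = pred.loc[pred["pred"] == 1, "hour"].sort_values()
    animal = str(pred["animal_id"].iloc[0]) if len(pred) else "?"
    alerts = [
        Alert(animal, "24h", run[MIN_RUN_24H - 1], tuple(run))
        for run in _runs(pos)
        if len(run) >= MIN_RUN_24H
    ]
    return merge_alerts(alerts)


def detect_6h_alerts(pred6: pd.DataFrame, pred24: pd.DataFrame) -> list[Alert]:
    """6-h alerts: hours positive under both models, grouped into runs.

    Both inputs hold (animal_id, hour, pred) for the same animal; hours
    present in only one frame count as negative there.
    """
    p6 = pred6.set_index("hour")["pred"]
    p24 = pred24.set_index("hour")["pred"]
    both = p6.reindex(p6.index.union(p24.index), fill_value=0).eq(1) & \
        p24.reindex(p6.index.union(p24.index), fill_value=0).eq(1)
    hours = both[both].index.to_series().sort_values()
    animal = str(pred6["animal_id"].iloc[0]) if len(pred6) else "?"
    return [Alert(animal, "6h", run[0], tuple(run)) for run in _runs(hours)]


def evaluate(alerts_by_animal: dict[str, list[Alert]],
             metas: list[AnimalMeta], horizon: str) -> AlertEvaluation:
    """Score alerts against actual calving times at the event level."""
    h = pd.Timedelta(hours=HORIZON_HOURS[horizon])
    tp = fn = fp = 0
    intervals: list[float] = []
    for meta in metas:
        calving = meta.actual_calving
        hit = False
        for alert in alerts_by_animal.get(meta.animal_id, []):
            if alert.time >= calving:
                continue  # post-calving: predicts nothing, not scored
            lead = calving - alert.time
            if lead <= h:
                hit = True
                intervals.append(lead / pd.Timedelta(hours=1))
            else:
                fp += 1
        if hit:
            tp += 1
        else:
            fn += 1
    return AlertEvaluation(horizon=horizon, tp=tp, fn=fn, fp=fp,
                           intervals_h=intervals)


def evaluation_table(evals: dict[tuple[str, str], AlertEvaluation]) -> pd.DataFrame:
    """Tabulate evaluations keyed (housing, horizon) into report columns."""
    rows = []
    for (housing, horizon), ev in evals.items():
        rows.append({
            "housing": housing, "horizon": horizon,
            "TP": ev.tp, "FN": ev.fn, "FP": ev.fp,
            "sensitivity": ev.sensitivity, "precision": ev.precision,
            "mean_interval": ev.mean_interval_h, "se_interval": ev.se_interval_h,
        })
    return pd.DataFrame(rows)
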