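"""Seeded synthetic herds of raw tail-sensor streams.

Real deployments attach a thermistor + 3-axis accelerometer to the ventral
tail base of pregnant cattle roughly two weeks before the expected calving
date and record at 3-min cadence until at least one day after calving.  This
module emulates those streams so the whole downstream pipeline is testable
without animal data:

* skin temperature: 24-h circadian rhythm around a ~38 deg C baseline with a
  biphasic pre-calving drop — gradual from -36 h to -16 h, then sharp over
  the last 6 h — and a linear post-partum recovery;
* activity intensity: stationary, with a condition-dependent step rise
  before calving (untethered cattle only, by default);
* posture: an alternating standing/lying bout process expressed through the
  roll angle; pre-calving the bout-switch rate rises (posture changes become
  more frequent) and, for untethered cattle, lying bouts shorten;
* tail-raising index: Y-axis acceleration, positive when the tail is down
  and negative when raised; shifts downward from ~ -12 h before calving.

All channels are quantized to the sensor's resolution and clipped to its
range.  Records are dropped missing-at-random; a dropped record appears as
an all-missing row on the complete 3-min grid, so forward-filling is a
downstream responsibility.  A fixed (seed, config) pair reproduces the herd
bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ScenarioConfig, HousingEffects, HOUSINGS

CADENCE = pd.Timedelta(minutes=3)
SLOTS_PER_HOUR = 20

#: channel -> (low, high, resolution)
SENSOR_RANGES = {
    "st": (20.0, 45.0, 0.05),
    "activity": (0.0, 102.3, 0.2),
    "roll": (-3.0, 3.0, 0.05),
    "y_accel": (-1000.0, 1000.0, 4.0),
}
CHANNELS = tuple(SENSOR_RANGES)


@dataclass
class AnimalMeta:
    """Deployment metadata for one animal."""

    animal_id: str
    housing: str
    expected_calving: pd.Timestamp
    actual_calving: pd.Timestamp
    stream_start: pd.Timestamp
    stream_end: pd.Timestamp

    def __post_init__(self) -> None:
        if self.housing not in HOUSINGS:
            raise ValueError(f"unknown housing {self.housing!r}")
        if not (self.stream_start < self.actual_calving < self.stream_end):
            raise ValueError(
                f"{self.animal_id}: require stream_start < actual_calving < stream_end"
            )
        if self.stream_end < self.actual_calving + pd.Timedelta(hours=24):
            raise ValueError(
                f"{self.animal_id}: stream must extend >= 24 h past calving"
            )


#: decimal places that losslessly represent each channel's resolution
_DECIMALS = {"st": 2, "activity": 1, "roll": 2, "y_accel": 0}


def quantize(values: np.ndarray, channel: str) -> np.ndarray:
    """Clip to the sensor range and round to the sensor resolution.

    A second decimal rounding pins the result to the value its CSV
    representation parses back to, so file round-trips are exact.
    """
    low, high, step = SENSOR_RANGES[channel]
    out = np.clip(values, low, high)
    return np.round(np.round(out / step) * step, _DECIMALS[channel])


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               low: float, high: float) -> float:
    """Resampling-truncated normal draw (deterministic under a fixed rng)."""
    if sd == 0:
        return float(np.clip(mean, low, high))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if low <= x <= high:
            return float(x)
    return float(np.clip(mean, low, high))


def _st_drop(rel_h: np.ndarray, gradual: float, sharp: float) -> np.ndarray:
    """Biphasic pre-calving temperature deflection at hours-to-calving rel_h."""
    drop = np.zeros_like(rel_h)
    ramp = (rel_h >= -36) & (rel_h < -16)
    drop[ramp] = -gradual * (rel_h[ramp] + 36) / 20.0
    plateau = (rel_h >= -16) & (rel_h < -6)
    drop[plateau] = -gradual
    sharp_ramp = (rel_h >= -6) & (rel_h < 0)
    drop[sharp_ramp] = -gradual - sharp * (rel_h[sharp_ramp] + 6) / 6.0
    post = rel_h >= 0
    drop[post] = -(gradual + sharp) * np.maximum(0.0, 1.0 - rel_h[post] / 12.0)
    return drop


def _bout_process(rng: np.random.Generator, rel_h: np.ndarray,
                  config: ScenarioConfig, eff: HousingEffects) -> np.ndarray:
    """Alternating standing(0)/lying(1) states per 3-min slot.

    Bout durations are exponential; their means at the time a bout starts
    reflect the pre-calving posture-change-rate rise and (untethered) lying
    fall, active from the configured onset until 6 h after calving.
    """
    n = len(rel_h)
    states = np.empty(n, dtype=np.int8)
    i = 0
    lying = bool(rng.integers(2))
    while i < n:
        t = rel_h[i]
        in_effect = t <= 6.0
        rate = eff.posture_rate_factor if (in_effect and t >= eff.posture_onset_h) else 1.0
        if lying:
            mean = config.lying_bout_mean_min
            if in_effect and t >= eff.lying_onset_h:
                mean *= eff.lying_bout_factor
        else:
            mean = config.standing_bout_mean_min
        mean /= max(rate, 1e-12)
        slots = max(1, int(round(rng.exponential(mean) / 3.0)))
        states[i:i + slots] = 1 if lying else 0
        i += slots
        lying = not lying
    return states


def _simulate_animal(rng: np.random.Generator, meta: AnimalMeta,
                     config: ScenarioConfig) -> pd.DataFrame:
    eff = config.per_housing[meta.housing]
    t = pd.date_range(meta.stream_start, meta.stream_end, freq=CADENCE)
    rel_h = ((t - meta.actual_calving) / pd.Timedelta(hours=1)).to_numpy(float)
    hod = (t.hour + t.minute / 60.0).to_numpy(float)

    circ = config.circadian_amp * np.cos(
        2 * np.pi * (hod - config.circadian_peak_hour) / 24.0)
    st = (config.baseline_st + circ
          + _st_drop(rel_h, config.gradual_drop, config.sharp_drop))
    if config.st_noise_sd > 0:
        st = st + rng.normal(0, config.st_noise_sd, len(t))

    in_window = rel_h <= 6.0
    activity = np.full(len(t), config.activity_baseline)
    activity[in_window & (rel_h >= eff.activity_onset_h)] += eff.activity_rise
    if config.activity_noise_sd > 0:
        activity = activity + rng.normal(0, config.activity_noise_sd, len(t))

    states = _bout_process(rng, rel_h, config, eff)
    roll = np.where(states == 1, config.roll_lying_mean, config.roll_standing_mean)
    if config.roll_noise_sd > 0:
        roll = roll + rng.normal(0, config.roll_noise_sd, len(t))

    tail = np.full(len(t), config.tail_baseline)
    tail[in_window & (rel_h >= eff.tail_onset_h)] += eff.tail_shift
    if config.tail_noise_sd > 0:
        tail = tail + rng.normal(0, config.tail_noise_sd, len(t))

    stream = pd.DataFrame(
        {
            "st": quantize(np.asarray(st, float), "st"),
            "activity": quantize(activity, "activity"),
            "roll": quantize(roll, "roll"),
            "y_accel": quantize(tail, "y_accel"),
        },
        index=pd.Index(t, name="t"),
    )
    if config.missing_fraction > 0:
        drop = rng.random(len(t)) < config.missing_fraction
        stream.loc[drop, :] = np.nan
    return stream


def simulate_herd(config: ScenarioConfig) -> tuple[list[AnimalMeta], list[pd.DataFrame]]:
    """Simulate a herd; returns per-animal metadata and raw 3-min streams.

    Streams sit on a complete 3-min grid; dropped records are all-NaN rows.
    Identical (config, seed) input reproduces the output exactly.
    """
    metas: list[AnimalMeta] = []
    streams: list[pd.DataFrame] = []
    base = pd.Timestamp(config.start_date)
    n_teth = int(round(config.n_animals * config.tethering_fraction))
    for i in range(config.n_animals):
        rng = np.random.default_rng([config.random_seed, i])
        housing = "tethering" if i < n_teth else "untethering"
        eff = config.per_housing[housing]
        expected = base + pd.Timedelta(days=i) + pd.Timedelta(hours=12)
        lead_d = _truncnorm(rng, config.attach_lead_mean_d, config.attach_lead_sd_d,
                            config.attach_lead_min_d, config.attach_lead_max_d)
        offset_d = _truncnorm(rng, eff.calving_offset_mean_d, eff.calving_offset_sd_d,
                              -config.calving_offset_trunc_d, config.calving_offset_trunc_d)
        # the sensor must be on the animal at least a day before it calves
        offset_d = max(offset_d, -(lead_d - 1.0))
        start = (expected - pd.Timedelta(days=lead_d)).floor("3min")
        actual = (expected + pd.Timedelta(days=offset_d)).round("3min")
        end = (actual + pd.Timedelta(hours=25)).ceil("3min")
        meta = AnimalMeta(
            animal_id=f"cow{i:03d}",
            housing=housing,
            expected_calving=expected,
            actual_calving=actual,
            stream_start=start,
            stream_end=end,
        )
        metas.append(meta)
        streams.append(_simulate_animal(rng, meta, config))
    return metas, streams
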