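"""Configuration objects for simulation, modelling, and pipeline runs.

Everything is a plain dataclass that round-trips through YAML, so a run is
reproducible from a config file plus an integer seed alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml

HOUSINGS = ("tethering", "untethering")
HORIZONS = ("24h", "6h")


@dataclass
class HousingEffects:
    """Pre-calving behavioural effect sizes for one housing condition.

    Onsets are in hours relative to calving (negative = before).  Magnitudes
    are not published for raw signals; the defaults reproduce the direction
    and onset timing of the observed mean curves for each condition.
    """

    #: additive rise in activity intensity from ``activity_onset_h`` on
    activity_rise: float = 0.0
    activity_onset_h: float = -18.0
    #: multiplier (< 1 shortens) applied to the mean lying-bout duration
    lying_bout_factor: float = 1.0
    lying_onset_h: float = -24.0
    #: divisor applied to both bout means, i.e. posture-change rate multiplier
    posture_rate_factor: float = 2.0
    posture_onset_h: float = -24.0
    #: additive shift of the tail-raising index (negative = tail raised)
    tail_shift: float = -400.0
    tail_onset_h: float = -12.0
    #: calving date offset vs the expected date, days (observed mean +- sd)
    calving_offset_mean_d: float = -0.5
    calving_offset_sd_d: float = 2.9


def _default_effects() -> dict[str, HousingEffects]:
    # Tethered cattle: activity and lying stay flat; posture changes rise
    # early (~ -24 h).  Untethered cattle: activity rises (~ -18 h), lying
    # falls (~ -24 h), posture changes rise late (~ -6 h).  Tail raising
    # (Y-acceleration falling) starts ~ -12 h in both conditions.
    return {
        "tethering": HousingEffects(
            activity_rise=0.0,
            lying_bout_factor=1.0,
            posture_rate_factor=2.0,
            posture_onset_h=-24.0,
            calving_offset_mean_d=-0.5,
            calving_offset_sd_d=2.9,
        ),
        "untethering": HousingEffects(
            activity_rise=6.0,
            activity_onset_h=-18.0,
            lying_bout_factor=0.5,
            lying_onset_h=-24.0,
            posture_rate_factor=2.5,
            posture_onset_h=-6.0,
            calving_offset_mean_d=1.4,
            calving_offset_sd_d=4.5,
        ),
    }


@dataclass
class ScenarioConfig:
    """Parameters of a simulated herd of tail-sensor streams.

    Temperature is in deg C, accelerations in milli-g, times in hours
    relative to each animal's actual calving unless stated otherwise.
    """

    n_animals: int = 20
    tethering_fraction: float = 0.5
    random_seed: int = 0
    start_date: str = "2020-06-01"

    # --- skin temperature ---
    baseline_st: float = 38.0
    circadian_amp: float = 0.3
    circadian_peak_hour: float = 18.0
    #: gradual pre-calving drop, reached linearly over [-36 h, -16 h]
    gradual_drop: float = 0.5
    #: additional sharp drop, reached linearly over the last 6 h
    sharp_drop: float = 1.0
    st_noise_sd: float = 0.25

    # --- activity intensity ---
    activity_baseline: float = 10.0
    activity_noise_sd: float = 2.0

    # --- posture (roll angle) ---
    lying_bout_mean_min: float = 50.0
    standing_bout_mean_min: float = 70.0
    roll_standing_mean: float = 0.2
    roll_lying_mean: float = 1.5
    roll_noise_sd: float = 0.15

    # --- tail-raising index (Y-axis acceleration) ---
    tail_baseline: float = 200.0
    tail_noise_sd: float = 40.0

    per_housing: dict[str, HousingEffects] = field(default_factory=_default_effects)

    # --- deployment ---
    attach_lead_mean_d: float = 15.0
    attach_lead_sd_d: float = 4.6
    attach_lead_min_d: float = 6.0
    attach_lead_max_d: float = 30.0
    calving_offset_trunc_d: float = 14.0
    #: probability that any individual 3-min record is dropped
    missing_fraction: float = 0.02

    def __post_init__(self) -> None:
        if self.n_animals <= 0:
            raise ValueError(f"n_animals must be positive, got {self.n_animals}")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must be in [0, 1)")
        for name in ("st_noise_sd", "activity_noise_sd", "roll_noise_sd",
                     "tail_noise_sd", "attach_lead_sd_d"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if isinstance(self.per_housing, dict):
            self.per_housing = {
                k: (v if isinstance(v, HousingEffects) else HousingEffects(**v))
                for k, v in self.per_housing.items()
            }
        for housing, eff in self.per_housing.items():
            if housing not in HOUSINGS:
                raise ValueError(f"unknown housing condition {housing!r}")
            if eff.calving_offset_sd_d < 0:
                raise ValueError("calving_offset_sd_d must be >= 0")
            for name in ("activity_onset_h", "lying_onset_h",
                         "posture_onset_h", "tail_onset_h"):
                if getattr(eff, name) >= 0:
                    raise ValueError(f"{name} must be negative (before calving)")


@dataclass(frozen=True)
class ModelSpec:
    """Hyperparameters of one class-weighted RBF SVM.

    ``sigma`` is the RBF kernel coefficient in exp(-sigma * ||u - v||^2)
    (the e1071 "gamma" convention); ``weight`` multiplies the positive
    class's misclassification cost, the negative class stays at 1.
    """

    horizon: str
    housing: str
    sigma: float
    cost: float
    weight: float

    def __post_init__(self) -> None:
        if self.horizon not in HORIZONS:
            raise ValueError(f"horizon must be one of {HORIZONS}")
        if self.housing not in HOUSINGS:
            raise ValueError(f"housing must be one of {HOUSINGS}")


#: Published hyperparameters, keyed (horizon, housing).
DEFAULT_SPECS: dict[tuple[str, str], ModelSpec] = {
    ("24h", "tethering"): ModelSpec("24h", "tethering", sigma=0.008, cost=0.46, weight=1.5),
    ("24h", "untethering"): ModelSpec("24h", "untethering", sigma=0.0037, cost=0.026, weight=3.5),
    ("6h", "tethering"): ModelSpec("6h", "tethering", sigma=0.008, cost=0.1, weight=1.5),
    ("6h", "untethering"): ModelSpec("6h", "untethering", sigma=0.0037, cost=0.03, weight=3.5),
}


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings: scenario, model specs, and guards."""

    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    specs: dict[str, ModelSpec] = field(default_factory=lambda: {
        f"{h}/{c}": s for (h, c), s in DEFAULT_SPECS.items()
    })
    roll_threshold: float = 1.0
    ewma_alpha: float = 0.1
    denominator_eps: float = 1e-6
    importance_repeats: int = 20
    run_importance: bool = True

    def __post_init__(self) -> None:
        if isinstance(self.scenario, dict):
            self.scenario = ScenarioConfig(**self.scenario)
        fixed = {}
        for key, spec in self.specs.items():
            if isinstance(spec, dict):
                horizon, housing = key.split("/")
                spec = ModelSpec(horizon=horizon, housing=housing, **{
                    k: v for k, v in spec.items() if k in ("sigma", "cost", "weight")
                })
            fixed[key] = spec
        self.specs = fixed

    def spec_for(self, horizon: str, housing: str) -> ModelSpec:
        return self.specs[f"{horizon}/{housing}"]


def to_yaml(config: ScenarioConfig | PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=True))


def _load(path: str | Path) -> dict[str, Any]:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"config file not found: {p}")
    return yaml.safe_load(p.read_text()) or {}


def scenario_from_yaml(path: str | Path) -> ScenarioConfig:
    return ScenarioConfig(**_load(path))


def pipeline_from_yaml(path: str | Path) -> PipelineConfig:
    return PipelineConfig(**_load(path))
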