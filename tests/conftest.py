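"""Shared fixtures: small, fast synthetic herds and their derived stages."""

from __future__ import annotations

import copy

import pytest

import tailsense as ts
from tailsense.config import ScenarioConfig


def fast_scenario(**overrides) -> ScenarioConfig:
    """A compact herd: short deployment, tight calving offsets, light missingness.

    Keeps per-test simulation cheap while exercising every code path
    (warm-up, pre-calving injections, missing records).
    """
    kwargs = dict(
        n_animals=3,
        tethering_fraction=1.0,
        random_seed=123,
        attach_lead_mean_d=6.5,
        attach_lead_sd_d=0.0,
        attach_lead_min_d=6.5,
        attach_lead_max_d=6.5,
        missing_fraction=0.01,
    )
    kwargs.update(overrides)
    cfg = ScenarioConfig(**kwargs)
    for eff in cfg.per_housing.values():
        eff.calving_offset_sd_d = 0.5
    return cfg


@pytest.fixture(scope="session")
def small_herd():
    return ts.simulate_herd(fast_scenario())


@pytest.fixture(scope="session")
def one_animal(small_herd):
    """One animal taken through preprocessing and signal derivation."""
    metas, streams = small_herd
    meta, stream = metas[0], streams[0]
    filled = ts.forward_fill(stream, meta.animal_id)
    hourly = ts.aggregate_hourly(filled, 1.0)
    derived = ts.derive(hourly)
    return {"meta": meta, "stream": stream, "filled": filled,
            "hourly": hourly, "derived": derived}


@pytest.fixture()
def scenario_factory():
    return lambda **kw: copy.deepcopy(fast_scenario(**kw))
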