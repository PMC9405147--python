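"""Synthetic herd generator: signal injection, determinism, and stream I/O."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import tailsense as ts
from tailsense.config import ScenarioConfig
from tailsense.synthetic import quantize, CADENCE
from tailsense import io

from conftest import fast_scenario


def zero_effect_scenario(**kw) -> ScenarioConfig:
    cfg = fast_scenario(
        gradual_drop=0.0, sharp_drop=0.0,
        st_noise_sd=0.0, activity_noise_sd=0.0, roll_noise_sd=0.0,
        tail_noise_sd=0.0, missing_fraction=0.0, **kw)
    for eff in cfg.per_housing.values():
        eff.activity_rise = 0.0
        eff.lying_bout_factor = 1.0
        eff.posture_rate_factor = 1.0
        eff.tail_shift = 0.0
    return cfg


class TestSimulateHerd:
    def test_zero_effect_zero_noise_gives_pure_circadian_temperature(self):
        cfg = zero_effect_scenario()
        metas, streams = ts.simulate_herd(cfg)
        for stream in streams:
            hod = stream.index.hour + stream.index.minute / 60.0
            expected = cfg.baseline_st + cfg.circadian_amp * np.cos(
                2 * np.pi * (hod - cfg.circadian_peak_hour) / 24.0)
            assert np.array_equal(stream["st"].to_numpy(),
                                  quantize(expected.to_numpy(), "st"))
            # behavioural channels carry no pre-calving structure
            assert stream["activity"].nunique() == 1
            assert stream["y_accel"].nunique() == 1

    def test_zero_missingness_has_no_missing_fields(self):
        cfg = fast_scenario(missing_fraction=0.0)
        _, streams = ts.simulate_herd(cfg)
        for stream in streams:
            assert stream.notna().all().all()

    def test_missingness_drops_whole_records_on_complete_grid(self):
        cfg = fast_scenario(missing_fraction=0.1)
        _, streams = ts.simulate_herd(cfg)
        stream = streams[0]
        # grid is complete at 3-min cadence
        assert (pd.Series(stream.index).diff().dropna() == CADENCE).all()
        nan_rows = stream.isna().all(axis=1)
        partial = stream.isna().any(axis=1) & ~nan_rows
        assert nan_rows.any() and not partial.any()

    def test_meta_invariants_hold(self, small_herd):
        metas, streams = small_herd
        for meta, stream in zip(metas, streams):
            assert meta.stream_start < meta.actual_calving < meta.stream_end
            assert meta.stream_end >= meta.actual_calving + pd.Timedelta(hours=24)
            assert stream.index[0] == meta.stream_start
            assert stream.index[-1] == meta.stream_end

    def test_values_quantized_to_sensor_resolution(self, small_herd):
        _, streams = small_herd
        stream = streams[0].dropna()
        for ch, step in [("st", 0.05), ("activity", 0.2), ("roll", 0.05),
                         ("y_accel", 4.0)]:
            rem = np.abs(np.round(stream[ch] / step) * step - stream[ch])
            assert rem.max() < 1e-9

    def test_identical_seed_and_config_reproduce_herd_exactly(self, tmp_path):
        cfg = fast_scenario(n_animals=2, random_seed=7)
        outs = []
        for run in range(2):
            metas, streams = ts.simulate_herd(fast_scenario(n_animals=2, random_seed=7))
            path = tmp_path / f"run{run}.csv"
            io.write_stream_csv(streams[0], path)
            outs.append(path.read_bytes())
        assert outs[0] == outs[1]
        _, other = ts.simulate_herd(fast_scenario(n_animals=2, random_seed=8))
        assert not streams[0].equals(other[0])

    def test_tail_injection_is_exact_without_noise(self):
        cfg = zero_effect_scenario()
        cfg.tail_baseline = 200.0
        for eff in cfg.per_housing.values():
            eff.tail_shift = -400.0
            eff.tail_onset_h = -12.0
        metas, streams = ts.simulate_herd(cfg)
        meta, stream = metas[0], streams[0]
        hourly = ts.aggregate_hourly(stream, 1.0)
        calving_hour = meta.actual_calving.floor("h")
        # hours fully inside the injection window
        inside = hourly.loc[calving_hour - pd.Timedelta(hours=10):
                            calving_hour - pd.Timedelta(hours=1)]
        assert (inside["tail_mean"] == -200.0).all()
        before = hourly.loc[:calving_hour - pd.Timedelta(hours=14)]
        assert (before["tail_mean"] == 200.0).all()

    def test_rejects_nonpositive_animal_count(self):
        with pytest.raises(ValueError, match="n_animals"):
            ScenarioConfig(n_animals=0)

    def test_any_integer_seed_accepted(self):
        for seed in (0, 1, 2**31 - 1):
            metas, _ = ts.simulate_herd(fast_scenario(n_animals=1, random_seed=seed))
            assert len(metas) == 1


class TestStreamCsv:
    def test_round_trip_identity_including_missing(self, small_herd, tmp_path):
        _, streams = small_herd
        stream = streams[0]
        path = tmp_path / "s.csv"
        io.write_stream_csv(stream, path)
        back = io.read_stream_csv(path)
        pd.testing.assert_frame_equal(back, stream)

    def test_timestamp_gap_read_as_missing_records(self, tmp_path):
        # hand-built 5-record file with a 2-slot gap after the second record
        lines = [
            "t,st,activity,roll,y_accel",
            "2020-01-01T00:00:00,38.00,10.0,0.20,200",
            "2020-01-01T00:03:00,38.05,10.2,0.20,200",
            "2020-01-01T00:12:00,38.10,10.4,0.25,204",
            "2020-01-01T00:15:00,38.15,10.6,0.25,204",
            "2020-01-01T00:18:00,38.20,10.8,0.30,208",
        ]
        path = tmp_path / "gap.csv"
        path.write_text("\n".join(lines) + "\n")
        stream = io.read_stream_csv(path)
        assert len(stream) == 7  # full grid from 00:00 to 00:18
        gap = stream.loc["2020-01-01T00:06:00":"2020-01-01T00:09:00"]
        assert gap.isna().all().all()

    def test_out_of_range_temperature_names_record(self, tmp_path):
        lines = [
            "t,st,activity,roll,y_accel",
            "2020-01-01T00:00:00,38.00,10.0,0.20,200",
            "2020-01-01T00:03:00,19.00,10.0,0.20,200",
        ]
        path = tmp_path / "bad.csv"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="record 1"):
            io.read_stream_csv(path)

    def test_non_monotone_timestamps_rejected(self, tmp_path):
        lines = [
            "t,st,activity,roll,y_accel",
            "2020-01-01T00:03:00,38.00,10.0,0.20,200",
            "2020-01-01T00:00:00,38.00,10.0,0.20,200",
        ]
        path = tmp_path / "mono.csv"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="non-monotone"):
            io.read_stream_csv(path)

    def test_herd_metadata_round_trip(self, small_herd, tmp_path):
        metas, _ = small_herd
        path = tmp_path / "herd.csv"
        io.write_herd_csv(metas, path)
        back = io.read_herd_csv(path)
        assert back == metas
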