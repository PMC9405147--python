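"""End-to-end orchestration: simulate -> preprocess -> signals -> features ->
LOOA classification -> alerts -> evaluation -> importance.

Every stage boundary is a CSV under the output directory, and a run manifest
records the config hash, seed, and library versions, so a run is reproducible
from config + seed alone.  Housing conditions are modelled separately end to
end: separate training sets, hyperparameters, and evaluations.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import sklearn
import yaml

from . import io
from .alerts import detect_24h_alerts, detect_6h_alerts, evaluate, evaluation_table
from .classifier import loo_animal_cv, standardize, train_svm
from .config import HORIZONS, HOUSINGS, PipelineConfig
from .features import extract_features, feature_names, label_rows
from .importance import permutation_importance
from .preprocessing import aggregate_hourly, forward_fill
from .signals import derive
from .synthetic import AnimalMeta, simulate_herd


def build_feature_tables(metas: list[AnimalMeta], hourlies: dict[str, pd.DataFrame],
                         config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Derived signals -> labelled feature matrix per horizon (all animals)."""
    tables: dict[str, list[pd.DataFrame]] = {h: [] for h in HORIZONS}
    for meta in metas:
        derived = derive(hourlies[meta.animal_id], alpha=config.ewma_alpha,
                         eps=config.denominator_eps)
        for horizon in HORIZONS:
            matrix = extract_features(derived, meta, horizon)
            tables[horizon].append(label_rows(matrix, meta, horizon))
    return {h: pd.concat(t, ignore_index=True) for h, t in tables.items()}


def run_pipeline(config: PipelineConfig, outdir: str | Path,
                 seed: int | None = None) -> dict:
    """Run every stage, writing all artifacts under ``outdir``.

    ``seed`` overrides the scenario's random seed when given.  Returns a
    dict with the in-memory stage outputs (metas, features, predictions,
    alerts, evaluation table, importances).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scenario = config.scenario
    if seed is not None:
        scenario = dataclasses.replace(scenario, random_seed=seed)

    metas, streams = simulate_herd(scenario)
    (outdir / "streams").mkdir(exist_ok=True)
    for meta, stream in zip(metas, streams):
        io.write_stream_csv(stream, outdir / "streams" / f"{meta.animal_id}.csv")
    io.write_herd_csv(metas, outdir / "herd.csv")

    hourlies = {}
    (outdir / "hourly").mkdir(exist_ok=True)
    for meta, stream in zip(metas, streams):
        filled = forward_fill(stream, meta.animal_id)
        hourly = aggregate_hourly(filled, config.roll_threshold)
        hourlies[meta.animal_id] = hourly
        io.write_hourly_csv(hourly, outdir / "hourly" / f"{meta.animal_id}.csv")

    features = build_feature_tables(metas, hourlies, config)
    for horizon, table in features.items():
        io.write_features_csv(table, outdir / f"features_{horizon}.csv")

    housing_of = {m.animal_id: m.housing for m in metas}
    preds: dict[tuple[str, str], pd.DataFrame] = {}
    for housing in HOUSINGS:
        ids = [m.animal_id for m in metas if m.housing == housing]
        if len(ids) < 2:
            if ids:
                warnings.warn(f"housing {housing!r} has <2 animals; skipped")
            continue
        for horizon in HORIZONS:
            table = features[horizon]
            subset = table[table["animal_id"].isin(ids)]
            preds[(housing, horizon)] = loo_animal_cv(subset,
                                                      config.spec_for(horizon, housing))
    pred_frames = []
    for (housing, horizon), p in preds.items():
        p = p.assign(housing=housing, horizon=horizon)
        pred_frames.append(p)
    predictions = (pd.concat(pred_frames, ignore_index=True)
                   if pred_frames else pd.DataFrame())
    io.write_predictions_csv(predictions, outdir / "predictions.csv")

    alerts: dict[tuple[str, str], dict[str, list]] = {}
    for (housing, horizon), p in preds.items():
        per_animal = {}
        for animal, grp in p.groupby("animal_id", sort=False):
            if horizon == "24h":
                per_animal[animal] = detect_24h_alerts(grp)
            else:
                p24 = preds[(housing, "24h")]
                per_animal[animal] = detect_6h_alerts(
                    grp, p24[p24["animal_id"] == animal])
        alerts[(housing, horizon)] = per_animal
    alert_rows = [
        {"animal_id": a.animal_id, "housing": housing, "horizon": horizon,
         "alert_time": a.time}
        for (housing, horizon), per_animal in alerts.items()
        for alist in per_animal.values() for a in alist
    ]
    pd.DataFrame(alert_rows, columns=["animal_id", "housing", "horizon",
                                      "alert_time"]).to_csv(
        outdir / "alerts.csv", index=False)

    evals = {}
    for (housing, horizon), per_animal in alerts.items():
        group_metas = [m for m in metas if m.housing == housing]
        evals[(housing, horizon)] = evaluate(per_animal, group_metas, horizon)
    table = evaluation_table(evals)
    table.to_csv(outdir / "evaluation.csv", index=False, float_format="%.4f")

    importances = {}
    if config.run_importance:
        for (housing, horizon) in preds:
            ids = [m.animal_id for m in metas if m.housing == housing]
            sub = features[horizon][features[horizon]["animal_id"].isin(ids)]
            cols = feature_names(horizon)
            scaling = standardize(sub[cols])
            model = train_svm(scaling.apply(sub[cols]), sub["label"].to_numpy(),
                              config.spec_for(horizon, housing))
            imp = permutation_importance(model, scaling.apply(sub[cols]),
                                         sub["label"].to_numpy(),
                                         n_repeats=config.importance_repeats,
                                         seed=scenario.random_seed)
            imp.to_csv(outdir / f"importance_{horizon}_{housing}.csv", index=False,
                       float_format="%.6f")
            importances[(housing, horizon)] = imp

    manifest = {
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(dataclasses.asdict(config), sort_keys=True).encode()
        ).hexdigest(),
        "seed": int(scenario.random_seed),
        "versions": {"numpy": np.__version__, "pandas": pd.__version__,
                     "sklearn": sklearn.__version__},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

    return {"metas": metas, "hourlies": hourlies, "features": features,
            "predictions": preds, "alerts": alerts, "evaluations": evals,
            "evaluation_table": table, "importances": importances,
            "manifest": manifest}
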