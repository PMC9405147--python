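"""Class-weighted RBF SVM with leave-one-animal-out cross-validation.

Hourly labelled feature rows are standardized (zero mean, unit variance,
parameters learned on the training fold only) and classified by a soft
margin SVM whose positive class carries an elevated misclassification cost
to counter the heavy class imbalance.  Under leave-one-animal-out (LOOA)
cross-validation every animal is scored by a model that never saw any of
its rows, mimicking deployment on a new animal.

The published hyperparameters (see ``config.DEFAULT_SPECS``) follow the
e1071 convention: ``sigma`` is the kernel coefficient in
exp(-sigma * ||u - v||^2) and ``cost`` the soft-margin C.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import GroupShuffleSplit
from sklearn.svm import SVC

from .config import ModelSpec
from .features import feature_names


@dataclass
class Scaling:
    """Per-feature standardization parameters learned from a training fold."""

    columns: list[str]
    mean: np.ndarray
    sd: np.ndarray

    def apply(self, matrix: pd.DataFrame) -> pd.DataFrame:
        return (matrix[self.columns] - self.mean) / self.sd


def standardize(train: pd.DataFrame) -> Scaling:
    """Learn zero-mean/unit-variance scaling; constant features are dropped."""
    if len(train) < 2:
        raise ValueError("standardization needs at least 2 training rows")
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        dropped = list(train.columns[~keep])
        warnings.warn(f"dropping constant feature(s): {dropped}", stacklevel=2)
    cols = list(train.columns[keep])
    return Scaling(columns=cols, mean=mean[keep].to_numpy(),
                   sd=sd[keep].to_numpy())


def train_svm(scaled: pd.DataFrame | np.ndarray, labels: np.ndarray,
              spec: ModelSpec) -> SVC:
    """Fit the class-weighted RBF SVM; deterministic given data and spec."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    model = SVC(kernel="rbf", gamma=spec.sigma, C=spec.cost,
                class_weight={0: 1.0, 1: spec.weight})
    model.fit(np.asarray(scaled, dtype=float), y)
    return model


def loo_animal_cv(labelled: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Leave-one-animal-out predictions for every row of a labelled matrix.

    ``labelled`` holds one row per animal-hour with the predictor columns
    for ``spec.horizon`` plus animal_id, hour, label.  For each fold the
    scaling and the model are functions of the other animals' rows only.
    Returns columns animal_id, hour, pred.
    """
    animals = list(dict.fromkeys(labelled["animal_id"]))
    if len(animals) < 2:
        raise ValueError("LOOA cross-validation needs at least 2 animals")
    cols = feature_names(spec.horizon)
    out = []
    for animal in animals:
        test = labelled[labelled["animal_id"] == animal]
        if test.empty:
            warnings.warn(f"animal {animal} has no feature rows; skipped",
                          stacklevel=2)
            continue
        train = labelled[labelled["animal_id"] != animal]
        scaling = standardize(train[cols])
        model = train_svm(scaling.apply(train[cols]), train["label"].to_numpy(), spec)
        pred = model.predict(scaling.apply(test[cols]).to_numpy())
        out.append(pd.DataFrame({
            "animal_id": animal,
            "hour": test["hour"].to_numpy(),
            "pred": pred.astype(int),
        }))
    return pd.concat(out, ignore_index=True)


def grid_search(labelled: pd.DataFrame, horizon: str, housing: str,
                grid: list[dict], seed: int = 0,
                test_fraction: float = 0.25) -> pd.DataFrame:
    """Score candidate hyperparameters on an internal animal-wise split.

    ``grid`` is a list of {sigma, cost, weight} dicts.  Candidates are
    scored by balanced accuracy on a held-out group of animals; the result
    is ranked but nothing is auto-selected.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    cols = feature_names(horizon)
    splitter = GroupShuffleSplit(n_splits=1, test_size=test_fraction,
                                 random_state=seed)
    idx_train, idx_val = next(splitter.split(labelled, groups=labelled["animal_id"]))
    train, val = labelled.iloc[idx_train], labelled.iloc[idx_val]
    scaling = standardize(train[cols])
    rows = []
    for cand in grid:
        spec = ModelSpec(horizon=horizon, housing=housing, **cand)
        model = train_svm(scaling.apply(train[cols]), train["label"].to_numpy(), spec)
        pred = model.predict(scaling.apply(val[cols]).to_numpy())
        rows.append({**cand,
                     "score": balanced_accuracy_score(val["label"], pred)})
    return (pd.DataFrame(rows)
            .sort_values("score", ascending=False)
            .reset_index(drop=True))
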