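"""Permutation feature importance as an error ratio.

Importance of a feature is the factor by which the model's classification
error grows when that feature's column is shuffled: shuffling an
uninformative feature leaves the error unchanged (ratio ~ 1), shuffling a
feature the model relies on inflates it (ratio > 1).  Each feature is
shuffled ``n_repeats`` times and the per-feature median and empirical 90%
quantile of the ratios are reported.  Importance is computed on the model
fitted to all rows, with in-sample error.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def permutation_importance(model, scaled: pd.DataFrame, labels: np.ndarray,
                           n_repeats: int = 20, seed: int = 0) -> pd.DataFrame:
    """Error-ratio permutation importance per feature, ranked by median.

    When the baseline error is exactly zero the ratio is ill-defined; both
    numerator and denominator are then floored at eps = 1/(2 n_rows) (half
    the smallest achievable nonzero error) and the result is flagged in the
    ``baseline_zero`` column.

    Returns columns: feature, median_importance, q90, repeats, seed,
    baseline_zero.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    rng = np.random.default_rng(seed)
    x = np.asarray(scaled, dtype=float)
    y = np.asarray(labels)
    n = len(y)
    baseline = float(np.mean(model.predict(x) != y))
    eps = 1.0 / (2 * n)
    flagged = baseline == 0.0
    rows = []
    for j, name in enumerate(scaled.columns):
        ratios = np.empty(n_repeats)
        for r in range(n_repeats):
            xp = x.copy()
            xp[:, j] = xp[rng.permutation(n), j]
            err = float(np.mean(model.predict(xp) != y))
            ratios[r] = max(err, eps) / max(baseline, eps)
        rows.append({
            "feature": name,
            "median_importance": float(np.median(ratios)),
            "q90": float(np.quantile(ratios, 0.9)),
            "repeats": n_repeats,
            "seed": seed,
            "baseline_zero": flagged,
        })
    return (pd.DataFrame(rows)
            .sort_values("median_importance", ascending=False)
            .reset_index(drop=True))
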