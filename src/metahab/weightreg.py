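"""Distance-based regression of community dissimilarity on body-weight difference.

The response is the upper triangle of a sample dissimilarity matrix; the
covariate is the absolute body-weight difference of each pair.  Because
pairwise distances are not independent, the significance of the OLS F
statistic is assessed by permuting the weight vector across samples (the
exchangeable unit) and recomputing the |dw| covariate each time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix

from .model import OtuTable, ValidationError

__all__ = ["DistanceRegressionResult", "fit_distance_regression", "habitat_regressions"]


@dataclass
class DistanceRegressionResult:
    slope: float  # dissimilarity per gram
    intercept: float
    F_observed: float
    permutations: int
    p_value: float
    n_pairs: int


def _ols_f(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Closed-form simple OLS slope, intercept and F for one covariate."""
    n = len(x)
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        raise ValidationError("degenerate covariate: all weights equal")
    slope = float(xc @ yc) / sxx
    intercept = float(y.mean() - slope * x.mean())
    ss_tot = float(yc @ yc)
    ss_reg = slope * slope * sxx
    ss_res = ss_tot - ss_reg
    if ss_res <= 0:
        f = np.inf if ss_reg > 0 else 0.0
    else:
        f = (ss_reg / 1.0) / (ss_res / (n - 2))
    return slope, intercept, f


def fit_distance_regression(
    dm: DistanceMatrix,
    weights: pd.Series,
    permutations: int = 1000,
    seed: int | None = None,
) -> DistanceRegressionResult:
    """OLS of pairwise dissimilarity on |weight difference|, permutation F-test.

    ``weights`` must cover every id of ``dm``.  The p-value is
    ``(#{F_perm >= F_obs} + 1) / (permutations + 1)`` over permutations of
    the per-sample weight vector (pairs are never shuffled independently).
    """
    ids = list(dm.ids)
    if len(ids) < 4:
        raise ValidationError("need >= 4 samples for distance regression")
    weights = pd.Series(weights)
    missing = [s for s in ids if s not in weights.index]
    if missing:
        raise ValidationError(f"samples without weights: {missing}")
    w = weights.loc[ids].to_numpy(dtype=float)
    if np.isnan(w).any():
        raise ValidationError("weights contain missing values")
    y = squareform(np.asarray(dm.data), checks=False)
    n = len(ids)
    iu = np.triu_indices(n, k=1)

    def cov(wvec: np.ndarray) -> np.ndarray:
        return np.abs(wvec[iu[0]] - wvec[iu[1]])

    slope, intercept, f_obs = _ols_f(cov(w), y)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        _, _, f = _ols_f(cov(rng.permutation(w)), y)
        if f >= f_obs - 1e-12:
            hits += 1
    p = (hits + 1) / (permutations + 1)
    return DistanceRegressionResult(
        slope=slope,
        intercept=intercept,
        F_observed=f_obs,
        permutations=permutations,
        p_value=p,
        n_pairs=len(y),
    )


def habitat_regressions(
    table: OtuTable,
    meta: pd.DataFrame,
    dm: DistanceMatrix,
    permutations: int = 1000,
    seed: int | None = None,
) -> dict[str, DistanceRegressionResult]:
    """Per-habitat fits plus a pooled fit over all weighed (non-water) samples.

    Water samples carry no body weight and are excluded from the pooled fit.
    Habitats with fewer than 4 samples are skipped.
    """
    meta = meta.loc[[s for s in dm.ids if s in meta.index]]
    weights = meta["body_weight_g"]
    results: dict[str, DistanceRegressionResult] = {}
    fish = meta.index[meta["habitat"] != "water"]
    if len(fish) >= 4:
        results["all"] = fit_distance_regression(
            dm.filter(list(fish)), weights, permutations, seed
        )
    for habitat, sub in meta.groupby("habitat", sort=False):
        if habitat == "water" or len(sub) < 4:
            continue
        results[habitat] = fit_distance_regression(
            dm.filter(list(sub.index)), weights, permutations, seed
        )
    return results
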