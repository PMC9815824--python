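"""Serial two-mediator path model with bias-corrected bootstrap CIs.

The model chains a predictor X (e.g. hippocampal-amygdala coupling)
through two mediators M1 and M2 (hippocampal-neocortical coupling) to
an outcome Y (associative memory performance):

    M1 = a1 X
    M2 = a2 X + d21 M1
    Y  = c' X + b1 M1 + b2 M2

fit as three OLS equations on standardized variables.  Indirect
effects are the path products a1*b1, a2*b2 and the serial a1*d21*b2;
their uncertainty is assessed by case-resampling bootstrap with
bias-corrected (BC) percentile intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["PathModel", "IndirectEffect", "fit_paths", "bootstrap_indirect"]

INDIRECT_LABELS = {
    "X->M1->Y": ("a1", "b1"),
    "X->M2->Y": ("a2", "b2"),
    "X->M1->M2->Y": ("a1", "d21", "b2"),
}


@dataclass
class PathModel:
    """Standardized path coefficients of the serial mediation model."""

    a1: float
    a2: float
    d21: float
    b1: float
    b2: float
    c_prime: float
    c: float
    r_squared: dict = field(default_factory=dict)

    def indirect(self, label: str) -> float:
        return float(np.prod([getattr(self, p) for p in INDIRECT_LABELS[label]]))

    def total_indirect(self) -> float:
        return float(sum(self.indirect(lbl) for lbl in INDIRECT_LABELS))

    def coefficients(self) -> dict:
        return {k: getattr(self, k) for k in ("a1", "a2", "d21", "b1", "b2", "c_prime", "c")}


@dataclass
class IndirectEffect:
    label: str
    estimate: float
    ci: tuple[float, float]
    n_boot: int
    seed: int
    excludes_zero: bool = False

    def __post_init__(self) -> None:
        self.excludes_zero = not (self.ci[0] <= 0.0 <= self.ci[1])


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=0)
    if sd == 0:
        raise ValueError("zero-variance variable cannot enter the path model")
    return (v - v.mean()) / sd


def _ols(y: np.ndarray, *preds: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones(len(y)), *preds])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


def _paths_from_arrays(X, M1, M2, Y) -> PathModel:
    a1 = _ols(M1, X)[1]
    a2, d21 = _ols(M2, X, M1)[1:]
    c_prime, b1, b2 = _ols(Y, X, M1, M2)[1:]
    c = _ols(Y, X)[1]

    def r2(y, yhat_beta, preds):
        Xd = np.column_stack([np.ones(len(y)), *preds])
        resid = y - Xd @ yhat_beta
        ss_tot = float(((y - y.mean()) ** 2).sum())
        return 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 0.0

    r_squared = {
        "M1": r2(M1, _ols(M1, X), [X]),
        "M2": r2(M2, _ols(M2, X, M1), [X, M1]),
        "Y": r2(Y, _ols(Y, X, M1, M2), [X, M1, M2]),
    }
    return PathModel(float(a1), float(a2), float(d21), float(b1), float(b2),
                     float(c_prime), float(c), r_squared)


def fit_paths(X, M1, M2, Y, standardize: bool = True) -> PathModel:
    """Fit the serial mediation model by three OLS regressions.

    With ``standardize=True`` (default) all variables are z-scored
    first, so coefficients are standardized path weights and the total
    effect decomposes exactly as c = c' + a1 b1 + a2 b2 + a1 d21 b2.
    """
    arrs = [np.asarray(v, float) for v in (X, M1, M2, Y)]
    n = len(arrs[0])
    if any(len(a) != n for a in arrs) or n < 10:
        raise ValueError("variables must share length >= 10")
    if any(not np.all(np.isfinite(a)) for a in arrs):
        raise ValueError("non-finite values in path-model inputs")
    if standardize:
        arrs = [_standardize(a) for a in arrs]
    elif any(a.std(ddof=0) == 0 for a in arrs):
        raise ValueError("zero-variance variable cannot enter the path model")
    return _paths_from_arrays(*arrs)


def bootstrap_indirect(
    data: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    columns: tuple[str, str, str, str] = ("X", "M1", "M2", "Y"),
    standardize: bool = True,
) -> dict[str, IndirectEffect]:
    """BC bootstrap intervals for every indirect effect (and their sum).

    Cases (rows) are resampled with replacement; the model is refit per
    resample and each indirect effect collected.  The bias-corrected
    percentile interval shifts the percentile points by z0, the normal
    quantile of the fraction of bootstrap estimates below the point
    estimate.  Degenerate resamples (a zero-variance column) are
    redrawn.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    arrs = [data[c].to_numpy(float) for c in columns]
    n = len(arrs[0])
    point = fit_paths(*arrs, standardize=standardize)
    labels = list(INDIRECT_LABELS) + ["total_indirect"]
    point_vals = {lbl: point.indirect(lbl) for lbl in INDIRECT_LABELS}
    point_vals["total_indirect"] = point.total_indirect()

    rng = np.random.default_rng(seed)
    boots = {lbl: np.empty(n_boot) for lbl in labels}
    b = 0
    redraws = 0
    mat = np.column_stack(arrs)
    while b < n_boot:
        idx = rng.integers(0, n, n)
        sample = mat[idx]
        if np.any(sample.std(axis=0) == 0):
            redraws += 1
            if redraws > 100 * n_boot:
                raise RuntimeError("too many degenerate bootstrap resamples")
            continue
        cols = [sample[:, j] for j in range(4)]
        if standardize:
            cols = [_standardize(cv) for cv in cols]
        model = _paths_from_arrays(*cols)
        for lbl in INDIRECT_LABELS:
            boots[lbl][b] = model.indirect(lbl)
        boots["total_indirect"][b] = model.total_indirect()
        b += 1

    out = {}
    for lbl in labels:
        ci = _bc_interval(boots[lbl], point_vals[lbl], alpha)
        out[lbl] = IndirectEffect(lbl, float(point_vals[lbl]), ci, n_boot, seed)
    return out


def _bc_interval(samples: np.ndarray, estimate: float,
                 alpha: float = 0.05) -> tuple[float, float]:
    """Bias-corrected percentile interval.

    z0 is the normal quantile of the fraction of bootstrap draws below
    the point estimate; the percentile points are shifted to
    Phi(2 z0 +/- z_{1-alpha/2}).  With a median-unbiased bootstrap
    distribution (z0 = 0) this is the plain percentile interval.
    """
    n = len(samples)
    zcrit = sps.norm.ppf(1 - alpha / 2)
    prop = np.clip(np.mean(samples < estimate), 1.0 / n, 1 - 1.0 / n)
    z0 = sps.norm.ppf(prop)
    lo_q = sps.norm.cdf(2 * z0 - zcrit)
    hi_q = sps.norm.cdf(2 * z0 + zcrit)
    return (float(np.quantile(samples, lo_q)), float(np.quantile(samples, hi_q)))
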