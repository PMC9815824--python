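"""Cross-validated prediction with a permutation null.

A brain-behavior relationship is tested by balanced fourfold
cross-validation of a simple linear regression: the model is fit on
three folds, used to predict the held-out fold, and the pooled
predictions are correlated with the observed outcome to give
r(predicted, observed).  Significance comes from shuffling participant
labels (1000 surrogates by default) and counting surrogates whose r
exceeds the true one.  Steiger's test compares two dependent,
non-overlapping correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "PredictionResult",
    "SteigerResult",
    "balanced_folds",
    "cv_predict_r",
    "permutation_p",
    "steiger_z",
]


@dataclass
class PredictionResult:
    r: float
    p: float | None = None
    n_perm: int | None = None
    seed: int | None = None
    predictions: np.ndarray | None = None


@dataclass
class SteigerResult:
    z: float
    p: float
    r1: float
    r2: float
    corr_matrix: np.ndarray


def balanced_folds(y, k: int = 4, seed: int = 0) -> np.ndarray:
    """Rank-stratified fold assignment (fold index per subject, 0..k-1).

    Subjects are ranked on the outcome; each consecutive block of k
    ranks contributes one subject to each fold (a trailing partial
    block fills distinct folds), so fold outcome distributions stay
    comparable and fold sizes differ by at most one.
    """
    y = np.asarray(y, float)
    n = len(y)
    if n < k:
        raise ValueError(f"need at least k={k} subjects, got {n}")
    rng = np.random.default_rng(seed)
    order = np.argsort(y, kind="stable")
    folds = np.empty(n, dtype=int)
    for start in range(0, n, k):
        block = order[start:start + k]
        folds[block] = rng.permutation(k)[: len(block)]
    return folds


def _linreg_predict(x_tr, y_tr, x_te):
    xm = x_tr.mean()
    xc = x_tr - xm
    sxx = xc @ xc
    if sxx == 0:
        raise ValueError("zero-variance predictor in a training fold")
    slope = (xc @ (y_tr - y_tr.mean())) / sxx
    return y_tr.mean() + slope * (x_te - xm)


def cv_predict_r(x, y, k: int = 4, seed: int = 0) -> PredictionResult:
    """r(predicted, observed) from balanced k-fold linear regression."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 2 * k:
        raise ValueError(f"need at least 2k={2 * k} subjects")
    folds = balanced_folds(y, k=k, seed=seed)
    pred = np.empty_like(y)
    for f in range(k):
        te = folds == f
        pred[te] = _linreg_predict(x[~te], y[~te], x[te])
    r = float(np.corrcoef(pred, y)[0, 1]) if pred.std() > 0 else 0.0
    return PredictionResult(r=r, seed=seed, predictions=pred)


def permutation_p(
    x,
    y,
    k: int = 4,
    n_perm: int = 1000,
    seed: int = 0,
    add_one: bool = False,
    two_sided: bool = False,
) -> PredictionResult:
    """Permutation test of r(predicted, observed).

    Participant labels of ``y`` are shuffled ``n_perm`` times and the
    CV prediction recomputed; p is the fraction of surrogate r values
    strictly greater than the observed one (one-sided in r).
    ``add_one`` switches to the conservative (1 + count)/(1 + n_perm)
    estimate; ``two_sided`` compares |r| instead.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    rng = np.random.default_rng(seed)
    obs = cv_predict_r(x, y, k=k, seed=seed).r
    stat = abs if two_sided else (lambda v: v)
    count = 0
    for _ in range(n_perm):
        y_perm = rng.permutation(y)
        r_perm = cv_predict_r(x, y_perm, k=k, seed=seed).r
        if stat(r_perm) > stat(obs):
            count += 1
    p = (count + 1) / (n_perm + 1) if add_one else count / n_perm
    return PredictionResult(r=obs, p=float(p), n_perm=n_perm, seed=seed)


def steiger_z(
    r1: float,
    r2: float,
    corr_matrix: np.ndarray,
    n: int,
) -> SteigerResult:
    """Steiger's Z for two dependent, non-overlapping correlations.

    ``corr_matrix`` is the 4x4 correlation matrix of the variables
    (x1, y1, x2, y2) measured on the same ``n`` subjects, with
    r1 = corr(x1, y1) and r2 = corr(x2, y2).  The Fisher-z difference
    is scaled by its standard error from the Pearson-Filon covariance
    evaluated at the pooled correlation; the p value is two-tailed.
    """
    if n <= 3:
        raise ValueError("need n > 3")
    R = np.asarray(corr_matrix, float)
    if R.shape != (4, 4) or not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1):
        raise ValueError("corr_matrix must be a symmetric 4x4 correlation matrix")
    if np.any(np.abs([r1, r2]) >= 1):
        raise ValueError("correlations must lie strictly inside (-1, 1)")
    if not np.isclose(R[0, 1], r1) or not np.isclose(R[2, 3], r2):
        raise ValueError("corr_matrix entries (0,1) and (2,3) must equal r1 and r2")
    if np.linalg.eigvalsh(R).min() < -1e-10:
        raise ValueError("corr_matrix is not positive semidefinite")

    # indices: j,k = variables of r1; h,m = variables of r2
    r_jh, r_jm = R[0, 2], R[0, 3]
    r_kh, r_km = R[1, 2], R[1, 3]
    rbar = (r1 + r2) / 2.0

    def psi(r_jk, r_hm):
        return 0.5 * (
            (r_jh - r_jk * r_kh) * (r_km - r_kh * r_hm)
            + (r_jm - r_jh * r_hm) * (r_kh - r_jh * r_jk)
            + (r_jh - r_jm * r_hm) * (r_km - r_jk * r_jm)
            + (r_jm - r_jk * r_km) * (r_kh - r_km * r_hm)
        )

    # pooled-r covariance of the two Fisher z's (Steiger's modification)
    s_bar = psi(rbar, rbar) / (1.0 - rbar**2) ** 2
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    z = float((z1 - z2) * np.sqrt((n - 3) / (2.0 - 2.0 * s_bar)))
    p = float(2 * sps.norm.sf(abs(z)))
    return SteigerResult(z=z, p=p, r1=float(r1), r2=float(r2), corr_matrix=R)
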