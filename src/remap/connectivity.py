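"""Task-dependent (gPPI) and task-free (rest) seed connectivity.

The gPPI path estimates neural seed activity by ridge-regularized
deconvolution of the canonical HRF, multiplies it with condition (or
condition-by-memory) indicators, re-convolves, and fits an OLS model
whose PPI betas isolate condition-specific coupling after removing the
seed's overall contribution and the task's common driving input.  The
rest path band-pass filters seed and targets (0.008-0.10 Hz),
regresses out nuisance series (6 motion + CSF + WM), Fisher-transforms
seed-target correlations per rest run, differences consecutive runs in
z-space, and relates the differences to per-condition memory scores in
a group regression whose contrast is the difference of the two memory
coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as spsig
from scipy import stats as sps
from scipy.linalg import toeplitz

from .firstlevel import HrfKernel, canonical_hrf
from .similarity import R_CLIP

__all__ = [
    "PpiDesign",
    "ConnectivityEstimate",
    "RestPreprocParams",
    "GroupRegressionResult",
    "deconvolve_neural",
    "condition_boxcars",
    "build_gppi_design",
    "fit_gppi_contrast",
    "preprocess_rest",
    "seed_connectivity",
    "rest_difference",
    "group_interaction_regression",
]


def _hrf_matrix(hrf: HrfKernel, n: int) -> np.ndarray:
    """Toeplitz operator H such that (H @ neural) == hrf * neural at TR."""
    kernel_tr = hrf.tr_kernel()
    col = np.zeros(n)
    m = min(n, len(kernel_tr))
    col[:m] = kernel_tr[:m]
    return toeplitz(col, np.zeros(n))


def deconvolve_neural(
    seed_ts: np.ndarray,
    hrf: HrfKernel | None = None,
    ridge_lambda: float | str = "gcv",
    tr: float = 2.0,
) -> np.ndarray:
    """Estimate neural activity underlying a BOLD seed series.

    Solves (H'H + lambda I) x = H' y where H is the HRF convolution
    operator at TR resolution.  ``ridge_lambda="gcv"`` picks lambda by
    generalized cross-validation over a log grid; a float fixes it.
    """
    y = np.asarray(seed_ts, float)
    if not np.all(np.isfinite(y)):
        raise ValueError("seed series must be finite")
    if hrf is None:
        hrf = canonical_hrf(tr)
    H = _hrf_matrix(hrf, len(y))
    if isinstance(ridge_lambda, str):
        if ridge_lambda != "gcv":
            raise ValueError("ridge_lambda must be a float or 'gcv'")
        lam = _gcv_lambda(H, y)
    else:
        lam = float(ridge_lambda)
        if lam < 0:
            raise ValueError("ridge_lambda must be >= 0")
    n = len(y)
    return np.linalg.solve(H.T @ H + lam * np.eye(n), H.T @ y)


def _gcv_lambda(H: np.ndarray, y: np.ndarray) -> float:
    """Generalized cross-validation choice of the ridge penalty."""
    u, s, _ = np.linalg.svd(H, full_matrices=False)
    uy = u.T @ y
    n = len(y)
    best, best_score = 1e-2, np.inf
    for lam in np.logspace(-6, 2, 25):
        shrink = s**2 / (s**2 + lam)
        resid = (1 - shrink) * uy
        denom = (1 - shrink.sum() / n) ** 2
        score = (resid @ resid) / n / max(denom, 1e-12)
        if score < best_score:
            best, best_score = lam, score
    return best


def condition_boxcars(
    design,
    n_volumes: int,
    tr: float = 2.0,
    cells: dict[str, np.ndarray] | None = None,
    duration: float = 2.0,
) -> dict[str, np.ndarray]:
    """TR-resolution task indicators per cell from a trial design.

    By default one boxcar per condition over the association stimuli;
    ``cells`` may map cell names to boolean trial masks (in design
    trial order) to form condition-by-memory cells instead.
    """
    trials = design.trials()
    if cells is None:
        cells = {c: (trials["condition"] == c).to_numpy()
                 for c in trials["condition"].unique()}
    t = np.arange(n_volumes) * tr
    out = {}
    for name, mask in cells.items():
        box = np.zeros(n_volumes)
        for onset in trials.loc[np.asarray(mask, bool), "onset"]:
            box[(t >= onset) & (t < onset + duration)] = 1.0
        out[name] = box
    return out


@dataclass
class PpiDesign:
    """gPPI design matrix: PPI, psychological, physiological, nuisance cols."""

    matrix: np.ndarray
    labels: list[str]
    ppi_labels: list[str]

    def __post_init__(self) -> None:
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise ValueError("PPI design is rank-deficient")


@dataclass
class ConnectivityEstimate:
    beta: pd.Series
    contrast: float
    t: float
    p: float
    df: int


def build_gppi_design(
    neural: np.ndarray,
    condition_boxcars: dict[str, np.ndarray],
    seed_ts: np.ndarray,
    hrf: HrfKernel | None = None,
    nuisance: pd.DataFrame | None = None,
    tr: float = 2.0,
) -> PpiDesign:
    """Assemble the gPPI GLM for one run.

    One PPI regressor per cell in ``condition_boxcars`` (the neural
    estimate gated by the cell's TR-resolution indicator, re-convolved
    with the HRF), plus the HRF-convolved psychological regressors, the
    seed physiological regressor, optional nuisance columns, and a
    constant.  Cells may be plain conditions or condition-by-memory
    combinations (e.g. the four remembered/forgotten x aversive/neutral
    cells).
    """
    neural = np.asarray(neural, float)
    n = len(neural)
    if hrf is None:
        hrf = canonical_hrf(tr)
    H = _hrf_matrix(hrf, n)
    boxes = {k: np.asarray(v, float) for k, v in condition_boxcars.items()}
    for name, box in boxes.items():
        if len(box) != n:
            raise ValueError(f"boxcar {name!r} length differs from neural series")
        if not box.any():
            raise ValueError(f"cell {name!r} has an all-zero boxcar")
    overlap = np.sum([b != 0 for b in boxes.values()], axis=0)
    if np.any(overlap > 1):
        raise ValueError("cell boxcars overlap; cells must partition task time")

    cols, labels, ppi_labels = [], [], []
    for name, box in boxes.items():
        cols.append(H @ (neural * box))
        labels.append(f"ppi_{name}")
        ppi_labels.append(f"ppi_{name}")
    for name, box in boxes.items():
        cols.append(H @ box)
        labels.append(f"psych_{name}")
    cols.append(np.asarray(seed_ts, float))
    labels.append("seed")
    if nuisance is not None:
        for name in nuisance.columns:
            cols.append(nuisance[name].to_numpy(float))
            labels.append(str(name))
    cols.append(np.ones(n))
    labels.append("constant")
    return PpiDesign(np.column_stack(cols), labels, ppi_labels)


def fit_gppi_contrast(
    target_ts: np.ndarray,
    ppi_design: PpiDesign,
    contrast_weights: dict[str, float] | None = None,
) -> ConnectivityEstimate:
    """OLS fit of a target series on a gPPI design plus a PPI contrast.

    ``contrast_weights`` maps PPI labels to weights (default:
    aversive - neutral over the two plain condition cells).
    """
    y = np.asarray(target_ts, float)
    X = ppi_design.matrix
    if len(y) != len(X):
        raise ValueError("target length must match design")
    if contrast_weights is None:
        contrast_weights = {"ppi_aversive": 1.0, "ppi_neutral": -1.0}
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    df = len(y) - X.shape[1]
    resid = y - X @ beta
    sigma2 = resid @ resid / df
    xtx_inv = np.linalg.inv(X.T @ X)
    c = np.zeros(X.shape[1])
    for name, w in contrast_weights.items():
        c[ppi_design.labels.index(name)] = w
    value = float(c @ beta)
    se = float(np.sqrt(sigma2 * c @ xtx_inv @ c))
    t = value / se if se > 0 else 0.0
    p = float(2 * sps.t.sf(abs(t), df))
    return ConnectivityEstimate(
        beta=pd.Series(beta, index=ppi_design.labels),
        contrast=value,
        t=float(t),
        p=p,
        df=df,
    )


@dataclass(frozen=True)
class RestPreprocParams:
    """Band-pass and nuisance settings for resting-state series."""

    band: tuple[float, float] = (0.008, 0.10)
    tr: float = 2.0
    order: int = 4

    def __post_init__(self) -> None:
        low, high = self.band
        nyq = 0.5 / self.tr
        if not 0 < low < high < nyq:
            raise ValueError(f"band must satisfy 0 < low < high < Nyquist ({nyq} Hz)")


def preprocess_rest(
    ts: np.ndarray,
    confounds: pd.DataFrame | np.ndarray | None,
    params: RestPreprocParams = RestPreprocParams(),
) -> np.ndarray:
    """Band-pass filter then regress nuisance series out of ``ts``.

    Zero-phase (forward-backward) Butterworth band-pass of both the
    data and the confounds, then OLS residualization of the filtered
    data on the filtered confounds plus an intercept.  Filtering the
    confounds with the same band prevents the regression step from
    reintroducing out-of-band energy.
    """
    y = np.asarray(ts, float)
    nyq = 0.5 / params.tr
    b, a = spsig.butter(params.order, [f / nyq for f in params.band],
                        btype="bandpass")
    # demean first, then Gustafsson edge handling: reflection padding lets
    # the slow high-pass edge leak stopband power into runs as short as a
    # rest scan, and the DC offset would dominate the edge optimization
    yf = spsig.filtfilt(b, a, y - y.mean(), method="gust")
    if confounds is None:
        return yf - yf.mean()
    C = np.asarray(confounds, float).reshape(len(y), -1)
    Cf = spsig.filtfilt(b, a, C - C.mean(axis=0), axis=0, method="gust")
    X = np.column_stack([np.ones(len(y)), Cf])
    beta, *_ = np.linalg.lstsq(X, yf, rcond=None)
    return yf - X @ beta


def seed_connectivity(seed_res: np.ndarray, target_res_set) -> pd.Series:
    """Fisher-z seed-target correlations for one rest run."""
    seed = np.asarray(seed_res, float)
    if isinstance(target_res_set, (pd.DataFrame, dict)):
        items = (target_res_set.items() if isinstance(target_res_set, dict)
                 else ((c, target_res_set[c].to_numpy()) for c in target_res_set))
    else:
        items = [("target", np.asarray(target_res_set, float))]
    out = {}
    for name, target in items:
        r = float(np.corrcoef(seed, np.asarray(target, float))[0, 1])
        out[name] = float(np.arctanh(np.clip(r, -R_CLIP, R_CLIP)))
    return pd.Series(out, name="z")


def rest_difference(map_late, map_early):
    """Late-minus-early connectivity change, element-wise in Fisher z."""
    late = np.asarray(map_late, float)
    early = np.asarray(map_early, float)
    if late.shape != early.shape:
        raise ValueError("maps must share shape")
    diff = late - early
    if isinstance(map_late, pd.Series):
        return pd.Series(diff, index=map_late.index)
    return diff


@dataclass
class GroupRegressionResult:
    coef_aversive: float
    coef_neutral: float
    interaction_t: float
    interaction_p: float
    df: int


def group_interaction_regression(
    diff_values: np.ndarray,
    mem_aversive: np.ndarray,
    mem_neutral: np.ndarray,
) -> GroupRegressionResult:
    """Memory-by-emotion interaction on connectivity-change values.

    Per-subject connectivity differences are regressed on the two
    per-condition memory scores (plus an intercept); the interaction
    contrast tests beta_aversive - beta_neutral.
    """
    d = np.asarray(diff_values, float)
    ma = np.asarray(mem_aversive, float)
    mn = np.asarray(mem_neutral, float)
    n = len(d)
    if not (len(ma) == len(mn) == n):
        raise ValueError("inputs must share length")
    if n < 3 + 4:
        raise ValueError("need at least 4 more subjects than regressors")
    if ma.std() == 0 or mn.std() == 0 or abs(np.corrcoef(ma, mn)[0, 1]) > 0.999:
        raise ValueError("memory covariates are (near-)collinear")
    X = np.column_stack([np.ones(n), ma, mn])
    beta, *_ = np.linalg.lstsq(X, d, rcond=None)
    df = n - 3
    resid = d - X @ beta
    sigma2 = resid @ resid / df
    xtx_inv = np.linalg.inv(X.T @ X)
    c = np.array([0.0, 1.0, -1.0])
    se = float(np.sqrt(sigma2 * c @ xtx_inv @ c))
    t = float(c @ beta / se) if se > 0 else 0.0
    p = float(2 * sps.t.sf(abs(t), df))
    return GroupRegressionResult(
        coef_aversive=float(beta[1]),
        coef_neutral=float(beta[2]),
        interaction_t=t,
        interaction_p=p,
        df=df,
    )
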