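"""Canonical-HRF general linear model machinery.

Produces condition-level and trial-level t-value patterns from BOLD-like
time series and trial designs.  The HRF is the SPM canonical
double-gamma (response peak 6 s, undershoot peak 16 s, dispersions 1 s,
peak:undershoot ratio 6:1, 32 s support), and regressors are boxcars
convolved with it at a microtime resolution before resampling at the TR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "HrfKernel",
    "DesignMatrix",
    "GlmResult",
    "canonical_hrf",
    "build_design_matrix",
    "dct_drift_basis",
    "fit_glm",
]


@dataclass(frozen=True)
class HrfKernel:
    """Sampled canonical HRF, normalized to unit peak.

    ``values[i]`` is the kernel at ``i * dt`` seconds with
    ``dt = tr / oversampling``.
    """

    values: np.ndarray
    tr: float
    oversampling: int
    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    duration: float = 32.0

    @property
    def dt(self) -> float:
        return self.tr / self.oversampling

    def tr_kernel(self) -> np.ndarray:
        """Bin-integrated kernel at TR resolution.

        ``tr_kernel()[k]`` is the integral of the HRF over the k-th TR
        bin, so ``np.convolve(neural, tr_kernel())`` approximates the
        continuous convolution of a TR-piecewise-constant neural series.
        Unlike point sampling (which starts at h(0) = 0) the first bin
        is nonzero, keeping the convolution operator invertible.
        """
        n_bins = int(np.ceil(len(self.values) / self.oversampling))
        pad = n_bins * self.oversampling - len(self.values)
        vals = np.concatenate([self.values, np.zeros(pad)])
        return vals.reshape(n_bins, self.oversampling).sum(axis=1) * self.dt


def canonical_hrf(tr: float, oversampling: int = 16) -> HrfKernel:
    """SPM-style canonical double-gamma HRF sampled at ``tr / oversampling``.

    Difference of two gamma densities: a response gamma peaking at 6 s
    and an undershoot gamma peaking at 16 s, both with dispersion 1 s,
    mixed 6:1, over a 32 s window; the kernel is rescaled to unit peak.
    """
    if tr <= 0:
        raise ValueError(f"tr must be positive, got {tr}")
    if oversampling < 1:
        raise ValueError("oversampling must be >= 1")
    dt = tr / oversampling
    t = np.arange(0, 32.0 + dt / 2, dt)
    # gamma densities parameterized by peak delay / dispersion as in SPM:
    # shape = delay / dispersion, scale = dispersion
    peak = sps.gamma.pdf(t, a=6.0, scale=1.0)
    undershoot = sps.gamma.pdf(t, a=16.0, scale=1.0)
    hrf = peak - undershoot / 6.0
    hrf = hrf / hrf.max()
    return HrfKernel(values=hrf, tr=tr, oversampling=oversampling)


@dataclass
class DesignMatrix:
    """GLM design: ``matrix`` is (n_volumes, n_regressors)."""

    matrix: np.ndarray
    labels: list[str]
    frame_times: np.ndarray

    def __post_init__(self) -> None:
        if len(self.labels) != self.matrix.shape[1]:
            raise ValueError("one label per column required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("column labels must be unique")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("design matrix has non-finite entries")

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.labels, index=self.frame_times)


def _convolved_regressor(
    onsets: np.ndarray,
    durations: np.ndarray,
    hrf: HrfKernel,
    n_volumes: int,
) -> np.ndarray:
    """Boxcar convolved with the HRF at microtime resolution, sampled at TR."""
    dt = hrf.dt
    n_fine = int(round(n_volumes * hrf.tr / dt))
    box = np.zeros(n_fine)
    for onset, dur in zip(onsets, durations):
        i0 = int(round(onset / dt))
        i1 = int(round((onset + dur) / dt))
        box[i0:max(i1, i0 + 1)] = 1.0
    conv = np.convolve(box, hrf.values)[:n_fine] * dt
    return conv[:: hrf.oversampling][:n_volumes]


def dct_drift_basis(n_volumes: int, tr: float, cutoff_s: float = 128.0) -> np.ndarray:
    """Discrete-cosine high-pass drift basis (1/cutoff Hz), constant excluded."""
    frame_times = np.arange(n_volumes) * tr
    order = int(np.floor(2 * n_volumes * tr / cutoff_s))
    basis = [
        np.sqrt(2.0 / n_volumes)
        * np.cos(np.pi * (2 * np.arange(n_volumes) + 1) * k / (2 * n_volumes))
        for k in range(1, order + 1)
    ]
    if not basis:
        return np.empty((len(frame_times), 0))
    return np.column_stack(basis)


def build_design_matrix(
    design,
    tr: float,
    n_volumes: int,
    mode: str = "trial",
    extra_regressors: pd.DataFrame | None = None,
    high_pass_s: float | None = None,
    event_duration: float = 2.0,
    oversampling: int = 16,
) -> DesignMatrix:
    """Build a condition- or trial-level GLM design matrix.

    ``mode="condition"`` yields one regressor per condition over the
    association events (and, for the emotional phase, one cue regressor
    per condition, as regressors of no interest); ``mode="trial"``
    yields one regressor per pair id — spanning every presentation of
    that pair, so repeated viewings collapse into a single column — plus
    a single cue regressor.  Events are modeled with ``event_duration``
    seconds from stimulus onset (2 s by default, regardless of the
    on-screen presentation time).  A constant column is always appended
    last; optional nuisance columns (e.g. motion) and a discrete-cosine
    drift basis can be inserted before it.
    """
    if mode not in ("condition", "trial"):
        raise ValueError(f"unknown mode {mode!r}")
    events = design.events
    frame_times = np.arange(n_volumes) * tr
    if len(events):
        t_end = (events["onset"] + events["duration"]).max()
        if t_end > n_volumes * tr + 1e-9:
            bad = events.loc[(events["onset"] + events["duration"]).idxmax()]
            raise ValueError(
                f"event {bad['event_kind']} (pair {bad['pair_id']}) at onset "
                f"{bad['onset']} s extends past scan end ({n_volumes * tr} s)"
            )

    hrf = canonical_hrf(tr, oversampling)
    stim = events[events["event_kind"].isin(["pair", "face_voice"])]
    cues = events[events["event_kind"] == "cue"]

    cols: list[np.ndarray] = []
    labels: list[str] = []

    def add(label: str, sub: pd.DataFrame) -> None:
        cols.append(
            _convolved_regressor(
                sub["onset"].to_numpy(float),
                np.full(len(sub), event_duration),
                hrf,
                n_volumes,
            )
        )
        labels.append(label)

    if mode == "condition":
        for cond in ("aversive", "neutral"):
            sub = stim[stim["condition"] == cond]
            if len(sub):
                add(cond, sub)
        for cond in ("aversive", "neutral"):
            sub = cues[cues["condition"] == cond]
            if len(sub):
                add(f"cue_{cond}", sub)
    else:
        for pid in pd.unique(stim["pair_id"]):
            add(f"pair_{pid}", stim[stim["pair_id"] == pid])
        if len(cues):
            add("cue", cues)

    if extra_regressors is not None:
        if len(extra_regressors) != n_volumes:
            raise ValueError("extra_regressors length must equal n_volumes")
        for name in extra_regressors.columns:
            cols.append(extra_regressors[name].to_numpy(float))
            labels.append(str(name))

    if high_pass_s is not None:
        drift = dct_drift_basis(n_volumes, tr, high_pass_s)
        for k in range(drift.shape[1]):
            cols.append(drift[:, k])
            labels.append(f"drift_{k + 1}")

    cols.append(np.ones(n_volumes))
    labels.append("constant")
    return DesignMatrix(np.column_stack(cols), labels, frame_times)


@dataclass
class GlmResult:
    """OLS estimates: one beta/t per regressor (columns if y was 2-D)."""

    beta: np.ndarray
    t: np.ndarray
    residual_variance: np.ndarray
    df: int
    labels: list[str] = field(default_factory=list)

    def pattern(self, label: str) -> np.ndarray:
        """t-values of one regressor across series (the multivoxel t-pattern)."""
        return np.atleast_2d(self.t)[self.labels.index(label)]


def fit_glm(timeseries: np.ndarray, design_matrix: DesignMatrix) -> GlmResult:
    """Ordinary least squares fit of one or many series on a shared design.

    ``timeseries`` is (n_volumes,) or (n_volumes, n_series); a t value is
    computed per regressor and series with ``df = n_volumes - rank(X)``.
    """
    X = design_matrix.matrix
    y = np.asarray(timeseries, float)
    squeeze = y.ndim == 1
    y = y.reshape(len(y), -1)
    if y.shape[0] != X.shape[0]:
        raise ValueError(
            f"time series has {y.shape[0]} volumes but design has {X.shape[0]}"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns for the error message
        _, r = np.linalg.qr(X)
        bad = [design_matrix.labels[i] for i in np.where(np.abs(np.diag(r)) < 1e-10)[0]]
        raise ValueError(f"design matrix is rank-deficient; collinear columns: {bad}")
    df = X.shape[0] - rank
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    if squeeze:
        beta, t, sigma2 = beta[:, 0], t[:, 0], sigma2[0]
    return GlmResult(
        beta=beta,
        t=t,
        residual_variance=sigma2,
        df=df,
        labels=list(design_matrix.labels),
    )
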