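"""Behavioral and psychophysiological statistics.

Covers the bespoke descriptive and inferential statistics of the
paradigm: the positional chance level of a 4-alternative matching
test, confidence/vividness binning of accuracy, one-sample and paired
t-tests with the d_av effect size, 2x2 repeated-measures ANOVA (with
optional between-subject covariates of no interest), a random-intercept
mixed model for trial-level rating relationships, and windowed skin
conductance level (SCL) means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "MixedModelResult",
    "chance_level",
    "bin_accuracy",
    "one_sample_t",
    "paired_t_dav",
    "rm_anova_2x2",
    "mixed_slope",
    "scl_mean",
]


@dataclass
class TestResult:
    statistic: float
    df: tuple[int, ...] | int
    p: float
    effect_size: float
    label: str = ""
    effect_size_name: str = ""


@dataclass
class MixedModelResult:
    slope: float
    se: float
    ci: tuple[float, float]
    random_intercept_var: float
    n_subjects: int
    n_obs: int


def chance_level(n_options: int) -> float:
    """Chance accuracy of sequentially matching ``n_options`` pairings.

    With n items matched one at a time without replacement, the k-th
    guess succeeds with probability 1/(n-k+1); the mean over positions
    is the expected proportion correct.  For n = 4 this is
    (1/4 + 1/3 + 1/2 + 1)/4 = 0.5208 (52% to the nearest percent).
    """
    if n_options < 1:
        raise ValueError("n_options must be >= 1")
    return float(np.mean([1.0 / (n_options - k) for k in range(n_options)]))


def bin_accuracy(
    table: pd.DataFrame,
    bin_on: str = "confidence",
    restrict: pd.Series | None = None,
) -> pd.DataFrame:
    """Accuracy split into high (ratings 3-4) and low (1-2) bins.

    One row per subject x condition x bin with the proportion correct
    and trial count; an empty bin yields NaN (flagged, never silently
    zero).  ``restrict`` is an optional boolean mask applied first,
    e.g. high-confidence-only trials before vividness binning.
    """
    if bin_on not in table.columns:
        raise ValueError(f"no column {bin_on!r} in table")
    t = table if restrict is None else table.loc[np.asarray(restrict, bool)]
    t = t.assign(bin=np.where(t[bin_on] >= 3, "high", "low"))
    cells = []
    for (subject, condition), sub in t.groupby(["subject", "condition"]):
        for b in ("high", "low"):
            inbin = sub[sub["bin"] == b]
            cells.append({
                "subject": subject,
                "condition": condition,
                "bin": b,
                "n_trials": len(inbin),
                "accuracy": inbin["chosen_correct"].mean() if len(inbin) else np.nan,
            })
    return pd.DataFrame(cells)


def one_sample_t(values, mu0: float = 0.0, label: str = "") -> TestResult:
    """Two-tailed one-sample t-test against ``mu0`` with Cohen's d."""
    v = np.asarray(values, float)
    if len(v) < 2:
        raise ValueError("need >= 2 values")
    t, p = sps.ttest_1samp(v, mu0)
    sd = v.std(ddof=1)
    d = (v.mean() - mu0) / sd if sd > 0 else 0.0
    if np.isnan(t):  # zero-variance sample exactly at mu0: no evidence
        t, p = 0.0, 1.0
    return TestResult(float(t), len(v) - 1, float(p), float(d), label, "d")


def paired_t_dav(x, y, label: str = "") -> TestResult:
    """Paired t-test with the d_av effect size.

    d_av uses the mean difference as numerator and the average of the
    two conditions' standard deviations as denominator.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or len(x) < 2:
        raise ValueError("x and y must be paired with length >= 2")
    t, p = sps.ttest_rel(x, y)
    denom = (x.std(ddof=1) + y.std(ddof=1)) / 2.0
    if denom == 0:
        raise ValueError("zero average SD: d_av undefined")
    dav = float((x - y).mean() / denom)
    if np.isnan(t):  # identical paired values: no effect, no evidence
        t, p = 0.0, 1.0
    return TestResult(float(t), len(x) - 1, float(p), dav, label, "d_av")


def _contrast_test(scores: np.ndarray, covariates: np.ndarray | None,
                   label: str) -> TestResult:
    """Test that a within-subject contrast has zero mean.

    Without covariates this is the one-sample t on the contrast scores
    (so F = t^2).  With covariates, the contrast is regressed on the
    mean-centered covariates and the intercept is tested — the
    convention mainstream statistics packages use for a
    repeated-measures ANCOVA.
    """
    n = len(scores)
    if covariates is None:
        X = np.ones((n, 1))
    else:
        cov = np.asarray(covariates, float).reshape(n, -1)
        if np.any(cov.std(axis=0) == 0):
            raise ValueError("zero-variance covariate")
        X = np.column_stack([np.ones(n), cov - cov.mean(axis=0)])
    df_err = n - X.shape[1]
    if df_err <= 0:
        raise ValueError("not enough subjects for the requested covariates")
    beta, *_ = np.linalg.lstsq(X, scores, rcond=None)
    resid = scores - X @ beta
    sse = float(resid @ resid)
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sse / df_err * xtx_inv[0, 0])
    tval = beta[0] / se if se > 0 else 0.0
    F = tval**2
    p = float(sps.f.sf(F, 1, df_err))
    eta_p2 = float(F / (F + df_err)) if (F + df_err) > 0 else 0.0
    return TestResult(float(F), (1, df_err), p, eta_p2, label, "partial_eta2")


def rm_anova_2x2(
    cells: np.ndarray,
    covariates: np.ndarray | None = None,
    factor_names: tuple[str, str] = ("A", "B"),
) -> dict[str, TestResult]:
    """2x2 repeated-measures ANOVA via within-subject contrasts.

    ``cells`` is (n_subjects, 2, 2).  Each effect (two main effects and
    the interaction) is its within-subject contrast tested against
    zero; without covariates F equals the squared paired-t of the
    corresponding difference scores, and partial eta^2 = F/(F+df_err).
    Mean-centered covariates of no interest implement the
    repeated-measures ANCOVA convention.
    """
    cells = np.asarray(cells, float)
    if cells.ndim != 3 or cells.shape[1:] != (2, 2):
        raise ValueError("cells must be (n_subjects, 2, 2)")
    if np.isnan(cells).any():
        bad = sorted(np.unique(np.where(np.isnan(cells))[0]).tolist())
        raise ValueError(f"missing cells for subjects at rows {bad}")
    a, b = factor_names
    contrasts = {
        a: cells[:, 0, :].mean(axis=1) - cells[:, 1, :].mean(axis=1),
        b: cells[:, :, 0].mean(axis=1) - cells[:, :, 1].mean(axis=1),
        f"{a}x{b}": (cells[:, 0, 0] - cells[:, 0, 1]) - (cells[:, 1, 0] - cells[:, 1, 1]),
    }
    return {name: _contrast_test(scores, covariates, name)
            for name, scores in contrasts.items()}


def mixed_slope(trial_table: pd.DataFrame, x: str, y: str) -> MixedModelResult:
    """Random-intercept linear mixed model slope of ``y`` on ``x``.

    All trials enter, with participant as a random effect; the fixed
    slope is reported with its Wald 95% CI.
    """
    t = trial_table.dropna(subset=[x, y])
    if t["subject"].nunique() < 2:
        raise ValueError("need >= 2 subjects for a mixed model")
    if t[x].std() == 0:
        raise ValueError(f"predictor {x!r} is constant")
    import statsmodels.formula.api as smf

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(f"{y} ~ {x}", data=t, groups=t["subject"])
        fit = model.fit(reml=True, method="lbfgs")
    slope = float(fit.params[x])
    se = float(fit.bse[x])
    zcrit = sps.norm.ppf(0.975)
    return MixedModelResult(
        slope=slope,
        se=se,
        ci=(slope - zcrit * se, slope + zcrit * se),
        random_intercept_var=float(fit.cov_re.iloc[0, 0]),
        n_subjects=int(t["subject"].nunique()),
        n_obs=len(t),
    )


def scl_mean(
    trace: np.ndarray,
    onsets: np.ndarray,
    sample_rate: float,
    window_s: float = 6.0,
    conditions: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean skin conductance level in a post-onset window per trial.

    The mean of the trace over [onset, onset + window) is computed for
    each stimulus onset; onsets whose window extends past the trace
    yield NaN with a warning.  Condition labels, when given, are
    carried through for aggregation.
    """
    trace = np.asarray(trace, float)
    onsets = np.asarray(onsets, float)
    rows = []
    n_short = 0
    for i, onset in enumerate(onsets):
        i0 = int(round(onset * sample_rate))
        i1 = int(round((onset + window_s) * sample_rate))
        if i1 > len(trace) or i0 < 0:
            val = np.nan
            n_short += 1
        else:
            val = float(trace[i0:i1].mean())
        rows.append({
            "trial": i,
            "onset": onset,
            "scl": val,
            "condition": conditions[i] if conditions is not None else None,
        })
    if n_short:
        warnings.warn(f"{n_short} onsets extend past the trace; SCL set to NaN",
                      stacklevel=2)
    return pd.DataFrame(rows)
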