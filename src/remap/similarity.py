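"""Multivoxel pattern-similarity (reactivation) measures.

Reinstatement of initial-learning activity during emotional learning is
quantified as the Fisher-transformed Pearson correlation between
trial-wise (or condition-wise) t-value patterns of the two phases.
Trial-level measures distinguish trial-specific reinstatement
(pair-specific similarity) from category-level representation
(across-pair similarity), and within-phase consistency measures
(within-encoding / within-arousal) capture pattern stability inside a
single phase.  A searchlight mapper applies any of these measures in a
spherical neighborhood around every in-mask voxel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PatternSet",
    "SearchlightMap",
    "TRIAL_MEASURES",
    "normalize_pattern",
    "similarity_z",
    "trial_measures",
    "condition_level_similarity",
    "searchlight_map",
]

#: correlations are clipped at this magnitude before atanh so identical
#: patterns give a large finite z instead of +inf
R_CLIP = 1.0 - 1e-7

TRIAL_MEASURES = (
    "pair_specific",
    "across_pair_within",
    "across_pair_between",
    "across_pair_combined",
    "within_encoding",
    "within_arousal",
)


@dataclass
class PatternSet:
    """Per-trial multivoxel t-patterns within one ROI and phase.

    ``patterns`` is (n_trials, n_voxels); ``meta`` carries ``pair_id``
    and ``condition`` per row.
    """

    patterns: np.ndarray
    meta: pd.DataFrame
    roi: str = "roi"
    phase: str = ""

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns, float)
        if self.patterns.ndim != 2:
            raise ValueError("patterns must be a (n_trials, n_voxels) matrix")
        if len(self.meta) != self.patterns.shape[0]:
            raise ValueError("metadata rows must match pattern rows")
        if self.meta["pair_id"].duplicated().any():
            raise ValueError("pair_ids must be unique within a phase")

    @property
    def n_trials(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.patterns.shape[1]

    def by_pair(self) -> pd.Series:
        """Row index per pair id."""
        return pd.Series(np.arange(self.n_trials), index=self.meta["pair_id"].values)

    def conditions(self) -> np.ndarray:
        return self.meta["condition"].to_numpy()


def normalize_pattern(vector: np.ndarray) -> np.ndarray:
    """z-score a pattern across voxels (mean 0, SD 1).

    Removes the mean activation so similarity reflects the relative
    voxel topography, not overall amplitude.
    """
    v = np.asarray(vector, float)
    if v.size < 2:
        raise ValueError("need at least 2 voxels")
    sd = v.std()
    if sd == 0:
        raise ValueError("constant pattern cannot be z-scored")
    return (v - v.mean()) / sd


def similarity_z(x: np.ndarray, y: np.ndarray) -> float:
    """Fisher-transformed Pearson correlation, z = atanh(clip(r))."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("inputs must share length >= 2")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input has undefined correlation")
    r = float(np.corrcoef(x, y)[0, 1])
    return float(np.arctanh(np.clip(r, -R_CLIP, R_CLIP)))


def _zscore_rows(m: np.ndarray) -> np.ndarray:
    sd = m.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("constant pattern rows cannot be z-scored")
    return (m - m.mean(axis=1, keepdims=True)) / sd


def _corr_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlations between rows of a and rows of b."""
    az = _zscore_rows(a)
    bz = _zscore_rows(b)
    return az @ bz.T / a.shape[1]


def _fisher(r: float) -> float:
    return float(np.arctanh(np.clip(r, -R_CLIP, R_CLIP)))


def trial_measures(
    set_init: PatternSet,
    set_emo: PatternSet,
    measures: tuple[str, ...] = TRIAL_MEASURES,
    average_before_transform: bool = True,
) -> pd.DataFrame:
    """Trial-level similarity measures per condition.

    For each emotional-learning trial the relevant Pearson correlations
    with initial-learning (or same-phase) patterns are computed on
    z-scored patterns, averaged within trial where the measure is an
    across-pair average, averaged across trials of the condition, and
    Fisher-transformed (by default after averaging; set
    ``average_before_transform=False`` to transform each trial-level
    value first).  The self-pair is excluded from all across-pair and
    within-phase averages.

    Returns a tidy frame with columns condition, measure, z.
    """
    unknown = set(measures) - set(TRIAL_MEASURES)
    if unknown:
        raise ValueError(f"unknown measures: {sorted(unknown)}")
    pairs_emo = set_emo.meta["pair_id"].to_numpy()
    pairs_init = set_init.meta["pair_id"].to_numpy()
    need_match = {"pair_specific", "across_pair_within", "across_pair_between",
                  "across_pair_combined"}
    if need_match & set(measures) and set(pairs_emo) != set(pairs_init):
        raise ValueError("pair ids must match across phases for between-phase measures")

    # align the initial-phase rows to the emotional-phase pair order
    order = set_init.by_pair().loc[pairs_emo].to_numpy()
    init_aligned = set_init.patterns[order]
    cond = set_emo.conditions()
    n = len(pairs_emo)

    cross = _corr_matrix(set_emo.patterns, init_aligned)  # emo x init(aligned)
    same_cond = cond[:, None] == cond[None, :]
    off_diag = ~np.eye(n, dtype=bool)

    rows = []
    for c in ("aversive", "neutral"):
        in_c = cond == c
        if not in_c.any():
            continue
        per_trial: dict[str, np.ndarray] = {}
        if "pair_specific" in measures:
            per_trial["pair_specific"] = np.diag(cross)[in_c]
        if {"across_pair_within", "across_pair_combined"} & set(measures):
            m = same_cond & off_diag
            if m[in_c].sum(axis=1).min() < 1:
                raise ValueError(f"condition {c!r} needs >= 2 trials for across-pair measures")
            per_trial["across_pair_within"] = _masked_row_mean(cross, m)[in_c]
        if {"across_pair_between", "across_pair_combined"} & set(measures):
            m = ~same_cond
            per_trial["across_pair_between"] = _masked_row_mean(cross, m)[in_c]
        if "across_pair_combined" in measures:
            m = off_diag
            per_trial["across_pair_combined"] = _masked_row_mean(cross, m)[in_c]
        if "within_arousal" in measures:
            within = _corr_matrix(set_emo.patterns, set_emo.patterns)
            m = same_cond & off_diag
            per_trial["within_arousal"] = _masked_row_mean(within, m)[in_c]
        if "within_encoding" in measures:
            cond_i = set_init.conditions()
            within = _corr_matrix(set_init.patterns, set_init.patterns)
            m = (cond_i[:, None] == cond_i[None, :]) & ~np.eye(len(cond_i), dtype=bool)
            vals = _masked_row_mean(within, m)[cond_i == c]
            per_trial["within_encoding"] = vals
        for name in measures:
            if name not in per_trial:
                continue
            vals = per_trial[name]
            if average_before_transform:
                z = _fisher(float(np.mean(vals)))
            else:
                z = float(np.mean([_fisher(v) for v in vals]))
            rows.append({"condition": c, "measure": name, "z": z})
    return pd.DataFrame(rows)


def _masked_row_mean(mat: np.ndarray, mask: np.ndarray) -> np.ndarray:
    counts = mask.sum(axis=1)
    if np.any(counts < 1):
        raise ValueError("a trial has no partners for an across-pair average")
    return (mat * mask).sum(axis=1) / counts


def condition_level_similarity(
    pattern_init: np.ndarray, pattern_emo: np.ndarray
) -> float:
    """Fisher z between a condition's initial- and emotional-phase t-patterns.

    Patterns are z-scored across voxels first, so the value reflects
    voxel topography rather than overall activation amplitude.
    """
    if np.shape(pattern_init) != np.shape(pattern_emo):
        raise ValueError("patterns must come from the same ROI (equal length)")
    return similarity_z(normalize_pattern(pattern_init), normalize_pattern(pattern_emo))


@dataclass
class SearchlightMap:
    """Voxelwise aversive-minus-neutral similarity contrast."""

    data: np.ndarray
    mask: np.ndarray
    radius_mm: float
    voxel_size_mm: tuple[float, float, float]


def _sphere_offsets(radius_mm: float, voxel_size_mm) -> np.ndarray:
    vs = np.asarray(voxel_size_mm, float)
    ranges = [np.arange(-int(radius_mm // v), int(radius_mm // v) + 1) for v in vs]
    grid = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, 3)
    dist = np.sqrt(((grid * vs) ** 2).sum(axis=1))
    return grid[dist <= radius_mm + 1e-9]


def searchlight_map(
    volumes_init: np.ndarray,
    volumes_emo: np.ndarray,
    meta_init: pd.DataFrame,
    meta_emo: pd.DataFrame,
    mask: np.ndarray,
    radius_mm: float = 6.0,
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0),
    measure: str = "pair_specific",
) -> SearchlightMap:
    """Whole-volume similarity contrast map by spherical searchlight.

    ``volumes_*`` are 4-D (x, y, z, n_trials) trial t-maps on a shared
    grid; at each in-mask voxel the chosen trial-level measure is
    computed over the sphere's in-mask voxels and the aversive-minus-
    neutral z difference is stored.  Spheres with fewer than 2 usable
    voxels yield NaN with a warning.
    """
    if volumes_init.shape[:3] != volumes_emo.shape[:3] or mask.shape != volumes_init.shape[:3]:
        raise ValueError("volumes and mask must share the spatial grid")
    if radius_mm < min(voxel_size_mm):
        raise ValueError("radius must be at least one voxel size")
    offsets = _sphere_offsets(radius_mm, voxel_size_mm)
    out = np.full(mask.shape, np.nan)
    centers = np.argwhere(mask != 0)
    shape = np.array(mask.shape)
    n_small = 0
    for center in centers:
        vox = center + offsets
        ok = np.all((vox >= 0) & (vox < shape), axis=1)
        vox = vox[ok]
        vox = vox[mask[vox[:, 0], vox[:, 1], vox[:, 2]] != 0]
        if len(vox) < 2:
            n_small += 1
            continue
        pat_i = volumes_init[vox[:, 0], vox[:, 1], vox[:, 2], :].T
        pat_e = volumes_emo[vox[:, 0], vox[:, 1], vox[:, 2], :].T
        tm = trial_measures(
            PatternSet(pat_i, meta_init, phase="initial"),
            PatternSet(pat_e, meta_emo, phase="emotional"),
            measures=(measure,),
        )
        z = tm.set_index("condition")["z"]
        out[tuple(center)] = z.get("aversive", np.nan) - z.get("neutral", np.nan)
    if n_small:
        warnings.warn(f"{n_small} searchlight centers had < 2 usable voxels", stacklevel=2)
    return SearchlightMap(out, mask, radius_mm, tuple(voxel_size_mm))
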