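"""NIfTI and TSV input/output helpers.

Trial pattern sets travel as 4-D NIfTI (trial as the 4th axis) with a
sidecar TSV of trial metadata; searchlight maps and ROI masks as 3-D
NIfTI.  All tabular outputs are tidy TSV.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .similarity import PatternSet, SearchlightMap

__all__ = [
    "write_pattern_set",
    "read_pattern_set",
    "read_mask",
    "write_searchlight_map",
]


def write_pattern_set(ps: PatternSet, path: str | Path,
                      voxel_size_mm: float = 2.0) -> Path:
    """Write patterns as 4-D NIfTI (voxels on the x-axis, trial as t).

    ROI pattern vectors have no intrinsic 3-D geometry, so voxels are
    laid out along a single spatial axis; the trial metadata goes to a
    ``<stem>_trials.tsv`` sidecar.
    """
    path = Path(path)
    data = ps.patterns.T.reshape(ps.n_voxels, 1, 1, ps.n_trials)
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(data.astype(np.float32), affine), path)
    ps.meta.to_csv(path.with_name(path.stem.split(".")[0] + "_trials.tsv"),
                   sep="\t", index=False)
    return path


def read_pattern_set(path: str | Path, roi: str = "roi",
                     phase: str = "") -> PatternSet:
    path = Path(path)
    img = nib.load(path)
    data = np.asarray(img.dataobj)
    patterns = data.reshape(-1, data.shape[-1]).T
    meta = pd.read_csv(path.with_name(path.stem.split(".")[0] + "_trials.tsv"),
                       sep="\t")
    return PatternSet(patterns, meta, roi=roi, phase=phase)


def read_mask(path: str | Path) -> np.ndarray:
    """Load an ROI mask; nonzero voxels are in-ROI."""
    return np.asarray(nib.load(Path(path)).dataobj) != 0


def write_searchlight_map(sl: SearchlightMap, path: str | Path) -> Path:
    path = Path(path)
    affine = np.diag(list(sl.voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(sl.data.astype(np.float32), affine), path)
    return path
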