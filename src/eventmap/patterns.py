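"""From preprocessed 4D series to object x repetition x voxel patterns.

Covers the three steps between a motion-corrected series and the
similarity analysis: voxelwise nuisance regression against the motion
parameters, selection of the analyzed volume of every trial (the third
volume after image onset, i.e. onset index + 2 with presentation locked to
volume starts), and mask intersection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .recipe import PVTRecipe
from .volumes import VolumeSeries

__all__ = ["TrialPatterns", "regress_motion", "select_trial_volumes", "intersect_masks"]

# offset, in volumes, of the analyzed volume relative to stimulus onset;
# with a 2.27 s TR this covers 4540-6810 ms after onset
ANALYZED_VOLUME_OFFSET = 2


@dataclass(frozen=True)
class TrialPatterns:
    """Activity patterns of every analyzed trial.

    ``values`` is object x repetition x voxel; repetitions are ordered by
    block, so no two repetitions of an object share a block by
    construction. ``voxel_coords`` are the 0-based integer grid coordinates
    of the analysis-mask voxels, in raveled (C-order) mask order.
    """

    values: np.ndarray
    object_ids: np.ndarray           # 1-based ids, ascending
    blocks: np.ndarray               # block per repetition column, 1-based
    voxel_coords: np.ndarray         # (n_voxels, 3)

    @property
    def n_objects(self) -> int:
        return self.values.shape[0]

    @property
    def n_repetitions(self) -> int:
        return self.values.shape[1]

    def subset_voxels(self, keep: np.ndarray) -> "TrialPatterns":
        """Restrict to a boolean or index subset of the current voxels."""
        keep = np.asarray(keep)
        return TrialPatterns(self.values[:, :, keep], self.object_ids, self.blocks, self.voxel_coords[keep])


def regress_motion(series: VolumeSeries) -> VolumeSeries:
    """Remove motion-explained variance from every voxel time series.

    Fits, per voxel, an ordinary least-squares model with an intercept and
    the six motion parameters, and returns the residual series. Constant
    (e.g. all-zero) motion columns carry no information beyond the
    intercept and are dropped; genuinely collinear non-constant regressors
    raise an error naming them.
    """
    motion = series.motion.to_numpy(float)
    names = list(series.motion.columns)
    keep = [i for i in range(motion.shape[1]) if np.ptp(motion[:, i]) > 0]
    design = np.column_stack([np.ones(series.n_volumes)] + [motion[:, i] for i in keep])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify the offending columns by greedy rank inspection
        bad = []
        cols = [np.ones(series.n_volumes)]
        for i in keep:
            cand = np.column_stack(cols + [motion[:, i]])
            if np.linalg.matrix_rank(cand) == len(cols):
                bad.append(names[i])
            else:
                cols.append(motion[:, i])
        raise ValueError(f"rank-deficient motion design; redundant regressors: {bad}")

    flat = series.data.reshape(-1, series.n_volumes).T          # volumes x voxels
    beta, *_ = np.linalg.lstsq(design, flat, rcond=None)
    resid = (flat - design @ beta).T.reshape(series.data.shape)
    return VolumeSeries(resid, series.voxel_size, series.mask, series.motion)


def select_trial_volumes(series: VolumeSeries, recipe: PVTRecipe, mask: np.ndarray | None = None) -> TrialPatterns:
    """Extract the analyzed volume of every non-target trial over a mask.

    For a trial with onset volume ``v`` the volume at index ``v + 2`` is
    read (third volume after image onset). Trials of the target object are
    discarded. Rows are sorted by object id, columns by block.
    """
    mask = series.mask if mask is None else np.asarray(mask, dtype=bool)
    if mask.shape != series.data.shape[:3]:
        raise ValueError("mask shape must match the series grid")
    analyzed = recipe.onsets + ANALYZED_VOLUME_OFFSET
    over = analyzed >= series.n_volumes
    if np.any(over):
        raise ValueError(
            f"analyzed volume beyond series end for trials {np.flatnonzero(over) + 1}"
        )
    keep = recipe.objects != recipe.target_object
    objects = recipe.objects[keep]
    blocks = recipe.blocks[keep]
    vols = analyzed[keep]

    flat = series.data.reshape(-1, series.n_volumes)
    vox = np.flatnonzero(mask.ravel())
    trials = flat[np.ix_(vox, vols)].T                         # trials x voxels

    object_ids = np.unique(objects)
    block_ids = np.unique(blocks)
    n_obj, n_rep = object_ids.size, block_ids.size
    values = np.empty((n_obj, n_rep, vox.size))
    for oi, o in enumerate(object_ids):
        rows = np.flatnonzero(objects == o)
        rows = rows[np.argsort(blocks[rows])]
        if not np.array_equal(np.sort(blocks[rows]), block_ids):
            raise ValueError(f"object {o} does not appear exactly once per block")
        values[oi] = trials[rows]

    coords = np.column_stack(np.unravel_index(vox, mask.shape))
    return TrialPatterns(values, object_ids, block_ids, coords)


def intersect_masks(mask_pre: np.ndarray, mask_post: np.ndarray, grey: np.ndarray) -> np.ndarray:
    """Voxelwise AND of the two session masks and the grey-matter mask."""
    masks = [np.asarray(m, dtype=bool) for m in (mask_pre, mask_post, grey)]
    if not (masks[0].shape == masks[1].shape == masks[2].shape):
        raise ValueError("masks must share one grid")
    out = masks[0] & masks[1] & masks[2]
    if not out.any():
        raise ValueError("mask intersection is empty")
    return out
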