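"""Synthetic pre/post 4D volume series with an implantable similarity change.

The generator writes one activity pattern per object into the analyzed
volume of every trial (onset + 2 volumes) and fills the rest of the series
with white voxel noise. No hemodynamic response is modeled: the pipeline
reads exactly the volume the pattern is written to, which keeps the
generator's acceptance surface about the similarity statistics rather than
HRF modeling.

Pattern construction is exact rather than asymptotic: object patterns are
built from an orthonormalized Gaussian basis, so their sample Pearson
correlation matrix equals the requested target matrix to machine
precision. The post-learning target inside the effect region is the
pre-learning structure plus a perturbation whose Spearman correlation with
a supplied distance model is calibrated to ``effect_size``; outside the
effect region the post patterns equal the pre patterns, so any pattern
similarity change there is pure trial noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import DistanceModel, pairs_to_squareform
from .recipe import PVTRecipe

__all__ = ["GridSpec", "EffectSpec", "VolumeSeries", "generate_volumes", "calibrated_perturbation"]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the synthetic acquisition grid."""

    shape: tuple[int, int, int] = (16, 16, 16)
    voxel_size: tuple[float, float, float] = (1.5, 1.5, 1.5)
    mask: np.ndarray | None = None  # analysis mask; defaults to the full grid

    def resolve_mask(self) -> np.ndarray:
        if self.mask is None:
            return np.ones(self.shape, dtype=bool)
        m = np.asarray(self.mask, dtype=bool)
        if m.shape != tuple(self.shape):
            raise ValueError("mask shape must match the grid shape")
        return m


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth effect implanted into the post-learning session.

    ``effect_size`` is the target Spearman correlation (in [-1, 0]) between
    the expected pattern-similarity change of object pairs inside
    ``effect_roi`` and the distance model; 0 implants nothing.
    """

    effect_roi: np.ndarray
    effect_size: float = -0.6
    noise_sd: float = 1.0
    seed: int = 0
    base_correlation: float = 0.0     # off-diagonal pre-learning pattern correlation
    perturbation_sd: float = 0.06     # scale of the implanted correlation change
    signal_sd: float = 1.0            # per-voxel sd of object patterns
    motion_amplitude: float = 0.0     # optional sinusoidal nuisance regressors

    def __post_init__(self):
        if not (-1.0 <= self.effect_size <= 0.0):
            raise ValueError("effect_size must lie in [-1, 0]")


@dataclass
class VolumeSeries:
    """A 4D series with its mask and nuisance table (one scanning session)."""

    data: np.ndarray                  # (x, y, z, volume)
    voxel_size: tuple[float, float, float]
    mask: np.ndarray                  # 3D boolean
    motion: pd.DataFrame              # 6 nuisance regressors x volumes

    def __post_init__(self):
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape must match the spatial shape of the data")
        if len(self.motion) != self.data.shape[3]:
            raise ValueError("motion table must have one row per volume")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


def calibrated_perturbation(
    model: DistanceModel,
    effect_size: float,
    rng: np.random.Generator,
    scale: float = 0.06,
    tol: float = 1e-3,
) -> np.ndarray:
    """Pair-vector perturbation whose Spearman with ``model`` hits ``effect_size``.

    Mixes the negated z-scored model with an independent Gaussian direction
    and bisects the mixing weight until the sample Spearman correlation of
    the mix with the model equals the target within ``tol``. Returned
    entries are scaled to standard deviation ``scale``.
    """
    m = model.pair_vector
    if not np.all(np.isfinite(m)):
        raise ValueError("distance model contains non-finite pair entries")
    if effect_size == 0.0:
        return np.zeros(m.size)
    zm = stats.zscore(m)
    noise = stats.zscore(rng.standard_normal(m.size))

    def mix(w: float) -> np.ndarray:
        return -(w * zm + (1.0 - w) * noise)

    lo, hi = 0.0, 1.0
    for _ in range(60):
        w = 0.5 * (lo + hi)
        rho = stats.spearmanr(mix(w), m).statistic
        if rho < effect_size:
            hi = w
        else:
            lo = w
    d = mix(0.5 * (lo + hi))
    achieved = stats.spearmanr(d, m).statistic
    if abs(achieved - effect_size) > max(tol, 0.02):
        raise RuntimeError(
            f"perturbation calibration failed: achieved Spearman {achieved:.3f} "
            f"vs target {effect_size:.3f}"
        )
    return d / d.std() * scale


def _exact_correlated_patterns(target: np.ndarray, rng: np.random.Generator, n_voxels: int) -> np.ndarray:
    """Rows with sample correlation matrix exactly ``target`` (k x n_voxels)."""
    k = target.shape[0]
    if n_voxels < k + 1:
        raise ValueError(f"need at least {k + 1} voxels to realize a {k}x{k} correlation target")
    try:
        chol = np.linalg.cholesky(target)
    except np.linalg.LinAlgError:
        # eigenvalue clipping onto the PSD cone, then re-unitize the diagonal
        w, v = np.linalg.eigh(target)
        w = np.clip(w, 1e-8, None)
        fixed = (v * w) @ v.T
        d = np.sqrt(np.diag(fixed))
        fixed = fixed / np.outer(d, d)
        chol = np.linalg.cholesky(fixed)
    g = rng.standard_normal((k, n_voxels))
    g -= g.mean(axis=1, keepdims=True)
    q, _ = np.linalg.qr(g.T)           # orthonormal, zero-mean basis vectors
    return (chol @ q.T) * np.sqrt(n_voxels)


def _target_matrices(
    model: DistanceModel, effect: EffectSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    n = model.n_objects
    pre = np.full((n, n), effect.base_correlation)
    np.fill_diagonal(pre, 1.0)
    delta = calibrated_perturbation(model, effect.effect_size, rng, scale=effect.perturbation_sd)
    post = pre + pairs_to_squareform(delta, n, diagonal=0.0)
    np.fill_diagonal(post, 1.0)
    return pre, post


def _sinusoidal_motion(n_volumes: int, amplitude: float) -> pd.DataFrame:
    cols = [f"mc{i}" for i in range(1, 7)]
    if amplitude == 0.0:
        return pd.DataFrame(np.zeros((n_volumes, 6)), columns=cols)
    t = np.arange(n_volumes)
    out = np.column_stack(
        [amplitude * np.sin(2 * np.pi * t / (40.0 + 7.0 * i) + i) for i in range(6)]
    )
    return pd.DataFrame(out, columns=cols)


def generate_volumes(
    recipe: PVTRecipe,
    model: DistanceModel,
    effect: EffectSpec,
    grid: GridSpec | None = None,
) -> tuple[VolumeSeries, VolumeSeries]:
    """Generate a (pre, post) session pair embodying a known similarity change.

    Both sessions share the trial recipe and the object patterns outside the
    effect region; inside the effect region the post session's pattern
    correlation structure is perturbed so that the expected pattern
    similarity change of pairs tracks the distance model at Spearman
    ``effect.effect_size``. Trial-wise voxel noise of sd ``effect.noise_sd``
    is added everywhere.
    """
    grid = grid or GridSpec()
    mask = grid.resolve_mask()
    roi = np.asarray(effect.effect_roi, dtype=bool)
    if roi.shape != mask.shape:
        raise ValueError("effect_roi shape must match the grid")
    if np.any(roi & ~mask):
        raise ValueError("effect_roi must lie within the analysis mask")

    n_model = model.n_objects
    n_objects = recipe.target_object  # includes the discarded target object
    rng = np.random.default_rng(effect.seed)
    pattern_rng, pre_rng, post_rng, target_rng = rng.spawn(4)

    roi_idx = np.flatnonzero(roi.ravel())
    out_idx = np.flatnonzero((mask & ~roi).ravel())

    pre_target, post_target = _target_matrices(model, effect, pattern_rng)
    pre_patterns = np.zeros((n_objects, mask.size))
    post_patterns = np.zeros((n_objects, mask.size))

    if roi_idx.size:
        # shared basis: identical trial-free patterns up to the implanted change
        k = n_model
        g = pattern_rng.standard_normal((k, roi_idx.size))
        g -= g.mean(axis=1, keepdims=True)
        q, _ = np.linalg.qr(g.T)
        basis = q.T * np.sqrt(roi_idx.size)
        pre_patterns[:k, roi_idx] = np.linalg.cholesky(pre_target) @ basis
        post_patterns[:k, roi_idx] = _psd_factor(post_target) @ basis
    if out_idx.size:
        base = _exact_correlated_patterns(
            _equicorrelation(n_model, effect.base_correlation), pattern_rng, out_idx.size
        )
        pre_patterns[:n_model, out_idx] = base
        post_patterns[:n_model, out_idx] = base
    # target object: its trials are discarded downstream; plain noise pattern
    if n_objects > n_model:
        tgt = target_rng.standard_normal((n_objects - n_model, mask.size)) * (mask.ravel())
        pre_patterns[n_model:] = tgt
        post_patterns[n_model:] = tgt

    pre_patterns *= effect.signal_sd
    post_patterns *= effect.signal_sd

    sessions = []
    for patterns, srng in ((pre_patterns, pre_rng), (post_patterns, post_rng)):
        n_vox = mask.size
        data = srng.standard_normal((n_vox, recipe.n_volumes), dtype=np.float32) * np.float32(effect.noise_sd)
        analyzed = recipe.onsets + 2
        data[:, analyzed] += patterns[recipe.objects - 1].T
        series = VolumeSeries(
            data.reshape(*mask.shape, recipe.n_volumes),
            grid.voxel_size,
            mask,
            _sinusoidal_motion(recipe.n_volumes, effect.motion_amplitude),
        )
        sessions.append(series)
    return sessions[0], sessions[1]


def _equicorrelation(k: int, rho: float) -> np.ndarray:
    m = np.full((k, k), rho)
    np.fill_diagonal(m, 1.0)
    return m


def _psd_factor(target: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(target)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(target)
        if w.min() < -0.05:
            raise ValueError(
                "post-learning correlation target is far from positive definite; "
                "reduce the perturbation scale"
            )
        w = np.clip(w, 1e-8, None)
        fixed = (v * w) @ v.T
        d = np.sqrt(np.diag(fixed))
        return np.linalg.cholesky(fixed / np.outer(d, d))
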