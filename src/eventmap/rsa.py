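"""Core representational-similarity computations.

The central quantity is the pattern-similarity change matrix PS': the
post-learning minus pre-learning object-by-object matrix of mean pairwise
pattern correlations. PS' is compared against behavioral or objective
distance structures with Spearman correlation, and each subject's
coefficient is standardized against a shuffle-null distribution obtained
by permuting the pairing between the two matrices.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .design import DistanceModel, combined_model, pair_index, pairs_to_squareform, squareform_to_pairs
from .patterns import TrialPatterns

__all__ = [
    "CrossCorrMatrix",
    "PSChangeMatrix",
    "SubjectZ",
    "crosscorr_matrix",
    "ps_change",
    "combined_model",
    "model_correlation",
    "subject_shuffle_z",
    "residualize",
]


@dataclass(frozen=True)
class CrossCorrMatrix:
    """Mean pairwise pattern correlations between objects for one session.

    Cell (i, j) averages the Pearson correlations between every repetition
    of object i and every repetition of object j from *different* blocks;
    with B blocks that is B^2 - B ordered combinations for distinct objects
    and B(B-1)/2 unordered combinations on the diagonal. ``n_included``
    reports how many correlations entered each mean after excluding any
    degenerate (zero-variance) trial vectors.
    """

    values: np.ndarray
    session: str
    n_included: np.ndarray
    object_ids: np.ndarray


@dataclass(frozen=True)
class PSChangeMatrix:
    """Post-minus-pre pattern similarity change (PS')."""

    values: np.ndarray
    object_ids: np.ndarray

    @property
    def pair_vector(self) -> np.ndarray:
        return squareform_to_pairs(self.values)


@dataclass(frozen=True)
class SubjectZ:
    """First-level shuffle-null statistic for one subject.

    z standardizes the observed matrix-model Spearman coefficient against
    the mean and sd of the surrogate coefficients; ``p_quantile`` is the
    fraction of surrogates at or below the observed value (one-tailed,
    negative direction), reported alongside.
    """

    rho: float
    surrogate_mean: float
    surrogate_sd: float
    z: float
    p_quantile: float
    n_shuffles: int
    seed: int | None


def crosscorr_matrix(patterns: TrialPatterns, session: str = "", fisher: bool = False) -> CrossCorrMatrix:
    """Object-by-object mean pattern correlation with same-block exclusion.

    Every trial's voxel vector is Pearson-correlated with every other
    trial's, except combinations of trials within the same block; the cell
    for an object pair averages the admissible correlations. Diagonal cells
    average the cross-block correlations of an object with itself. Setting
    ``fisher`` averages Fisher-z transformed coefficients instead of raw
    ones (and transforms back).
    """
    n_obj, n_rep, n_vox = patterns.values.shape
    if n_vox < 2:
        raise ValueError("need at least 2 voxels for pattern correlations")
    if n_rep < 2:
        raise ValueError("need at least 2 blocks to exclude within-block pairs")
    flat = patterns.values.reshape(n_obj * n_rep, n_vox)
    sd = flat.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(flat)
    valid = (sd > 0)[:, None] & (sd > 0)[None, :]
    corr4 = corr.reshape(n_obj, n_rep, n_obj, n_rep)
    valid4 = valid.reshape(n_obj, n_rep, n_obj, n_rep)

    cross_block = ~np.eye(n_rep, dtype=bool)                    # different blocks only
    admissible = valid4 & cross_block[None, :, None, :]
    if fisher:
        corr4 = np.arctanh(np.clip(corr4, -0.999999, 0.999999))
    sums = np.where(admissible, np.nan_to_num(corr4), 0.0).sum(axis=(1, 3))
    counts = admissible.sum(axis=(1, 3)).astype(float)
    # diagonal: each unordered cross-block pair was counted twice
    np.fill_diagonal(sums, np.diag(sums) / 2.0)
    np.fill_diagonal(counts, np.diag(counts) / 2.0)
    with np.errstate(invalid="ignore"):
        values = sums / counts
    if fisher:
        values = np.tanh(values)
    return CrossCorrMatrix(values, session, counts.astype(int), patterns.object_ids)


def ps_change(pre: CrossCorrMatrix, post: CrossCorrMatrix) -> PSChangeMatrix:
    """Cell-wise post - pre similarity change."""
    if not np.array_equal(pre.object_ids, post.object_ids):
        raise ValueError("pre and post sessions cover different object sets")
    return PSChangeMatrix(post.values - pre.values, pre.object_ids)


def _pair_vector(x) -> np.ndarray:
    if isinstance(x, PSChangeMatrix) or isinstance(x, DistanceModel):
        return x.pair_vector
    return np.asarray(x, dtype=float)


def model_correlation(ps, model, method: str = "spearman") -> float:
    """Spearman correlation between PS' pairs and model distances.

    Self-similarity (diagonal) cells never enter: both inputs are reduced
    to the canonical off-diagonal pair vectors. Ties get average ranks.
    """
    a, b = _pair_vector(ps), _pair_vector(model)
    if a.shape != b.shape:
        raise ValueError("pair vectors differ in length")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant pair vector; correlation undefined")
    if method == "spearman":
        return float(stats.spearmanr(a, b).statistic)
    if method == "pearson":
        return float(stats.pearsonr(a, b).statistic)
    raise ValueError(f"unknown method {method!r}")


def _rank_z(v: np.ndarray) -> np.ndarray:
    r = stats.rankdata(v)
    return (r - r.mean()) / r.std()


def subject_shuffle_z(
    ps,
    model,
    n_shuffles: int = 10_000,
    seed: int | np.random.Generator | None = 0,
    exhaustive: bool | None = None,
    mode: str = "pair",
) -> SubjectZ:
    """Standardize the observed Spearman coefficient against a shuffle null.

    Surrogates permute the model pair entries against the fixed PS' pair
    vector (``mode='pair'``, the default). ``mode='label'`` instead permutes
    object labels of the model matrix (a Mantel-style null that preserves
    the within-matrix dependence). With ``exhaustive`` (or automatically for
    pair vectors of at most 8 entries) all permutations are enumerated.
    """
    a, b = _pair_vector(ps), _pair_vector(model)
    if n_shuffles < 100:
        raise ValueError("need at least 100 shuffles for a stable null")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant pair vector; shuffle null degenerate")
    ra, rb = _rank_z(a), _rank_z(b)
    n = a.size
    observed = float(ra @ rb / n)

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if exhaustive is None:
        exhaustive = mode == "pair" and n <= 8

    if mode == "pair":
        if exhaustive:
            if n > 8:
                raise ValueError("exhaustive pair enumeration limited to 8 entries")
            perms = np.array(list(itertools.permutations(range(n))))
        else:
            perms = rng.permuted(np.tile(np.arange(n), (n_shuffles, 1)), axis=1)
        surr = perms_to_rhos(rb, ra, perms)
    elif mode == "label":
        mat = pairs_to_squareform(b, _n_from_pairs(n))
        n_obj = mat.shape[0]
        iu = pair_index(n_obj)
        surr = np.empty(n_shuffles)
        for s in range(n_shuffles):
            p = rng.permutation(n_obj)
            surr[s] = _rank_z(mat[np.ix_(p, p)][iu]) @ ra / n
    else:
        raise ValueError(f"unknown shuffle mode {mode!r}")

    mean, sd = float(surr.mean()), float(surr.std())
    if sd == 0:
        raise ValueError("degenerate shuffle null (zero surrogate variance)")
    p_q = float(np.mean(surr <= observed)) if exhaustive else float(
        (np.sum(surr <= observed) + 1) / (surr.size + 1)
    )
    return SubjectZ(
        rho=observed,
        surrogate_mean=mean,
        surrogate_sd=sd,
        z=(observed - mean) / sd,
        p_quantile=p_q,
        n_shuffles=int(surr.size),
        seed=None if isinstance(seed, np.random.Generator) else seed,
    )


def perms_to_rhos(rb: np.ndarray, ra: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """Spearman coefficients of permuted ``rb`` against fixed ``ra``.

    Both inputs are already rank-z-scored; permuting values permutes their
    ranks, so the coefficient is a plain dot product of z-scored ranks.
    """
    return rb[perms] @ ra / ra.size


def _n_from_pairs(n_pairs: int) -> int:
    n = int(round((1 + math.isqrt(1 + 8 * n_pairs)) / 2))
    if n * (n - 1) // 2 != n_pairs:
        raise ValueError(f"{n_pairs} is not a triangular number")
    return n


def residualize(ps_pairs, covariate) -> np.ndarray:
    """Residuals of PS' pairs after removing a covariate distance structure.

    Ordinary least squares with an intercept; the residuals are meant to be
    fed back into :func:`model_correlation` with the other domain's
    distances, yielding the "other-domain removed" model variants.
    """
    y, x = _pair_vector(ps_pairs), _pair_vector(covariate)
    if y.shape != x.shape:
        raise ValueError("pair vectors differ in length")
    if np.ptp(x) == 0:
        raise ValueError("constant covariate cannot be regressed out")
    design = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta
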