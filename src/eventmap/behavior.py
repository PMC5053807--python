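"""Behavioral analyses of distance ratings, free recall, and the map test.

All correlation-type analyses work on z-scored quantities, which makes the
results invariant to any common affine rescaling of raw distances; the
slider scale of the ratings and the arbitrary map units of the true
distances therefore never need calibrating against each other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .behavior_sim import BehavioralDataset
from .design import DistanceModel

__all__ = [
    "CorrelationResult",
    "rating_accuracy",
    "rating_glm",
    "error_bias",
    "recall_order_analysis",
    "map_error",
    "fisher_z",
    "group_t",
]

FISHER_CAP = 0.9999  # |r| at which Fisher z is capped and flagged


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    defined: bool = True
    flag: str = ""


def fisher_z(r: float) -> tuple[float, bool]:
    """Fisher z-transform, capped at |r| = 0.9999 to stay finite.

    Returns the transformed value and whether capping was applied.
    """
    capped = abs(r) >= FISHER_CAP
    return float(np.arctanh(np.clip(r, -FISHER_CAP, FISHER_CAP))), capped


def _domain_ratings(behavior: BehavioralDataset, domain: str) -> pd.DataFrame:
    sub = behavior.ratings[behavior.ratings["domain"] == domain]
    if sub.empty:
        raise ValueError(f"no ratings for domain {domain!r}")
    return sub


def _truth_for_pairs(truth: DistanceModel, sub: pd.DataFrame) -> np.ndarray:
    return truth.values[sub["pair_i"].to_numpy(), sub["pair_j"].to_numpy()]


def rating_accuracy(
    behavior: BehavioralDataset,
    truth: DistanceModel,
    domain: str,
    method: str = "pearson",
) -> CorrelationResult:
    """Goodness of fit between remembered and actual pair distances.

    Pearson correlation (default) of z-scored remembered against z-scored
    actual distances, with a two-sided p-value; Spearman is available as an
    option since the coefficient operates on ranks anyway.
    """
    sub = _domain_ratings(behavior, domain)
    actual = _truth_for_pairs(truth, sub)
    remembered = sub["rating"].to_numpy(float)
    if sub.shape[0] < 3:
        return CorrelationResult(np.nan, np.nan, sub.shape[0], False, "insufficient pairs")
    if np.ptp(actual) == 0 or np.ptp(remembered) == 0:
        return CorrelationResult(np.nan, np.nan, sub.shape[0], False, "constant input")
    if method == "pearson":
        res = stats.pearsonr(stats.zscore(remembered), stats.zscore(actual))
    elif method == "spearman":
        res = stats.spearmanr(remembered, actual)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(float(res.statistic), float(res.pvalue), sub.shape[0])


def rating_glm(
    behavior: BehavioralDataset,
    actual_spatial: DistanceModel,
    actual_temporal: DistanceModel,
    domain: str,
    standardize_criterion: bool = True,
) -> dict[str, float]:
    """Standardized betas of actual spatial and temporal distance on ratings.

    Ordinary least squares of the ratings of one domain on the z-scored
    actual distances of both domains, with an intercept. By default the
    ratings are z-scored too, making the betas fully standardized
    coefficients (and invariant to the slider's arbitrary scale);
    ``standardize_criterion=False`` leaves the criterion on its raw scale.
    Returns ``{"beta_space": ..., "beta_time": ...}``.
    """
    sub = _domain_ratings(behavior, domain)
    xs = stats.zscore(_truth_for_pairs(actual_spatial, sub))
    xt = stats.zscore(_truth_for_pairs(actual_temporal, sub))
    if abs(np.corrcoef(xs, xt)[0, 1]) > 0.99:
        raise ValueError("actual spatial and temporal distances are collinear")
    y = sub["rating"].to_numpy(float)
    if standardize_criterion:
        y = stats.zscore(y)
    design = np.column_stack([np.ones_like(y), xs, xt])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return {"beta_space": float(beta[1]), "beta_time": float(beta[2])}


def error_bias(
    behavior: BehavioralDataset,
    truth: DistanceModel,
    other: DistanceModel,
    domain: str,
    split_by_order: bool = False,
) -> dict[str, CorrelationResult]:
    """Correlation of rating errors with the other domain's distances.

    The error of a pair is z(actual) - z(remembered) within the judged
    domain; a negative correlation with the other domain's distance means
    pairs far apart in the other domain are remembered as closer than they
    are in this one. The per-subject coefficient is Fisher z-transformed
    (capped and flagged at |r| = 1) for group testing. With
    ``split_by_order`` the correlation is additionally computed separately
    for pairs whose first probe was the spatial vs the temporal domain.
    """

    sub = _domain_ratings(behavior, domain)

    def one(rows: pd.DataFrame, label: str) -> CorrelationResult:
        if rows.shape[0] < 3:
            return CorrelationResult(np.nan, np.nan, rows.shape[0], False, f"{label}: insufficient pairs")
        err = stats.zscore(_truth_for_pairs(truth, rows)) - stats.zscore(rows["rating"].to_numpy(float))
        x = _truth_for_pairs(other, rows)
        # z-scores are O(1); differences at rounding level are a constant vector
        if np.ptp(err) < 1e-10 or np.ptp(x) == 0:
            return CorrelationResult(np.nan, np.nan, rows.shape[0], False, f"{label}: constant vector")
        res = stats.pearsonr(err, x)
        z, capped = fisher_z(float(res.statistic))
        return CorrelationResult(
            float(res.statistic), float(res.pvalue), rows.shape[0], True,
            f"{label}: fisher z capped" if capped else "",
        )

    out = {"all": one(sub, "all")}
    if split_by_order:
        for first in ("space", "time"):
            out[f"{first}_first"] = one(sub[sub["tested_first"] == first], f"{first}_first")
    return out


def recall_order_analysis(
    recall_sequence: np.ndarray,
    spatial: DistanceModel,
    temporal: DistanceModel,
    method: str = "pearson",
) -> dict[str, CorrelationResult]:
    """Relate free-recall order to the task's spatial and temporal structure.

    The recall-order distance of two recalled objects is the absolute
    difference of their positions in the recall sequence; only pairs of
    recalled objects enter. The order distances are correlated with each
    domain's task distances.
    """
    seq = np.asarray(recall_sequence, dtype=int)
    if seq.size < 3:
        return {
            "space": CorrelationResult(np.nan, np.nan, 0, False, "fewer than 3 recalled"),
            "time": CorrelationResult(np.nan, np.nan, 0, False, "fewer than 3 recalled"),
        }
    pos = {o: k for k, o in enumerate(seq)}
    ii, jj = np.triu_indices(seq.size, k=1)
    a, b = seq[ii], seq[jj]
    order_dist = np.abs(ii - jj).astype(float)

    out = {}
    for name, model in (("space", spatial), ("time", temporal)):
        task = model.values[a, b]
        if np.ptp(task) == 0 or np.ptp(order_dist) == 0:
            out[name] = CorrelationResult(np.nan, np.nan, a.size, False, "constant vector")
            continue
        if method == "pearson":
            res = stats.pearsonr(order_dist, task)
        else:
            res = stats.spearmanr(order_dist, task)
        out[name] = CorrelationResult(float(res.statistic), float(res.pvalue), a.size)
    return out


def map_error(map_responses: pd.DataFrame, true_coords: np.ndarray, map_side: float) -> float:
    """Mean displacement of map placements as a fraction of the map side."""
    resp = map_responses[["x", "y"]].to_numpy(float)
    truth = np.asarray(true_coords, dtype=float)
    if np.any((resp < 0) | (resp > map_side)):
        import warnings

        warnings.warn("map responses outside the map; scored anyway", stacklevel=2)
    return float(np.mean(np.linalg.norm(resp - truth, axis=1)) / map_side)


def group_t(values: np.ndarray, popmean: float = 0.0) -> tuple[float, float]:
    """One-sample t-test across subjects (two-sided)."""
    res = stats.ttest_1samp(np.asarray(values, dtype=float), popmean)
    return float(res.statistic), float(res.pvalue)
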