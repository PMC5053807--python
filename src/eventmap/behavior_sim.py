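"""Synthetic behavioral responses: distance ratings, free recall, map test.

Ratings emulate a participant whose judgment of one domain is driven
mostly by the true distance in that domain, partly contaminated by the
other domain (cross-domain leakage), plus response noise, squashed onto
the [0, 1] slider. Free recall is an adjacency-biased walk along the route
order; map responses are the true coordinates plus isotropic jitter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .design import DistanceModel, RouteDesign, pair_index, pairs_to_squareform

__all__ = ["BehaviorParams", "BehavioralDataset", "generate_behavior", "ratings_to_distance_model"]

DOMAINS = ("space", "time")


@dataclass(frozen=True)
class BehaviorParams:
    """Generating parameters of the behavioral model.

    ``own_weight`` and ``cross_weight`` are the standardized contributions
    of the judged domain and of the other domain to a rating;
    ``rating_noise_sd`` is the residual standard deviation on the same
    latent scale. The default noise is chosen so that the latent judgment
    has roughly unit variance, making the weights directly comparable to
    standardized regression coefficients recovered from the ratings.
    """

    own_weight: float = 0.6
    cross_weight: float = 0.16
    rating_noise_sd: float = 0.78
    recall_mean: float = 13.0          # mean number of recalled objects
    recall_sd: float = 3.0
    recall_adjacency_bias: float = 1.0  # decay rate of transition preference with route-rank gap
    map_jitter_frac: float = 0.155      # map-response jitter sd as a fraction of map side
    squash: bool = True                 # logistic squash onto the [0,1] slider


@dataclass(frozen=True)
class BehavioralDataset:
    """Responses of one simulated participant.

    ``ratings`` holds one row per pair per domain (240 rows for 16
    objects): pair indices (0-based), domain, the [0, 1] slider rating, and
    which domain was probed first for that pair.
    """

    ratings: pd.DataFrame
    recall_sequence: np.ndarray         # ordered recalled object indices (0-based)
    map_responses: pd.DataFrame         # object, x, y, confidence


def _latent_to_rating(x: np.ndarray, squash: bool) -> np.ndarray:
    if squash:
        return expit(x)
    # affine fallback used in analytic tests; still bounded on typical ranges
    return np.clip(0.5 + 0.25 * x, 0.0, 1.0)


def generate_behavior(
    route: RouteDesign,
    params: BehaviorParams | None = None,
    seed: int | np.random.Generator = 0,
) -> BehavioralDataset:
    """Simulate one participant's memory-test responses for a route."""
    params = params or BehaviorParams()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = route.n_objects
    iu = pair_index(n)
    spatial = stats.zscore(route.spatial_distances().pair_vector)
    temporal = stats.zscore(route.temporal_distances().pair_vector)

    rows = []
    tested_first = rng.permuted(np.repeat(DOMAINS, [iu[0].size - iu[0].size // 2, iu[0].size // 2]))
    for domain, own, other in (("space", spatial, temporal), ("time", temporal, spatial)):
        latent = (
            params.own_weight * own
            + params.cross_weight * other
            + rng.normal(0.0, params.rating_noise_sd, size=own.size)
        )
        rating = _latent_to_rating(latent, params.squash)
        if np.std(rating) < 1e-9:
            raise ValueError(
                "degenerate (constant) ratings; own/cross weights and noise "
                "leave no variance on the slider"
            )
        rows.append(
            pd.DataFrame(
                {
                    "pair_i": iu[0],
                    "pair_j": iu[1],
                    "domain": domain,
                    "rating": rating,
                    "tested_first": tested_first,
                }
            )
        )
    ratings = pd.concat(rows, ignore_index=True)

    # free recall: adjacency-biased walk over route ranks
    n_recall = int(np.clip(round(rng.normal(params.recall_mean, params.recall_sd)), 3, n))
    rank = route.route_position
    remaining = list(range(n))
    current = int(rng.integers(n))
    seq = [current]
    remaining.remove(current)
    while len(seq) < n_recall:
        gaps = np.array([abs(rank[o] - rank[seq[-1]]) for o in remaining], dtype=float)
        w = np.exp(-params.recall_adjacency_bias * gaps)
        w /= w.sum()
        nxt = remaining[rng.choice(len(remaining), p=w)]
        seq.append(nxt)
        remaining.remove(nxt)

    jitter = rng.normal(0.0, params.map_jitter_frac * route.map_side, size=(n, 2))
    # clicks are constrained to the displayed map
    resp = np.clip(route.coords + jitter, 0.0, route.map_side)
    err = np.linalg.norm(resp - route.coords, axis=1)
    conf = 1.0 - np.clip(err / route.map_side, 0.0, 1.0)
    map_responses = pd.DataFrame(
        {"object": np.arange(n), "x": resp[:, 0], "y": resp[:, 1], "confidence": conf}
    )
    return BehavioralDataset(ratings, np.asarray(seq, dtype=int), map_responses)


def ratings_to_distance_model(behavior: BehavioralDataset, domain: str, n_objects: int | None = None) -> DistanceModel:
    """Remembered-distance structure of one domain from the rating table."""
    sub = behavior.ratings[behavior.ratings["domain"] == domain]
    if sub.empty:
        raise ValueError(f"no ratings for domain {domain!r}")
    if n_objects is None:
        n_objects = int(max(sub["pair_i"].max(), sub["pair_j"].max())) + 1
    mat = pairs_to_squareform(np.zeros(sub.shape[0]), n_objects)
    mat[sub["pair_i"], sub["pair_j"]] = sub["rating"].to_numpy()
    mat[sub["pair_j"], sub["pair_i"]] = sub["rating"].to_numpy()
    label = "spatial" if domain == "space" else "temporal"
    return DistanceModel(mat, label)
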