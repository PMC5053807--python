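"""Route designs and pairwise distance structures.

A route design places objects at 2D map positions and threads them onto a
one-way route. Spatial distance between two objects is the Euclidean
distance between their map positions; temporal distance is the summed
traversal time of the route segments separating them. Teleporter segments
break the otherwise tight coupling between the two: they bridge a large
spatial span in (almost) no time, which is what makes spatial and temporal
pair distances statistically independent across the design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RouteConfig",
    "RouteDesign",
    "DistanceModel",
    "RouteConstraintError",
    "generate_route",
    "pair_index",
    "squareform_to_pairs",
    "pairs_to_squareform",
]


class RouteConstraintError(RuntimeError):
    """Raised when no route satisfying the decorrelation constraint is found."""


def pair_index(n_objects: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical pair order: row-major upper triangle (i < j)."""
    return np.triu_indices(n_objects, k=1)


def squareform_to_pairs(matrix: np.ndarray) -> np.ndarray:
    """Extract the canonical off-diagonal pair vector from a symmetric matrix."""
    matrix = np.asarray(matrix)
    iu = pair_index(matrix.shape[0])
    return matrix[iu]


def pairs_to_squareform(pairs: np.ndarray, n_objects: int, diagonal: float = np.nan) -> np.ndarray:
    """Inverse of :func:`squareform_to_pairs`; the diagonal is left undefined."""
    out = np.full((n_objects, n_objects), diagonal, dtype=float)
    iu = pair_index(n_objects)
    out[iu] = pairs
    out[iu[1], iu[0]] = pairs
    return out


@dataclass(frozen=True)
class DistanceModel:
    """Symmetric object-by-object distance structure.

    The diagonal is undefined (self-distances never enter any model fit) and
    is stored as NaN. ``pair_vector`` holds the 120 unique off-diagonal
    entries (for 16 objects) in the canonical row-major upper-triangle order.
    """

    values: np.ndarray
    domain: str = "spatial"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float).copy()
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        np.fill_diagonal(v, np.nan)
        off = squareform_to_pairs(v)
        if not np.allclose(v[pair_index(v.shape[0])], v.T[pair_index(v.shape[0])], equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if np.any(off < 0):
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "values", v)

    @property
    def n_objects(self) -> int:
        return self.values.shape[0]

    @property
    def pair_vector(self) -> np.ndarray:
        return squareform_to_pairs(self.values)

    def normalized(self) -> "DistanceModel":
        """Min-max rescale of the pair entries onto [0, 1]."""
        p = self.pair_vector
        lo, hi = p.min(), p.max()
        if hi == lo:
            raise ValueError("cannot normalize a constant distance matrix")
        return DistanceModel(pairs_to_squareform((p - lo) / (hi - lo), self.n_objects), self.domain)


@dataclass(frozen=True)
class RouteConfig:
    """Parameters of the random route generator.

    All distances are in arbitrary map units; only ranks and z-scores of the
    resulting pair distances matter downstream, so no real-world calibration
    is attempted.
    """

    n_objects: int = 16
    n_teleporters: int = 3
    map_side: float = 100.0
    walking_speed: float = 2.0          # map units per second
    teleporter_duration: float = 1.0    # seconds; "instantaneous" transport
    min_teleporter_span: float = 40.0   # minimum spatial span of a teleporter segment
    decorrelation_threshold: float = 0.1
    max_retries: int = 500
    duration_jitter_sd: float = 0.0     # per-repetition traversal-time jitter (s)
    n_repetitions: int = 14             # route traversals used when jitter > 0
    coords: np.ndarray | None = None    # fixed layout (disables resampling)
    order: np.ndarray | None = None     # fixed route order


@dataclass(frozen=True)
class RouteDesign:
    """A realized route: object layout, ordering, and segment timings."""

    coords: np.ndarray                  # (n_objects, 2) map positions
    order: np.ndarray                   # route sequence of object indices
    segment_durations: np.ndarray       # (n_objects - 1,) seconds per segment
    teleporter_after: frozenset[int]    # route positions followed by a teleporter
    map_side: float

    @property
    def n_objects(self) -> int:
        return self.coords.shape[0]

    @property
    def route_position(self) -> np.ndarray:
        """Position of each object along the route (inverse of ``order``)."""
        pos = np.empty(self.n_objects, dtype=int)
        pos[self.order] = np.arange(self.n_objects)
        return pos

    def spatial_distances(self) -> DistanceModel:
        """Pairwise Euclidean distances between object map positions."""
        diff = self.coords[:, None, :] - self.coords[None, :, :]
        return DistanceModel(np.linalg.norm(diff, axis=-1), "objective_spatial")

    def temporal_distances(self) -> DistanceModel:
        """Pairwise along-route traversal times.

        The temporal distance of a pair is the sum of segment durations
        between their route positions on the one-way route.
        """
        cum = np.concatenate([[0.0], np.cumsum(self.segment_durations)])
        t = cum[self.route_position]
        return DistanceModel(np.abs(t[:, None] - t[None, :]), "objective_temporal")

    def factorial_cells(self) -> np.ndarray:
        """2x2 high/low cell label per pair, by median split within each domain.

        Returns an integer vector over the canonical pairs with labels
        0 = low space/low time, 1 = low/high, 2 = high/low, 3 = high/high.
        """
        s = self.spatial_distances().pair_vector
        t = self.temporal_distances().pair_vector
        hs = (s > np.median(s)).astype(int)
        ht = (t > np.median(t)).astype(int)
        return 2 * hs + ht


def _candidate(config: RouteConfig, rng: np.random.Generator) -> RouteDesign:
    n = config.n_objects
    coords = config.coords
    if coords is None:
        coords = rng.uniform(0.0, config.map_side, size=(n, 2))
    else:
        coords = np.asarray(coords, dtype=float)
    order = config.order
    if order is None:
        order = rng.permutation(n)
    else:
        order = np.asarray(order, dtype=int)

    seg_vec = coords[order[1:]] - coords[order[:-1]]
    seg_len = np.linalg.norm(seg_vec, axis=1)
    durations = seg_len / config.walking_speed
    if config.duration_jitter_sd > 0:
        # per-repetition traversal jitter, aggregated by the median as a
        # navigator's walking time would be
        reps = durations[None, :] + rng.normal(
            0.0, config.duration_jitter_sd, size=(config.n_repetitions, durations.size)
        )
        durations = np.median(np.clip(reps, 0.05, None), axis=0)

    tele: frozenset[int] = frozenset()
    if config.n_teleporters > 0:
        eligible = np.flatnonzero(seg_len >= config.min_teleporter_span)
        if eligible.size < config.n_teleporters:
            # fall back to the longest segments available
            eligible = np.argsort(seg_len)[-config.n_teleporters :]
        chosen = eligible[np.argsort(seg_len[eligible])[-config.n_teleporters :]]
        durations = durations.copy()
        durations[chosen] = config.teleporter_duration
        tele = frozenset(int(c) for c in chosen)

    return RouteDesign(coords, order, durations, tele, config.map_side)


def generate_route(config: RouteConfig | None = None, seed: int | np.random.Generator = 0) -> RouteDesign:
    """Draw route designs until spatial and temporal distances decorrelate.

    Candidate layouts are sampled and rejected until the Pearson correlation
    between z-scored spatial and temporal pair distances satisfies
    ``|r| < decorrelation_threshold`` and every cell of the 2x2 high/low
    factorial is populated.

    Raises
    ------
    RouteConstraintError
        If no candidate satisfies the constraint within ``max_retries``
        attempts (e.g. a fixed collinear layout where time is proportional
        to distance).
    """
    config = config or RouteConfig()
    if config.n_objects < 4:
        raise ValueError("need at least 4 objects for a pairwise design")
    if not (0 < config.decorrelation_threshold <= 1):
        raise ValueError("decorrelation threshold must be in (0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    fixed = config.coords is not None and config.order is not None
    last_r = np.nan
    for _ in range(config.max_retries):
        design = _candidate(config, rng)
        s = stats.zscore(design.spatial_distances().pair_vector)
        t = stats.zscore(design.temporal_distances().pair_vector)
        last_r = float(np.corrcoef(s, t)[0, 1])
        if abs(last_r) < config.decorrelation_threshold:
            cells = design.factorial_cells()
            if np.unique(cells).size == 4:
                return design
        if fixed and config.duration_jitter_sd == 0:
            break  # deterministic candidate; retrying cannot help
    raise RouteConstraintError(
        f"no route with |r| < {config.decorrelation_threshold} between spatial and "
        f"temporal pair distances found in {config.max_retries} attempts "
        f"(last |r| = {abs(last_r):.3f}); the configuration may couple the two "
        "domains structurally (e.g. no teleporters on a constant-speed route)"
    )


def combined_model(spatial: DistanceModel, temporal: DistanceModel) -> DistanceModel:
    """Cell-wise product of two distance structures on the [0, 1] rating scale.

    The lowest values of the product mark pairs that are close in *both*
    dimensions. Inputs not already on [0, 1] are min-max normalized first.
    """
    a, b = spatial.pair_vector, temporal.pair_vector
    if a.shape != b.shape:
        raise ValueError("distance structures must cover the same pairs")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("combined model requires non-negative entries")
    if a.max() > 1:
        a = spatial.normalized().pair_vector
    if b.max() > 1:
        b = temporal.normalized().pair_vector
    return DistanceModel(pairs_to_squareform(a * b, spatial.n_objects), "combined")


def design_manifest(design: RouteDesign) -> dict:
    """JSON-serializable description of a route design."""
    return {
        "n_objects": design.n_objects,
        "map_side": design.map_side,
        "coords": design.coords.tolist(),
        "order": design.order.tolist(),
        "segment_durations": design.segment_durations.tolist(),
        "teleporter_after": sorted(design.teleporter_after),
    }


def design_from_manifest(d: dict) -> RouteDesign:
    return RouteDesign(
        np.asarray(d["coords"], dtype=float),
        np.asarray(d["order"], dtype=int),
        np.asarray(d["segment_durations"], dtype=float),
        frozenset(d["teleporter_after"]),
        float(d["map_side"]),
    )
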