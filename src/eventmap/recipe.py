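"""Picture-viewing-task (PVT) trial recipes.

A recipe fixes, for one participant, which object is shown in which trial
and the inter-trial interval of every trial. The same recipe is reused
verbatim for the pre- and post-learning scanning sessions so that any
change in pattern similarity between them cannot stem from timing or
ordering differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["PVTRecipe", "RecipeError", "generate_pvt_recipe"]

TR_SECONDS = 2.27  # EPI repetition time


class RecipeError(RuntimeError):
    pass


@dataclass(frozen=True)
class PVTRecipe:
    """Ordered trial list for one scanning session.

    ``objects`` are 1-based ids; the highest id is the target object whose
    trials are discarded from all similarity analyses. Onsets are 0-based
    volume indices; stimulus presentation is locked to the start of a
    volume. ``itis`` give, in TRs, the interval from one trial's onset to
    the next trial's onset.
    """

    objects: np.ndarray        # (n_trials,) object id per trial, 1-based
    blocks: np.ndarray         # (n_trials,) block index per trial, 1-based
    onsets: np.ndarray         # (n_trials,) onset volume index, 0-based
    itis: np.ndarray           # (n_trials,) inter-trial interval in TRs
    tr: float = TR_SECONDS
    target_object: int = 17

    @property
    def n_trials(self) -> int:
        return self.objects.size

    @property
    def n_blocks(self) -> int:
        return int(self.blocks.max())

    @property
    def n_volumes(self) -> int:
        """Number of volumes a session must contain to cover every trial."""
        return int(self.onsets.max()) + 4

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(1, self.n_trials + 1),
                "object": self.objects,
                "block": self.blocks,
                "onset_volume": self.onsets,
                "iti_tr": self.itis,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, tr: float = TR_SECONDS, target_object: int | None = None) -> "PVTRecipe":
        target = int(frame["object"].max()) if target_object is None else target_object
        return cls(
            frame["object"].to_numpy(int),
            frame["block"].to_numpy(int),
            frame["onset_volume"].to_numpy(int),
            frame["iti_tr"].to_numpy(int),
            tr=tr,
            target_object=target,
        )


def position_anova_p(objects: np.ndarray) -> float:
    """One-way F-test of within-block trial positions across objects.

    A significant result means at least one object lands consistently early
    or late within blocks; such recipes are discarded. Positions are taken
    within blocks (trial index modulo block length) because the block
    offsets common to all objects carry no ordering information.
    """
    n_objects = np.unique(objects).size
    positions = np.arange(objects.size) % n_objects
    groups = [positions[objects == o] for o in np.unique(objects)]
    return float(stats.f_oneway(*groups).pvalue)


def generate_pvt_recipe(
    n_objects: int = 17,
    n_blocks: int = 12,
    seed: int | np.random.Generator = 0,
    start_volume: int = 3,
    block_gap_volumes: int = 13,
    alpha: float = 0.05,
    max_retries: int = 1000,
    tr: float = TR_SECONDS,
) -> PVTRecipe:
    """Generate a semi-random trial recipe with order-balance rejection.

    Each object appears exactly once per block (the block order is an
    independent shuffle per block). Inter-trial intervals of 2 and 3 TRs are
    assigned to exactly half of the trials each. Candidate recipes whose
    one-way ANOVA of trial positions across objects is significant at
    ``alpha`` are discarded and regenerated, so no object is systematically
    early or late. ``block_gap_volumes`` inserts a rest gap between blocks
    (about 30 s at the default TR).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_trials = n_objects * n_blocks
    if n_trials % 2:
        raise ValueError("trial count must be even to balance 2/3-TR intervals")

    for _ in range(max_retries):
        objects = np.concatenate([rng.permutation(n_objects) + 1 for _ in range(n_blocks)])
        if n_objects > 1 and position_anova_p(objects) <= alpha:
            continue
        itis = rng.permutation(np.repeat([2, 3], n_trials // 2))
        blocks = np.repeat(np.arange(1, n_blocks + 1), n_objects)
        onsets = np.empty(n_trials, dtype=int)
        cur = start_volume
        for k in range(n_trials):
            onsets[k] = cur
            cur += int(itis[k])
            if k + 1 < n_trials and blocks[k + 1] != blocks[k]:
                cur += block_gap_volumes
        return PVTRecipe(objects, blocks, onsets, itis, tr=tr, target_object=n_objects)

    raise RecipeError(
        f"no order-balanced recipe found in {max_retries} attempts "
        f"(ANOVA rejection at alpha={alpha})"
    )
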