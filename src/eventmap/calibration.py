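"""Cohort-level calibration experiments: null error rates and power.

These experiments are the acceptance surface of the synthetic generator:
on zero-effect cohorts the first-level shuffle z must be standard-normal
calibrated and the second-level sign-flip test must reject at its nominal
rate; on implanted-effect cohorts the effect region must light up and a
control region must not. They run the full pipeline — volume generation,
motion regression, trial extraction, cross-correlation, model fit,
shuffle null, sign-flip test — at a reduced problem size (8^3 voxel grid,
1000 shuffles and flips) chosen so a several-hundred-cohort experiment
completes in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .group import roi_pipeline
from .pipeline import simulate_cohort

__all__ = ["CalibrationResult", "PowerResult", "null_calibration_run", "power_run"]

CAL_GRID = (8, 8, 8)


@dataclass(frozen=True)
class CalibrationResult:
    """Null-cohort calibration summary."""

    n_cohorts: int
    n_subjects: int
    rejection_rate: float       # fraction of cohorts with group p < alpha
    alpha: float
    subject_z_mean: float       # pooled over all subjects of all cohorts
    subject_z_sd: float


@dataclass(frozen=True)
class PowerResult:
    """Implanted-effect recovery summary."""

    n_cohorts: int
    n_subjects: int
    power: dict                  # model name -> fraction of cohorts with p < alpha
    control_rate: dict           # model name -> same for the control region
    alpha: float


def null_calibration_run(
    n_cohorts: int = 200,
    n_subjects: int = 26,
    seed: int = 0,
    alpha: float = 0.05,
    n_shuffles: int = 1000,
    n_flips: int = 1000,
    grid_shape: tuple[int, int, int] = CAL_GRID,
) -> CalibrationResult:
    """Type-I error and first-level z calibration on zero-effect cohorts.

    Each cohort is fully simulated with ``effect_size=0`` and analysed for
    the effect region with the remembered-spatial model; a rejection is a
    one-tailed group p below ``alpha``.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    zs = []
    for _ in range(n_cohorts):
        cseed = int(rng.integers(2**31 - 1))
        _, subjects, rois = simulate_cohort(
            n_subjects=n_subjects, seed=cseed, effect_size=0.0, grid_shape=grid_shape
        )
        table = roi_pipeline(
            subjects,
            {"effect": rois["effect"]},
            ("spatial",),
            n_shuffles=n_shuffles,
            n_flips=n_flips,
            seed=int(rng.integers(2**31 - 1)),
        )
        p = float(table["p"].iloc[0])
        zs.append(table.attrs["subject_zs"][("effect", "spatial")])
        if p < alpha:
            rejections += 1
    pooled = np.concatenate(zs)
    return CalibrationResult(
        n_cohorts=n_cohorts,
        n_subjects=n_subjects,
        rejection_rate=rejections / n_cohorts,
        alpha=alpha,
        subject_z_mean=float(pooled.mean()),
        subject_z_sd=float(pooled.std()),
    )


def power_run(
    n_cohorts: int = 100,
    n_subjects: int = 26,
    seed: int = 0,
    effect_size: float = -0.6,
    noise_sd: float = 0.3,
    alpha: float = 0.05,
    n_shuffles: int = 1000,
    n_flips: int = 1000,
    grid_shape: tuple[int, int, int] = CAL_GRID,
    models: tuple[str, ...] = ("spatial", "temporal", "combined"),
) -> PowerResult:
    """Recovery of an implanted similarity-change effect across cohorts.

    The implant tracks each subject's remembered combined distance
    structure at Spearman ``effect_size`` inside the effect region under
    low trial noise; the mirrored control region receives no implant.
    """
    rng = np.random.default_rng(seed)
    hits = {m: 0 for m in models}
    false_hits = {m: 0 for m in models}
    for _ in range(n_cohorts):
        cseed = int(rng.integers(2**31 - 1))
        _, subjects, rois = simulate_cohort(
            n_subjects=n_subjects,
            seed=cseed,
            effect_size=effect_size,
            noise_sd=noise_sd,
            grid_shape=grid_shape,
        )
        table = roi_pipeline(
            subjects,
            {"effect": rois["effect"], "control": rois["control"]},
            models,
            n_shuffles=n_shuffles,
            n_flips=n_flips,
            seed=int(rng.integers(2**31 - 1)),
        )
        for m in models:
            p_eff = float(table.loc[(table.roi == "effect") & (table.model == m), "p"].iloc[0])
            p_ctl = float(table.loc[(table.roi == "control") & (table.model == m), "p"].iloc[0])
            hits[m] += p_eff < alpha
            false_hits[m] += p_ctl < alpha
    return PowerResult(
        n_cohorts=n_cohorts,
        n_subjects=n_subjects,
        power={m: hits[m] / n_cohorts for m in models},
        control_rate={m: false_hits[m] / n_cohorts for m in models},
        alpha=alpha,
    )
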