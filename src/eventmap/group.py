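"""Second-level nonparametric inference and ROI pipeline orchestration.

Subject-level shuffle-null z statistics are tested across participants
with a sign-flip test: under the null hypothesis of no consistent effect
the sign of each subject's statistic is exchangeable, so the observed mean
is compared against means of randomly sign-flipped samples. Families of
ROI-by-model tests are corrected with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .design import DistanceModel, combined_model
from .patterns import regress_motion, select_trial_volumes
from .rsa import crosscorr_matrix, ps_change, residualize, subject_shuffle_z

__all__ = [
    "GroupResult",
    "signflip_group_test",
    "fdr_adjust",
    "objective_2x2_anova",
    "subject_models",
    "subject_ps_change",
    "roi_pipeline",
    "DEFAULT_MODELS",
]

# the five model variants of the remembered-distance ROI analysis
DEFAULT_MODELS = (
    "spatial",
    "temporal",
    "combined",
    "temporal_without_spatial",
    "spatial_without_temporal",
)

EXHAUSTIVE_FLIP_LIMIT = 2**20


@dataclass(frozen=True)
class GroupResult:
    """Outcome of the second-level sign-flip test for one ROI x model cell."""

    mean_z: float
    group_z: float
    p: float
    n_flips: int
    n_subjects: int
    tail: str = "negative"
    p_fdr: float | None = None
    seed: int | None = None


def signflip_group_test(
    subject_zs: np.ndarray,
    n_flips: int = 10_000,
    seed: int | np.random.Generator | None = 0,
    tail: str = "negative",
    exhaustive: bool | None = None,
) -> GroupResult:
    """Sign-flip test of the mean subject statistic against zero.

    Surrogate means are built by randomly negating the per-subject values
    and averaging. The one-tailed p is the fraction of surrogate means at
    or beyond the observed mean in the tested direction (negative by
    default). When ``2^n`` flip assignments are enumerable
    (``2^n <= 2^20``), the exact distribution is used; otherwise a
    Monte-Carlo sample of ``n_flips`` assignments with the add-one p-value
    correction.
    """
    v = np.asarray(subject_zs, dtype=float)
    n = v.size
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if np.all(v == 0):
        raise ValueError("all-zero subject statistics; sign-flip null degenerate")
    if tail not in ("negative", "positive"):
        raise ValueError("tail must be 'negative' or 'positive'")
    observed = float(v.mean())

    if exhaustive is None:
        exhaustive = 2**n <= EXHAUSTIVE_FLIP_LIMIT
    if exhaustive:
        codes = np.arange(2**n, dtype=np.int64)
        signs = 1 - 2 * ((codes[:, None] >> np.arange(n)) & 1)   # (2^n, n) of +-1
        surr = signs @ v / n
        if tail == "negative":
            p = float(np.mean(surr <= observed))
        else:
            p = float(np.mean(surr >= observed))
        n_used = surr.size
    else:
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        signs = rng.integers(0, 2, size=(n_flips, n)) * 2 - 1
        surr = signs @ v / n
        if tail == "negative":
            p = float((np.sum(surr <= observed) + 1) / (n_flips + 1))
        else:
            p = float((np.sum(surr >= observed) + 1) / (n_flips + 1))
        n_used = n_flips

    sd = float(surr.std())
    group_z = (observed - float(surr.mean())) / sd if sd > 0 else np.nan
    return GroupResult(
        mean_z=observed,
        group_z=float(group_z),
        p=p,
        n_flips=int(n_used),
        n_subjects=n,
        tail=tail,
        seed=None if isinstance(seed, np.random.Generator) else seed,
    )


def fdr_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def objective_2x2_anova(cell_means: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """2x2 within-subject ANOVA on per-subject PS' cell means.

    ``cell_means`` holds one row per subject and the four factorial cells
    in the column order (low space/low time, low/high, high/low,
    high/high). For a 2x2 within-subject design every effect has one
    degree of freedom, so each F statistic is exactly the square of the
    paired t on the corresponding contrast: space = (HS - LS), time =
    (HT - LT), interaction = the difference of differences.
    """
    m = cell_means.to_numpy(float) if isinstance(cell_means, pd.DataFrame) else np.asarray(cell_means, float)
    if m.ndim != 2 or m.shape[1] != 4:
        raise ValueError("cell-mean table must be subjects x 4 (LL, LH, HL, HH)")
    if np.any(~np.isfinite(m)):
        raise ValueError("missing factorial cell")
    n = m.shape[0]
    ll, lh, hl, hh = m.T
    contrasts = {
        "space": (hl + hh - ll - lh) / 2.0,
        "time": (lh + hh - ll - hl) / 2.0,
        "interaction": (hh - hl) - (lh - ll),
    }
    rows = []
    for name, c in contrasts.items():
        sd = c.std(ddof=1)
        if sd == 0:
            t = 0.0 if c.mean() == 0 else np.inf
        else:
            t = c.mean() / (sd / np.sqrt(n))
        f = t**2
        p = float(stats.f.sf(f, 1, n - 1)) if np.isfinite(f) else 0.0
        rows.append({"effect": name, "F": float(f), "df1": 1, "df2": n - 1, "p": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ROI pipeline


def subject_ps_change(pre, post, recipe, roi_mask: np.ndarray, motion_regressed: bool = False):
    """PS' matrix of one subject for one ROI, from the raw session pair."""
    if not motion_regressed:
        pre, post = regress_motion(pre), regress_motion(post)
    pat_pre = select_trial_volumes(pre, recipe, roi_mask)
    pat_post = select_trial_volumes(post, recipe, roi_mask)
    cc_pre = crosscorr_matrix(pat_pre, "pre")
    cc_post = crosscorr_matrix(pat_post, "post")
    return ps_change(cc_pre, cc_post)


def subject_models(spatial: DistanceModel, temporal: DistanceModel) -> dict[str, DistanceModel]:
    """The five distance-model variants derived from one subject's structures."""
    return {
        "spatial": spatial,
        "temporal": temporal,
        "combined": combined_model(spatial.normalized(), temporal.normalized()),
        "temporal_without_spatial": temporal,   # residualization happens at fit time
        "spatial_without_temporal": spatial,
    }


def _fit_one(ps, models: dict[str, DistanceModel], name: str, n_shuffles: int, rng: np.random.Generator):
    """Model fit for one variant, residualizing PS' where the variant asks."""
    ps_pairs = ps.pair_vector
    if name == "temporal_without_spatial":
        ps_pairs = residualize(ps_pairs, models["spatial"])
        target = models["temporal"]
    elif name == "spatial_without_temporal":
        ps_pairs = residualize(ps_pairs, models["temporal"])
        target = models["spatial"]
    else:
        target = models[name]
    return subject_shuffle_z(ps_pairs, target, n_shuffles=n_shuffles, seed=rng, exhaustive=False)


def roi_pipeline(
    subjects: list[dict],
    roi_masks: dict[str, np.ndarray],
    model_names: tuple[str, ...] = DEFAULT_MODELS,
    n_shuffles: int = 10_000,
    n_flips: int = 10_000,
    seed: int = 0,
    tail: str = "negative",
) -> pd.DataFrame:
    """Full first- plus second-level ROI analysis with FDR over the family.

    Each subject dict provides ``pre``/``post`` (VolumeSeries), ``recipe``,
    and per-model distance structures under ``models`` (see
    :func:`subject_models`). The FDR family is every ROI x model cell.
    Returns a table with one row per cell: mean z, group z, raw one-tailed
    p and the FDR-adjusted p.
    """
    rng = np.random.default_rng(seed)
    rows = []
    subject_zs: dict[tuple[str, str], np.ndarray] = {}
    for roi_name, roi_mask in roi_masks.items():
        ps_list = [
            subject_ps_change(s["pre"], s["post"], s["recipe"], roi_mask,
                              motion_regressed=s.get("motion_regressed", False))
            for s in subjects
        ]
        for model_name in model_names:
            zs = np.array(
                [
                    _fit_one(ps, s["models"], model_name, n_shuffles, rng).z
                    for ps, s in zip(ps_list, subjects)
                ]
            )
            subject_zs[(roi_name, model_name)] = zs
            res = signflip_group_test(zs, n_flips=n_flips, seed=rng, tail=tail, exhaustive=False)
            rows.append(
                {
                    "roi": roi_name,
                    "model": model_name,
                    "mean_z": res.mean_z,
                    "group_z": res.group_z,
                    "p": res.p,
                    "n_subjects": res.n_subjects,
                }
            )
    table = pd.DataFrame(rows)
    table["p_fdr"] = fdr_adjust(table["p"].to_numpy())
    table.attrs["family_size"] = len(table)
    table.attrs["subject_zs"] = subject_zs
    return table
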