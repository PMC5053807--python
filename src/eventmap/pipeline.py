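"""End-to-end orchestration: simulate a cohort, analyse it, write a report.

The simulated study mirrors the design the analysis expects: one route
design shared by the cohort, one trial recipe per participant reused for
both scanning sessions, behavioral responses derived from the route, and
pre/post volume series with a similarity-change effect implanted (or not)
in a designated region. The implanted change tracks each participant's
*remembered* combined (spatial x temporal) distance structure, so all
remembered-distance model variants carry signal in the effect region.
"""

from __future__ import annotations

import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as emio
from .behavior import (
    error_bias,
    fisher_z,
    group_t,
    map_error,
    rating_accuracy,
    rating_glm,
    recall_order_analysis,
)
from .behavior_sim import BehaviorParams, BehavioralDataset, generate_behavior, ratings_to_distance_model
from .config import RunConfig
from .design import RouteConfig, RouteDesign, design_from_manifest, design_manifest, generate_route
from .group import objective_2x2_anova, roi_pipeline, subject_models, subject_ps_change
from .recipe import generate_pvt_recipe
from .searchlight import SearchlightSpec, group_searchlight, searchlight_map
from .patterns import regress_motion, select_trial_volumes
from .volumes import EffectSpec, GridSpec, generate_volumes

__all__ = [
    "default_rois",
    "simulate_subject",
    "simulate_cohort",
    "run_simulate",
    "load_dataset",
    "run_analysis",
]


def default_rois(shape: tuple[int, int, int]) -> dict[str, np.ndarray]:
    """Built-in effect and control boxes for a synthetic grid.

    The effect region occupies a corner cube covering just under half of
    each axis; the control region is the mirrored opposite corner. Both
    comfortably exceed the number of objects, which the exact pattern
    construction requires.
    """
    shape = tuple(shape)
    half = [max(2, s // 2 - s // 8) for s in shape]
    effect = np.zeros(shape, dtype=bool)
    control = np.zeros(shape, dtype=bool)
    effect[: half[0], : half[1], : half[2]] = True
    control[-half[0] :, -half[1] :, -half[2] :] = True
    return {"effect": effect, "control": control}


def simulate_subject(
    route: RouteDesign,
    grid: GridSpec,
    effect_roi: np.ndarray,
    effect_size: float,
    noise_sd: float,
    recipe_seed: int | np.random.Generator,
    behavior_seed: int | np.random.Generator,
    volume_seed: int,
    behavior_params: BehaviorParams | None = None,
) -> dict:
    """One participant: recipe, behavior, models, and the pre/post sessions."""
    recipe = generate_pvt_recipe(seed=recipe_seed)
    behavior = generate_behavior(route, behavior_params, seed=behavior_seed)
    spatial = ratings_to_distance_model(behavior, "space", route.n_objects)
    temporal = ratings_to_distance_model(behavior, "time", route.n_objects)
    models = subject_models(spatial, temporal)
    implant = models["combined"]
    effect = EffectSpec(
        effect_roi=effect_roi, effect_size=effect_size, noise_sd=noise_sd, seed=volume_seed
    )
    pre, post = generate_volumes(recipe, implant, effect, grid)
    return {
        "recipe": recipe,
        "behavior": behavior,
        "models": models,
        "pre": pre,
        "post": post,
    }


def simulate_cohort(
    n_subjects: int = 26,
    seed: int = 0,
    effect_size: float = -0.6,
    noise_sd: float = 1.0,
    grid_shape: tuple[int, int, int] = (16, 16, 16),
    voxel_size: tuple[float, float, float] = (1.5, 1.5, 1.5),
    behavior_params: BehaviorParams | None = None,
) -> tuple[RouteDesign, list[dict], dict[str, np.ndarray]]:
    """Simulate a full cohort sharing one route design.

    Returns the route, the per-subject data dictionaries consumed by
    :func:`eventmap.group.roi_pipeline`, and the named ROI masks.
    """
    rng = np.random.default_rng(seed)
    route = generate_route(RouteConfig(), seed=rng)
    rois = default_rois(grid_shape)
    grid = GridSpec(shape=tuple(grid_shape), voxel_size=tuple(voxel_size))
    subjects = []
    for _ in range(n_subjects):
        vol_seed = int(rng.integers(2**31 - 1))
        subjects.append(
            simulate_subject(
                route,
                grid,
                rois["effect"],
                effect_size,
                noise_sd,
                recipe_seed=rng.spawn(1)[0],
                behavior_seed=rng.spawn(1)[0],
                volume_seed=vol_seed,
                behavior_params=behavior_params,
            )
        )
    return route, subjects, rois


# ---------------------------------------------------------------------------
# disk-backed pipeline


def run_simulate(config: RunConfig, out_dir: str | Path | None = None) -> Path:
    """Generate and write a full synthetic dataset directory."""
    config.validate()
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    route = generate_route(RouteConfig(), seed=config.seeds["design"])
    rois = default_rois(tuple(config.grid_shape))
    grid = GridSpec(shape=tuple(config.grid_shape), voxel_size=tuple(config.voxel_size))
    vs = tuple(config.voxel_size)
    emio.write_json(design_manifest(route), out / "route.json")
    for name, mask in rois.items():
        emio.save_mask(mask, out / f"roi_{name}.nii", voxel_size=vs)
    emio.save_mask(grid.resolve_mask(), out / "mask.nii", voxel_size=vs)

    rec_rng = np.random.default_rng(config.seeds["design"] + 1)
    beh_rng = np.random.default_rng(config.seeds["behavior"])
    vol_rng = np.random.default_rng(config.seeds["volumes"])

    subject_entries = []
    for s in range(1, config.n_subjects + 1):
        sd = out / f"sub-{s:02d}"
        sd.mkdir(exist_ok=True)
        subj = simulate_subject(
            route,
            grid,
            rois["effect"],
            config.effect_size,
            config.noise_sd,
            recipe_seed=rec_rng.spawn(1)[0],
            behavior_seed=beh_rng.spawn(1)[0],
            volume_seed=int(vol_rng.integers(2**31 - 1)),
        )
        emio.save_recipe(subj["recipe"], sd / "events.tsv")
        emio.save_ratings(subj["behavior"].ratings, sd / "ratings.tsv")
        emio.write_json(
            {"recall_sequence": subj["behavior"].recall_sequence.tolist()}, sd / "recall.json"
        )
        subj["behavior"].map_responses.to_csv(sd / "map_responses.tsv", sep="\t", index=False)
        for sess in ("pre", "post"):
            emio.save_series(subj[sess], sd / f"{sess}.nii", sd / f"{sess}_motion.tsv")
        subject_entries.append(
            {"id": f"sub-{s:02d}", "n_trials": int(subj["recipe"].n_trials), "sessions": ["pre", "post"]}
        )

    manifest = {
        "config": config.to_dict(),
        "rois": sorted(rois),
        "subjects": subject_entries,
    }
    emio.write_json(manifest, out / "manifest.json")
    return out


def load_dataset(dataset_dir: str | Path) -> tuple[RunConfig, RouteDesign, list[dict], dict[str, np.ndarray]]:
    """Load a dataset directory written by :func:`run_simulate`."""
    root = Path(dataset_dir)
    manifest = emio.read_json(root / "manifest.json")
    config = RunConfig.from_dict(manifest["config"])
    route = design_from_manifest(emio.read_json(root / "route.json"))
    rois = {name: emio.load_mask(root / f"roi_{name}.nii") for name in manifest["rois"]}
    for name, path in config.roi_mask_paths.items():
        rois[name] = emio.load_mask(path)

    subjects = []
    for entry in manifest["subjects"]:
        sd = root / entry["id"]
        recipe = emio.load_recipe(sd / "events.tsv")
        ratings = emio.load_ratings(sd / "ratings.tsv")
        recall = np.asarray(emio.read_json(sd / "recall.json")["recall_sequence"], dtype=int)
        map_responses = pd.read_csv(sd / "map_responses.tsv", sep="\t")
        behavior = BehavioralDataset(ratings, recall, map_responses)
        spatial = ratings_to_distance_model(behavior, "space", route.n_objects)
        temporal = ratings_to_distance_model(behavior, "time", route.n_objects)
        subjects.append(
            {
                "id": entry["id"],
                "recipe": recipe,
                "behavior": behavior,
                "models": subject_models(spatial, temporal),
                "pre": emio.load_series(sd / "pre.nii", root / "mask.nii", sd / "pre_motion.tsv"),
                "post": emio.load_series(sd / "post.nii", root / "mask.nii", sd / "post_motion.tsv"),
            }
        )
    return config, route, subjects, rois


def behavior_table(route: RouteDesign, subjects: list[dict]) -> tuple[pd.DataFrame, dict]:
    """Per-subject behavioral results and the group summary."""
    spatial_truth = route.spatial_distances()
    temporal_truth = route.temporal_distances()
    rows = []
    for k, subj in enumerate(subjects):
        b = subj["behavior"]
        acc_s = rating_accuracy(b, spatial_truth, "space")
        acc_t = rating_accuracy(b, temporal_truth, "time")
        glm_s = rating_glm(b, spatial_truth, temporal_truth, "space")
        glm_t = rating_glm(b, spatial_truth, temporal_truth, "time")
        bias_s = error_bias(b, spatial_truth, temporal_truth, "space")["all"]
        bias_t = error_bias(b, temporal_truth, spatial_truth, "time")["all"]
        recall = recall_order_analysis(b.recall_sequence, spatial_truth, temporal_truth)
        rows.append(
            {
                "subject": subj.get("id", f"sub-{k + 1:02d}"),
                "accuracy_space_r": acc_s.r,
                "accuracy_time_r": acc_t.r,
                "glm_space_beta_space": glm_s["beta_space"],
                "glm_space_beta_time": glm_s["beta_time"],
                "glm_time_beta_space": glm_t["beta_space"],
                "glm_time_beta_time": glm_t["beta_time"],
                "error_bias_space_r": bias_s.r,
                "error_bias_time_r": bias_t.r,
                "recall_space_r": recall["space"].r,
                "recall_time_r": recall["time"].r,
                "n_recalled": int(b.recall_sequence.size),
                "map_error_ratio": map_error(b.map_responses, route.coords, route.map_side),
            }
        )
    table = pd.DataFrame(rows)

    def _group(col):
        vals = table[col].dropna().to_numpy()
        if vals.size < 2:
            return {"mean": float("nan"), "t": float("nan"), "p": float("nan")}
        t, p = group_t(vals)
        return {"mean": float(vals.mean()), "t": t, "p": p}

    recall_z = np.array(
        [
            fisher_z(r)[0] - fisher_z(s)[0]
            for r, s in zip(table["recall_time_r"], table["recall_space_r"])
            if np.isfinite(r) and np.isfinite(s)
        ]
    )
    summary = {
        "accuracy_space": _group("accuracy_space_r"),
        "accuracy_time": _group("accuracy_time_r"),
        "error_bias_space": _group("error_bias_space_r"),
        "error_bias_time": _group("error_bias_time_r"),
        "recall_time_vs_space": (
            {"t": group_t(recall_z)[0], "p": group_t(recall_z)[1]} if recall_z.size >= 2 else {}
        ),
        "map_error_ratio_mean": float(table["map_error_ratio"].mean()),
        "mean_n_recalled": float(table["n_recalled"].mean()),
    }
    return table, summary


def objective_anova_table(route: RouteDesign, subjects: list[dict], roi_mask: np.ndarray) -> pd.DataFrame:
    """2x2 objective-distance ANOVA on PS' cell means for one ROI."""
    cells = route.factorial_cells()
    table = np.zeros((len(subjects), 4))
    for k, subj in enumerate(subjects):
        ps = subject_ps_change(subj["pre"], subj["post"], subj["recipe"], roi_mask)
        pairs = ps.pair_vector
        for c in range(4):
            table[k, c] = pairs[cells == c].mean()
    return objective_2x2_anova(table)


def run_analysis(config: RunConfig, dataset_dir: str | Path, out_dir: str | Path) -> Path:
    """Analyse a simulated dataset; write tables, maps, and a report."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = []

    def log(msg):
        log_lines.append(f"[{time.strftime('%H:%M:%S')}] {msg}")

    t0 = time.time()
    _, route, subjects, rois = load_dataset(dataset_dir)
    log(f"loaded dataset with {len(subjects)} subjects ({time.time() - t0:.1f}s)")

    try:
        t0 = time.time()
        btable, bsummary = behavior_table(route, subjects)
        btable.to_csv(out / "behavior.tsv", sep="\t", index=False)
        emio.write_json(bsummary, out / "behavior_summary.json")
        log(f"behavioral analyses done ({time.time() - t0:.1f}s)")

        t0 = time.time()
        roi_masks = {name: rois[name] for name in config.rois}
        roi_table = roi_pipeline(
            subjects,
            roi_masks,
            tuple(config.models),
            n_shuffles=config.n_shuffles,
            n_flips=config.n_flips,
            seed=config.seeds["shuffles"],
            tail=config.tail,
        )
        roi_table.to_csv(out / "roi_results.tsv", sep="\t", index=False)
        log(f"ROI pipeline done, family size {len(roi_table)} ({time.time() - t0:.1f}s)")

        t0 = time.time()
        anova = objective_anova_table(route, subjects, roi_masks[config.rois[0]])
        anova.to_csv(out / "objective_anova.tsv", sep="\t", index=False)
        log(f"objective 2x2 ANOVA done ({time.time() - t0:.1f}s)")

        if config.run_searchlight:
            t0 = time.time()
            spec = SearchlightSpec(
                radius=config.searchlight_radius,
                min_voxels=config.searchlight_min_voxels,
                voxel_size=tuple(config.voxel_size),
            )
            import nibabel as nib

            aff = np.diag([*config.voxel_size, 1.0])
            maps = []
            for k, subj in enumerate(subjects, start=1):
                pre = regress_motion(subj["pre"])
                post = regress_motion(subj["post"])
                full_mask = pre.mask
                pat_pre = select_trial_volumes(pre, subj["recipe"], full_mask)
                pat_post = select_trial_volumes(post, subj["recipe"], full_mask)
                smap = searchlight_map(pat_pre, pat_post, subj["models"]["combined"], spec, full_mask)
                # subject maps are stored independently; the group stage below
                # could equally be run later from these files alone
                nib.save(
                    nib.Nifti1Image(smap.values.astype(np.float32), aff),
                    str(out / f"sub-{k:02d}_searchlight_rho.nii"),
                )
                maps.append(smap)
            t_map, p_map = group_searchlight(
                maps, n_flips=config.n_flips, seed=config.seeds["flips"], svc_mask=rois["effect"]
            )
            nib.save(nib.Nifti1Image(t_map.values.astype(np.float32), aff), str(out / "searchlight_t.nii"))
            nib.save(nib.Nifti1Image(p_map.values.astype(np.float32), aff), str(out / "searchlight_p_corr.nii"))
            log(f"searchlight done over {int(t_map.valid.sum())} centers ({time.time() - t0:.1f}s)")

        report = _render_report(config, bsummary, roi_table, anova)
        (out / "report.md").write_text(report)
    except Exception as exc:  # pragma: no cover - failure path
        (out / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
        raise
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out


def _render_report(config: RunConfig, bsummary: dict, roi_table: pd.DataFrame, anova: pd.DataFrame) -> str:
    lines = [
        "# Event-map pattern similarity analysis",
        "",
        "## Parameters",
        f"- subjects: {config.n_subjects}",
        f"- seeds: {config.seeds}",
        f"- shuffles: {config.n_shuffles}, sign flips: {config.n_flips}, tail: {config.tail}",
        f"- implanted effect size: {config.effect_size}, trial noise sd: {config.noise_sd}",
        "",
        "## Behavioral summary",
    ]
    for key, val in bsummary.items():
        lines.append(f"- {key}: {val}")
    lines += ["", "## ROI results (FDR over the full ROI x model family)", ""]
    lines.append(roi_table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    lines += ["", "## Objective-distance 2x2 repeated-measures ANOVA", ""]
    lines.append(anova.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    lines.append("")
    return "\n".join(lines)
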