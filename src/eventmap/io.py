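"""Reading and writing the pipeline's on-disk formats.

Volumes and masks are NIfTI; event tables, motion parameters, ratings and
result tables are TSV; manifests and group summaries are JSON. All writers
are deterministic so that regenerating a dataset from the same seeds
yields byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .recipe import PVTRecipe
from .volumes import VolumeSeries

__all__ = [
    "save_series",
    "load_series",
    "save_mask",
    "load_mask",
    "save_recipe",
    "load_recipe",
    "save_ratings",
    "load_ratings",
    "write_json",
    "read_json",
]


def _affine(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def save_series(series: VolumeSeries, nii_path: Path, motion_path: Path | None = None) -> None:
    img = nib.Nifti1Image(series.data.astype(np.float32), _affine(series.voxel_size))
    img.header.set_zooms((*series.voxel_size, 1.0))
    nib.save(img, str(nii_path))
    if motion_path is not None:
        series.motion.to_csv(motion_path, sep="\t", index=False)


def load_series(nii_path: Path, mask_path: Path, motion_path: Path) -> VolumeSeries:
    img = nib.load(str(nii_path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    mask = load_mask(mask_path)
    motion = pd.read_csv(motion_path, sep="\t")
    return VolumeSeries(data, voxel_size, mask, motion)


def save_mask(mask: np.ndarray, path: Path, voxel_size=(1.5, 1.5, 1.5)) -> None:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(voxel_size))
    nib.save(img, str(path))


def load_mask(path: Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj) > 0


def save_recipe(recipe: PVTRecipe, path: Path) -> None:
    recipe.to_frame().to_csv(path, sep="\t", index=False)


def load_recipe(path: Path, tr: float | None = None, target_object: int | None = None) -> PVTRecipe:
    frame = pd.read_csv(path, sep="\t")
    kwargs = {} if tr is None else {"tr": tr}
    return PVTRecipe.from_frame(frame, target_object=target_object, **kwargs)


def save_ratings(ratings: pd.DataFrame, path: Path) -> None:
    ratings.to_csv(path, sep="\t", index=False)


def load_ratings(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj: dict, path: Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: Path) -> dict:
    return json.loads(Path(path).read_text())
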