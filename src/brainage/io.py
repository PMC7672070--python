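"""File-format plumbing: NIfTI volumes, typed TSV tables, checkpoints.

Volumes and atlases travel as NIfTI (via nibabel) with a shared identity
affine within a cohort; tabular data as tab-separated values.  Trait-type
declarations live in a YAML sidecar next to the trait table.  Model
checkpoints are NumPy ``.npz`` archives with the config embedded as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .cohort import Atlas, VolumeSample
from .model import AgeModel, ModelConfig

__all__ = [
    "save_volume", "load_volume", "save_atlas", "load_atlas",
    "save_cohort", "load_cohort",
    "save_trait_table", "load_trait_table",
    "save_summary_stats", "load_summary_stats",
    "save_checkpoint", "load_checkpoint",
]

_IDENTITY_AFFINE = np.eye(4)


def save_volume(path: str | Path, voxels: np.ndarray,
                affine: np.ndarray | None = None) -> None:
    img = nib.Nifti1Image(np.asarray(voxels, dtype=np.float32),
                          _IDENTITY_AFFINE if affine is None else affine)
    nib.save(img, str(path))


def load_volume(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata(), dtype=np.float32)


def save_atlas(path: str | Path, atlas: Atlas) -> None:
    img = nib.Nifti1Image(atlas.labels.astype(np.int32), _IDENTITY_AFFINE)
    nib.save(img, str(path))


def load_atlas(path: str | Path) -> Atlas:
    labels = np.asarray(nib.load(str(path)).get_fdata()).astype(np.int32)
    return Atlas(labels=labels)


def save_cohort(directory: str | Path, samples: Sequence[VolumeSample],
                atlas: Atlas | None = None) -> None:
    """Write one NIfTI per subject plus an ages manifest (and optional atlas)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for s in samples:
        fname = f"{s.subject_id}.nii.gz"
        save_volume(directory / fname, s.voxels)
        manifest.append({"subject_id": s.subject_id, "age": s.age, "file": fname})
    pd.DataFrame(manifest).to_csv(directory / "participants.tsv", sep="\t", index=False)
    if atlas is not None:
        save_atlas(directory / "atlas.nii.gz", atlas)


def load_cohort(directory: str | Path) -> tuple[list[VolumeSample], Atlas | None]:
    directory = Path(directory)
    manifest = pd.read_csv(directory / "participants.tsv", sep="\t")
    samples = [VolumeSample(subject_id=str(row.subject_id),
                            voxels=load_volume(directory / row.file),
                            age=float(row.age))
               for row in manifest.itertuples()]
    atlas_path = directory / "atlas.nii.gz"
    atlas = load_atlas(atlas_path) if atlas_path.exists() else None
    return samples, atlas


def save_trait_table(path: str | Path, data: pd.DataFrame,
                     types: dict[str, str]) -> None:
    """TSV trait table with a YAML sidecar declaring each trait's type."""
    path = Path(path)
    data.to_csv(path, sep="\t", index=False)
    with open(path.with_suffix(".types.yaml"), "w") as fh:
        yaml.safe_dump({"trait_types": dict(types)}, fh)


def load_trait_table(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    path = Path(path)
    data = pd.read_csv(path, sep="\t")
    with open(path.with_suffix(".types.yaml")) as fh:
        types = yaml.safe_load(fh)["trait_types"]
    return data, types


def save_summary_stats(path: str | Path, table: pd.DataFrame) -> None:
    cols = ["variant_id", "effect_allele", "other_allele", "beta", "se", "pval", "eaf"]
    table[cols].to_csv(path, sep="\t", index=False)


def load_summary_stats(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_checkpoint(path: str | Path, model: AgeModel) -> None:
    state = model.get_state()
    arrays = {f"param_{i}": v for i, v in enumerate(state["params"])}
    for i, (mean, var) in enumerate(state["running"]):
        arrays[f"bn_mean_{i}"] = mean
        arrays[f"bn_var_{i}"] = var
    cfg = dataclasses.asdict(model.cfg)
    np.savez(str(path), config=json.dumps(cfg),
             output_offset=state["output_offset"], **arrays)


def load_checkpoint(path: str | Path) -> AgeModel:
    with np.load(str(path), allow_pickle=False) as data:
        cfg_dict = json.loads(str(data["config"]))
        for key in ("input_shape", "channels"):
            cfg_dict[key] = tuple(cfg_dict[key])
        model = AgeModel(ModelConfig(**cfg_dict))
        n_params = len(model.params())
        n_bn = len(model._buffers())
        state = {
            "params": [data[f"param_{i}"] for i in range(n_params)],
            "running": [(data[f"bn_mean_{i}"], data[f"bn_var_{i}"])
                        for i in range(n_bn)],
            "output_offset": float(data["output_offset"]),
        }
    model.set_state(state)
    return model
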