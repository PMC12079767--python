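"""NIfTI image I/O, manifests, and YAML configuration.

Images round-trip losslessly through NIfTI-1 (data, spacing, affine).
Vector fields are stored as multi-component NIfTI volumes (components in the
last axis) with a JSON sidecar recording the field role and the
voxel-displacement convention. Manifests are CSV tables with columns
``path, age`` plus optional ``sex``, ``participant``, ``label_path`` and
true-volume columns.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .grids import ImageGrid, VectorField

__all__ = [
    "read_image",
    "write_image",
    "read_field",
    "write_field",
    "read_manifest",
    "write_manifest",
    "split_manifest",
    "load_config",
    "save_config",
]


def _affine_for(img: ImageGrid | VectorField) -> np.ndarray:
    aff = np.asarray(img.affine, dtype=float)
    if aff.shape == (4, 4):
        return aff
    return np.eye(4)


def read_image(path: str | Path) -> ImageGrid:
    """Load a single-channel 2-D/3-D NIfTI volume."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    nii = nib.load(str(path))
    data = np.asanyarray(nii.dataobj)
    data = np.squeeze(data)
    if data.ndim not in (2, 3):
        raise ValueError(f"{path}: expected a 2-D/3-D single-channel volume, got shape {data.shape}")
    spacing = np.asarray(nii.header.get_zooms()[: data.ndim], dtype=float)
    return ImageGrid(data.astype(float), spacing, np.asarray(nii.affine))


def write_image(img: ImageGrid, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nii = nib.Nifti1Image(np.asarray(img.data, dtype=np.float32), _affine_for(img))
    nii.header.set_zooms(tuple(img.spacing))
    nib.save(nii, str(path))


def write_field(field: VectorField, path: str | Path) -> None:
    """Save a vector field as component-last NIfTI plus a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.moveaxis(np.asarray(field.data, dtype=np.float32), 0, -1)
    nii = nib.Nifti1Image(data, _affine_for(field))
    nib.save(nii, str(path))
    sidecar = {
        "role": field.role,
        "convention": "displacement-from-identity in voxel units, component-last",
        "spacing_mm": [float(s) for s in field.spacing],
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def read_field(path: str | Path) -> VectorField:
    path = Path(path)
    nii = nib.load(str(path))
    data = np.moveaxis(np.asanyarray(nii.dataobj), -1, 0)
    sidecar_path = Path(str(path) + ".json")
    role = "deformation"
    if sidecar_path.exists():
        role = json.loads(sidecar_path.read_text()).get("role", "deformation")
    return VectorField(data.astype(float), role, affine=np.asarray(nii.affine))


# -- manifests ----------------------------------------------------------------


def read_manifest(path: str | Path, check_paths: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "path" not in df.columns or "age" not in df.columns:
        raise ValueError("manifest requires 'path' and 'age' columns")
    if df["path"].duplicated().any():
        raise ValueError("manifest contains duplicate image paths")
    if not np.all(np.isfinite(df["age"].to_numpy(dtype=float))):
        raise ValueError("manifest ages must be finite")
    if check_paths:
        root = Path(path).parent
        for p in df["path"]:
            full = Path(p) if Path(p).is_absolute() else root / p
            if not full.exists():
                raise FileNotFoundError(f"manifest references missing image: {full}")
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def split_manifest(
    df: pd.DataFrame, fractions: tuple[float, float, float], seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Participant-disjoint train/val/test split, deterministic given seed.

    If no ``participant`` column exists, each row is its own participant.
    """
    if abs(sum(fractions) - 1.0) > 1e-9 or any(f < 0 for f in fractions):
        raise ValueError("fractions must be non-negative and sum to 1")
    participants = (
        df["participant"] if "participant" in df.columns else pd.Series(df["path"].values)
    )
    unique = np.asarray(pd.unique(participants))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unique))
    n_train = int(round(fractions[0] * len(unique)))
    n_val = int(round(fractions[1] * len(unique)))
    train_ids = set(unique[order[:n_train]])
    val_ids = set(unique[order[n_train : n_train + n_val]])
    in_train = participants.isin(train_ids).to_numpy()
    in_val = participants.isin(val_ids).to_numpy()
    return (
        df[in_train].reset_index(drop=True),
        df[in_val].reset_index(drop=True),
        df[~(in_train | in_val)].reset_index(drop=True),
    )


# -- configuration ------------------------------------------------------------


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def save_config(cfg: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
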