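"""Reading and validating co-registered volumes, masks and label volumes.

The pipeline assumes its inputs are already skull-stripped,
intensity-normalized and affinely registered to one common space (done
upstream with standard tools); this module enforces the shared-space
contract — identical shapes and voxel sizes across the cohort — rather
than performing any spatial processing itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = ["BrainVolume", "LabelVolume", "load_volume", "save_volume", "load_cohort", "load_label_volume"]


@dataclass
class BrainVolume:
    data: np.ndarray
    subject_id: str
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError(f"{self.subject_id}: volume must be 3D, got {self.data.ndim}D")
        if not np.isfinite(self.data).all():
            raise ValueError(f"{self.subject_id}: non-finite intensities")


@dataclass
class LabelVolume:
    """Integer region codes in the shared space; code 0 = unlabeled."""

    data: np.ndarray
    lut: dict[int, str]


def subject_id_from_path(path: str | Path) -> str:
    name = Path(path).name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return name[: -len(suf)]
    return Path(path).stem


def load_volume(path: str | Path, subject_id: str | None = None) -> BrainVolume:
    img = nib.load(str(path))
    return BrainVolume(
        data=np.asarray(img.dataobj, dtype=float),
        subject_id=subject_id or subject_id_from_path(path),
        voxel_size=tuple(float(z) for z in img.header.get_zooms()[:3]),
    )


def save_volume(data: np.ndarray, path: str | Path, voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> None:
    data = np.asarray(data)
    if data.dtype == np.int64:  # NIfTI-1 has no 64-bit int
        data = data.astype(np.int32)
    affine = np.diag([*voxel_size, 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def default_mask(volumes: list[BrainVolume], min_fraction: float = 0.5) -> np.ndarray:
    """Voxels with positive intensity in at least ``min_fraction`` of subjects.

    Skull-stripped volumes have zero background, so this recovers a brain
    mask when none is supplied.
    """
    pos = np.mean([v.data > 0 for v in volumes], axis=0)
    return pos >= min_fraction


def load_cohort(paths: list[str | Path], labels_path: str | Path,
                mask_path: str | Path | None = None) -> tuple[list[BrainVolume], np.ndarray, np.ndarray]:
    """Load a cohort and verify the shared-space contract.

    Returns ``(volumes, labels, mask)`` with labels aligned to the volume
    order by subject id.  An error-free return guarantees all volumes share
    shape and voxel size and that each class has at least 2 subjects.
    """
    volumes = [load_volume(p) for p in paths]
    if not volumes:
        raise ValueError("no volumes given")
    ref = volumes[0]
    for v in volumes[1:]:
        if v.data.shape != ref.data.shape:
            raise ValueError(
                f"shape mismatch: {ref.subject_id} is {ref.data.shape} but {v.subject_id} is {v.data.shape}"
            )
        if not np.allclose(v.voxel_size, ref.voxel_size):
            raise ValueError(
                f"voxel-size mismatch: {ref.subject_id} is {ref.voxel_size} but {v.subject_id} is {v.voxel_size}"
            )
    tab = pd.read_csv(labels_path, dtype={"subject_id": str})
    lut = dict(zip(tab["subject_id"], tab["group"].astype(int)))
    missing = [v.subject_id for v in volumes if v.subject_id not in lut]
    if missing:
        raise ValueError(f"labels file has no entry for subject(s): {', '.join(missing)}")
    labels = np.array([lut[v.subject_id] for v in volumes])
    for cls in np.unique(labels):
        if (labels == cls).sum() < 2:
            raise ValueError(f"class {cls} has fewer than 2 subjects")
    if len(np.unique(labels)) < 2:
        raise ValueError("cohort has a single class; two are required")

    if mask_path is not None:
        m = load_volume(mask_path, "mask")
        if m.data.shape != ref.data.shape:
            raise ValueError(f"shape mismatch: mask is {m.data.shape} but {ref.subject_id} is {ref.data.shape}")
        mask = m.data > 0
    else:
        mask = default_mask(volumes)
    return volumes, labels, mask


def load_label_volume(path: str | Path, lut_path: str | Path, cohort_shape: tuple[int, ...] | None = None) -> LabelVolume:
    """Load an anatomical label volume with its code -> region-name table.

    Every nonzero code present in the data must have a lookup entry.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj).astype(int)
    if cohort_shape is not None and data.shape != tuple(cohort_shape):
        raise ValueError(f"label volume shape {data.shape} != cohort shape {tuple(cohort_shape)}")
    tab = pd.read_csv(lut_path)
    lut = {int(c): str(n) for c, n in zip(tab["code"], tab["region_name"])}
    present = set(np.unique(data).tolist()) - {0}
    unknown = sorted(present - set(lut))
    if unknown:
        raise ValueError(f"label volume contains codes without lookup names: {unknown}")
    return LabelVolume(data=data, lut=lut)
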