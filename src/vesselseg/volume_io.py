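"""Volume containers, NIfTI input/output, masking, and subject splitting.

All algorithms in this package operate in voxel-index space: coordinates
are 0-based ``(x, y, z)`` indices into the array in its native order, and
every distance is expressed in (isotropic) voxel units.  The affine is
carried through unchanged so that outputs can be overlaid on the inputs in
a viewer, but it is never consulted by the algorithms themselves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "AngioVolume",
    "BinaryVolume",
    "SplitManifest",
    "load_case",
    "save_case",
    "apply_mask",
    "split_subjects",
]


def _identity_affine() -> np.ndarray:
    return np.eye(4)


@dataclass
class AngioVolume:
    """A 3D angiographic intensity volume.

    Parameters
    ----------
    data
        3D array of scalar intensities (arbitrary units). Must be finite.
    affine
        4x4 voxel-to-world map; defaults to identity (unit isotropic voxels).
    subject_id
        Free-form identifier used in manifests and provenance tables.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=_identity_affine)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class BinaryVolume:
    """A binary 3D grid (brain mask or vessel label) companion to an
    :class:`AngioVolume`.  Values are stored as uint8 in {0, 1}."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=_identity_affine)
    subject_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={arr.ndim}")
        # Anything positive counts as foreground; loaders may hand us
        # {0, 255}-coded masks.
        self.data = (arr > 0).astype(np.uint8)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def astype_bool(self) -> np.ndarray:
        return self.data.astype(bool)


# Aliases that make call sites read like the domain.
BrainMask = BinaryVolume
LabelVolume = BinaryVolume


def _read_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D NIfTI, got shape {data.shape}")
    return data, img.affine


def load_case(
    image_path: str | Path,
    mask_path: str | Path,
    label_path: str | Path | None = None,
    subject_id: str | None = None,
):
    """Load an (image, brain-mask[, vessel-label]) NIfTI triplet.

    Masks and labels are binarized (>0 -> 1) on load.  Shapes must agree.

    Returns
    -------
    (AngioVolume, BinaryVolume, BinaryVolume | None)
    """
    sid = subject_id if subject_id is not None else Path(image_path).name.split(".")[0]
    img_data, img_aff = _read_nifti(image_path)
    mask_data, mask_aff = _read_nifti(mask_path)
    if img_data.shape != mask_data.shape:
        raise ValueError(
            f"image shape {img_data.shape} != mask shape {mask_data.shape}"
        )
    volume = AngioVolume(img_data.astype(np.float32), img_aff, sid)
    mask = BinaryVolume(mask_data, mask_aff, sid)
    label = None
    if label_path is not None:
        lab_data, lab_aff = _read_nifti(label_path)
        if lab_data.shape != img_data.shape:
            raise ValueError(
                f"image shape {img_data.shape} != label shape {lab_data.shape}"
            )
        label = BinaryVolume(lab_data, lab_aff, sid)
    return volume, mask, label


def save_case(
    out_dir: str | Path,
    volume: AngioVolume,
    mask: BinaryVolume | None = None,
    label: BinaryVolume | None = None,
) -> dict[str, Path]:
    """Write a case as NIfTI files ``<sid>_tof.nii.gz`` etc.

    Labels/masks go out as uint8, intensities as float32.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sid = volume.subject_id or "case"
    paths: dict[str, Path] = {}
    img = nib.Nifti1Image(volume.data.astype(np.float32), volume.affine)
    paths["image"] = out_dir / f"{sid}_tof.nii.gz"
    nib.save(img, str(paths["image"]))
    if mask is not None:
        paths["mask"] = out_dir / f"{sid}_mask.nii.gz"
        nib.save(nib.Nifti1Image(mask.data, mask.affine), str(paths["mask"]))
    if label is not None:
        paths["label"] = out_dir / f"{sid}_label.nii.gz"
        nib.save(nib.Nifti1Image(label.data, label.affine), str(paths["label"]))
    return paths


def save_probability(path: str | Path, prob: np.ndarray, affine: np.ndarray) -> None:
    """Write a probability volume as float32 NIfTI."""
    nib.save(nib.Nifti1Image(prob.astype(np.float32), affine), str(path))


def apply_mask(volume: AngioVolume, mask: BinaryVolume) -> AngioVolume:
    """Zero every voxel outside the brain mask (skull-stripping product)."""
    if volume.shape != mask.shape:
        raise ValueError(f"volume shape {volume.shape} != mask shape {mask.shape}")
    return AngioVolume(volume.data * mask.data, volume.affine, volume.subject_id)


@dataclass
class SplitManifest:
    """Disjoint train/validation/test assignment of subject ids."""

    train: list[str]
    validation: list[str]
    test: list[str]
    seed: int = 0

    def __post_init__(self) -> None:
        roles = [set(self.train), set(self.validation), set(self.test)]
        total = sum(len(r) for r in roles)
        if len(set.union(*roles)) != total:
            raise ValueError("split roles must be disjoint")

    def role_of(self, subject_id: str) -> str:
        for role in ("train", "validation", "test"):
            if subject_id in getattr(self, role):
                return role
        raise KeyError(subject_id)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "train": self.train,
            "validation": self.validation,
            "test": self.test,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitManifest":
        payload = json.loads(Path(path).read_text())
        return cls(**payload)


def split_subjects(
    ids: Sequence[str], counts: Sequence[int], seed: int = 0
) -> SplitManifest:
    """Randomly partition subject ids into train/validation/test.

    ``counts`` gives the three role sizes and must sum to ``len(ids)``,
    mirroring cohort-level splits such as 41/11/14 of 66 subjects.
    Deterministic for a given seed.
    """
    ids = list(ids)
    counts = list(counts)
    if len(counts) != 3:
        raise ValueError("counts must be (n_train, n_validation, n_test)")
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    if sum(counts) != len(ids):
        raise ValueError(
            f"counts sum to {sum(counts)} but there are {len(ids)} subject ids"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    shuffled = [ids[i] for i in order]
    n_tr, n_va, _ = counts
    return SplitManifest(
        train=shuffled[:n_tr],
        validation=shuffled[n_tr : n_tr + n_va],
        test=shuffled[n_tr + n_va :],
        seed=seed,
    )
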