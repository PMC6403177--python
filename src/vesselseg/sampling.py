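"""Balanced 2D patch extraction from masked angiography volumes.

With vessels at ~0.9% of brain voxels, uniformly sampled training patches
would be almost entirely background.  Training therefore draws, per
subject, a fixed number of patches whose *central voxel* is a vessel and
an equal number whose central voxel is background (default 500 + 500),
from axial slices, each patch standardized to zero mean and unit variance.

"Background-centered" means only that the central voxel is unlabeled —
the patch may still contain vessels, which preserves hard negatives near
vessel boundaries.  Background centers are restricted to the brain mask
so patches come from tissue rather than air.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volume_io import AngioVolume, BinaryVolume

__all__ = [
    "PatchPair",
    "SamplerConfig",
    "InsufficientCentersError",
    "eligible_centers",
    "sample_patches",
    "normalize_patch",
    "patches_to_arrays",
    "provenance_table",
]

logger = logging.getLogger(__name__)

#: The axis along which 2D slices are taken (axial plane = first two axes).
SLICE_AXIS = 2


class InsufficientCentersError(RuntimeError):
    """Raised when a class has no eligible centers but patches of that
    class were requested."""


@dataclass
class PatchPair:
    """An image patch with its aligned binary label patch and provenance.

    ``center`` is the (row, col) voxel index of the patch's central voxel
    — the voxel at offset ``(P//2, P//2)`` within the patch — in the
    coordinates of slice ``slice_index``.
    """

    image_patch: np.ndarray
    label_patch: np.ndarray
    subject_id: str = ""
    slice_index: int = 0
    center: tuple[int, int] = (0, 0)
    is_vessel: bool = False

    def __post_init__(self) -> None:
        if self.image_patch.shape != self.label_patch.shape:
            raise ValueError("image and label patches must have equal shape")


@dataclass
class SamplerConfig:
    """How many patches of each class to draw per subject, and at what size.

    Defaults follow the balanced 500 vessel-centered + 500 background-
    centered patches per subject; standard patch sizes are 16, 32, 64, 96.
    """

    patch_size: int = 96
    n_vessel_per_subject: int = 500
    n_background_per_subject: int = 500
    normalize: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.patch_size < 2:
            raise ValueError("patch_size must be >= 2")
        if self.n_vessel_per_subject < 0 or self.n_background_per_subject < 0:
            raise ValueError("patch counts must be >= 0")


def eligible_centers(
    label: BinaryVolume | np.ndarray,
    mask: BinaryVolume | np.ndarray,
    patch_size: int,
    want_vessel: bool,
) -> np.ndarray:
    """All (slice, row, col) centers of fitting patches of one class.

    A center is eligible when the ``P x P`` patch around it fits entirely
    inside the axial slice, the central voxel is inside the brain mask,
    and the central voxel's label equals ``want_vessel``.

    Returns an ``(N, 3)`` int array; may be empty.
    """
    lab = (label.data if isinstance(label, BinaryVolume) else np.asarray(label)) > 0
    msk = (mask.data if isinstance(mask, BinaryVolume) else np.asarray(mask)) > 0
    if lab.shape != msk.shape:
        raise ValueError(f"label shape {lab.shape} != mask shape {msk.shape}")
    P = int(patch_size)
    H, W = lab.shape[0], lab.shape[1]
    if P > H or P > W:
        raise ValueError(f"patch size {P} exceeds in-plane dimensions {(H, W)}")
    h0 = P // 2
    valid = msk & (lab if want_vessel else ~lab)
    # patch rows span [r-h0, r-h0+P); require r >= h0 and r-h0+P <= H
    fit = np.zeros_like(valid)
    fit[h0 : H - P + h0 + 1, h0 : W - P + h0 + 1, :] = True
    coords = np.argwhere(valid & fit)  # (row, col, slice)
    return coords[:, [2, 0, 1]]  # -> (slice, row, col)


def normalize_patch(image_patch: np.ndarray) -> np.ndarray:
    """Standardize a patch to zero mean and unit (population) variance.

    A constant patch (sd < 1e-8) maps to all zeros.
    """
    patch = np.asarray(image_patch, dtype=np.float32)
    mu = patch.mean()
    sd = patch.std()
    if sd < 1e-8:
        return np.zeros_like(patch)
    return (patch - mu) / sd


def _draw(
    rng: np.random.Generator, centers: np.ndarray, n: int, class_name: str
) -> np.ndarray:
    if n == 0:
        return centers[:0]
    if len(centers) == 0:
        raise InsufficientCentersError(
            f"no eligible {class_name} centers but {n} requested"
        )
    if len(centers) >= n:
        idx = rng.choice(len(centers), size=n, replace=False)
    else:
        logger.warning(
            "only %d eligible %s centers for %d requested patches; "
            "sampling with replacement",
            len(centers),
            class_name,
            n,
        )
        idx = rng.choice(len(centers), size=n, replace=True)
    return centers[idx]


def sample_patches(
    volume: AngioVolume,
    label: BinaryVolume,
    mask: BinaryVolume,
    config: SamplerConfig,
) -> list[PatchPair]:
    """Draw the configured balanced set of patch pairs from one subject.

    Centers are drawn uniformly without replacement from each class's
    eligible set (with replacement, logged, only if a set is smaller than
    requested).  Deterministic given ``config.seed``.
    """
    config.validate()
    P = config.patch_size
    h0 = P // 2
    rng = np.random.default_rng(config.seed)
    vessel_centers = eligible_centers(label, mask, P, want_vessel=True)
    bg_centers = eligible_centers(label, mask, P, want_vessel=False)
    picks = [
        (_draw(rng, vessel_centers, config.n_vessel_per_subject, "vessel"), True),
        (_draw(rng, bg_centers, config.n_background_per_subject, "background"), False),
    ]
    img = volume.data
    lab = label.data
    pairs: list[PatchPair] = []
    for centers, is_vessel in picks:
        for s, r, c in centers:
            window = (slice(r - h0, r - h0 + P), slice(c - h0, c - h0 + P), s)
            image_patch = img[window].astype(np.float32)
            if config.normalize:
                image_patch = normalize_patch(image_patch)
            pairs.append(
                PatchPair(
                    image_patch=image_patch,
                    label_patch=lab[window].astype(np.uint8),
                    subject_id=volume.subject_id,
                    slice_index=int(s),
                    center=(int(r), int(c)),
                    is_vessel=is_vessel,
                )
            )
    return pairs


def patches_to_arrays(pairs: list[PatchPair]) -> tuple[np.ndarray, np.ndarray]:
    """Stack patch pairs into (N, 1, P, P) image and label arrays."""
    images = np.stack([p.image_patch for p in pairs])[:, None].astype(np.float32)
    labels = np.stack([p.label_patch for p in pairs])[:, None].astype(np.float32)
    return images, labels


def provenance_table(pairs: list[PatchPair]) -> pd.DataFrame:
    """Provenance of a patch set (subject, slice, row, col, is_vessel)."""
    return pd.DataFrame(
        {
            "subject": [p.subject_id for p in pairs],
            "slice": [p.slice_index for p in pairs],
            "row": [p.center[0] for p in pairs],
            "col": [p.center[1] for p in pairs],
            "is_vessel": [p.is_vessel for p in pairs],
        }
    )


def save_patch_set(path, pairs: list[PatchPair]) -> None:
    """Persist a patch set as an .npz container plus a CSV provenance
    table alongside it."""
    images, labels = patches_to_arrays(pairs)
    np.savez_compressed(path, images=images, labels=labels)
    provenance_table(pairs).to_csv(str(path) + ".csv", index=False)
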