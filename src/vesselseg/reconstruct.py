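"""Full-volume segmentation by patch-wise prediction and stitching.

Each axial slice is symmetrically zero-padded, tiled into P x P windows
on a regular stride grid, every window is standardized exactly as the
training patches were, predicted, and written back; where windows
overlap, predictions are averaged.  Probabilities are zeroed outside the
brain mask before thresholding, so the binary output is always a subset
of the mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sampling import normalize_patch
from .volume_io import AngioVolume, BinaryVolume

__all__ = ["SegmentationResult", "tile_slice", "predict_volume"]


@dataclass
class SegmentationResult:
    """Probability and thresholded binary volume for one case."""

    probability: np.ndarray  # float32 in [0, 1], input shape
    binary: np.ndarray  # uint8 in {0, 1}, subset of the brain mask
    threshold: float
    model_id: str = ""

    def as_label(self, affine: np.ndarray, subject_id: str = "") -> BinaryVolume:
        return BinaryVolume(self.binary, affine, subject_id)


def tile_slice(
    slice_shape: tuple[int, int], patch_size: int, stride: int
) -> tuple[list[tuple[int, int]], tuple[int, int], tuple[int, int]]:
    """Window origins covering a slice on a stride grid.

    The slice is symmetrically zero-padded so that ``P x P`` windows
    placed every ``stride`` pixels cover every pixel at least once.

    Returns ``(origins, padded_shape, pad_before)`` where ``origins`` are
    (row, col) corners in padded coordinates.
    """
    P, stride = int(patch_size), int(stride)
    if stride > P:
        raise ValueError(f"stride {stride} > patch size {P} would leave coverage gaps")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    padded = []
    pad_before = []
    for dim in slice_shape:
        n_steps = int(np.ceil(max(dim - P, 0) / stride))
        target = P + n_steps * stride
        padded.append(target)
        pad_before.append((target - dim) // 2)
    origins = [
        (r, c)
        for r in range(0, padded[0] - P + 1, stride)
        for c in range(0, padded[1] - P + 1, stride)
    ]
    return origins, (padded[0], padded[1]), (pad_before[0], pad_before[1])


def _predict_fn(model):
    """Accept a UNet2D-like object (``.predict``) or a plain callable
    mapping (N, 1, P, P) -> (N, P, P) or (N, 1, P, P)."""
    fn = model.predict if hasattr(model, "predict") else model

    def run(batch: np.ndarray) -> np.ndarray:
        out = np.asarray(fn(batch))
        if out.ndim == 4:
            out = out[:, 0]
        return out

    return run


def predict_volume(
    model,
    volume: AngioVolume,
    mask: BinaryVolume,
    patch_size: int | None = None,
    stride: int | None = None,
    threshold: float = 0.5,
    normalize: bool = True,
    batch_size: int = 32,
) -> SegmentationResult:
    """Segment a whole volume slice by slice.

    Parameters
    ----------
    model
        Trained network (or any per-patch predictor; see ``_predict_fn``).
    patch_size, stride
        Window geometry; default ``patch_size`` from the model config and
        non-overlapping ``stride = patch_size`` (overlapping strides are
        averaged).
    threshold
        Probability cut for the binary volume (default 0.5).
    normalize
        Standardize each window as during training (disable only for
        stub predictors that expect raw intensities).
    """
    if volume.shape != mask.shape:
        raise ValueError(f"volume shape {volume.shape} != mask shape {mask.shape}")
    P = patch_size or getattr(getattr(model, "config", None), "patch_size", None)
    if P is None:
        raise ValueError("patch_size not given and model carries no config")
    stride = stride or P
    run = _predict_fn(model)
    H, W, n_slices = volume.shape
    origins, (ph, pw), (p0, p1) = tile_slice((H, W), P, stride)
    prob = np.zeros(volume.shape, dtype=np.float32)
    mask_bool = mask.astype_bool()
    for k in range(n_slices):
        mask_slice = mask_bool[:, :, k]
        if not mask_slice.any():
            continue
        padded = np.zeros((ph, pw), dtype=np.float32)
        padded[p0 : p0 + H, p1 : p1 + W] = volume.data[:, :, k]
        padded_mask = np.zeros((ph, pw), dtype=bool)
        padded_mask[p0 : p0 + H, p1 : p1 + W] = mask_slice
        acc = np.zeros((ph, pw), dtype=np.float32)
        cnt = np.zeros((ph, pw), dtype=np.float32)
        windows, kept = [], []
        for r, c in origins:
            if not padded_mask[r : r + P, c : c + P].any():
                continue  # fully outside the brain: probability stays 0
            patch = padded[r : r + P, c : c + P]
            windows.append(normalize_patch(patch) if normalize else patch)
            kept.append((r, c))
        for i in range(0, len(windows), batch_size):
            batch = np.stack(windows[i : i + batch_size])[:, None]
            preds = run(batch)
            for pred, (r, c) in zip(preds, kept[i : i + batch_size]):
                acc[r : r + P, c : c + P] += pred
                cnt[r : r + P, c : c + P] += 1.0
        covered = cnt > 0
        acc[covered] /= cnt[covered]
        prob[:, :, k] = acc[p0 : p0 + H, p1 : p1 + W]
    prob *= mask_bool
    binary = ((prob >= threshold) & mask_bool).astype(np.uint8)
    model_id = getattr(model, "__class__", type(model)).__name__
    return SegmentationResult(prob, binary, threshold, model_id)
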