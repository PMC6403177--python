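"""On-the-fly geometric augmentation of patch pairs.

Convolutional encoders are not equivariant to rotation or shear, so the
training loop perturbs each patch with a random composition of flips, a
rotation, and a shear (a cheap stand-in for elastic deformation),
applying the *same* transform to image and label.  Images are
interpolated bilinearly with edge replication; labels nearest-neighbor
and re-binarized, so label mass is approximately preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["AugmentConfig", "augment_pair"]


@dataclass
class AugmentConfig:
    """Ranges of the random transforms (degrees; probabilities in [0,1])."""

    rotation_deg: float = 30.0
    shear_deg: float = 10.0
    flip_horizontal_prob: float = 0.5
    flip_vertical_prob: float = 0.5


def _transform_matrix(cfg: AugmentConfig, rng: np.random.Generator) -> np.ndarray:
    theta = np.deg2rad(rng.uniform(-cfg.rotation_deg, cfg.rotation_deg))
    shear = np.deg2rad(rng.uniform(-cfg.shear_deg, cfg.shear_deg))
    flip_h = rng.random() < cfg.flip_horizontal_prob
    flip_v = rng.random() < cfg.flip_vertical_prob
    rot = np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )
    shr = np.array([[1.0, np.tan(shear)], [0.0, 1.0]])
    flp = np.diag([-1.0 if flip_v else 1.0, -1.0 if flip_h else 1.0])
    return flp @ rot @ shr


def augment_pair(
    image_patch: np.ndarray,
    label_patch: np.ndarray,
    config: AugmentConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one random flip/rotation/shear jointly to an aligned pair.

    Output shapes equal input shapes; the label comes back binary.
    """
    if image_patch.shape != label_patch.shape:
        raise ValueError("image and label patches must have equal shape")
    matrix = _transform_matrix(config, rng)
    center = (np.array(image_patch.shape) - 1) / 2.0
    offset = center - matrix @ center
    img = ndimage.affine_transform(
        image_patch.astype(np.float32), matrix, offset=offset, order=1, mode="nearest"
    )
    lab = ndimage.affine_transform(
        label_patch.astype(np.float32), matrix, offset=offset, order=0, mode="nearest"
    )
    return img, (lab > 0.5).astype(np.uint8)
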