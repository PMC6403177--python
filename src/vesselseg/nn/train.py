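"""Training loop: Adam on the soft-Dice loss over balanced patch batches.

``PRESETS`` carries the published per-architecture hyperparameter
settings, one per optimization target metric (Dice / 95th-percentile
Hausdorff / average Hausdorff):

=============  ========  =============  ==========  =======
architecture   metric    learning rate  batch size  dropout
=============  ========  =============  ==========  =======
unet           dice      1e-4           16          0
unet           hd95      1e-4           64          0
unet           avd       1e-5           8           0
half_unet      dice      1e-4           64          0.1
half_unet      hd95      1e-4           32          0.2
half_unet      avd       1e-4           32          0.1
=============  ========  =============  ==========  =======
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ..sampling import PatchPair, patches_to_arrays
from .augment import AugmentConfig, augment_pair
from .loss import soft_dice, soft_dice_loss_gradient
from .model import UNet2D, UNetConfig
from .optim import Adam

__all__ = ["PRESETS", "preset_config", "TrainingHistory", "train"]

logger = logging.getLogger(__name__)

PRESETS: dict[tuple[str, str], dict] = {
    ("unet", "dice"): dict(base_width=64, learning_rate=1e-4, batch_size=16, dropout_rate=0.0),
    ("unet", "hd95"): dict(base_width=64, learning_rate=1e-4, batch_size=64, dropout_rate=0.0),
    ("unet", "avd"): dict(base_width=64, learning_rate=1e-5, batch_size=8, dropout_rate=0.0),
    ("half_unet", "dice"): dict(base_width=32, learning_rate=1e-4, batch_size=64, dropout_rate=0.1),
    ("half_unet", "hd95"): dict(base_width=32, learning_rate=1e-4, batch_size=32, dropout_rate=0.2),
    ("half_unet", "avd"): dict(base_width=32, learning_rate=1e-4, batch_size=32, dropout_rate=0.1),
}


def preset_config(arch: str, metric: str, **overrides) -> UNetConfig:
    """A :class:`UNetConfig` loaded from the published presets,
    e.g. ``preset_config("half_unet", "dice", patch_size=96)``."""
    key = (arch, metric)
    if key not in PRESETS:
        raise KeyError(
            f"unknown preset {key}; available: {sorted(PRESETS)}"
        )
    return replace(UNetConfig(**PRESETS[key]), **overrides)


@dataclass
class TrainingHistory:
    """Per-epoch mean training loss and soft-Dice (plus validation
    soft-Dice when a validation set is supplied)."""

    loss: list[float] = field(default_factory=list)
    train_dice: list[float] = field(default_factory=list)
    val_dice: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        data = {"epoch": np.arange(1, len(self.loss) + 1), "loss": self.loss,
                "train_dice": self.train_dice}
        if self.val_dice:
            data["val_dice"] = self.val_dice
        return pd.DataFrame(data)


def _eval_dice(model: UNet2D, images: np.ndarray, labels: np.ndarray,
               batch_size: int) -> float:
    dices = []
    for i in range(0, len(images), batch_size):
        probs = model.forward(images[i : i + batch_size], train=False)
        dices.append(soft_dice(probs, labels[i : i + batch_size]))
    return float(np.mean(dices))


def train(
    model: UNet2D,
    patches: list[PatchPair],
    config: UNetConfig | None = None,
    val_patches: list[PatchPair] | None = None,
    augment: AugmentConfig | None = None,
    keep_best: bool = True,
) -> TrainingHistory:
    """Fit the model on balanced patch pairs.

    Minimizes ``1 - soft_dice`` per batch with Adam; augmentation (when
    enabled) is applied on the fly per patch per epoch.  Fully seeded:
    batch order, augmentation draws and dropout masks all derive from
    ``config.seed``.  When a validation set is given and ``keep_best``
    is set, the weights with the best validation soft-Dice are restored
    at the end.

    Returns the per-epoch history.
    """
    if not patches:
        raise ValueError("empty patch set")
    config = config or model.config
    images, labels = patches_to_arrays(patches)
    val_arrays = patches_to_arrays(val_patches) if val_patches else None
    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    history = TrainingHistory()
    best_val, best_state = -np.inf, None
    n = len(images)
    bs = config.batch_size
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses, epoch_dices = [], []
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            batch_x = images[idx]
            batch_g = labels[idx]
            if augment is not None:
                batch_x = batch_x.copy()
                batch_g = batch_g.copy()
                for j in range(len(idx)):
                    img, lab = augment_pair(
                        batch_x[j, 0], batch_g[j, 0], augment, rng
                    )
                    batch_x[j, 0] = img
                    batch_g[j, 0] = lab
            probs = model.forward(batch_x, train=True)
            loss, dprob = soft_dice_loss_gradient(probs, batch_g)
            model.backward(dprob)
            optimizer.step()
            epoch_losses.append(loss)
            epoch_dices.append(1.0 - loss)
        history.loss.append(float(np.mean(epoch_losses)))
        history.train_dice.append(float(np.mean(epoch_dices)))
        msg = f"epoch {epoch + 1}/{config.epochs} loss={history.loss[-1]:.4f}"
        if val_arrays is not None:
            vd = _eval_dice(model, *val_arrays, batch_size=bs)
            history.val_dice.append(vd)
            msg += f" val_dice={vd:.4f}"
            if keep_best and vd > best_val:
                best_val, best_state = vd, model.state_copy()
        logger.info(msg)
    if best_state is not None:
        model.load_state(best_state)
    return history
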