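"""The full and half U-net architectures, pinned by parameter counts.

The encoder applies, on 4 levels, two padded 3x3/stride-1 convolutions
(each followed by ReLU, with dropout after the first) and a 2x2/stride-2
max-pool; channel width doubles at each descent from ``base_width`` (64
for the full net, 32 for the half net).  The bottom level is two further
3x3 convolutions.  The decoder at each level up-samples by a
parameter-free 2x nearest-neighbor repetition, concatenates the skip
connection from the matching encoder level, and applies two 3x3
convolutions (ReLU after both, dropout after the first).  A final 1x1
convolution and a pixel-wise sigmoid map the feature vector to the
vessel probability.  All convolutions carry biases; there is no batch
normalization.

The parameter-free up-sampling is load-bearing: with base width 64 and
depth 4 this schedule has exactly 31,377,793 trainable parameters
(7,846,081 for the half net); replacing the repetition by a learned 2x2
up-convolution would give 31,030,593 instead.  ``count_parameters``
exposes the closed-form count for both variants so the architecture can
be discriminated without building it.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .layers import Conv2d, Dropout, MaxPool2x2, ReLU, Upsample2x

__all__ = ["UNetConfig", "UNet2D", "count_parameters", "FULL_UNET", "HALF_UNET"]


@dataclass
class UNetConfig:
    """Architecture and training hyperparameters.

    ``base_width`` is the channel count of the first encoder block (64
    full / 32 half); ``depth`` the number of max-pool levels (4);
    ``patch_size`` must be divisible by ``2**depth``.
    """

    base_width: int = 64
    depth: int = 4
    patch_size: int = 96
    dropout_rate: float = 0.0
    learning_rate: float = 1e-4
    batch_size: int = 16
    epochs: int = 20
    seed: int = 0

    def validate(self) -> None:
        if self.base_width < 1:
            raise ValueError("base_width must be positive")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.patch_size % (2**self.depth) != 0:
            raise ValueError(
                f"patch_size {self.patch_size} must be divisible by 2**depth = {2**self.depth}"
            )
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "UNetConfig":
        return cls(**json.loads(Path(path).read_text()))


#: The two published variants.
FULL_UNET = UNetConfig(base_width=64)
HALF_UNET = UNetConfig(base_width=32)


def _conv_params(c_in: int, c_out: int, k: int) -> int:
    return k * k * c_in * c_out + c_out


def count_parameters(config: UNetConfig, upsampling: str = "nearest") -> int:
    """Closed-form trainable parameter count of the architecture.

    Each 3x3 convolution contributes ``9*C_in*C_out + C_out``; pooling,
    nearest-neighbor up-sampling and activations contribute nothing; the
    final 1x1 convolution contributes ``C_in + 1``.  With
    ``upsampling="transpose"`` the count instead includes learned 2x2
    up-convolutions (the variant this architecture is *not*).
    """
    config.validate()
    if upsampling not in ("nearest", "transpose"):
        raise ValueError("upsampling must be 'nearest' or 'transpose'")
    w = config.base_width
    enc = [w * 2**i for i in range(config.depth)]
    bottom = w * 2**config.depth
    total = 0
    c_prev = 1
    for c in enc:
        total += _conv_params(c_prev, c, 3) + _conv_params(c, c, 3)
        c_prev = c
    total += _conv_params(c_prev, bottom, 3) + _conv_params(bottom, bottom, 3)
    c_prev = bottom
    for c in reversed(enc):
        if upsampling == "transpose":
            total += _conv_params(c_prev, c, 2)  # learned 2x2 up-conv
            c_cat = c + c
        else:
            c_cat = c_prev + c  # skip concat after parameter-free upsample
        total += _conv_params(c_cat, c, 3) + _conv_params(c, c, 3)
        c_prev = c
    total += _conv_params(c_prev, 1, 1)
    return total


class _ConvBlock:
    """conv-ReLU-[dropout]-conv-ReLU, the repeated unit of both paths."""

    def __init__(self, c_in: int, c_out: int, dropout: float, rng: np.random.Generator):
        self.conv1 = Conv2d(c_in, c_out, 3, rng)
        self.relu1 = ReLU()
        self.drop = Dropout(dropout, rng)
        self.conv2 = Conv2d(c_out, c_out, 3, rng)
        self.relu2 = ReLU()
        self.layers = [self.conv1, self.relu1, self.drop, self.conv2, self.relu2]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class UNet2D:
    """The network: a callable mapping (N, 1, P, P) patches to (N, 1, P, P)
    vessel-probability maps in (0, 1)."""

    def __init__(self, config: UNetConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence(config.seed).spawn(1)[0]
        )
        w = config.base_width
        widths = [w * 2**i for i in range(config.depth)]
        bottom = w * 2**config.depth
        dr = config.dropout_rate

        self.encoder: list[_ConvBlock] = []
        c_prev = 1
        for c in widths:
            self.encoder.append(self._block(c_prev, c, dr, rng))
            c_prev = c
        self.pools = [MaxPool2x2() for _ in widths]
        self.bottom = self._block(c_prev, bottom, dr, rng)
        self.ups = [Upsample2x() for _ in widths]
        self.decoder: list[_ConvBlock] = []
        c_prev = bottom
        for c in reversed(widths):
            self.decoder.append(self._block(c_prev + c, c, dr, rng))
            c_prev = c
        self.final = Conv2d(c_prev, 1, 1, rng)
        self._prob: np.ndarray | None = None
        self._dtype = np.dtype(np.float32)

    def _block(self, c_in, c_out, dr, rng) -> _ConvBlock:
        block = _ConvBlock(c_in, c_out, dr, rng)
        block.drop.rng = self._dropout_rng  # one stream for all dropout masks
        return block

    # -- introspection ------------------------------------------------

    def _conv_layers(self) -> list[Conv2d]:
        convs: list[Conv2d] = []
        for block in [*self.encoder, self.bottom, *self.decoder]:
            convs.extend([block.conv1, block.conv2])
        convs.append(self.final)
        return convs

    def num_parameters(self) -> int:
        """Total trainable parameters of the built model."""
        return sum(c.n_params for c in self._conv_layers())

    def to_dtype(self, dtype) -> "UNet2D":
        """Convert all weights in place (float32 default; float64 makes
        finite-difference verification of the backward pass exact)."""
        self._dtype = np.dtype(dtype)
        for _, params, grads in self.parameters():
            for key in params:
                params[key] = params[key].astype(self._dtype)
                grads[key] = grads[key].astype(self._dtype)
        return self

    def parameters(self) -> list[tuple[str, dict, dict]]:
        """(name, params, grads) triples for the optimizer."""
        return [
            (f"conv{i}", c.params, c.grads) for i, c in enumerate(self._conv_layers())
        ]

    # -- forward / backward -------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=self._dtype)
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError(f"expected (N, 1, H, W) input, got {x.shape}")
        skips = []
        for block, pool in zip(self.encoder, self.pools):
            x = block.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottom.forward(x, train)
        self._skip_channels = []
        for up, block, skip in zip(self.ups, self.decoder, reversed(skips)):
            x = up.forward(x, train)
            self._skip_channels.append(x.shape[1])
            x = np.concatenate([x, skip], axis=1)
            x = block.forward(x, train)
        a = self.final.forward(x, train)
        prob = 1.0 / (1.0 + np.exp(-a))
        self._prob = prob if train else None
        return prob

    __call__ = forward

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Inference: (N, 1, P, P) -> (N, P, P) probability maps."""
        return self.forward(x, train=False)[:, 0]

    def backward(self, dprob: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the output probabilities
        (chains through the sigmoid internally)."""
        assert self._prob is not None, "backward requires forward(train=True)"
        da = (dprob * self._prob * (1.0 - self._prob)).astype(self._dtype)
        dx = self.final.backward(da)
        dskips = []
        for up, block, c_up in zip(
            reversed(self.ups),
            reversed(self.decoder),
            reversed(self._skip_channels),
        ):
            dx = block.backward(dx)
            dskips.append(dx[:, c_up:])
            dx = up.backward(dx[:, :c_up])
        dx = self.bottom.backward(dx)
        # dskips was filled from the last decoder level (paired with the
        # shallowest encoder block) to the first; reverse to walk the
        # encoder deepest-first.
        for block, pool, dskip in zip(
            reversed(self.encoder), reversed(self.pools), reversed(dskips)
        ):
            dx = pool.backward(dx)
            dx = block.backward(dx + dskip)
        self._prob = None

    # -- serialization -------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Checkpoint weights (.npz) with a JSON config sidecar."""
        arrays = {}
        for name, params, _ in self.parameters():
            for key, arr in params.items():
                arrays[f"{name}.{key}"] = arr
        np.savez(path, **arrays)
        self.config.to_json(str(path) + ".json")

    @classmethod
    def load(cls, path: str | Path) -> "UNet2D":
        config = UNetConfig.from_json(str(path) + ".json")
        model = cls(config)
        with np.load(path) as data:
            for name, params, _ in model.parameters():
                for key in params:
                    params[key][...] = data[f"{name}.{key}"]
        return model

    def state_copy(self) -> dict[str, np.ndarray]:
        return {
            f"{name}.{key}": arr.copy()
            for name, params, _ in self.parameters()
            for key, arr in params.items()
        }

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for name, params, _ in self.parameters():
            for key in params:
                params[key][...] = state[f"{name}.{key}"]
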