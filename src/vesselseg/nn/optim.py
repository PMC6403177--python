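"""Adam optimizer (default moment parameters; only the learning rate is
exposed, matching how the models are parametrized)."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam"]


class Adam:
    def __init__(
        self,
        parameters: list[tuple[str, dict, dict]],
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.parameters = parameters
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {
            (name, key): np.zeros_like(arr)
            for name, params, _ in parameters
            for key, arr in params.items()
        }
        self.v = {k: np.zeros_like(v) for k, v in self.m.items()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for name, params, grads in self.parameters:
            for key in params:
                g = grads[key]
                m = self.m[(name, key)]
                v = self.v[(name, key)]
                m *= b1
                m += (1.0 - b1) * g
                v *= b2
                v += (1.0 - b2) * g * g
                update = (self.lr / bias1) * m / (np.sqrt(v / bias2) + self.eps)
                params[key] -= update.astype(params[key].dtype)
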