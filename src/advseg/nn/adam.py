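"""Adam optimiser over the explicit layer parameter dictionaries."""

from __future__ import annotations

import numpy as np


class Adam:
    """Standard Adam (beta1=0.9, beta2=0.999, eps=1e-8) on a network's layers."""

    def __init__(self, layers, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.layers = list(layers)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [
            {k: np.zeros_like(v) for k, v in layer.params.items()} for layer in self.layers
        ]
        self.v = [
            {k: np.zeros_like(v) for k, v in layer.params.items()} for layer in self.layers
        ]

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for layer, m, v in zip(self.layers, self.m, self.v):
            for key, p in layer.params.items():
                g = layer.grads[key]
                m[key] += (1 - self.beta1) * (g - m[key])
                v[key] += (1 - self.beta2) * (g * g - v[key])
                p -= self.lr * (m[key] / b1c) / (np.sqrt(v[key] / b2c) + self.eps)

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {"t": np.array(self.t)}
        for i, (m, v) in enumerate(zip(self.m, self.v)):
            for key in m:
                out[f"m{i}.{key}"] = m[key]
                out[f"v{i}.{key}"] = v[key]
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        self.t = int(state["t"])
        for i, (m, v) in enumerate(zip(self.m, self.v)):
            for key in m:
                m[key][...] = state[f"m{i}.{key}"]
                v[key][...] = state[f"v{i}.{key}"]
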