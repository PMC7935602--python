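"""Shallow VGG-style discriminator.

Four basic modules of [conv 3x3x3 stride 2 -> batch norm -> ReLU] reduce
the spatial scale 16-fold, followed by global average pooling, a dense
projection to one unit and a sigmoid.  The output is the estimated
probability that the (image, segmentation) pair came from manual
annotation.  It consumes the segmentation as 3 soft channels
concatenated with the single image channel; ground-truth labels are
one-hot encoded to the same layout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import BatchNorm3d, ConvDown3, GlobalAvgPool, Layer, Linear, ReLU


@dataclass(frozen=True)
class DiscNetSpec:
    """Architecture hyperparameters for the discriminator."""

    channels: tuple = (16, 32, 64, 128)
    image_channels: int = 1
    seg_channels: int = 3

    def __post_init__(self):
        object.__setattr__(self, "channels", tuple(int(c) for c in self.channels))
        if len(self.channels) != 4:
            raise ValueError("the discriminator uses exactly 4 basic modules")
        if any(c < 1 for c in self.channels):
            raise ValueError("channel counts must be positive")

    @property
    def in_channels(self) -> int:
        return self.image_channels + self.seg_channels


class DiscNet:
    """Trainable discriminator emitting one scalar in (0, 1) per item."""

    def __init__(self, spec: DiscNetSpec, seed: int | np.random.Generator = 0):
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        self.spec = spec
        self.modules: list[Layer] = []
        c_prev = spec.in_channels
        for c in spec.channels:
            self.modules += [ConvDown3(c_prev, c, rng), BatchNorm3d(c), ReLU()]
            c_prev = c
        self.gap = GlobalAvgPool()
        self.head = Linear(c_prev, 1, rng)

    @property
    def layers(self) -> list[Layer]:
        return [*self.modules, self.gap, self.head]

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self.layers)

    def zero_grads(self) -> None:
        for layer in self.layers:
            layer.zero_grads()

    def forward(self, image: np.ndarray, seg: np.ndarray, train: bool = True) -> np.ndarray:
        """(B,1,D,H,W) image + (B,3,D,H,W) segmentation -> (B,) probabilities."""
        if image.shape[0] != seg.shape[0] or image.shape[2:] != seg.shape[2:]:
            raise ValueError(f"misaligned image {image.shape} and segmentation {seg.shape}")
        h = np.concatenate([image, seg], axis=1)
        if not np.issubdtype(h.dtype, np.floating):
            h = h.astype(np.float32)
        for layer in self.modules:
            h = layer.forward(h, train)
        h = self.gap.forward(h, train)
        z = self.head.forward(h, train)[:, 0]
        self._p = 1.0 / (1.0 + np.exp(-z))
        return self._p

    def backward(self, gp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Backpropagate gradient w.r.t. the output probabilities.

        Returns ``(g_image, g_seg)``, the input gradients split by role;
        parameter gradients accumulate in the layers (call
        ``zero_grads`` between optimisation steps).
        """
        p = self._p
        gz = np.asarray(gp * p * (1.0 - p))[:, None]
        g = self.head.backward(gz)
        g = self.gap.backward(g)
        for layer in reversed(self.modules):
            g = layer.backward(g)
        self._p = None
        ic = self.spec.image_channels
        return g[:, :ic], g[:, ic:]

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for name, p in layer.params.items():
                out[f"L{i}.{name}"] = p
            if isinstance(layer, BatchNorm3d):
                out[f"L{i}.running_mean"] = layer.running_mean
                out[f"L{i}.running_var"] = layer.running_var
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for key, target in self.state_arrays().items():
            target[...] = state[key]


def build_discriminator(spec: DiscNetSpec, seed: int | np.random.Generator = 0) -> DiscNet:
    return DiscNet(spec, seed)


def forward_discriminate(net: DiscNet, image_block: np.ndarray, seg: np.ndarray) -> float:
    """Inference-mode score for one (image block, segmentation) pair."""
    return float(net.forward(image_block[None, None], seg[None], train=False)[0])
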