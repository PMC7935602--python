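"""3D U-Net-style encoder-decoder segmentation network.

Each encoder scale is two stacked [conv 3x3x3 (stride 1) -> batch norm ->
ReLU] units; max pooling halves the spatial scale while the channel
count doubles.  The decoder mirrors the encoder with 2x2x2 stride-2
transposed convolutions (halving channels, doubling scale) and
concatenates the same-scale encoder output before its conv pair.  A
final pointwise convolution maps to 3 class channels, followed by a
per-voxel softmax.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import (
    BatchNorm3d,
    Conv1x1,
    Conv3x3,
    ConvTranspose2,
    Layer,
    MaxPool2,
    ReLU,
    softmax_channels,
)


@dataclass(frozen=True)
class SegNetSpec:
    """Architecture hyperparameters for the segmentation network."""

    scales: int = 4
    base_channels: int = 16
    in_channels: int = 1
    n_classes: int = 3

    def __post_init__(self):
        if self.scales < 1:
            raise ValueError("scales must be >= 1")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")

    def channels_at(self, k: int) -> int:
        return self.base_channels * (2 ** k)

    def check_patch(self, patch_size: int) -> None:
        div = 2 ** (self.scales - 1)
        if patch_size % div != 0:
            raise ValueError(
                f"patch size {patch_size} not divisible by 2**(scales-1) = {div}"
            )


def _conv_block(c_in: int, c_out: int, rng) -> list[Layer]:
    return [
        Conv3x3(c_in, c_out, rng), BatchNorm3d(c_out), ReLU(),
        Conv3x3(c_out, c_out, rng), BatchNorm3d(c_out), ReLU(),
    ]


class SegNet:
    """Trainable segmenter; ``forward`` emits a per-voxel class simplex."""

    def __init__(self, spec: SegNetSpec, seed: int | np.random.Generator = 0):
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        self.spec = spec
        s = spec.scales
        self.enc_blocks: list[list[Layer]] = []
        for k in range(s):
            c_in = spec.in_channels if k == 0 else spec.channels_at(k - 1)
            self.enc_blocks.append(_conv_block(c_in, spec.channels_at(k), rng))
        self.pools = [MaxPool2() for _ in range(s - 1)]
        self.deconvs: list[ConvTranspose2] = []
        self.dec_blocks: list[list[Layer]] = []
        for k in range(s - 2, -1, -1):
            self.deconvs.append(ConvTranspose2(spec.channels_at(k + 1), spec.channels_at(k), rng))
            self.dec_blocks.append(_conv_block(2 * spec.channels_at(k), spec.channels_at(k), rng))
        self.final = Conv1x1(spec.base_channels, spec.n_classes, rng)
        self.enc_blocks[0][0].compute_input_grad = False  # input grad unused

    # -- bookkeeping ---------------------------------------------------
    @property
    def layers(self) -> list[Layer]:
        out: list[Layer] = []
        for blk in self.enc_blocks:
            out.extend(blk)
        out.extend(self.pools)
        for dc, blk in zip(self.deconvs, self.dec_blocks):
            out.append(dc)
            out.extend(blk)
        out.append(self.final)
        return out

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self.layers)

    def zero_grads(self) -> None:
        for layer in self.layers:
            layer.zero_grads()

    # -- forward / backward --------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """(B, 1, D, H, W) image blocks -> (B, 3, D, H, W) probabilities."""
        x = np.asarray(x)
        if not np.issubdtype(x.dtype, np.floating):
            x = x.astype(np.float32)
        if x.ndim != 5 or x.shape[1] != self.spec.in_channels:
            raise ValueError(f"expected (B, {self.spec.in_channels}, D, H, W), got {x.shape}")
        for d in x.shape[2:]:
            self.spec.check_patch(d)
        s = self.spec.scales
        skips = []
        h = x
        for k in range(s):
            for layer in self.enc_blocks[k]:
                h = layer.forward(h, train)
            if k < s - 1:
                skips.append(h)
                h = self.pools[k].forward(h, train)
        for idx, k in enumerate(range(s - 2, -1, -1)):
            u = self.deconvs[idx].forward(h, train)
            h = np.concatenate([u, skips[k]], axis=1)
            for layer in self.dec_blocks[idx]:
                h = layer.forward(h, train)
        z = self.final.forward(h, train)
        self._probs = softmax_channels(z)
        return self._probs

    def backward(self, gprobs: np.ndarray | None = None,
                 glogits: np.ndarray | None = None) -> np.ndarray:
        """Backpropagate gradients w.r.t. the output.

        ``gprobs`` is a gradient w.r.t. the softmax probabilities (the
        softmax Jacobian is applied internally); ``glogits`` is a
        gradient w.r.t. the pre-softmax logits, used by the fused
        cross-entropy form, and the two add.  Parameter gradients
        accumulate in the layers; returns the gradient w.r.t. the input.
        """
        p = self._probs
        gz = np.zeros_like(p)
        if gprobs is not None:
            gz = gz + p * (gprobs - (gprobs * p).sum(axis=1, keepdims=True))
        if glogits is not None:
            gz = gz + glogits
        g = self.final.backward(np.ascontiguousarray(gz))
        s = self.spec.scales
        gskips: dict[int, np.ndarray] = {}
        for idx in range(s - 2, -1, -1):  # reverse of decoder execution order
            k = s - 2 - idx
            for layer in reversed(self.dec_blocks[idx]):
                g = layer.backward(g)
            ck = self.spec.channels_at(k)
            gskips[k] = g[:, ck:]
            g = self.deconvs[idx].backward(np.ascontiguousarray(g[:, :ck]))
        for k in range(s - 1, -1, -1):
            for layer in reversed(self.enc_blocks[k]):
                g = layer.backward(g)
            if k > 0:
                g = self.pools[k - 1].backward(g)
                g = g + gskips[k - 1]
        self._probs = None
        return g

    # -- state ----------------------------------------------------------
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


def build_segmenter(spec: SegNetSpec, seed: int | np.random.Generator = 0) -> SegNet:
    return SegNet(spec, seed)


def forward_segment(net: SegNet, image_block: np.ndarray) -> np.ndarray:
    """Inference-mode forward pass on a single (D, H, W) block."""
    return net.forward(image_block[None, None], train=False)[0]
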