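"""Minimal trainable 3D layers with explicit forward/backward passes.

Every layer caches what its backward pass needs during forward; the
networks are used single-threaded and strictly in forward-then-backward
order.  Parameter gradients *accumulate* into ``grads`` so a loss made
of several forward passes (the discriminator sees a real and a fake
batch per step) can sum its contributions; call ``zero_grads`` before a
new optimisation step.
"""

from __future__ import annotations

import numpy as np

from .kernels import conv3x3_forward, conv3x3_grad_weight

F32 = np.float32


class Layer:
    """Base class: parameter-free identity."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grads(self) -> None:
        for g in self.grads.values():
            g[...] = 0

    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())


def _pad1(x: np.ndarray) -> np.ndarray:
    return np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))


class Conv3x3(Layer):
    """3x3x3 convolution, stride 1, same padding."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        fan_in = c_in * 27
        self.params = {
            "w": rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, c_in, 3, 3, 3)).astype(F32),
            "b": np.zeros(c_out, dtype=F32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.compute_input_grad = True  # the first layer of a net can skip it

    def forward(self, x, train=True):
        self._xp = _pad1(np.ascontiguousarray(x))
        out = np.empty((x.shape[0], self.params["w"].shape[0]) + x.shape[2:], dtype=x.dtype)
        conv3x3_forward(self._xp, self.params["w"].astype(x.dtype), out)
        out += self.params["b"][None, :, None, None, None]
        return out

    def backward(self, gy):
        gy = np.ascontiguousarray(gy)
        gw = np.zeros(self.grads["w"].shape, dtype=gy.dtype)
        conv3x3_grad_weight(self._xp, gy, gw)
        self.grads["w"] += gw
        self.grads["b"] += gy.sum(axis=(0, 2, 3, 4))
        if not self.compute_input_grad:
            self._xp = None
            return None
        # input gradient = conv with spatially flipped, channel-transposed kernel
        w_t = np.ascontiguousarray(
            self.params["w"][:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        ).astype(gy.dtype)
        gx = np.empty((gy.shape[0], w_t.shape[0]) + gy.shape[2:], dtype=gy.dtype)
        conv3x3_forward(_pad1(gy), w_t, gx)
        self._xp = None
        return gx


class ConvDown3(Layer):
    """3x3x3 convolution, stride 2, pad 1: halves each (even) spatial dim."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        fan_in = c_in * 27
        self.params = {
            "w": rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, c_in, 3, 3, 3)).astype(F32),
            "b": np.zeros(c_out, dtype=F32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    @staticmethod
    def _slices(i, j, k, do, ho, wo):
        return (
            slice(i, i + 2 * do - 1, 2),
            slice(j, j + 2 * ho - 1, 2),
            slice(k, k + 2 * wo - 1, 2),
        )

    def forward(self, x, train=True):
        B, C, D, H, W = x.shape
        if D % 2 or H % 2 or W % 2:
            raise ValueError(f"ConvDown3 needs even spatial dims, got {(D, H, W)}")
        do, ho, wo = D // 2, H // 2, W // 2
        self._xp = _pad1(np.ascontiguousarray(x))
        w = self.params["w"].astype(x.dtype)
        out = np.zeros((B, w.shape[0], do, ho, wo), dtype=x.dtype)
        of = out.reshape(B, w.shape[0], -1)
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    sd, sh, sw = self._slices(i, j, k, do, ho, wo)
                    xs = self._xp[:, :, sd, sh, sw].reshape(B, C, -1)
                    of += np.matmul(w[:, :, i, j, k], xs)
        out += self.params["b"][None, :, None, None, None]
        self._out_shape = (do, ho, wo)
        return out

    def backward(self, gy):
        B, O, do, ho, wo = gy.shape
        gy = np.ascontiguousarray(gy)
        gyf = gy.reshape(B, O, -1)
        w = self.params["w"]
        C = w.shape[1]
        gxp = np.zeros_like(self._xp)
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    sd, sh, sw = self._slices(i, j, k, do, ho, wo)
                    xs = self._xp[:, :, sd, sh, sw].reshape(B, C, -1)
                    self.grads["w"][:, :, i, j, k] += np.einsum("bon,bcn->oc", gyf, xs)
                    gxp[:, :, sd, sh, sw] += np.matmul(w[:, :, i, j, k].T, gyf).reshape(
                        B, C, do, ho, wo
                    )
        self.grads["b"] += gy.sum(axis=(0, 2, 3, 4))
        self._xp = None
        return gxp[:, :, 1:-1, 1:-1, 1:-1]


class Conv1x1(Layer):
    """Pointwise channel-mixing convolution."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.params = {
            "w": rng.normal(0.0, np.sqrt(1.0 / c_in), (c_out, c_in)).astype(F32),
            "b": np.zeros(c_out, dtype=F32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, train=True):
        B, C = x.shape[:2]
        self._x = x
        out = np.matmul(self.params["w"], x.reshape(B, C, -1)).reshape(
            (B, self.params["w"].shape[0]) + x.shape[2:]
        )
        out += self.params["b"][None, :, None, None, None]
        return out

    def backward(self, gy):
        B, O = gy.shape[:2]
        gyf = gy.reshape(B, O, -1)
        xf = self._x.reshape(B, self._x.shape[1], -1)
        self.grads["w"] += np.einsum("bon,bcn->oc", gyf, xf)
        self.grads["b"] += gy.sum(axis=(0, 2, 3, 4))
        gx = np.matmul(self.params["w"].T, gyf).reshape(self._x.shape)
        self._x = None
        return gx


class ConvTranspose2(Layer):
    """2x2x2 transposed convolution, stride 2: doubles each spatial dim."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        fan_in = c_in  # each output voxel receives one kernel tap per input channel
        self.params = {
            "w": rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_in, c_out, 2, 2, 2)).astype(F32),
            "b": np.zeros(c_out, dtype=F32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, train=True):
        B, C, D, H, W = x.shape
        O = self.params["w"].shape[1]
        self._x = x
        xf = x.reshape(B, C, -1)
        out = np.empty((B, O, 2 * D, 2 * H, 2 * W), dtype=x.dtype)
        for i in range(2):
            for j in range(2):
                for k in range(2):
                    wk = self.params["w"][:, :, i, j, k]
                    out[:, :, i::2, j::2, k::2] = np.matmul(wk.T, xf).reshape(B, O, D, H, W)
        out += self.params["b"][None, :, None, None, None]
        return out

    def backward(self, gy):
        B, O = gy.shape[:2]
        C, D = self._x.shape[1], self._x.shape[2]
        H, W = self._x.shape[3], self._x.shape[4]
        xf = self._x.reshape(B, C, -1)
        gx = np.zeros_like(self._x)
        gxf = gx.reshape(B, C, -1)
        for i in range(2):
            for j in range(2):
                for k in range(2):
                    gys = np.ascontiguousarray(gy[:, :, i::2, j::2, k::2]).reshape(B, O, -1)
                    self.grads["w"][:, :, i, j, k] += np.einsum("bcn,bon->co", xf, gys)
                    gxf += np.matmul(self.params["w"][:, :, i, j, k], gys)
        self.grads["b"] += gy.sum(axis=(0, 2, 3, 4))
        self._x = None
        return gx


class BatchNorm3d(Layer):
    """Per-channel batch normalisation with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.params = {
            "gamma": np.ones(channels, dtype=F32),
            "beta": np.zeros(channels, dtype=F32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(channels, dtype=F32)
        self.running_var = np.ones(channels, dtype=F32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, train=True):
        sh = (1, -1, 1, 1, 1)
        self._train = train
        if train:
            mean = x.mean(axis=(0, 2, 3, 4))
            var = x.var(axis=(0, 2, 3, 4))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean = self.running_mean
            var = self.running_var
        self._ivar = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean.reshape(sh)) * self._ivar.reshape(sh)
        self._m = x.size // x.shape[1]
        return self.params["gamma"].reshape(sh) * self._xhat + self.params["beta"].reshape(sh)

    def backward(self, gy):
        sh = (1, -1, 1, 1, 1)
        m = self._m
        self.grads["gamma"] += (gy * self._xhat).sum(axis=(0, 2, 3, 4))
        self.grads["beta"] += gy.sum(axis=(0, 2, 3, 4))
        gxhat = gy * self.params["gamma"].reshape(sh)
        if self._train:
            t1 = gxhat.sum(axis=(0, 2, 3, 4)).reshape(sh)
            t2 = (gxhat * self._xhat).sum(axis=(0, 2, 3, 4)).reshape(sh)
            gx = (self._ivar.reshape(sh) / m) * (m * gxhat - t1 - self._xhat * t2)
        else:
            # running statistics are constants: the map is affine per channel
            gx = gxhat * self._ivar.reshape(sh)
        self._xhat = None
        return np.ascontiguousarray(gx)


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, x * 0)

    def backward(self, gy):
        gx = np.where(self._mask, gy, gy * 0)
        self._mask = None
        return gx


class MaxPool2(Layer):
    """2x2x2 max pooling, stride 2."""

    def forward(self, x, train=True):
        B, C, D, H, W = x.shape
        if D % 2 or H % 2 or W % 2:
            raise ValueError(f"MaxPool2 needs even spatial dims, got {(D, H, W)}")
        xr = x.reshape(B, C, D // 2, 2, H // 2, 2, W // 2, 2)
        xr = xr.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(B, C, D // 2, H // 2, W // 2, 8)
        self._arg = np.argmax(xr, axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(xr, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, gy):
        B, C, D, H, W = self._in_shape
        g = np.zeros((B, C, D // 2, H // 2, W // 2, 8), dtype=gy.dtype)
        np.put_along_axis(g, self._arg[..., None], gy[..., None], axis=-1)
        g = g.reshape(B, C, D // 2, H // 2, W // 2, 2, 2, 2).transpose(0, 1, 2, 5, 3, 6, 4, 7)
        self._arg = None
        return np.ascontiguousarray(g.reshape(B, C, D, H, W))


class GlobalAvgPool(Layer):
    """Mean over spatial axes: (B, C, D, H, W) -> (B, C)."""

    def forward(self, x, train=True):
        self._in_shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, gy):
        B, C, D, H, W = self._in_shape
        return np.ascontiguousarray(np.broadcast_to(
            gy[:, :, None, None, None] / (D * H * W), self._in_shape
        ))


class Linear(Layer):
    """Dense layer on (B, C) activations."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.params = {
            "w": rng.normal(0.0, np.sqrt(1.0 / c_in), (c_out, c_in)).astype(F32),
            "b": np.zeros(c_out, dtype=F32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, train=True):
        self._x = x
        return x @ self.params["w"].T + self.params["b"]

    def backward(self, gy):
        self.grads["w"] += gy.T @ self._x
        self.grads["b"] += gy.sum(axis=0)
        gx = gy @ self.params["w"]
        self._x = None
        return gx


def softmax_channels(z: np.ndarray) -> np.ndarray:
    """Per-voxel softmax over the channel axis of (B, C, D, H, W)."""
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)
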