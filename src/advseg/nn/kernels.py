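"""JIT-compiled inner loops for 3x3x3 stride-1 convolution.

Layout is channel-first (B, C, D, H, W) with the last axis contiguous so
the innermost loops vectorise.  Inputs arrive pre-padded by one voxel on
each spatial side.  Both kernels keep an output-channel-blocked
accumulator resident in cache while streaming each input row once.  The
input gradient of a stride-1 convolution is itself a stride-1
convolution with the spatially flipped, channel-transposed kernel, so
only forward and weight-gradient kernels exist.
"""

import numpy as np
from numba import njit


@njit(fastmath=True, cache=True)
def conv3x3_forward(xp, w, out):
    # xp: (B, C, D+2, H+2, W+2); w: (O, C, 3, 3, 3); out: (B, O, D, H, W)
    B, O, D, H, W = out.shape
    C = xp.shape[1]
    acc = np.empty((O, W), dtype=xp.dtype)
    for b in range(B):
        for d in range(D):
            for h in range(H):
                for o in range(O):
                    for k in range(W):
                        acc[o, k] = 0.0
                for c in range(C):
                    for i in range(3):
                        for j in range(3):
                            row = xp[b, c, d + i, h + j]
                            for o in range(O):
                                w0 = w[o, c, i, j, 0]
                                w1 = w[o, c, i, j, 1]
                                w2 = w[o, c, i, j, 2]
                                for k in range(W):
                                    acc[o, k] += w0 * row[k] + w1 * row[k + 1] + w2 * row[k + 2]
                for o in range(O):
                    for k in range(W):
                        out[b, o, d, h, k] = acc[o, k]


@njit(fastmath=True, cache=True)
def conv3x3_grad_weight(xp, gy, gw):
    # xp: padded input; gy: (B, O, D, H, W); gw: (O, C, 3, 3, 3) accumulated
    B, O, D, H, W = gy.shape
    C = xp.shape[1]
    acc = np.zeros((O, C, 3, 3, 3), dtype=gy.dtype)
    for b in range(B):
        for d in range(D):
            for h in range(H):
                for o in range(O):
                    g = gy[b, o, d, h]
                    for c in range(C):
                        for i in range(3):
                            for j in range(3):
                                row = xp[b, c, d + i, h + j]
                                a0 = g[0] * 0.0
                                a1 = a0
                                a2 = a0
                                for k in range(W):
                                    a0 += g[k] * row[k]
                                    a1 += g[k] * row[k + 1]
                                    a2 += g[k] * row[k + 2]
                                acc[o, c, i, j, 0] += a0
                                acc[o, c, i, j, 1] += a1
                                acc[o, c, i, j, 2] += a2
    gw += acc
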