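"""Standardization, block extraction, axial dihedral augmentation and
overlap-averaged reassembly.

Blocks are cubes of ``patch_size`` voxels per side.  Training samples
them at uniformly random offsets; inference tiles the volume with a
regular grid whose final origin per axis is clamped so the last block
abuts the boundary, guaranteeing full coverage without padding.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .types import LabelMap, Volume


def standardize(volume: Volume) -> Volume:
    """Z-score a volume: subtract the mean, divide by the *sample*
    standard deviation (n-1 denominator).

    Raises
    ------
    ValueError
        If the volume is constant (zero sample standard deviation) or
        has fewer than two voxels.
    """
    x = np.asarray(volume.data, dtype=np.float64)
    if x.size < 2:
        raise ValueError("standardize requires at least 2 voxels")
    mean = x.mean()
    s = x.std(ddof=1)
    if s == 0 or not np.isfinite(s):
        raise ValueError("cannot standardize a constant volume (zero sample std)")
    return Volume(data=((x - mean) / s).astype(np.float32), spacing=volume.spacing)


@dataclass(frozen=True)
class PatchPair:
    """An image block and the label block cut at the same offsets."""

    image: np.ndarray
    labels: np.ndarray
    origin: tuple[int, int, int]

    def __post_init__(self):
        if self.image.shape != self.labels.shape:
            raise ValueError("image and label blocks must share a shape")


def sample_random_patch(
    volume: Volume | np.ndarray,
    labels: LabelMap | np.ndarray,
    patch_size: int,
    rng: np.random.Generator,
) -> PatchPair:
    """Cut a ``patch_size**3`` block at a uniformly random origin.

    Each axis offset is drawn independently from ``[0, dim - patch_size]``
    inclusive; the label block is cut at the identical offsets.
    """
    img = volume.data if isinstance(volume, Volume) else np.asarray(volume)
    lab = labels.data if isinstance(labels, LabelMap) else np.asarray(labels)
    if img.shape != lab.shape:
        raise ValueError(f"volume {img.shape} and labels {lab.shape} must share a shape")
    if any(d < patch_size for d in img.shape):
        raise ValueError(f"volume shape {img.shape} smaller than patch size {patch_size}")
    origin = tuple(int(rng.integers(0, d - patch_size + 1)) for d in img.shape)
    sl = tuple(slice(o, o + patch_size) for o in origin)
    return PatchPair(image=img[sl].copy(), labels=lab[sl].copy(), origin=origin)


@dataclass(frozen=True)
class AugmentOp:
    """One element of the order-8 axial dihedral-like group.

    ``rot_quarters`` rotates the axial plane (last two axes) by that many
    quarter turns about axis 0; ``flip`` mirrors across the axial plane
    (reverses axis 0).  Both are pure index permutations, so integer
    labels pass through unchanged.
    """

    rot_quarters: int = 0
    flip: bool = False

    def __post_init__(self):
        if self.rot_quarters not in (0, 1, 2, 3):
            raise ValueError(f"rot_quarters must be in 0..3, got {self.rot_quarters}")

    def apply(self, block: np.ndarray) -> np.ndarray:
        out = block
        if self.flip:
            out = out[::-1]
        if self.rot_quarters:
            out = np.rot90(out, k=self.rot_quarters, axes=(-2, -1))
        return np.ascontiguousarray(out)

    def inverse(self) -> "AugmentOp":
        # flip commutes with the in-plane rotation, so the inverse just
        # reverses the rotation count
        return AugmentOp(rot_quarters=(-self.rot_quarters) % 4, flip=self.flip)

    def compose(self, other: "AugmentOp") -> "AugmentOp":
        """The op equivalent to applying ``self`` after ``other``."""
        return AugmentOp(
            rot_quarters=(self.rot_quarters + other.rot_quarters) % 4,
            flip=self.flip ^ other.flip,
        )


ALL_AUGMENTS: tuple[AugmentOp, ...] = tuple(
    AugmentOp(rot_quarters=r, flip=f) for f in (False, True) for r in range(4)
)


def apply_augment(pair: PatchPair, op: AugmentOp) -> PatchPair:
    """Transform image and label blocks by the identical spatial map."""
    return PatchPair(image=op.apply(pair.image), labels=op.apply(pair.labels), origin=pair.origin)


def random_augment(rng: np.random.Generator) -> AugmentOp:
    """Draw one of the 8 ops uniformly."""
    return ALL_AUGMENTS[int(rng.integers(0, len(ALL_AUGMENTS)))]


@dataclass(frozen=True)
class PatchGrid:
    """Ordered block origins tiling a volume with a fixed stride."""

    origins: tuple[tuple[int, int, int], ...]
    patch_size: int
    stride: int
    shape: tuple[int, int, int]


def _axis_origins(dim: int, patch_size: int, stride: int) -> list[int]:
    origins = list(range(0, dim - patch_size + 1, stride))
    if origins[-1] != dim - patch_size:
        origins.append(dim - patch_size)
    return origins


def make_grid(shape: tuple[int, int, int], patch_size: int, stride: int) -> PatchGrid:
    """Regular overlapping grid covering every voxel of ``shape``.

    Per axis the origins are 0, stride, 2*stride, ... with the final
    origin clamped to ``dim - patch_size`` so the last block abuts the
    boundary.
    """
    if any(d < patch_size for d in shape):
        raise ValueError(f"shape {shape} smaller than patch size {patch_size}")
    if not (0 < stride <= patch_size):
        raise ValueError(f"stride must satisfy 0 < stride <= patch_size, got {stride}")
    per_axis = [_axis_origins(d, patch_size, stride) for d in shape]
    origins = tuple(product(*per_axis))
    return PatchGrid(origins=origins, patch_size=patch_size, stride=stride, shape=tuple(shape))


def extract_blocks(data: np.ndarray, grid: PatchGrid) -> list[np.ndarray]:
    """Cut the grid's blocks out of a volume-shaped array.

    Works on 3D arrays and on channel-first 4D arrays (channels kept whole).
    """
    blocks = []
    for origin in grid.origins:
        sl = tuple(slice(o, o + grid.patch_size) for o in origin)
        if data.ndim == 4:
            blocks.append(data[(slice(None),) + sl].copy())
        else:
            blocks.append(data[sl].copy())
    return blocks


def assemble(prob_blocks: list[np.ndarray], grid: PatchGrid, shape: tuple[int, int, int]) -> np.ndarray:
    """Average overlapping per-block probability maps into a full map.

    Each voxel's class vector is the arithmetic mean over every block
    covering it, so the result stays on the probability simplex whenever
    the inputs do.
    """
    if len(prob_blocks) != len(grid.origins):
        raise ValueError(
            f"got {len(prob_blocks)} blocks for {len(grid.origins)} grid origins"
        )
    n_channels = prob_blocks[0].shape[0]
    p = grid.patch_size
    acc = np.zeros((n_channels,) + tuple(shape), dtype=np.float64)
    count = np.zeros(shape, dtype=np.int32)
    for block, origin in zip(prob_blocks, grid.origins):
        if block.shape != (n_channels, p, p, p):
            raise ValueError(f"block shape {block.shape} != ({n_channels},{p},{p},{p})")
        sl = tuple(slice(o, o + p) for o in origin)
        acc[(slice(None),) + sl] += block
        count[sl] += 1
    if (count == 0).any():
        raise ValueError("grid does not cover the volume")  # unreachable for make_grid output
    return (acc / count).astype(np.float32)
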