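"""Synthetic cardiac-like phantoms: a bright blood-pool blob, a thin
myocardial shell of intermediate intensity, Gaussian noise and a smooth
multiplicative intensity inhomogeneity.

The geometry is a union of axis-aligned ellipsoids (the "blood pool")
whose Euclidean boundary band of configurable thickness forms the
"myocardium" shell — deliberately simple so every property (shell voxel
counts, adjacency, class ordering) can be verified by brute force, while
still exhibiting the features that make thin-walled cardiac structures
hard to segment: a thin intermediate-intensity shell between a bright
pool and a dark background, under noise and bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .types import BACKGROUND, BLOOD_POOL, MYOCARDIUM, LabelMap, Volume


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters for one phantom case.

    Intensity means must be ordered background < shell < pool; the noise
    standard deviation and the multiplicative bias amplitude control how
    far the observed intensity classes overlap.
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    n_lobes: int = 3
    shell_thickness: float = 3.0
    mean_background: float = 0.15
    mean_shell: float = 0.50
    mean_pool: float = 0.95
    noise_sigma: float = 0.05
    bias_amplitude: float = 0.10
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(d) for d in self.shape))
        if len(self.shape) != 3 or any(d < 64 for d in self.shape):
            raise ValueError(f"shape must be 3D with every axis >= 64, got {self.shape}")
        if self.shell_thickness < 1:
            raise ValueError("shell_thickness must be >= 1 voxel")
        if not (self.mean_background < self.mean_shell < self.mean_pool):
            raise ValueError("class means must be ordered background < shell < pool")
        if self.n_lobes < 1:
            raise ValueError("n_lobes must be >= 1")
        if self.noise_sigma < 0 or self.bias_amplitude < 0:
            raise ValueError("noise_sigma and bias_amplitude must be >= 0")


@dataclass(frozen=True)
class PhantomCase:
    """A generated volume, its ground-truth labels and the spec used."""

    volume: Volume
    labels: LabelMap
    spec: PhantomSpec


def _ellipsoid_mask(shape, center, semiaxes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, d) for d in shape)]
    acc = np.zeros(shape, dtype=np.float64)
    for g, c, a in zip(grids, center, semiaxes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def _bias_field(shape, amplitude, rng) -> np.ndarray:
    """Smooth multiplicative field 1 + amplitude * q(z,y,x), where q is a
    random quadratic polynomial in centred, normalised coordinates with
    max |q| = 1."""
    coords = [
        (np.arange(d, dtype=np.float64) - (d - 1) / 2) / d for d in shape
    ]
    z, y, x = np.meshgrid(*coords, indexing="ij", sparse=True)
    c = rng.uniform(-1.0, 1.0, size=10)
    q = (
        c[0] + c[1] * z + c[2] * y + c[3] * x
        + c[4] * z * y + c[5] * z * x + c[6] * y * x
        + c[7] * z * z + c[8] * y * y + c[9] * x * x
    )
    peak = np.abs(q).max()
    if peak > 0:
        q = q / peak
    return 1.0 + amplitude * q


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Generate one phantom, fully determined by ``spec`` (incl. its seed).

    The blood-pool mask is a union of ellipsoids; the myocardial shell is
    the band of voxels outside the pool whose Euclidean distance to the
    pool is at most ``shell_thickness`` (a Euclidean-ball dilation minus
    the pool itself).
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    center0 = np.array([d / 2 for d in shape]) + rng.uniform(-6, 6, 3)
    semi0 = rng.uniform(18, 24, 3)
    pool = _ellipsoid_mask(shape, center0, semi0)
    for _ in range(spec.n_lobes - 1):
        center = center0 + rng.uniform(-14, 14, 3)
        semi = rng.uniform(12, 18, 3)
        pool |= _ellipsoid_mask(shape, center, semi)

    dist = ndimage.distance_transform_edt(~pool)
    shell = (dist <= spec.shell_thickness) & ~pool

    labels = np.zeros(shape, dtype=np.int16)
    labels[shell] = MYOCARDIUM
    labels[pool] = BLOOD_POOL

    means = np.array([spec.mean_background, spec.mean_shell, spec.mean_pool])
    data = means[labels]
    if spec.bias_amplitude > 0:
        data = data * _bias_field(shape, spec.bias_amplitude, rng)
    if spec.noise_sigma > 0:
        data = data + rng.normal(0.0, spec.noise_sigma, shape)

    case = PhantomCase(
        volume=Volume(data=data.astype(np.float32)),
        labels=LabelMap(data=labels),
        spec=spec,
    )
    present = set(np.unique(labels).tolist())
    if present != {BACKGROUND, MYOCARDIUM, BLOOD_POOL}:
        raise ValueError(f"degenerate phantom: classes present {sorted(present)}")
    return case


def generate_dataset(
    n_cases: int,
    seed: int = 0,
    spec: PhantomSpec | None = None,
    lobes_range: tuple[int, int] = (2, 4),
    thickness_range: tuple[float, float] = (2.0, 4.0),
) -> list[PhantomCase]:
    """Generate ``n_cases`` independent phantoms with per-case derived seeds.

    Per-case lobe counts and shell thicknesses are drawn uniformly from
    the given inclusive ranges; everything else comes from ``spec``.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    lo, hi = lobes_range
    tlo, thi = thickness_range
    if lo < 1 or hi < lo or tlo < 1 or thi < tlo:
        raise ValueError("invalid lobes_range or thickness_range")
    base = spec or PhantomSpec()
    master = np.random.SeedSequence(seed)
    cases = []
    for child in master.spawn(n_cases):
        rng = np.random.default_rng(child)
        case_seed = int(rng.integers(0, 2**31 - 1))
        case_spec = replace(
            base,
            n_lobes=int(rng.integers(lo, hi + 1)),
            shell_thickness=float(rng.uniform(tlo, thi)),
            seed=case_seed,
        )
        cases.append(generate_phantom(case_spec))
    return cases
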