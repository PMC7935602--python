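"""Core in-memory containers for volumetric images and their annotations.

Axis convention
---------------
All 3D arrays in this package are indexed ``(z, y, x)`` where the *axial
plane* is spanned by the last two axes.  In-plane augmentation rotates
about axis 0; the "symmetric flip about the axial plane" mirrors axis 0.
Loaders normalise external data to this order once, at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Integer class ids used throughout the package.
BACKGROUND, MYOCARDIUM, BLOOD_POOL = 0, 1, 2
N_CLASSES = 3
CLASS_NAMES = {BACKGROUND: "background", MYOCARDIUM: "myocardium", BLOOD_POOL: "blood_pool"}


@dataclass
class Volume:
    """A 3D scalar image with per-axis voxel spacing in millimetres.

    Parameters
    ----------
    data : ndarray of shape (D, H, W)
        Real-valued intensities; must be finite.
    spacing : tuple of 3 floats
        Voxel size along each axis, mm; strictly positive.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got {self.data.ndim}D")
        if min(self.data.shape) < 1:
            raise ValueError(f"every dimension must be >= 1, got {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume intensities must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive numbers, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelMap:
    """A voxel-wise 3-class annotation aligned to a :class:`Volume`.

    Values are 0 = background, 1 = myocardium, 2 = blood pool.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"LabelMap data must be 3D, got {self.data.ndim}D")
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if not np.array_equal(rounded, self.data):
                raise ValueError("LabelMap values must be integral")
            self.data = rounded.astype(np.int16)
        bad = np.setdiff1d(np.unique(self.data), [BACKGROUND, MYOCARDIUM, BLOOD_POOL])
        if bad.size:
            raise ValueError(f"label values must be in {{0,1,2}}, found {bad.tolist()}")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def check_aligned(self, volume: Volume) -> None:
        if self.data.shape != volume.data.shape:
            raise ValueError(
                f"label shape {self.data.shape} does not match volume shape {volume.data.shape}"
            )


def one_hot(labels: np.ndarray, n_classes: int = N_CLASSES) -> np.ndarray:
    """Encode an integer label block as ``(n_classes, *spatial)`` float32."""
    labels = np.asarray(labels)
    out = np.zeros((n_classes,) + labels.shape, dtype=np.float32)
    for c in range(n_classes):
        out[c] = labels == c
    return out
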