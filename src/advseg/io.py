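"""NIfTI reading and writing for volumes and label maps.

nibabel stores data in (x, y, z) Fortran-style order with axial slices in
the first two axes for an identity affine; this package uses (z, y, x)
with the axial plane in the *last* two axes, so arrays are transposed at
the boundary in both directions.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .types import LabelMap, Volume


def _to_canonical(data: np.ndarray) -> np.ndarray:
    # nibabel (x, y, z) -> package (z, y, x)
    return np.ascontiguousarray(np.transpose(data, (2, 1, 0)))


def _from_canonical(data: np.ndarray) -> np.ndarray:
    return np.transpose(data, (2, 1, 0))


def load_volume(path: str | Path) -> Volume:
    """Read a 3D NIfTI file as a :class:`Volume`.

    Spacing is taken from the header zooms and reordered to the package's
    (z, y, x) convention.

    Raises
    ------
    IOError
        If the file cannot be read.
    ValueError
        If the image is not 3D.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several error types
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return Volume(data=_to_canonical(np.asarray(data, dtype=np.float32)), spacing=spacing)


def load_labels(path: str | Path, remap: dict[int, int] | None = None) -> LabelMap:
    """Read a 3D NIfTI label image as a :class:`LabelMap`.

    Parameters
    ----------
    remap : dict, optional
        Mapping from on-disk integer codes to the package's
        0/1/2 = background/myocardium/blood-pool convention, applied
        before validation.  External datasets that code the classes
        differently are normalised here, at load time.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D label image, got {data.ndim}D")
    data = np.rint(np.asarray(data)).astype(np.int16)
    if remap:
        out = np.full_like(data, -1)
        for src, dst in remap.items():
            out[data == src] = dst
        if (out < 0).any():
            missing = np.unique(data[out < 0]).tolist()
            raise ValueError(f"{path}: label codes {missing} missing from remap table")
        data = out
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return LabelMap(data=_to_canonical(data), spacing=spacing)


def save_volume(obj: Volume | LabelMap, path: str | Path) -> None:
    """Write a Volume (float32) or LabelMap (int16) to a NIfTI file.

    The voxel spacing is stored in the affine diagonal and header zooms,
    so a save → load round trip preserves both data and spacing.
    """
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    if isinstance(obj, LabelMap):
        data = obj.data.astype(np.int16)
    elif isinstance(obj, Volume):
        data = obj.data.astype(np.float32)
    else:
        raise TypeError(f"expected Volume or LabelMap, got {type(obj)!r}")
    sx, sy, sz = obj.spacing[2], obj.spacing[1], obj.spacing[0]
    affine = np.diag([sx, sy, sz, 1.0])
    img = nib.Nifti1Image(_from_canonical(data), affine)
    img.header.set_zooms((sx, sy, sz))
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise IOError(f"cannot write NIfTI file {path}: {exc}") from exc
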