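"""Slice-stack volume I/O and intensity projections.

A volume is a stack of 2D grayscale slice images, one per horizontal
soil plane, held as a (z, y, x)-indexed array of 8-bit intensities.
``z`` increases with soil depth: ``z = 0`` is the topmost slice.  Node
coordinates are continuous and expressed publicly in (x, y, z) voxel
units; voxel ``(z, y, x)`` occupies the half-open cube
``[z, z+1) x [y, y+1) x [x, x+1)``, so its centre sits at index + 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

log = logging.getLogger(__name__)

#: file extensions recognised as volume slices (lower case)
SUPPORTED_EXTENSIONS = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}

_AXIS_INDEX = {"z": 0, "y": 1, "x": 2}


@dataclass
class Volume:
    """A segmented root volume: 8-bit intensities plus voxel resolution.

    Parameters
    ----------
    intensities:
        ``(depth, height, width)`` array of ``uint8`` values indexed
        ``(z, y, x)``; bright voxels are root.
    resolution_mm:
        Isotropic voxel edge length in mm/voxel (``r``); must be > 0.
    """

    intensities: np.ndarray
    resolution_mm: float

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError("volume intensities must be a 3D (z, y, x) array")
        if self.intensities.dtype != np.uint8:
            raise ValueError("volume intensities must be 8-bit (uint8)")
        if not self.resolution_mm > 0:
            raise ValueError("resolution must be > 0 mm/voxel")

    @property
    def shape(self) -> tuple[int, int, int]:
        """(depth, height, width) in voxels."""
        return self.intensities.shape  # type: ignore[return-value]

    def contains_point(self, xyz) -> bool:
        """True if an (x, y, z) coordinate lies inside the volume extent."""
        x, y, z = float(xyz[0]), float(xyz[1]), float(xyz[2])
        d, h, w = self.shape
        return 0.0 <= x <= w and 0.0 <= y <= h and 0.0 <= z <= d


def _to_gray_uint8(img: np.ndarray, name: str) -> np.ndarray:
    if img.ndim == 3:  # colour image: collapse channels to luminance
        img = img[..., :3].mean(axis=-1)
    if img.ndim != 2:
        raise ValueError(f"inconsistent slice dimensions: {name} is not a 2D image")
    if img.dtype == np.uint8:
        return img
    log.warning("%s is not 8-bit (%s); rescaling to uint8", name, img.dtype)
    img = img.astype(np.float64)
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros(img.shape, dtype=np.uint8)
    return np.round((img - lo) / (hi - lo) * 255.0).astype(np.uint8)


def load_volume(directory, resolution_mm: float) -> Volume:
    """Read a directory of grayscale slice images into a :class:`Volume`.

    Slices are stacked in lexicographic filename order; the stack position
    becomes the ``z`` index.  8-bit input values are preserved exactly;
    other bit depths are min-max rescaled to 8-bit with a logged warning.

    Raises
    ------
    ValueError
        ``"no slices found"`` for an empty directory,
        ``"inconsistent slice dimensions"`` when shapes differ.
    """
    directory = Path(directory)
    files = sorted(
        p for p in directory.iterdir()
        if p.is_file() and p.suffix.lower() in SUPPORTED_EXTENSIONS
    )
    if not files:
        raise ValueError(f"no slices found in {directory}")
    slices = []
    for p in files:
        img = _to_gray_uint8(iio.imread(p), p.name)
        if slices and img.shape != slices[0].shape:
            raise ValueError(
                f"inconsistent slice dimensions: {p.name} is {img.shape}, "
                f"expected {slices[0].shape}"
            )
        slices.append(img)
    return Volume(np.stack(slices, axis=0), resolution_mm)


def write_volume(volume: Volume, directory) -> list[Path]:
    """Write a volume as one zero-padded 8-bit PNG per slice.

    Files are named ``slice_0000.png``, ``slice_0001.png``, ... so that
    :func:`load_volume` reconstructs the identical stack.
    """
    if volume.shape[0] == 0:
        raise ValueError("empty volume")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for z in range(volume.shape[0]):
        path = directory / f"slice_{z:04d}.png"
        iio.imwrite(path, volume.intensities[z])
        paths.append(path)
    return paths


def project(volume: Volume, axis: str = "z", mode: str = "max") -> np.ndarray:
    """Collapse the volume along one axis into a 2D 8-bit image.

    ``mode="max"`` gives a maximum-intensity projection (the usual quick
    look at a root system); ``mode="mean"`` an average-intensity one.
    """
    if axis not in _AXIS_INDEX:
        raise ValueError(f"axis must be one of z, y, x; got {axis!r}")
    if mode == "max":
        return volume.intensities.max(axis=_AXIS_INDEX[axis])
    if mode == "mean":
        return np.round(
            volume.intensities.mean(axis=_AXIS_INDEX[axis])
        ).astype(np.uint8)
    raise ValueError(f"mode must be 'max' or 'mean'; got {mode!r}")


def save_projection(volume: Volume, path, axis: str = "z", mode: str = "max") -> Path:
    """Write a projection image to ``path`` as PNG and return the path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, project(volume, axis=axis, mode=mode))
    return path
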