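"""Raster containers and file I/O for spherical panoramas.

A panoramic street scene lives on the unit sphere.  Two pixel geometries are
supported:

* ``equirectangular`` — the native output of consumer panoramic cameras:
  longitude and latitude are linear in pixel coordinates, the aspect ratio is
  exactly 2:1, and every pixel is valid.  Pixel *area* over-represents high
  latitudes by ``1/cos(lat)``.
* ``hammer`` — the Hammer equal-area ellipse used for auditing.  Only pixels
  inside the ellipse carry data; the validity mask travels with the raster.
  Equal pixel counts correspond to equal solid angles.

Rasters carry either RGB values ``(H, W, 3)`` or integer category labels
``(H, W)``.  Label files use the reserved value :data:`MASK_LABEL` for
out-of-ellipse pixels and are accompanied by a small YAML sidecar recording
the geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

EQUIRECTANGULAR = "equirectangular"
HAMMER = "hammer"
GEOMETRIES = (EQUIRECTANGULAR, HAMMER)

#: Reserved label value marking out-of-ellipse pixels in label files.
MASK_LABEL = 255


@dataclass
class SphericalRaster:
    """A pixel grid tagged with its spherical geometry.

    Parameters
    ----------
    values
        ``(H, W)`` integer labels or ``(H, W, 3)`` RGB samples.
    geometry
        ``"equirectangular"`` (requires ``W == 2 * H``) or ``"hammer"``.
    mask
        Boolean per-pixel validity.  ``None`` means all-valid, which is the
        only sensible choice for equirectangular grids; Hammer rasters carry
        the ellipse-interior mask.
    """

    values: np.ndarray
    geometry: str = EQUIRECTANGULAR
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.geometry not in GEOMETRIES:
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.values.ndim == 3:
            if self.values.shape[2] != 3:
                raise ValueError("RGB raster must have exactly 3 channels")
        elif self.values.ndim != 2:
            raise ValueError("raster values must be (H, W) or (H, W, 3)")
        h, w = self.values.shape[:2]
        if self.geometry == EQUIRECTANGULAR and w != 2 * h:
            raise ValueError(
                f"equirectangular raster must have 2:1 aspect, got {w}x{h}"
            )
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (h, w):
                raise ValueError("mask shape does not match raster shape")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def is_rgb(self) -> bool:
        return self.values.ndim == 3

    @property
    def is_categorical(self) -> bool:
        return self.values.ndim == 2

    def valid_mask(self) -> np.ndarray:
        """Boolean validity mask (all-``True`` when no mask is stored)."""
        if self.mask is None:
            return np.ones(self.values.shape[:2], dtype=bool)
        return self.mask


def lon_centers(width: int) -> np.ndarray:
    """Longitudes (rad) of pixel-column centers; column 0 is lon = -pi side."""
    return -np.pi + (np.arange(width) + 0.5) * (2.0 * np.pi / width)


def lat_centers(height: int) -> np.ndarray:
    """Latitudes (rad) of pixel-row centers; row 0 is the +pi/2 (sky) side."""
    return np.pi / 2.0 - (np.arange(height) + 0.5) * (np.pi / height)


# ---------------------------------------------------------------------------
# File I/O


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def read_rgb(path: str | Path, geometry: str = EQUIRECTANGULAR) -> SphericalRaster:
    """Read an RGB panorama from PNG/JPEG."""
    arr = iio.imread(Path(path))
    if arr.ndim == 2:  # grayscale: replicate
        arr = np.stack([arr] * 3, axis=-1)
    arr = arr[..., :3]
    mask = None
    sidecar = _sidecar_path(Path(path))
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text())
        geometry = meta.get("geometry", geometry)
    if geometry == HAMMER:
        # reconstruct the ellipse mask geometrically
        from .projection import hammer_grid_mask

        mask = hammer_grid_mask(arr.shape[1], arr.shape[0])
    return SphericalRaster(arr.astype(np.uint8), geometry, mask)


def write_rgb(raster: SphericalRaster, path: str | Path) -> None:
    path = Path(path)
    iio.imwrite(path, raster.values.astype(np.uint8))
    _write_sidecar(raster, path)


def read_labels(path: str | Path, geometry: str | None = None) -> SphericalRaster:
    """Read an integer label raster from indexed PNG or whitespace text."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        arr = np.asarray(iio.imread(path))
        if arr.ndim == 3:
            arr = arr[..., 0]
    else:
        arr = np.loadtxt(path, dtype=np.int64)
        arr = np.atleast_2d(arr)
    arr = arr.astype(np.int64)
    sidecar = _sidecar_path(path)
    if geometry is None:
        geometry = EQUIRECTANGULAR
        if sidecar.exists():
            meta = yaml.safe_load(sidecar.read_text())
            geometry = meta.get("geometry", geometry)
    mask = None
    if geometry == HAMMER:
        mask = arr != MASK_LABEL
    return SphericalRaster(arr, geometry, mask)


def write_labels(raster: SphericalRaster, path: str | Path) -> None:
    """Write a label raster (PNG if ``.png``, else whitespace text).

    Out-of-mask pixels are stored as :data:`MASK_LABEL`; a YAML sidecar
    records the geometry and the reserved value.
    """
    if raster.is_rgb:
        raise ValueError("write_labels expects a categorical raster")
    path = Path(path)
    vals = raster.values.copy()
    if raster.mask is not None:
        vals[~raster.mask] = MASK_LABEL
    if vals.min() < 0 or vals.max() > 255:
        raise ValueError("label values must fit in uint8 (0..255) for storage")
    if path.suffix.lower() == ".png":
        iio.imwrite(path, vals.astype(np.uint8))
    else:
        np.savetxt(path, vals, fmt="%d")
    _write_sidecar(raster, path)


def _write_sidecar(raster: SphericalRaster, path: Path) -> None:
    meta = {"geometry": raster.geometry, "mask_label": MASK_LABEL}
    _sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=True))
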