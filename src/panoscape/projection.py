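"""Hammer equal-area projection of spherical panoramas.

Equirectangular panoramas assign equal pixel counts to equal *latitude
bands*, not to equal solid angles, so naive pixel counting over-represents
the zenith and nadir by a factor ``1/cos(lat)``.  Area-based scene auditing
must therefore resample the sphere to an equal-area projection first.  This
module implements the Hammer projection (Snyder's standard equations),
which maps the whole sphere onto a 2:1 ellipse with

.. math::

    x = \\frac{2\\sqrt{2}\\,\\cos\\varphi\\,\\sin(\\lambda/2)}{D}, \\qquad
    y = \\frac{\\sqrt{2}\\,\\sin\\varphi}{D}, \\qquad
    D = \\sqrt{1 + \\cos\\varphi\\,\\cos(\\lambda/2)}

for longitude ``lambda`` in ``[-pi, pi)`` and latitude ``phi`` in
``[-pi/2, pi/2]``.  Valid image points satisfy
``(x / (2*sqrt(2)))**2 + (y / sqrt(2))**2 <= 1``.

The inverse is closed-form: with ``z = sqrt(1 - (x/4)**2 - (y/2)**2)``,
``lambda = 2*atan2(z*x, 2*(2*z**2 - 1))`` and ``phi = asin(z*y)``; points with
``(x/4)**2 + (y/2)**2 > 1/2`` lie outside the ellipse.
"""

from __future__ import annotations

import numpy as np

from .rasters import (
    EQUIRECTANGULAR,
    HAMMER,
    MASK_LABEL,
    SphericalRaster,
    lat_centers,
    lon_centers,
)

SQRT2 = np.sqrt(2.0)
#: Semi-axes of the Hammer ellipse.
HALF_WIDTH = 2.0 * SQRT2
HALF_HEIGHT = SQRT2

_POLE_CLAMP = np.pi / 2.0 - 1e-12
_RANGE_TOL = 1e-9


def hammer_forward(lon, lat):
    """Project spherical coordinates (radians) to Hammer plane coordinates.

    Accepts scalars or arrays; raises ``ValueError`` for out-of-range input.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if np.any(lon < -np.pi - _RANGE_TOL) or np.any(lon > np.pi + _RANGE_TOL):
        raise ValueError("longitude must lie in [-pi, pi)")
    if np.any(np.abs(lat) > np.pi / 2.0 + _RANGE_TOL):
        raise ValueError("latitude must lie in [-pi/2, pi/2]")
    half = lon / 2.0
    d = np.sqrt(1.0 + np.cos(lat) * np.cos(half))
    x = HALF_WIDTH * np.cos(lat) * np.sin(half) / d
    y = HALF_HEIGHT * np.sin(lat) / d
    if x.ndim == 0:
        return float(x), float(y)
    return x, y


def hammer_contains(x, y, tol: float = 1e-12):
    """True for points inside (or on) the Hammer ellipse image of the sphere."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return (x / 4.0) ** 2 + (y / 2.0) ** 2 <= 0.5 + tol


def hammer_inverse(x, y, strict: bool = True):
    """Invert the Hammer projection.

    Parameters
    ----------
    x, y
        Plane coordinates (scalars or arrays).
    strict
        If ``True``, any exterior point raises ``ValueError``; otherwise
        exterior points yield ``NaN`` so callers can build validity masks.

    Returns
    -------
    (lon, lat) in radians, with ``|lat|`` clamped just below ``pi/2`` so the
    longitude stays determinate at the poles.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    inside = hammer_contains(x, y)
    if strict and not np.all(inside):
        raise ValueError("point outside the Hammer ellipse (exterior)")
    s = np.where(inside, (x / 4.0) ** 2 + (y / 2.0) ** 2, 0.0)
    z = np.sqrt(1.0 - s)
    lon = 2.0 * np.arctan2(z * x, 2.0 * (2.0 * z * z - 1.0))
    lat = np.arcsin(np.clip(z * y, -1.0, 1.0))
    lat = np.clip(lat, -_POLE_CLAMP, _POLE_CLAMP)
    lon = np.where(inside, lon, np.nan)
    lat = np.where(inside, lat, np.nan)
    if lon.ndim == 0:
        return float(lon), float(lat)
    return lon, lat


def hammer_grid_mask(width: int, height: int) -> np.ndarray:
    """Validity mask for a ``width x height`` pixel grid covering the ellipse."""
    x, y = _plane_grid(width, height)
    return hammer_contains(x, y)


def _plane_grid(width: int, height: int):
    """Plane coordinates of pixel centers for a grid spanning the ellipse
    bounding box ``[-2*sqrt(2), 2*sqrt(2)] x [-sqrt(2), sqrt(2)]``; row 0 is
    the +y (sky) side."""
    xs = -HALF_WIDTH + (np.arange(width) + 0.5) * (2.0 * HALF_WIDTH / width)
    ys = HALF_HEIGHT - (np.arange(height) + 0.5) * (2.0 * HALF_HEIGHT / height)
    return np.meshgrid(xs, ys)


def equirect_to_hammer(
    src: SphericalRaster,
    out_width: int | None = None,
    interpolation: str = "nearest",
) -> SphericalRaster:
    """Resample an equirectangular raster onto the Hammer ellipse.

    Every valid output pixel is sampled at the sphere point obtained by
    inverting its center.  Categorical rasters must use nearest-neighbor
    sampling (interpolation must never invent labels); RGB rasters may use
    ``"bilinear"``.  Default output width preserves the source width.
    """
    if src.geometry != EQUIRECTANGULAR:
        raise ValueError("source raster must be equirectangular")
    if interpolation not in ("nearest", "bilinear"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if src.is_categorical and interpolation != "nearest":
        raise ValueError("categorical rasters require nearest-neighbor sampling")

    out_width = int(out_width) if out_width else src.width
    out_height = max(out_width // 2, 1)
    h, w = src.height, src.width

    x, y = _plane_grid(out_width, out_height)
    lon, lat = hammer_inverse(x, y, strict=False)
    valid = np.isfinite(lon)
    lon = np.nan_to_num(lon)
    lat = np.nan_to_num(lat)

    colf = (lon + np.pi) / (2.0 * np.pi) * w - 0.5
    rowf = (np.pi / 2.0 - lat) / np.pi * h - 0.5

    if interpolation == "nearest":
        ci = np.mod(np.rint(colf).astype(np.int64), w)
        ri = np.clip(np.rint(rowf).astype(np.int64), 0, h - 1)
        out = src.values[ri, ci]
    else:
        from scipy.ndimage import map_coordinates

        # pad one wrapped column on each side so bilinear lookups cross the seam
        padded = np.concatenate(
            [src.values[:, -1:], src.values, src.values[:, :1]], axis=1
        )
        coords = np.array([rowf, colf + 1.0])
        if src.is_rgb:
            out = np.stack(
                [
                    map_coordinates(
                        padded[..., c].astype(float), coords, order=1, mode="nearest"
                    )
                    for c in range(3)
                ],
                axis=-1,
            )
            out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
        else:  # pragma: no cover - guarded above
            raise AssertionError

    if src.is_categorical:
        out = out.astype(np.int64)
        out[~valid] = MASK_LABEL
    else:
        out = out.copy()
        out[~valid] = 0
    return SphericalRaster(out, HAMMER, valid)


def solid_angle_proportions(src: SphericalRaster) -> dict:
    """Class proportions of an equirectangular categorical raster, weighting
    each pixel by ``cos(lat)`` of its row center (proportional to the solid
    angle it subtends).  Serves as the independent equal-area oracle for
    :func:`equirect_to_hammer` pixel counting.
    """
    if src.geometry != EQUIRECTANGULAR:
        raise ValueError("solid_angle_proportions expects an equirectangular raster")
    if src.is_rgb:
        raise ValueError("solid_angle_proportions expects a categorical raster")
    if src.values.size == 0:
        raise ValueError("empty raster")
    weights = np.cos(lat_centers(src.height))[:, None]
    wgrid = np.broadcast_to(weights, src.values.shape)
    mask = src.valid_mask()
    labels, inverse = np.unique(src.values[mask], return_inverse=True)
    sums = np.bincount(inverse, weights=wgrid[mask], minlength=labels.size)
    total = sums.sum()
    return {int(lab): float(s / total) for lab, s in zip(labels, sums)}


def naive_proportions(src: SphericalRaster) -> dict:
    """Unweighted (per-pixel) class shares of a categorical raster.

    On an equirectangular grid this is the biased count the equal-area
    pipeline corrects: high-latitude classes come out too large.
    """
    if src.is_rgb:
        raise ValueError("naive_proportions expects a categorical raster")
    mask = src.valid_mask()
    labels, counts = np.unique(src.values[mask], return_counts=True)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty raster")
    return {int(lab): float(c / total) for lab, c in zip(labels, counts)}


def masked_class_proportions(src: SphericalRaster) -> dict:
    """Class shares over the valid mask of a Hammer raster (equal-area, so
    plain pixel counts are solid-angle proportions)."""
    if src.geometry != HAMMER:
        raise ValueError("expects a Hammer raster")
    return naive_proportions(src)
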