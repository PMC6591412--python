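"""Moment-based shape descriptors of (binary) phosphene drawings.

Every drawing is summarized by three parameter-free descriptors computed
from image moments ``M_ij = sum_x sum_y x^i y^j I(x, y)``:

* **area** — ``M_00`` (pixel count for a binary image);
* **orientation** ``theta`` — the axial angle (deg, ``[-90, 90)``) of the
  principal eigenvector of the image covariance matrix,
  ``theta = 1/2 * atan2(2 mu'_11, mu'_20 - mu'_02)``;
* **elongation** ``E = sqrt(1 - l2 / l1)`` with ``l1 >= l2`` the covariance
  eigenvalues: 0 for a circle, approaching 1 for an infinitesimally thin
  line.

Pixel coordinates are 0-based with ``x`` = column and ``y`` = row.  The
two-argument arctangent is used so that vertically elongated shapes yield
``|theta| = 90``; the degenerate case ``mu'_20 == mu'_02`` *and*
``mu'_11 == 0`` (e.g. a disc) is assigned ``theta = 0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class ShapeDescriptors:
    """(area, centroid, orientation, elongation) of one image.

    ``orientation`` and ``elongation`` are NaN for an empty image.
    ``area`` is in pixels unless a ``pixel_size`` was supplied to
    :func:`describe`, in which case it is in squared units of that size.
    """

    area: float
    centroid: tuple[float, float]  # (x, y) pixels
    orientation: float  # deg, axial, [-90, 90)
    elongation: float  # [0, 1]

    @property
    def is_empty(self) -> bool:
        return self.area == 0


def _image_data(img) -> np.ndarray:
    """Accept bare arrays or objects with a ``.data`` raster attribute."""
    return np.asarray(getattr(img, "data", img), dtype=float)


def raw_moment(img, i: int, j: int) -> float:
    """Raw image moment ``M_ij = sum_x sum_y x^i y^j I(x, y)``."""
    data = _image_data(img)
    ny, nx = data.shape
    xs = np.arange(nx, dtype=float) ** i
    ys = np.arange(ny, dtype=float) ** j
    return float(ys @ data @ xs)


def describe(img, pixel_size: float | None = None) -> ShapeDescriptors:
    """Compute area, centroid, orientation and elongation of an image.

    Works on grayscale or binary rasters.  An image with no nonzero pixel
    returns area 0 with NaN orientation/elongation; a single-pixel image has
    zero covariance and is treated as circular (``theta = 0``, ``E = 0``).
    """
    data = _image_data(img)
    m00 = float(data.sum())
    if m00 == 0:
        return ShapeDescriptors(0.0, (math.nan, math.nan), math.nan, math.nan)

    ny, nx = data.shape
    xs = np.arange(nx, dtype=float)
    ys = np.arange(ny, dtype=float)
    colsum = data.sum(axis=0)
    rowsum = data.sum(axis=1)
    xbar = float(colsum @ xs) / m00
    ybar = float(rowsum @ ys) / m00
    mu20 = float(colsum @ xs**2) / m00 - xbar**2
    mu02 = float(rowsum @ ys**2) / m00 - ybar**2
    mu11 = float(ys @ data @ xs) / m00 - xbar * ybar

    if mu20 == mu02 and mu11 == 0.0:
        theta = 0.0
    else:
        theta = 0.5 * math.degrees(math.atan2(2.0 * mu11, mu20 - mu02))
        theta = (theta + 90.0) % 180.0 - 90.0

    half_trace = (mu20 + mu02) / 2.0
    half_gap = math.sqrt(4.0 * mu11**2 + (mu20 - mu02) ** 2) / 2.0
    l1, l2 = half_trace + half_gap, half_trace - half_gap
    elong = math.sqrt(min(1.0, max(0.0, 1.0 - l2 / l1))) if l1 > 0 else 0.0
    if l1 <= 0:
        theta = 0.0

    area = m00 if pixel_size is None else m00 * pixel_size**2
    return ShapeDescriptors(area, (xbar, ybar), theta, elong)


def angular_error(theta1: float, theta2: float) -> float:
    """Absolute difference between two axial angles, deg in ``[0, 90]``.

    NaN inputs propagate.
    """
    if math.isnan(theta1) or math.isnan(theta2):
        return math.nan
    d = abs(theta1 - theta2) % 180.0
    return min(d, 180.0 - d)


def average_drawings(imgs) -> np.ndarray:
    """Average a set of drawings aligned at their centers of mass.

    Each image is shifted by an integer number of pixels so its centroid
    coincides with the mean centroid, then the pixel-wise mean is taken.
    Pixels shifted beyond the edge are cropped (filled with 0).
    """
    rasters = [_image_data(im) for im in imgs]
    if not rasters:
        raise ValueError("need at least one drawing")
    descs = [describe(r) for r in rasters]
    if any(d.is_empty for d in descs):
        raise ValueError("cannot center-align an empty drawing")
    cx = float(np.mean([d.centroid[0] for d in descs]))
    cy = float(np.mean([d.centroid[1] for d in descs]))
    out = np.zeros_like(rasters[0], dtype=float)
    for r, d in zip(rasters, descs):
        # floor(x + 1/2) is shift-equivariant, so images whose centroids
        # differ by whole pixels align exactly regardless of the target
        shift = (
            math.floor(cy - d.centroid[1] + 0.5),
            math.floor(cx - d.centroid[0] + 0.5),
        )
        out += ndimage.shift(r, shift, order=0, mode="constant", cval=0.0)
    return out / len(rasters)
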