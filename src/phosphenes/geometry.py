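"""Retinal coordinate systems, subject geometry, and electrode-array layouts.

Two coordinate frames are used throughout:

* **Retinal frame** — microns on the retinal surface, fovea at the origin,
  ``x`` positive toward the optic disc (nasal retina), ``y`` positive toward
  superior retina.  All rendering and axon-trajectory math happens here.
* **Visual-field frame** — degrees of visual angle.  Because the eye's optics
  invert the image, superior retina maps to the *lower* visual field: the
  conversion flips the vertical axis.  Landmark inputs (optic-disc center)
  are specified in degrees *on retinal axes* (nasal-positive, superior-
  positive), matching how fundus-derived landmarks are reported.

The default µm↔deg conversion is linear at 3.6 deg/mm; a different callable
pair can be supplied wherever a ``converter`` argument is accepted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import NamedTuple

import numpy as np

#: Default linear conversion: 1 mm of retinal distance subtends 3.6 deg.
DEGREES_PER_MICRON = 3.6 / 1000.0
MICRONS_PER_DEGREE = 1000.0 / 3.6


class LinearConverter:
    """Linear retina↔visual-angle conversion (``deg = k * mm``).

    Applied radially from the fovea, so it commutes with rotations about
    the origin.
    """

    def __init__(self, degrees_per_mm: float = 3.6):
        self.degrees_per_mm = float(degrees_per_mm)

    def um_to_deg(self, um):
        return np.asarray(um, dtype=float) * (self.degrees_per_mm / 1000.0)

    def deg_to_um(self, deg):
        return np.asarray(deg, dtype=float) * (1000.0 / self.degrees_per_mm)


DEFAULT_CONVERTER = LinearConverter()


class Eye(Enum):
    RIGHT = "RE"
    LEFT = "LE"


class ImplantType(Enum):
    ARGUS_I = "ArgusI"
    ARGUS_II = "ArgusII"


class RetinalPoint(NamedTuple):
    """Point on the retinal surface, µm, fovea-centered, nasal-positive x."""

    x: float
    y: float


class VisualFieldPoint(NamedTuple):
    """Point in the visual field, degrees (azimuth, elevation)."""

    azimuth: float
    elevation: float


def retinal_to_visual(p, converter=None) -> VisualFieldPoint:
    """Convert a retinal point (µm) to visual-field degrees.

    The conversion is applied radially from the fovea and the vertical axis
    is sign-flipped (superior retina sees the lower visual field).
    """
    conv = converter or DEFAULT_CONVERTER
    x, y = p
    return VisualFieldPoint(float(conv.um_to_deg(x)), float(-conv.um_to_deg(y)))


def visual_to_retinal(p, converter=None) -> RetinalPoint:
    """Exact inverse of :func:`retinal_to_visual`."""
    conv = converter or DEFAULT_CONVERTER
    az, el = p
    return RetinalPoint(float(conv.deg_to_um(az)), float(-conv.deg_to_um(el)))


@dataclass(frozen=True)
class SubjectGeometry:
    """Placement of an implant and the optic disc in one subject's eye.

    Parameters
    ----------
    implant_type
        ``ARGUS_I`` (4×4, 800 µm pitch) or ``ARGUS_II`` (6×10, 525 µm pitch).
    array_center
        Center of the electrode array in retinal µm, fovea-centered.
    array_rotation
        Rotation of the array in degrees, counterclockwise with respect to
        the horizontal raphe, in ``[-180, 180)``.
    optic_disc_center
        Optic-disc center in degrees on retinal axes (nasal-positive x,
        superior-positive y), e.g. ``(15.5, 1.5)``.
    eye
        Implanted eye; a LEFT eye is handled by mirroring x once.
    """

    implant_type: ImplantType
    array_center: tuple[float, float]
    array_rotation: float
    optic_disc_center: tuple[float, float]
    eye: Eye = Eye.RIGHT
    subject_id: str = ""

    def __post_init__(self):
        if not -180.0 <= self.array_rotation < 180.0:
            raise ValueError("array_rotation must lie in [-180, 180)")
        if self.optic_disc_center[0] <= 0:
            raise ValueError(
                "optic-disc azimuth must be positive (nasal-positive convention)"
            )

    def optic_disc_um(self, converter=None) -> RetinalPoint:
        """Optic-disc center in retinal µm (pure scaling, no vertical flip)."""
        conv = converter or DEFAULT_CONVERTER
        ax, ay = self.optic_disc_center
        sign = -1.0 if self.eye is Eye.LEFT else 1.0
        return RetinalPoint(sign * float(conv.deg_to_um(ax)), float(conv.deg_to_um(ay)))

    def array_center_um(self) -> RetinalPoint:
        """Array center in anatomical retinal µm (x mirrored for LEFT eyes)."""
        sign = -1.0 if self.eye is Eye.LEFT else 1.0
        return RetinalPoint(sign * float(self.array_center[0]), float(self.array_center[1]))

    def mirrored(self) -> "SubjectGeometry":
        """Same geometry attributed to the fellow eye.

        All fields are stored in the nasal-positive convention, so the
        numbers are unchanged; realized anatomical coordinates (array,
        disc, axon map) come out x-mirrored.  The mirror is applied exactly
        once, at realization time.
        """
        return SubjectGeometry(
            implant_type=self.implant_type,
            array_center=self.array_center,
            array_rotation=self.array_rotation,
            optic_disc_center=self.optic_disc_center,
            eye=Eye.LEFT if self.eye is Eye.RIGHT else Eye.RIGHT,
            subject_id=self.subject_id,
        )


# (rows, cols, pitch µm, diameters)
_IMPLANT_SPECS = {
    ImplantType.ARGUS_I: dict(rows=4, cols=4, pitch=800.0),
    ImplantType.ARGUS_II: dict(rows=6, cols=10, pitch=525.0),
}


@dataclass(frozen=True)
class ElectrodeArray:
    """Named electrode centers (retinal µm) with disc diameters (µm)."""

    names: tuple[str, ...]
    centers: np.ndarray  # (n, 2) µm
    diameters: np.ndarray  # (n,) µm

    def __len__(self) -> int:
        return len(self.names)

    def __getitem__(self, name: str) -> RetinalPoint:
        i = self.names.index(name)
        return RetinalPoint(*self.centers[i])

    def as_dict(self) -> dict[str, RetinalPoint]:
        return {n: RetinalPoint(*c) for n, c in zip(self.names, self.centers)}


def build_array(geometry: SubjectGeometry) -> ElectrodeArray:
    """Place the subject's electrode grid on the retina.

    Electrodes form a regular grid at the implant pitch, named row-major
    (row letters from the top row, column numbers from 1), rotated
    counterclockwise by ``array_rotation`` about the array center and
    translated to ``array_center``.  Argus I diameters alternate 260/520 µm
    in a checkerboard; Argus II discs are all 200 µm.
    """
    try:
        spec = _IMPLANT_SPECS[geometry.implant_type]
    except KeyError:  # pragma: no cover - defensive
        raise ValueError(f"unknown implant type: {geometry.implant_type!r}")
    rows, cols, pitch = spec["rows"], spec["cols"], spec["pitch"]

    names, offsets, diams = [], [], []
    for r in range(rows):
        for c in range(cols):
            names.append(f"{chr(ord('A') + r)}{c + 1}")
            # row A at the top (largest y) before rotation
            offsets.append(
                [(c - (cols - 1) / 2.0) * pitch, ((rows - 1) / 2.0 - r) * pitch]
            )
            if geometry.implant_type is ImplantType.ARGUS_I:
                diams.append(260.0 if (r + c) % 2 == 0 else 520.0)
            else:
                diams.append(200.0)

    offsets = np.asarray(offsets)
    th = math.radians(geometry.array_rotation)
    rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    centers = offsets @ rot.T + np.asarray(geometry.array_center, dtype=float)
    if geometry.eye is Eye.LEFT:
        centers = centers * np.array([-1.0, 1.0])
    return ElectrodeArray(tuple(names), centers, np.asarray(diams))


@dataclass(frozen=True)
class Grid:
    """Uniform raster over the visual field, degrees, retinal-axis orientation.

    Row 0 is the *bottom* of the array (most inferior y); exporters flip
    vertically when writing visual-field images.  Pixel centers are at
    ``min + (i + 1/2) * step``.
    """

    x_range: tuple[float, float] = (-32.0, 32.0)
    y_range: tuple[float, float] = (-24.0, 24.0)
    step: float = 0.2

    @property
    def shape(self) -> tuple[int, int]:
        ny = int(round((self.y_range[1] - self.y_range[0]) / self.step))
        nx = int(round((self.x_range[1] - self.x_range[0]) / self.step))
        return ny, nx

    @property
    def xs(self) -> np.ndarray:
        """Pixel-center x coordinates, deg."""
        nx = self.shape[1]
        return self.x_range[0] + (np.arange(nx) + 0.5) * self.step

    @property
    def ys(self) -> np.ndarray:
        """Pixel-center y coordinates, deg (increasing with row index)."""
        ny = self.shape[0]
        return self.y_range[0] + (np.arange(ny) + 0.5) * self.step

    def pixel_centers_um(self, converter=None) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid of pixel centers in retinal µm, shape ``(ny, nx)`` each."""
        conv = converter or DEFAULT_CONVERTER
        xx, yy = np.meshgrid(conv.deg_to_um(self.xs), conv.deg_to_um(self.ys))
        return xx, yy

    @property
    def pixel_size_um(self) -> float:
        return float(DEFAULT_CONVERTER.deg_to_um(self.step))
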