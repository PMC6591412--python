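"""Ganglion axon bundle trajectories (spiral model) and per-subject axon maps.

Retinal ganglion cell axons follow stereotyped arcuate paths from their soma
to the optic disc.  Following the classic fundus-derived trajectory model,
a bundle is a spiral in a polar frame ``(r, phi)`` centered on the optic
disc::

    phi(r) = phi0 + b(phi0) * (r - r0) ** c(phi0)

where ``phi0`` is the angular position on a starting circle of radius ``r0``
around the disc, ``b`` sets the curvature and ``c`` the locus of maximal
curvature.  ``b`` and ``c`` take separate superior (``phi0 > 0``) and
inferior (``phi0 < 0``) parameterizations; superior bundles curve upward
(``b > 0``), inferior ones downward (``b < 0``), and neither crosses the
horizontal raphe temporal to the disc (trajectories are truncated at
``|phi| = 180``).

Radii and ``phi`` are in degrees; trajectories are converted to
fovea-centered retinal µm through the subject geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import DEFAULT_CONVERTER, Eye, SubjectGeometry

#: Radius (deg) of the starting circle around the optic disc.
DEFAULT_R0 = 4.0
DEFAULT_R_MAX = 45.0
DEFAULT_STEP = 0.25
DEFAULT_PHI0_SAMPLES = 500


def spiral_b(phi0):
    """Spiral curvature coefficient ``b`` (dimensionless).

    Superior branch (``phi0 > 0``)::

        b = exp(-1.9 + 3.9 * tanh(-(phi0 - 121) / 14))

    Inferior branch (``phi0 < 0``)::

        b = -exp(0.7 + 1.5 * tanh(-(-phi0 - 90) / 25))

    The branch is selected on the sign of ``phi0`` (superior vs inferior
    hemiretina).
    """
    phi0 = np.asarray(phi0, dtype=float)
    sup = np.exp(-1.9 + 3.9 * np.tanh(-(phi0 - 121.0) / 14.0))
    inf = -np.exp(0.7 + 1.5 * np.tanh(-(-phi0 - 90.0) / 25.0))
    out = np.where(phi0 >= 0, sup, inf)
    return out if out.ndim else float(out)


def spiral_c(phi0):
    """Spiral exponent ``c > 0`` locating the point of maximal curvature."""
    phi0 = np.asarray(phi0, dtype=float)
    sup = 1.9 + 1.4 * np.tanh((phi0 - 121.0) / 14.0)
    inf = 1.0 + 0.5 * np.tanh((-phi0 - 90.0) / 25.0)
    out = np.where(phi0 >= 0, sup, inf)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class BundleTrajectory:
    """One axon bundle as a polyline in retinal µm, ordered periphery→disc.

    ``arclengths[j]`` is the path length (µm) from vertex ``j`` to the
    disc-ward end of the polyline.
    """

    phi0: float
    points: np.ndarray  # (n, 2) µm
    arclengths: np.ndarray  # (n,) µm, nonincreasing

    def __len__(self) -> int:
        return len(self.points)


def _spiral_polyline_deg(phi0: float, r_max: float, step: float, r0: float):
    """Disc-centered polyline in degrees, periphery→disc, raphe-truncated."""
    if r_max <= r0:
        raise ValueError(f"r_max ({r_max}) must exceed r0 ({r0})")
    n = int(np.floor((r_max - r0) / step))
    rs = r0 + step * np.arange(n, -1, -1, dtype=float)  # r_max-ish .. r0
    phi = phi0 + spiral_b(phi0) * (rs - r0) ** spiral_c(phi0)
    keep = np.abs(phi) <= 180.0  # do not wrap across the raphe
    rs, phi = rs[keep], phi[keep]
    return rs * np.cos(np.radians(phi)), rs * np.sin(np.radians(phi))


def bundle_trajectory(
    phi0: float,
    geometry: SubjectGeometry,
    r_max: float = DEFAULT_R_MAX,
    step: float = DEFAULT_STEP,
    r0: float = DEFAULT_R0,
    converter=None,
) -> BundleTrajectory:
    """Trajectory for one bundle, in fovea-centered retinal µm.

    The spiral is evaluated in the disc-centered polar frame (degrees) and
    translated so the optic disc sits at the subject's estimated disc
    location; degrees are then scaled to µm.
    """
    conv = converter or DEFAULT_CONVERTER
    dx, dy = _spiral_polyline_deg(phi0, r_max, step, r0)
    odx, ody = geometry.optic_disc_center
    # The spiral frame's horizontal is the temporal raphe: translate x by the
    # full disc azimuth, but apply the disc's elevation only nasal of the
    # disc, so that the superior/inferior seam runs through the fovea (y=0)
    # temporally while the disc sits at its estimated elevation.
    x_um = np.asarray(conv.deg_to_um(dx + odx), dtype=float)
    y_um = np.asarray(conv.deg_to_um(dy + np.where(dx > 1e-9, ody, 0.0)), dtype=float)
    if geometry.eye is Eye.LEFT:
        x_um = -x_um
    pts = np.column_stack([x_um, y_um])
    seg = np.hypot(np.diff(pts[:, 0]), np.diff(pts[:, 1]))
    arclen = np.concatenate([np.cumsum(seg[::-1])[::-1], [0.0]])
    return BundleTrajectory(float(phi0), pts, arclen)


def _axial_deg(angles_deg: np.ndarray) -> np.ndarray:
    """Map angles to the axial range ``[-90, 90)``."""
    return (np.asarray(angles_deg, dtype=float) + 90.0) % 180.0 - 90.0


@dataclass
class AxonMap:
    """A subject-specific set of axon bundle trajectories.

    Holds the bundle polylines plus flat per-vertex arrays used for fast
    nearest-bundle queries: points, arclength-to-disc, tangent angle
    (axial, deg), and the owning bundle index.
    """

    bundles: list[BundleTrajectory]
    geometry: SubjectGeometry
    points: np.ndarray = field(repr=False)  # (N, 2) µm, all vertices
    arclengths: np.ndarray = field(repr=False)  # (N,) µm to disc-ward end
    tangents: np.ndarray = field(repr=False)  # (N,) axial deg
    bundle_index: np.ndarray = field(repr=False)  # (N,) int
    bundle_ptr: np.ndarray = field(repr=False)  # (n_bundles + 1,) int

    def __post_init__(self):
        self._tree = None

    @property
    def tree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.points)
        return self._tree

    def nearest_vertex(self, xy_um: np.ndarray) -> np.ndarray:
        """Flat index of the closest bundle vertex for each query point."""
        _, idx = self.tree.query(np.atleast_2d(xy_um), k=1)
        return idx

    def to_dataframe(self) -> pd.DataFrame:
        """Export as a multi-polyline table (CSV-ready)."""
        vertex = np.concatenate([np.arange(len(b)) for b in self.bundles])
        return pd.DataFrame(
            {
                "bundle": self.bundle_index,
                "vertex": vertex,
                "x_um": self.points[:, 0],
                "y_um": self.points[:, 1],
                "arclength_um": self.arclengths,
            }
        )


def build_axon_map(
    geometry: SubjectGeometry,
    phi0_samples: int = DEFAULT_PHI0_SAMPLES,
    r_max: float = DEFAULT_R_MAX,
    step: float = DEFAULT_STEP,
    r0: float = DEFAULT_R0,
    converter=None,
) -> AxonMap:
    """Sample bundles uniformly in ``phi0`` over ``(-180, 180)``, excluding 0.

    Samples are placed at half-step offsets so that neither the raphe
    (``phi0 = 0``) nor the degenerate ``|phi0| = 180`` seam is hit; a
    sample landing exactly on 0 (odd counts) is nudged by a quarter step.
    """
    if phi0_samples < 2:
        raise ValueError("phi0_samples must be >= 2")
    dphi = 360.0 / phi0_samples
    phi0s = -180.0 + dphi * (np.arange(phi0_samples) + 0.5)
    phi0s[np.isclose(phi0s, 0.0)] = dphi / 4.0

    bundles = [
        bundle_trajectory(p0, geometry, r_max=r_max, step=step, r0=r0, converter=converter)
        for p0 in phi0s
    ]
    return assemble_axon_map(bundles, geometry)


def assemble_axon_map(bundles: list[BundleTrajectory], geometry: SubjectGeometry) -> AxonMap:
    """Build an :class:`AxonMap` from explicit bundle polylines.

    Degenerate bundles (fewer than 2 vertices) are dropped.  Useful for
    constructing idealized maps (e.g. straight parallel fibers) in tests
    and closed-form checks.
    """
    bundles = [b for b in bundles if len(b) >= 2]

    pts = np.concatenate([b.points for b in bundles])
    arclen = np.concatenate([b.arclengths for b in bundles])
    bidx = np.concatenate(
        [np.full(len(b), i, dtype=np.int64) for i, b in enumerate(bundles)]
    )
    ptr = np.concatenate([[0], np.cumsum([len(b) for b in bundles])]).astype(np.int64)

    tangents = np.empty(len(pts))
    for i, b in enumerate(bundles):
        d = np.diff(b.points, axis=0)
        ang = np.degrees(np.arctan2(d[:, 1], d[:, 0]))
        t = np.concatenate([ang, ang[-1:]])  # vertex j -> segment (j, j+1)
        tangents[ptr[i] : ptr[i + 1]] = _axial_deg(t)

    return AxonMap(
        bundles=bundles,
        geometry=geometry,
        points=pts,
        arclengths=arclen,
        tangents=tangents,
        bundle_index=bidx,
        bundle_ptr=ptr,
    )


def nearest_bundle_tangent(p, axon_map: AxonMap) -> float:
    """Axial tangent angle (deg in ``[-90, 90)``) of the nearest bundle.

    The tangent is taken at the bundle vertex closest to ``p`` (retinal µm).
    """
    if not axon_map.bundles:
        raise ValueError("axon map contains no bundles")
    idx = axon_map.nearest_vertex(np.asarray(p, dtype=float))
    return float(axon_map.tangents[idx[0]])
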