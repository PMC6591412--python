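"""Percept rendering under the scoreboard and axon-map models.

The **scoreboard** model treats each electrode as an isolated light source:
the intensity at retinal position ``(x, y)`` for an electrode at
``(x_stim, y_stim)`` is an isotropic Gaussian,

    I_score = exp(-((x - x_stim)² + (y - y_stim)²) / (2 rho²)),

so the binary percept (threshold ``1/sqrt(e)``) is a disc of radius ``rho``.

The **axon-map** model accounts for stimulation of passing axon fibers: a
pixel is treated as a ganglion-cell soma whose axon follows the nearest
bundle toward the optic disc.  Activating any point of that axon elicits a
percept at the soma's visual-field location, so the pixel intensity is the
maximum over disc-ward path points of a product of two Gaussian decays —
orthogonal to the fiber (electrode-to-path distance, constant ``rho``) and
along the fiber (soma-to-path arclength, constant ``lambda``).  The image
is normalized to peak 1 before thresholding.

Intensities depend on ``(rho, lambda)`` only through ``u = 1/(2 rho²)`` and
``v = 1/(2 lambda²)``, linearly in the exponent; :class:`AxonRenderEngine`
exploits this to precompute per-pixel candidate fronts per electrode,
making repeated evaluation at new parameters (model fitting) fast.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np

from . import _kernels
from .axon_map import AxonMap
from .geometry import DEFAULT_CONVERTER, Grid

#: Default binarization threshold: intensity 1/sqrt(e), i.e. distance rho
#: from the electrode under the scoreboard model.
DEFAULT_THRESHOLD = 1.0 / math.sqrt(math.e)


@dataclass(frozen=True)
class ModelParams:
    """Decay constants (µm) and binarization threshold of a percept model.

    ``rho`` is the spread orthogonal to axons (the only scoreboard
    parameter); ``lam`` is the decay along the axon and is ``None`` for the
    scoreboard model.
    """

    rho: float
    lam: float | None = None
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self):
        if not self.rho > 0:
            raise ValueError("rho must be positive")
        if self.lam is not None and not self.lam > 0:
            raise ValueError("lam must be positive when present")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")


@dataclass
class IntensityImage:
    """Raster of model intensities in ``[0, 1]`` on a visual-field grid."""

    data: np.ndarray
    grid: Grid


@dataclass
class PerceptImage:
    """Binary percept raster with provenance metadata."""

    data: np.ndarray
    grid: Grid
    provenance: dict = dc_field(default_factory=dict)


def render_scoreboard(
    electrode, params: ModelParams, grid: Grid, converter=None
) -> IntensityImage:
    """Isotropic Gaussian intensity profile centered on the electrode."""
    conv = converter or DEFAULT_CONVERTER
    ex, ey = electrode
    if not (
        grid.x_range[0] <= conv.um_to_deg(ex) <= grid.x_range[1]
        and grid.y_range[0] <= conv.um_to_deg(ey) <= grid.y_range[1]
    ):
        warnings.warn("electrode lies outside the rendering grid", stacklevel=2)
    xx, yy = grid.pixel_centers_um(conv)
    d2 = (xx - ex) ** 2 + (yy - ey) ** 2
    return IntensityImage(np.exp(-d2 / (2.0 * params.rho**2)), grid)


def scoreboard_intensity_at(point, electrode, rho: float) -> float:
    """Closed-form scoreboard intensity at an arbitrary retinal point (µm)."""
    d2 = (point[0] - electrode[0]) ** 2 + (point[1] - electrode[1]) ** 2
    return math.exp(-d2 / (2.0 * rho**2))


class AxonRenderEngine:
    """Axon-map renderer bound to one (axon map, grid) pair.

    Precomputes the pixel→nearest-bundle assignment once, and per electrode
    the convex ``(g2, s2)`` fronts (see :mod:`phosphenes._kernels`), after
    which rendering at any ``(rho, lambda)`` is a cheap minimum over fronts.
    """

    def __init__(self, axon_map: AxonMap, grid: Grid, converter=None):
        self.axon_map = axon_map
        self.grid = grid
        self.converter = converter or DEFAULT_CONVERTER
        xx, yy = grid.pixel_centers_um(self.converter)
        self._px = xx.ravel()
        self._py = yy.ravel()
        ny, nx = grid.shape
        iyy, ixx = np.mgrid[0:ny, 0:nx]
        self._ix = ixx.ravel().astype(np.float64)
        self._iy = iyy.ravel().astype(np.float64)
        self._vidx = axon_map.nearest_vertex(np.column_stack([self._px, self._py]))
        self._fronts: dict[tuple[float, float], tuple] = {}

    @property
    def n_pixels(self) -> int:
        return self._px.size

    def fronts(self, electrode):
        """Cached per-pixel candidate fronts for one electrode (µm)."""
        key = (round(float(electrode[0]), 6), round(float(electrode[1]), 6))
        hit = self._fronts.get(key)
        if hit is not None:
            return hit
        amap = self.axon_map
        path_left = amap.bundle_ptr[amap.bundle_index[self._vidx] + 1] - self._vidx
        offsets = np.concatenate([[0], np.cumsum(path_left)]).astype(np.int64)
        g2f = np.empty(offsets[-1])
        s2f = np.empty(offsets[-1])
        counts = np.empty(self.n_pixels, dtype=np.int64)
        _kernels.build_fronts(
            self._vidx.astype(np.int64),
            amap.bundle_index,
            amap.bundle_ptr,
            amap.points,
            amap.arclengths,
            float(electrode[0]),
            float(electrode[1]),
            offsets,
            g2f,
            s2f,
            counts,
        )
        # compact the ragged fronts
        fptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
        keep = np.concatenate(
            [np.arange(o, o + c) for o, c in zip(offsets[:-1], counts)]
        )
        front = (fptr, np.ascontiguousarray(g2f[keep]), np.ascontiguousarray(s2f[keep]))
        self._fronts[key] = front
        return front

    def min_exponent(self, electrode, rho: float, lam: float) -> np.ndarray:
        fptr, fg2, fs2 = self.fronts(electrode)
        out = np.empty(self.n_pixels)
        _kernels.min_exponent(
            fptr, fg2, fs2, 1.0 / (2.0 * rho**2), 1.0 / (2.0 * lam**2), out
        )
        return out

    def render(self, electrode, params: ModelParams) -> IntensityImage:
        """Normalized (peak 1) axon-map intensity image."""
        m = self.min_exponent(electrode, params.rho, params.lam)
        data = np.exp(-(m - m.min())).reshape(self.grid.shape)
        return IntensityImage(data, self.grid)

    def batched_descriptors(self, electrode, rhos, lams, threshold=DEFAULT_THRESHOLD):
        """Raw binary-percept moments for many (rho, lambda) at once.

        Returns an ``(n, 6)`` array of ``(m00, Σx, Σy, Σx², Σxy, Σy²)`` in
        pixel units, one row per parameter pair.
        """
        fptr, fg2, fs2 = self.fronts(electrode)
        rhos = np.atleast_1d(np.asarray(rhos, dtype=float))
        lams = np.atleast_1d(np.asarray(lams, dtype=float))
        out = np.empty((rhos.size, 6))
        scratch = np.empty(self.n_pixels)
        _kernels.batched_moments(
            fptr,
            fg2,
            fs2,
            1.0 / (2.0 * rhos**2),
            1.0 / (2.0 * lams**2),
            math.log(1.0 / threshold),
            self._ix,
            self._iy,
            scratch,
            out,
        )
        return out


def _render_axon_generic(
    electrode, params: ModelParams, axon_map: AxonMap, grid: Grid,
    metric: str, aggregate: str, converter=None,
) -> IntensityImage:
    """Reference axon-map renderer supporting all metric/aggregation modes.

    Slower, fully vectorized per bundle; used directly for the
    ``euclidean`` soma-distance metric and ``sum`` aggregation, and as a
    cross-check for the fast engine.
    """
    conv = converter or DEFAULT_CONVERTER
    xx, yy = grid.pixel_centers_um(conv)
    px, py = xx.ravel(), yy.ravel()
    vidx = axon_map.nearest_vertex(np.column_stack([px, py]))
    ex, ey = float(electrode[0]), float(electrode[1])
    u = 1.0 / (2.0 * params.rho**2)
    v = 1.0 / (2.0 * params.lam**2)

    intensity = np.zeros(px.size)
    ptr = axon_map.bundle_ptr
    for b, bundle in enumerate(axon_map.bundles):
        sel = np.flatnonzero(
            (vidx >= ptr[b]) & (vidx < ptr[b + 1])
        )
        if sel.size == 0:
            continue
        k = vidx[sel] - ptr[b]
        pts = bundle.points
        g2 = (pts[:, 0] - ex) ** 2 + (pts[:, 1] - ey) ** 2  # (nj,)
        if metric == "arclength":
            s2 = (bundle.arclengths[k][:, None] - bundle.arclengths[None, :]) ** 2
        elif metric == "euclidean":
            s2 = (px[sel][:, None] - pts[None, :, 0]) ** 2 + (
                py[sel][:, None] - pts[None, :, 1]
            ) ** 2
        else:
            raise ValueError(f"unknown soma-distance metric: {metric!r}")
        contrib = np.exp(-(g2[None, :] * u + s2 * v))
        discward = np.arange(len(pts))[None, :] >= k[:, None]
        contrib = np.where(discward, contrib, 0.0)
        if aggregate == "max":
            intensity[sel] = contrib.max(axis=1)
        elif aggregate == "sum":
            intensity[sel] = contrib.sum(axis=1)
        else:
            raise ValueError(f"unknown aggregation rule: {aggregate!r}")

    peak = intensity.max()
    if peak > 0:
        intensity = intensity / peak
    return IntensityImage(intensity.reshape(grid.shape), grid)


def render_axon(
    electrode,
    params: ModelParams,
    axon_map: AxonMap,
    grid: Grid,
    metric: str = "arclength",
    aggregate: str = "max",
    engine: AxonRenderEngine | None = None,
    converter=None,
) -> IntensityImage:
    """Axon-map intensity image for one electrode (retinal µm).

    ``metric`` selects how the soma-to-path distance entering the
    ``lambda`` decay is measured: ``"arclength"`` along the bundle
    (default; axonal conduction follows the fiber) or ``"euclidean"``
    straight-line.  ``aggregate`` is ``"max"`` (a fiber fires when any
    segment is driven) or ``"sum"``.  Pass an :class:`AxonRenderEngine` to
    reuse precomputed fronts across calls.
    """
    if params.lam is None:
        raise ValueError("axon-map rendering requires lam")
    if metric == "arclength" and aggregate == "max":
        if engine is None:
            engine = AxonRenderEngine(axon_map, grid, converter)
        return engine.render(electrode, params)
    return _render_axon_generic(
        electrode, params, axon_map, grid, metric, aggregate, converter
    )


def threshold_percept(
    img: IntensityImage, threshold: float = DEFAULT_THRESHOLD, provenance=None
) -> PerceptImage:
    """Binarize an intensity image at a fractional threshold (``I >= t``)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    return PerceptImage(
        img.data >= threshold, img.grid, dict(provenance or {}, threshold=threshold)
    )


def simulate_distance_series(
    electrode,
    rho_list,
    lam: float,
    axon_map: AxonMap,
    grid: Grid,
    threshold: float = DEFAULT_THRESHOLD,
    engine: AxonRenderEngine | None = None,
) -> list[PerceptImage]:
    """Percepts for a series of ``rho`` values at fixed ``lambda``.

    Emulates increasing electrode-retina distance: lift-off widens the
    current spread ``rho`` while leaving the axonal decay ``lambda``
    unchanged, so percepts grow and become less elongated as ``rho``
    overtakes ``lambda``.
    """
    if engine is None:
        engine = AxonRenderEngine(axon_map, grid)
    out = []
    for rho in rho_list:
        params = ModelParams(rho=rho, lam=lam, threshold=threshold)
        img = engine.render(electrode, params)
        out.append(
            threshold_percept(
                img, threshold,
                provenance=dict(model="axon_map", rho=rho, lam=lam, electrode=tuple(electrode)),
            )
        )
    return out
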