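"""Resampling statistics for phosphene drawings.

Implements the four analyses used to relate drawings to the axon map:

* **SEM consistency test** — are drawings more similar within an electrode
  than across electrodes?  The observed statistic is the mean (over
  electrodes) per-electrode SEM of a shape descriptor; the null resamples
  electrode-sized groups with replacement from the subject's pooled
  drawings.
* **Orientation alignment test** — are drawn orientations closer to the
  local axon-bundle tangent than chance?  Two null models: NM1 draws
  orientations uniformly from [-90°, 90°); NM2 keeps the drawn orientations
  but places the array at random on the retina and recomputes tangents.
* **Orientation variance explained** — R² of bundle tangents as predictors
  of drawn orientations, residuals wrapped axially.
* **Elongation–area correlation** — Pearson r across pooled drawings.

All angles are axial (theta and theta+180 identified).  Means and SEMs of
orientations use the doubled-angle circular mean.  One-tailed p-values use
the ``(1 + #{null <= observed}) / (1 + iters)`` convention.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .axon_map import AxonMap, _axial_deg
from .geometry import Grid, SubjectGeometry, build_array
from .shapes import angular_error, describe

_DESCRIPTORS = ("area", "orientation", "elongation")


def axial_mean(thetas_deg) -> float:
    """Circular mean of axial angles via angle doubling, deg in [-90, 90)."""
    t = np.radians(np.asarray(thetas_deg, dtype=float) * 2.0)
    return float(_axial_deg(math.degrees(math.atan2(np.sin(t).mean(), np.cos(t).mean())) / 2.0))


def axial_residuals(thetas_deg, center_deg) -> np.ndarray:
    """Signed axial differences wrapped to [-90, 90)."""
    return _axial_deg(np.asarray(thetas_deg, dtype=float) - center_deg)


@dataclass
class DrawingSet:
    """Per-electrode trial drawings for one subject.

    ``drawings`` maps electrode name to a list of binary percept images
    (objects with a ``.data`` raster); ``geometry`` is required for
    analyses that need electrode positions on the retina.
    """

    subject_id: str
    grid: Grid
    drawings: dict[str, list]
    geometry: SubjectGeometry | None = None
    _table: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    @property
    def electrodes(self) -> list[str]:
        return list(self.drawings.keys())

    @property
    def n_drawings(self) -> int:
        return sum(len(v) for v in self.drawings.values())

    def descriptor_table(self) -> pd.DataFrame:
        """Shape descriptors of every drawing (cached).

        Columns: electrode, trial, area (px), orientation (deg),
        elongation, centroid_x, centroid_y.
        """
        if self._table is None:
            rows = []
            for el, imgs in self.drawings.items():
                for t, img in enumerate(imgs):
                    d = describe(img)
                    rows.append(
                        dict(
                            electrode=el,
                            trial=t,
                            area=d.area,
                            orientation=d.orientation,
                            elongation=d.elongation,
                            centroid_x=d.centroid[0],
                            centroid_y=d.centroid[1],
                        )
                    )
            self._table = pd.DataFrame(rows)
        return self._table


@dataclass(frozen=True)
class ResamplingResult:
    """Observed statistic, its resampled null distribution, and p-value."""

    observed: float
    null: np.ndarray
    p: float
    seed: int

    def __post_init__(self):
        assert 0.0 <= self.p <= 1.0


def _p_value(null: np.ndarray, observed: float) -> float:
    return (1.0 + int(np.sum(null <= observed))) / (1.0 + null.size)


def _electrode_sem(values: np.ndarray, descriptor: str) -> float:
    """Per-electrode SEM of one descriptor across trials.

    Area SEM is normalized by the electrode's mean area; orientation SEM is
    computed on axial residuals about the doubled-angle circular mean.
    """
    m = values.size
    if descriptor == "orientation":
        res = axial_residuals(values, axial_mean(values))
        return float(np.std(res, ddof=1) / math.sqrt(m))
    sem = float(np.std(values, ddof=1) / math.sqrt(m))
    if descriptor == "area":
        mean = float(np.mean(values))
        sem = sem / mean if mean > 0 else 0.0
    return sem


def _descriptor_values(ds: DrawingSet, descriptor: str) -> dict[str, np.ndarray]:
    if descriptor not in _DESCRIPTORS:
        raise ValueError(f"unknown descriptor: {descriptor!r}")
    tab = ds.descriptor_table()
    out = {}
    for el in ds.electrodes:
        vals = tab.loc[tab.electrode == el, descriptor].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        if not ok.all():
            warnings.warn(
                f"electrode {el}: {np.sum(~ok)} drawings with undefined "
                f"{descriptor} excluded", stacklevel=3,
            )
            vals = vals[ok]
        if vals.size >= 2:
            out[el] = vals
    return out


def sem_consistency_test(
    ds: DrawingSet, descriptor: str, iters: int = 1000, seed: int = 0
) -> ResamplingResult:
    """Within- vs across-electrode consistency of one shape descriptor.

    Observed: mean over electrodes of the per-electrode trial SEM.  Null:
    the same statistic after resampling electrode-sized groups with
    replacement from the subject's pooled drawings; small observed values
    relative to the null indicate percepts consistent within an electrode.
    """
    groups = _descriptor_values(ds, descriptor)
    if len(groups) < 2:
        raise ValueError("need at least 2 electrodes with >= 2 valid trials")
    observed = float(np.mean([_electrode_sem(v, descriptor) for v in groups.values()]))

    pooled = np.concatenate(list(groups.values()))
    sizes = [v.size for v in groups.values()]
    rng = np.random.default_rng(seed)
    null = np.empty(iters)
    for i in range(iters):
        sems = [
            _electrode_sem(rng.choice(pooled, size=m, replace=True), descriptor)
            for m in sizes
        ]
        null[i] = np.mean(sems)
    return ResamplingResult(observed, null, _p_value(null, observed), seed)


def _electrode_tangents(
    names, centers: np.ndarray, axon_map: AxonMap
) -> np.ndarray:
    idx = axon_map.nearest_vertex(centers)
    return axon_map.tangents[idx]


def _alignment_statistic(orients_by_el: list[np.ndarray], tangents: np.ndarray) -> float:
    per_el = [
        np.mean([angular_error(o, t) for o in orients])
        for orients, t in zip(orients_by_el, tangents)
    ]
    return float(np.mean(per_el))


def orientation_alignment_test(
    ds: DrawingSet,
    axon_map: AxonMap,
    null_model: str = "NM1",
    iters: int = 1000,
    seed: int = 0,
) -> ResamplingResult:
    """Alignment of drawn orientations with the nearest bundle tangent.

    Observed: mean over electrodes of the mean absolute angular error
    between each trial's orientation and the tangent of the axon bundle
    nearest the electrode.  ``null_model="NM1"`` replaces orientations by
    uniform draws from [-90°, 90°); ``"NM2"`` keeps the orientations but
    places the array uniformly at random (center x in [-6000, 4000] µm,
    y in [-4000, 4000] µm, rotation in [-90°, 90°]) and recomputes
    tangents.
    """
    if ds.geometry is None:
        raise ValueError("drawing set has no subject geometry")
    tab = ds.descriptor_table()
    array = build_array(ds.geometry)
    positions = array.as_dict()

    names, centers, orients_by_el = [], [], []
    for el in ds.electrodes:
        o = tab.loc[tab.electrode == el, "orientation"].to_numpy(dtype=float)
        o = o[np.isfinite(o)]
        if o.size == 0:
            warnings.warn(f"electrode {el}: no defined orientations, skipped", stacklevel=2)
            continue
        if el not in positions:
            warnings.warn(f"electrode {el}: not in implant layout, skipped", stacklevel=2)
            continue
        names.append(el)
        centers.append(positions[el])
        orients_by_el.append(o)
    centers = np.asarray(centers, dtype=float)
    tangents = _electrode_tangents(names, centers, axon_map)
    observed = _alignment_statistic(orients_by_el, tangents)

    rng = np.random.default_rng(seed)
    null = np.empty(iters)
    if null_model == "NM1":
        for i in range(iters):
            rand = [rng.uniform(-90.0, 90.0, size=o.size) for o in orients_by_el]
            null[i] = _alignment_statistic(rand, tangents)
    elif null_model == "NM2":
        geo = ds.geometry
        for i in range(iters):
            placed = SubjectGeometry(
                implant_type=geo.implant_type,
                array_center=(rng.uniform(-6000, 4000), rng.uniform(-4000, 4000)),
                array_rotation=rng.uniform(-90.0, 90.0),
                optic_disc_center=geo.optic_disc_center,
                eye=geo.eye,
            )
            pos = build_array(placed).as_dict()
            cen = np.asarray([pos[n] for n in names], dtype=float)
            null[i] = _alignment_statistic(
                orients_by_el, _electrode_tangents(names, cen, axon_map)
            )
    else:
        raise ValueError(f"unknown null model: {null_model!r}")
    return ResamplingResult(observed, null, _p_value(null, observed), seed)


def orientation_variance_explained(
    ds: DrawingSet, axon_map: AxonMap, per_trial: bool = True
) -> float:
    """Fraction of orientation variance explained by bundle tangents.

    ``R² = 1 - SS_res / SS_tot`` with residuals wrapped axially to
    [-90°, 90°); SS_tot is taken about the circular mean of the observed
    orientations.  Can be negative (tangents worse than the mean).  With
    ``per_trial=False``, per-electrode circular-mean orientations are used.
    """
    if ds.geometry is None:
        raise ValueError("drawing set has no subject geometry")
    tab = ds.descriptor_table()
    positions = build_array(ds.geometry).as_dict()

    s, s_hat = [], []
    for el in ds.electrodes:
        o = tab.loc[tab.electrode == el, "orientation"].to_numpy(dtype=float)
        o = o[np.isfinite(o)]
        if o.size == 0 or el not in positions:
            continue
        t = float(
            _electrode_tangents([el], np.asarray([positions[el]]), axon_map)[0]
        )
        if per_trial:
            s.extend(o)
            s_hat.extend([t] * o.size)
        else:
            s.append(axial_mean(o))
            s_hat.append(t)
    s = np.asarray(s)
    s_hat = np.asarray(s_hat)
    ss_res = float(np.sum(axial_residuals(s, s_hat) ** 2))
    ss_tot = float(np.sum(axial_residuals(s, axial_mean(s)) ** 2))
    if ss_tot == 0:
        warnings.warn("zero total orientation variance; R² undefined", stacklevel=2)
        return math.nan
    return 1.0 - ss_res / ss_tot


def elongation_area_correlation(ds: DrawingSet):
    """Pearson correlation between elongation and area across drawings."""
    tab = ds.descriptor_table()
    ok = np.isfinite(tab.elongation) & np.isfinite(tab.area)
    e = tab.elongation[ok].to_numpy()
    a = tab.area[ok].to_numpy()
    if e.size < 3:
        raise ValueError("need at least 3 drawings with defined descriptors")
    if np.ptp(e) == 0 or np.ptp(a) == 0:
        warnings.warn("zero variance in a descriptor; correlation undefined", stacklevel=2)
        return math.nan, math.nan
    r, p = sps.pearsonr(e, a)
    return float(r), float(p)
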