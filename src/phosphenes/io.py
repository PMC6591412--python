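"""Reading and writing drawings, traces, geometry configs, and datasets.

On-disk dataset layout (all plain text / PNG)::

    dataset/
      geometry.yaml        # subject geometry (one record)
      dataset.json         # grid bounds, pixel size, subject id
      manifest.csv         # subject, electrode, trial, mask file
      masks/<electrode>_<trial>.png   # single-channel, 0/255

Touchscreen traces are ordered 2-D point sequences in screen pixels with
the recorded viewing distance; they are converted to visual-angle
coordinates, closed by joining first and last points, and flood-filled
into binary masks.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image
from skimage.draw import polygon as sk_polygon

from .geometry import Eye, Grid, ImplantType, SubjectGeometry, build_array
from .render import PerceptImage
from .stats import DrawingSet

_EYE = {"RE": Eye.RIGHT, "LE": Eye.LEFT}
_IMPLANT = {"ArgusI": ImplantType.ARGUS_I, "ArgusII": ImplantType.ARGUS_II}


# ---------------------------------------------------------------- geometry

def _geometry_from_record(rec: dict) -> SubjectGeometry:
    return SubjectGeometry(
        implant_type=_IMPLANT[rec["implant"]],
        array_center=tuple(rec["array_center_um"]),
        array_rotation=float(rec["array_rotation_deg"]),
        optic_disc_center=tuple(rec["optic_disc_deg"]),
        eye=_EYE.get(rec.get("eye", "RE"), Eye.RIGHT),
        subject_id=str(rec.get("id", "")),
    )


def _geometry_to_record(geo: SubjectGeometry) -> dict:
    return dict(
        id=geo.subject_id,
        implant=geo.implant_type.value,
        array_center_um=[float(v) for v in geo.array_center],
        array_rotation_deg=float(geo.array_rotation),
        optic_disc_deg=[float(v) for v in geo.optic_disc_center],
        eye=geo.eye.value,
    )


def load_geometry(path) -> SubjectGeometry:
    """Read a single-subject geometry config (YAML)."""
    with open(path) as f:
        rec = yaml.safe_load(f)
    return _geometry_from_record(rec)


def save_geometry(geo: SubjectGeometry, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(_geometry_to_record(geo), f, sort_keys=False)


def load_bundled_subjects() -> dict[str, SubjectGeometry]:
    """Geometry fixtures for the four implanted study subjects."""
    text = resources.files("phosphenes.data").joinpath("subjects.yaml").read_text()
    recs = yaml.safe_load(text)["subjects"]
    return {str(r["id"]): _geometry_from_record(r) for r in recs}


# ------------------------------------------------------------------ traces

@dataclass
class Trace:
    """Raw touchscreen trace: ordered 2-D points in screen pixels.

    ``distance_cm`` is the subject-to-screen viewing distance and
    ``px_per_cm`` the screen resolution; together they convert pixel
    offsets from the screen center (``center_px``) to visual degrees.
    """

    points: np.ndarray  # (n, 2) screen px
    distance_cm: float
    px_per_cm: float
    center_px: tuple[float, float] = (0.0, 0.0)
    subject: str = ""
    electrode: str = ""
    trial: int = 0

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[0] < 3:
            raise ValueError("a trace needs at least 3 points")

    def to_degrees(self) -> np.ndarray:
        """Points as visual-angle coordinates (deg from screen center)."""
        cm = (self.points - np.asarray(self.center_px)) / self.px_per_cm
        return np.degrees(np.arctan2(cm, self.distance_cm))


def trace_to_mask(trace: Trace, grid: Grid) -> PerceptImage:
    """Rasterize a trace into a filled binary mask on ``grid``.

    The trace is converted to visual degrees, closed by connecting the
    first and last points, and its interior flood-filled (even-odd rule;
    for a self-intersecting outline this fills the enclosed regions and a
    warning is emitted).
    """
    deg = trace.to_degrees()
    if np.hypot(*(deg[0] - deg[-1])) > 1e-9:
        deg = np.vstack([deg, deg[:1]])  # close the shape

    cols = (deg[:, 0] - grid.x_range[0]) / grid.step - 0.5
    rows = (deg[:, 1] - grid.y_range[0]) / grid.step - 0.5
    if _self_intersects(deg):
        warnings.warn("self-intersecting trace; filling enclosed regions", stacklevel=2)
    rr, cc = sk_polygon(rows, cols, shape=grid.shape)
    mask = np.zeros(grid.shape, dtype=bool)
    mask[rr, cc] = True
    return PerceptImage(
        mask, grid,
        dict(subject=trace.subject, electrode=trace.electrode, trial=trace.trial,
             source="trace"),
    )


def _self_intersects(poly: np.ndarray) -> bool:
    """Naive O(n²) proper-crossing test on a closed polyline."""
    def cross2(a, b):
        return a[0] * b[1] - a[1] * b[0]

    def crosses(p, q, r, s):
        d1 = cross2(q - p, r - p)
        d2 = cross2(q - p, s - p)
        d3 = cross2(s - r, p - r)
        d4 = cross2(s - r, q - r)
        return (d1 * d2 < 0) and (d3 * d4 < 0)

    n = len(poly) - 1
    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue
            if crosses(poly[i], poly[i + 1], poly[j], poly[j + 1]):
                return True
    return False


# ---------------------------------------------------------------- datasets

def save_drawing_set(ds: DrawingSet, root, truth: dict | None = None) -> Path:
    """Write a dataset directory (geometry, grid sidecar, manifest, masks)."""
    root = Path(root)
    (root / "masks").mkdir(parents=True, exist_ok=True)
    if ds.geometry is not None:
        save_geometry(ds.geometry, root / "geometry.yaml")
    grid = ds.grid
    with open(root / "dataset.json", "w") as f:
        json.dump(
            dict(
                subject=ds.subject_id,
                x_range=list(grid.x_range),
                y_range=list(grid.y_range),
                step_deg=grid.step,
            ),
            f,
            indent=2,
        )
    if truth is not None:
        with open(root / "truth.json", "w") as f:
            json.dump(truth, f, indent=2)

    rows = []
    for el, imgs in ds.drawings.items():
        for t, img in enumerate(imgs):
            rel = f"masks/{el}_{t}.png"
            # row 0 is inferior; PNGs are written top-down (visual-field view)
            arr = (np.flipud(np.asarray(img.data, dtype=bool)) * 255).astype(np.uint8)
            Image.fromarray(arr, mode="L").save(root / rel)
            rows.append(dict(subject=ds.subject_id, electrode=el, trial=t, mask=rel))
    pd.DataFrame(rows).to_csv(root / "manifest.csv", index=False)
    return root


def read_dataset(root) -> DrawingSet:
    """Load a dataset directory written by :func:`save_drawing_set`.

    Raises ``FileNotFoundError`` for missing masks, ``ValueError`` for
    non-binary images or electrode names that are invalid for the
    subject's implant type.
    """
    root = Path(root)
    with open(root / "dataset.json") as f:
        meta = json.load(f)
    grid = Grid(tuple(meta["x_range"]), tuple(meta["y_range"]), meta["step_deg"])
    geometry = None
    geo_path = root / "geometry.yaml"
    if geo_path.exists():
        geometry = load_geometry(geo_path)
        valid_names = set(build_array(geometry).names)
    else:
        valid_names = None

    manifest = pd.read_csv(root / "manifest.csv")
    drawings: dict[str, list[PerceptImage]] = {}
    for rec in manifest.itertuples():
        el = str(rec.electrode)
        if valid_names is not None and el not in valid_names:
            raise ValueError(f"electrode {el!r} invalid for implant")
        path = root / rec.mask
        if not path.exists():
            raise FileNotFoundError(f"mask file missing: {path}")
        arr = np.asarray(Image.open(path).convert("L"))
        vals = np.unique(arr)
        if not np.all(np.isin(vals, [0, 255])):
            raise ValueError(f"mask not binary (values {vals[:5]}...): {path}")
        data = np.flipud(arr > 0)  # back to row 0 = inferior
        drawings.setdefault(el, []).append(
            PerceptImage(data, grid, dict(subject=rec.subject, electrode=el, trial=rec.trial))
        )
    return DrawingSet(
        subject_id=str(meta["subject"]), grid=grid, drawings=drawings, geometry=geometry
    )


def descriptor_csv(ds: DrawingSet, path) -> None:
    """Write the per-drawing shape-descriptor table as CSV."""
    tab = ds.descriptor_table().copy()
    tab.insert(0, "subject", ds.subject_id)
    tab.to_csv(path, index=False)
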