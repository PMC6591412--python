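"""Synthetic subjects and trial drawings with known ground truth.

The generator emulates the statistical structure of a single-electrode
drawing study: a subject geometry sampled from published landmark ranges
(optic disc ~15.5° ± 1.1° nasal, 1.5° ± 0.9° superior; array center and
rotation spanning the implanted subjects' estimates), a subject-specific
axon map, and per-electrode trial drawings obtained by perturbing the
noiseless axon-map percept rendered at the true ``(rho*, lambda*)``.

Trial-to-trial noise mimics drawing variability: a centroid jitter (hand
placement), a small random rotation (orientation error), a global area
rescaling (no depth reference — perceived size is uncalibrated), and
boundary roughening of fixed physical amplitude (stroke wobble).  All
noise magnitudes are configurable and zero-noise reproduces the model
percept exactly.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
from scipy import ndimage

from .axon_map import AxonMap, build_axon_map, DEFAULT_R_MAX, DEFAULT_STEP
from .geometry import Grid, ImplantType, SubjectGeometry, build_array
from .render import (
    DEFAULT_THRESHOLD,
    AxonRenderEngine,
    ModelParams,
    PerceptImage,
    threshold_percept,
)
from .stats import DrawingSet


@dataclass
class SynthConfig:
    """Study conditions for the synthetic generator.

    Geometry ranges span the implanted subjects' estimated placements;
    the optic-disc location is drawn from the population distribution
    (mean ± SD, truncated at 2 SD).  ``rho``/``lam`` are the true decay
    constants (µm) used to render the noiseless percepts.
    """

    implant_type: ImplantType = ImplantType.ARGUS_II
    n_electrodes: int = 12
    trials: int = 5
    rho: float = 300.0
    lam: float = 1000.0
    threshold: float = DEFAULT_THRESHOLD
    # geometry sampling ranges (uniform) / distributions (normal, 2 SD trunc)
    center_x_um: tuple[float, float] = (-2150.0, -650.0)
    center_y_um: tuple[float, float] = (-850.0, 400.0)
    rotation_deg: tuple[float, float] = (-54.0, -22.0)
    disc_azimuth_deg: tuple[float, float] = (15.5, 1.1)  # mean, sd
    disc_elevation_deg: tuple[float, float] = (1.5, 0.9)  # mean, sd
    # trial-to-trial noise
    centroid_jitter_um: float = 200.0
    orientation_jitter_deg: float = 10.0
    area_scale_sigma: float = 0.15
    #: boundary roughening amplitude as a retinal length (≈ one pixel of the
    #: default 0.2°/px raster); kept in physical units so the noise does not
    #: depend on the analysis raster
    roughness_um: float = 56.0
    # axon map sampling
    phi0_samples: int = 500
    axon_r_max: float = DEFAULT_R_MAX
    axon_step: float = DEFAULT_STEP
    seed: int = 0

    def __post_init__(self):
        if self.trials < 1:
            raise ValueError("trials must be >= 1")
        for name in ("centroid_jitter_um", "orientation_jitter_deg", "area_scale_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _truncated_normal(rng, mean: float, sd: float, n_sd: float = 2.0) -> float:
    if sd == 0:
        return mean
    while True:
        x = rng.normal(mean, sd)
        if abs(x - mean) <= n_sd * sd:
            return float(x)


def generate_subject(cfg: SynthConfig, rng=None):
    """Sample a subject geometry and build its axon map."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    geometry = SubjectGeometry(
        implant_type=cfg.implant_type,
        array_center=(
            rng.uniform(*cfg.center_x_um),
            rng.uniform(*cfg.center_y_um),
        ),
        array_rotation=rng.uniform(*cfg.rotation_deg),
        optic_disc_center=(
            _truncated_normal(rng, *cfg.disc_azimuth_deg),
            _truncated_normal(rng, *cfg.disc_elevation_deg),
        ),
        subject_id=f"synth-{cfg.seed}",
    )
    axon_map = build_axon_map(
        geometry,
        phi0_samples=cfg.phi0_samples,
        r_max=cfg.axon_r_max,
        step=cfg.axon_step,
    )
    return geometry, axon_map


def _jitter_drawing(mask: np.ndarray, cfg: SynthConfig, pixel_um: float, rng) -> np.ndarray:
    """Apply one trial's worth of drawing noise to a binary mask."""
    out = mask.astype(float)
    angle = rng.normal(0.0, cfg.orientation_jitter_deg)
    lin_scale = math.exp(rng.normal(0.0, cfg.area_scale_sigma)) ** 0.5
    shift_px = rng.normal(0.0, cfg.centroid_jitter_um / pixel_um, size=2)

    if angle != 0.0 or lin_scale != 1.0 or np.any(shift_px != 0.0):
        cy, cx = ndimage.center_of_mass(out)
        a = math.radians(angle)
        # output->input map: rotate by -a and unscale about the centroid,
        # then undo the (dy, dx) translation
        rot = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
        m = rot.T / lin_scale
        center = np.array([cy, cx])
        offset = center - m @ (center + shift_px[::-1])
        out = ndimage.affine_transform(out, m, offset=offset, order=0, mode="constant")

    binary = out > 0.5
    if cfg.roughness_um > 0 and binary.any() and not binary.all():
        # Stroke wobble: displace the outline by a smooth, mean-zero random
        # field with RMS amplitude roughness_um.  The signed distance to the
        # boundary is perturbed and re-thresholded, which keeps the noise
        # spatially correlated (no speckle) and area-neutral in expectation.
        amp_px = cfg.roughness_um / pixel_um
        corr_px = max(1.0, 280.0 / pixel_um)  # ~1 deg wobble wavelength
        sd = ndimage.distance_transform_edt(binary) - ndimage.distance_transform_edt(~binary)
        field = ndimage.gaussian_filter(rng.standard_normal(binary.shape), corr_px)
        rms = float(np.sqrt(np.mean(field**2)))
        if rms > 0:
            binary = (sd + field * (amp_px / rms)) > 0
    return binary


def generate_drawings(
    geometry: SubjectGeometry,
    axon_map: AxonMap,
    cfg: SynthConfig,
    grid: Grid | None = None,
    rng=None,
):
    """Render noiseless percepts and emit jittered trial drawings.

    Electrodes are a random subset of the implant whose noiseless percept
    is non-empty; each gets ``cfg.trials`` independently perturbed copies.
    Returns ``(DrawingSet, truth)`` where ``truth`` records the generating
    parameters and per-electrode noiseless descriptors.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    grid = grid or Grid()
    engine = AxonRenderEngine(axon_map, grid)
    params = ModelParams(rho=cfg.rho, lam=cfg.lam, threshold=cfg.threshold)
    array = build_array(geometry)

    # keep electrodes that land inside the raster with margin
    xs_deg = np.asarray([grid.x_range, grid.y_range])
    ok = []
    for name, c in array.as_dict().items():
        az, el = c[0] / 1000 * 3.6, c[1] / 1000 * 3.6
        if (
            xs_deg[0][0] + 2 < az < xs_deg[0][1] - 2
            and xs_deg[1][0] + 2 < el < xs_deg[1][1] - 2
        ):
            ok.append(name)
    chosen = [str(n) for n in rng.choice(ok, size=min(cfg.n_electrodes, len(ok)), replace=False)]

    drawings: dict[str, list[PerceptImage]] = {}
    skipped = []
    for name in chosen:
        center = array[name]
        percept = threshold_percept(
            engine.render(center, params),
            cfg.threshold,
            provenance=dict(model="axon_map", electrode=name, rho=cfg.rho, lam=cfg.lam),
        )
        if not percept.data.any():
            skipped.append(name)
            continue
        trials = []
        for t in range(cfg.trials):
            noisy = _jitter_drawing(percept.data, cfg, grid.pixel_size_um, rng)
            trials.append(
                PerceptImage(noisy, grid, dict(percept.provenance, trial=t, synthetic=True))
            )
        drawings[name] = trials

    ds = DrawingSet(
        subject_id=geometry.subject_id or "synth",
        grid=grid,
        drawings=drawings,
        geometry=geometry,
    )
    truth = dict(
        rho=cfg.rho,
        lam=cfg.lam,
        threshold=cfg.threshold,
        electrodes=list(drawings.keys()),
        skipped_empty=skipped,
        geometry=dict(
            implant_type=geometry.implant_type.value,
            array_center=list(geometry.array_center),
            array_rotation=geometry.array_rotation,
            optic_disc_center=list(geometry.optic_disc_center),
        ),
        config={**asdict(cfg), "implant_type": cfg.implant_type.value},
    )
    return ds, truth


def generate_dataset(cfg: SynthConfig, grid: Grid | None = None):
    """Convenience: sample a subject and its drawings in one call."""
    rng = np.random.default_rng(cfg.seed)
    geometry, axon_map = generate_subject(cfg, rng)
    ds, truth = generate_drawings(geometry, axon_map, cfg, grid, rng)
    return geometry, axon_map, ds, truth
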