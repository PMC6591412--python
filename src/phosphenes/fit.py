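"""Model fitting: descriptor cost, particle-swarm search, and LOEO-CV.

Models are fit to drawings through their shape descriptors only (area,
orientation, elongation — location is deliberately not compared).  For a
candidate parameter set, one percept is rendered per electrode and a
coefficient of determination is computed per descriptor across drawings,

    R²_d = 1 - SS_res / SS_tot,

with the predicted descriptor of a drawing being that of its electrode's
rendered percept, and orientation residuals wrapped axially.  The cost is

    c = sum_d (1 - R²_d),   d in {area, orientation, elongation}.

The cost surface is nonconvex, so it is minimized by particle swarm
optimization (swarm size 10 × number of parameters, 5 random restarts,
best run kept).  Model comparison uses leave-one-electrode-out
cross-validation: models with different parameter counts (scoreboard: rho;
axon map: rho, lambda) are compared on held-out prediction error, scored
per electrode and tested with a two-tailed Wilcoxon signed-rank test on
log errors.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .axon_map import AxonMap, _axial_deg
from .geometry import DEFAULT_CONVERTER, Grid, build_array
from .render import DEFAULT_THRESHOLD, AxonRenderEngine, ModelParams
from .stats import DrawingSet, axial_mean, axial_residuals

#: Default parameter bounds, µm (generous margins around plausible fits).
DEFAULT_BOUNDS = {"rho": (10.0, 3000.0), "lam": (10.0, 5000.0)}

#: PSO hyperparameters, logged in every FitResult.
PSO_CONFIG = dict(
    inertia=0.7,
    cognitive=1.5,
    social=1.5,
    swarm_per_param=10,
    restarts=5,
    max_iters=40,
    tol=1e-8,
    patience=8,
)

_EPS_LOG = 1e-9


def descriptor_r2(observed, predicted, angular: bool = False) -> float:
    """Coefficient of determination of predicted shape descriptors.

    ``SS_tot`` is taken about the mean of the observed values (circular
    doubled-angle mean when ``angular``); angular residuals are wrapped to
    [-90°, 90°).  Returns NaN (with a warning) when ``SS_tot`` is zero.
    """
    s = np.asarray(observed, dtype=float)
    s_hat = np.asarray(predicted, dtype=float)
    if s.size != s_hat.size or s.size < 2:
        raise ValueError("observed/predicted must have equal length >= 2")
    if angular:
        ss_res = float(np.sum(axial_residuals(s, s_hat) ** 2))
        ss_tot = float(np.sum(axial_residuals(s, axial_mean(s)) ** 2))
    else:
        ss_res = float(np.sum((s - s_hat) ** 2))
        ss_tot = float(np.sum((s - s.mean()) ** 2))
    if ss_tot == 0:
        warnings.warn("zero SS_tot; R² undefined", stacklevel=2)
        return math.nan
    return 1.0 - ss_res / ss_tot


def _moments_to_descriptors(m: np.ndarray):
    """Vectorized (area, orientation, elongation) from raw binary moments.

    ``m`` is ``(n, 6)``: (m00, Σx, Σy, Σx², Σxy, Σy²) in pixel units.
    Empty percepts yield area 0 and NaN orientation/elongation.
    """
    m = np.atleast_2d(m)
    m00 = m[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        xbar = m[:, 1] / m00
        ybar = m[:, 2] / m00
        mu20 = m[:, 3] / m00 - xbar**2
        mu02 = m[:, 5] / m00 - ybar**2
        mu11 = m[:, 4] / m00 - xbar * ybar
        theta = _axial_deg(0.5 * np.degrees(np.arctan2(2.0 * mu11, mu20 - mu02)))
        half_gap = np.sqrt(4.0 * mu11**2 + (mu20 - mu02) ** 2) / 2.0
        l1 = (mu20 + mu02) / 2.0 + half_gap
        l2 = (mu20 + mu02) / 2.0 - half_gap
        elong = np.sqrt(np.clip(1.0 - l2 / l1, 0.0, 1.0))
    degen = (mu11 == 0) & (mu20 == mu02)
    theta = np.where(degen, 0.0, theta)
    point = l1 <= 0
    theta = np.where(point, 0.0, theta)
    elong = np.where(point, 0.0, elong)
    empty = m00 == 0
    theta = np.where(empty, np.nan, theta)
    elong = np.where(empty, np.nan, elong)
    return m00, theta, elong


class CostEvaluator:
    """Batched evaluator of the descriptor cost for one model and dataset.

    Precomputes observed descriptors, per-electrode rendering state
    (candidate fronts for the axon map; pixel distances for the
    scoreboard), and per-descriptor total sums of squares.  ``costs``
    then evaluates a whole swarm of parameter vectors cheaply.
    """

    def __init__(
        self,
        model: str,
        ds: DrawingSet,
        axon_map: AxonMap | None,
        grid: Grid,
        electrodes: list[str] | None = None,
        threshold: float = DEFAULT_THRESHOLD,
        engine: AxonRenderEngine | None = None,
    ):
        if model not in ("scoreboard", "axon_map"):
            raise ValueError(f"unknown model: {model!r}")
        if model == "axon_map" and axon_map is None:
            raise ValueError("axon_map model requires an AxonMap")
        self.model = model
        self.grid = grid
        self.threshold = threshold
        self.electrodes = list(electrodes) if electrodes is not None else ds.electrodes

        tab = ds.descriptor_table()
        tab = tab[tab.electrode.isin(self.electrodes)]
        self.obs_area = tab.area.to_numpy(dtype=float)
        self.obs_theta = tab.orientation.to_numpy(dtype=float)
        self.obs_elong = tab.elongation.to_numpy(dtype=float)
        names = self.electrodes
        self.el_of_drawing = np.asarray([names.index(e) for e in tab.electrode])
        self.n_drawings = len(tab)

        # per-drawing mean squared deviations (the SS_tot terms)
        self.msd = {
            "area": float(np.nanvar(self.obs_area)),
            "orientation": float(
                np.nanmean(
                    axial_residuals(
                        self.obs_theta[np.isfinite(self.obs_theta)],
                        axial_mean(self.obs_theta[np.isfinite(self.obs_theta)]),
                    )
                    ** 2
                )
            ),
            "elongation": float(np.nanvar(self.obs_elong)),
        }

        positions = build_array(ds.geometry).as_dict() if ds.geometry else None
        if positions is None:
            raise ValueError("drawing set has no subject geometry")
        self.centers = np.asarray([positions[e] for e in names], dtype=float)

        if model == "axon_map":
            self.engine = engine or AxonRenderEngine(axon_map, grid)
            for c in self.centers:
                self.engine.fronts(c)  # warm the per-electrode cache
        else:
            xx, yy = grid.pixel_centers_um(DEFAULT_CONVERTER)
            self._d2 = np.stack(
                [(xx.ravel() - c[0]) ** 2 + (yy.ravel() - c[1]) ** 2 for c in self.centers]
            )  # (n_el, n_pix)
            ny, nx = grid.shape
            iyy, ixx = np.mgrid[0:ny, 0:nx]
            ix, iy = ixx.ravel().astype(float), iyy.ravel().astype(float)
            self._basis = np.stack(
                [np.ones_like(ix), ix, iy, ix**2, ix * iy, iy**2]
            )  # (6, n_pix)

    def predicted_descriptors(self, params: np.ndarray):
        """Per-electrode (area, theta, elongation), each ``(n_particles, n_el)``."""
        params = np.atleast_2d(np.asarray(params, dtype=float))
        n_p = params.shape[0]
        n_el = len(self.electrodes)
        area = np.empty((n_p, n_el))
        theta = np.empty((n_p, n_el))
        elong = np.empty((n_p, n_el))
        if self.model == "axon_map":
            for j, c in enumerate(self.centers):
                mom = self.engine.batched_descriptors(
                    c, params[:, 0], params[:, 1], self.threshold
                )
                area[:, j], theta[:, j], elong[:, j] = _moments_to_descriptors(mom)
        else:
            # scoreboard: binary disc = d² <= -2 rho² ln(threshold)
            cut = -2.0 * params[:, 0] ** 2 * math.log(self.threshold)  # (n_p,)
            for j in range(n_el):
                mask = self._d2[j][None, :] <= cut[:, None]  # (n_p, n_pix)
                mom = mask @ self._basis.T  # (n_p, 6)
                area[:, j], theta[:, j], elong[:, j] = _moments_to_descriptors(mom)
        return area, theta, elong

    def costs(self, params: np.ndarray, msd_override: dict | None = None) -> np.ndarray:
        """Cost ``c = sum_d (1 - R²_d)`` for each parameter vector.

        ``msd_override`` supplies per-drawing mean squared deviations from a
        different (training) set, for held-out evaluation.
        """
        params = np.atleast_2d(np.asarray(params, dtype=float))
        area, theta, elong = self.predicted_descriptors(params)
        msd = msd_override or self.msd
        idx = self.el_of_drawing
        out = np.zeros(params.shape[0])

        # area
        pred = area[:, idx]
        obs = self.obs_area[None, :]
        out += self._one_minus_r2(((obs - pred) ** 2), msd["area"])
        # orientation: undefined observed or predicted -> worst-case residual
        pred = theta[:, idx]
        obs = self.obs_theta[None, :]
        res = _axial_deg(obs - pred)
        res = np.where(np.isfinite(res), res, 90.0)
        out += self._one_minus_r2(res**2, msd["orientation"])
        # elongation
        pred = elong[:, idx]
        obs = self.obs_elong[None, :]
        res = obs - pred
        res = np.where(np.isfinite(res), res, 1.0)
        out += self._one_minus_r2(res**2, msd["elongation"])
        return out

    def _one_minus_r2(self, sq_res: np.ndarray, msd: float) -> np.ndarray:
        ss_tot = msd * self.n_drawings
        if ss_tot <= 0:
            # degenerate descriptor variance: contribute residuals on an
            # absolute scale so the term stays finite and >= 0
            return np.sum(sq_res, axis=1) / max(self.n_drawings, 1)
        return np.sum(sq_res, axis=1) / ss_tot


def cost(
    params: ModelParams,
    model: str,
    ds: DrawingSet,
    axon_map: AxonMap | None,
    grid: Grid,
) -> float:
    """Descriptor cost of one parameter set (convenience wrapper)."""
    ev = CostEvaluator(model, ds, axon_map, grid, threshold=params.threshold)
    vec = [params.rho] if model == "scoreboard" else [params.rho, params.lam]
    return float(ev.costs(np.asarray([vec]))[0])


def _pso_minimize(batch_cost, bounds: np.ndarray, n_particles: int, rng,
                  max_iters: int, tol: float, patience: int):
    """Minimize with a standard global-best particle swarm (bounded)."""
    lo, hi = bounds[:, 0], bounds[:, 1]
    span = hi - lo
    ndim = bounds.shape[0]
    pos = rng.uniform(lo, hi, size=(n_particles, ndim))
    vel = rng.uniform(-span, span, size=(n_particles, ndim)) * 0.1

    costs = batch_cost(pos)
    bad = ~np.isfinite(costs)
    while bad.any():
        pos[bad] = rng.uniform(lo, hi, size=(int(bad.sum()), ndim))
        costs[bad] = batch_cost(pos[bad])
        bad = ~np.isfinite(costs)
    pbest, pcost = pos.copy(), costs.copy()
    g = int(np.argmin(pcost))
    gbest, gcost = pbest[g].copy(), float(pcost[g])

    stall = 0
    w, c1, c2 = PSO_CONFIG["inertia"], PSO_CONFIG["cognitive"], PSO_CONFIG["social"]
    for _ in range(max_iters):
        r1 = rng.random((n_particles, ndim))
        r2 = rng.random((n_particles, ndim))
        vel = w * vel + c1 * r1 * (pbest - pos) + c2 * r2 * (gbest[None, :] - pos)
        pos = pos + vel
        clipped = (pos < lo) | (pos > hi)
        pos = np.clip(pos, lo, hi)
        vel[clipped] = 0.0
        costs = batch_cost(pos)
        resample = ~np.isfinite(costs)
        if resample.any():
            pos[resample] = rng.uniform(lo, hi, size=(int(resample.sum()), ndim))
            vel[resample] = 0.0
            costs[resample] = batch_cost(pos[resample])
        better = costs < pcost
        pbest[better], pcost[better] = pos[better], costs[better]
        g = int(np.argmin(pcost))
        if pcost[g] < gcost - tol:
            stall = 0
        else:
            stall += 1
        if pcost[g] < gcost:
            gbest, gcost = pbest[g].copy(), float(pcost[g])
        if stall >= patience:
            break
    return gbest, gcost


def pso_fit(
    model: str,
    ds: DrawingSet,
    axon_map: AxonMap | None,
    grid: Grid,
    bounds: dict | None = None,
    seed: int = 0,
    electrodes: list[str] | None = None,
    evaluator: CostEvaluator | None = None,
    threshold: float = DEFAULT_THRESHOLD,
):
    """Fit model parameters by particle swarm optimization.

    Swarm size is 10 × the number of parameters; the search is restarted 5
    times from random initializations and the best run is kept.  Fully
    deterministic given ``seed``.  Returns ``(ModelParams, best_cost)``.
    """
    b = dict(DEFAULT_BOUNDS, **(bounds or {}))
    if evaluator is None:
        evaluator = CostEvaluator(
            model, ds, axon_map, grid, electrodes=electrodes, threshold=threshold
        )
    n_params = 1 if model == "scoreboard" else 2
    arr = np.asarray(
        [b["rho"]] if n_params == 1 else [b["rho"], b["lam"]], dtype=float
    )
    rng = np.random.default_rng(seed)
    best, best_cost = None, np.inf
    for _ in range(PSO_CONFIG["restarts"]):
        x, c = _pso_minimize(
            evaluator.costs,
            arr,
            n_particles=PSO_CONFIG["swarm_per_param"] * n_params,
            rng=rng,
            max_iters=PSO_CONFIG["max_iters"],
            tol=PSO_CONFIG["tol"],
            patience=PSO_CONFIG["patience"],
        )
        if c < best_cost:
            best, best_cost = x, c
    params = (
        ModelParams(rho=float(best[0]), threshold=threshold)
        if n_params == 1
        else ModelParams(rho=float(best[0]), lam=float(best[1]), threshold=threshold)
    )
    return params, float(best_cost)


@dataclass
class FitResult:
    """Leave-one-electrode-out cross-validation result for one model."""

    model: str
    fold_electrodes: list[str]
    fold_params: list[ModelParams]
    fold_costs: list[float]  # held-out cost per electrode
    summary: dict = field(default_factory=dict)  # param -> (mean, sem)
    pso_config: dict = field(default_factory=dict)

    @property
    def mean_params(self) -> dict:
        return {k: v[0] for k, v in self.summary.items()}

    def log_errors(self) -> np.ndarray:
        """Natural log of per-electrode held-out cost (+ small epsilon)."""
        return np.log(np.asarray(self.fold_costs, dtype=float) + _EPS_LOG)

    def to_json(self, path) -> None:
        payload = dict(
            model=self.model,
            fold_electrodes=self.fold_electrodes,
            fold_params=[
                {k: v for k, v in vars(p).items() if v is not None}
                for p in self.fold_params
            ],
            fold_costs=self.fold_costs,
            summary=self.summary,
            pso_config=self.pso_config,
        )
        with open(path, "w") as f:
            json.dump(payload, f, indent=2)

    @classmethod
    def from_json(cls, path) -> "FitResult":
        with open(path) as f:
            d = json.load(f)
        return cls(
            model=d["model"],
            fold_electrodes=d["fold_electrodes"],
            fold_params=[ModelParams(**p) for p in d["fold_params"]],
            fold_costs=d["fold_costs"],
            summary={k: tuple(v) for k, v in d["summary"].items()},
            pso_config=d["pso_config"],
        )


def loeo_cv(
    model: str,
    ds: DrawingSet,
    axon_map: AxonMap | None,
    grid: Grid,
    seed: int = 0,
    bounds: dict | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> FitResult:
    """Leave-one-electrode-out cross-validation of a percept model.

    For every electrode, a single (rho[, lambda]) is fit to all other
    electrodes' drawings and the held-out electrode's drawings are scored
    with the same descriptor cost, normalizing by the training set's
    descriptor variances.  Failed folds are recorded (cost NaN) without
    aborting the remaining folds.
    """
    names = ds.electrodes
    if len(names) < 2:
        raise ValueError("need at least 2 electrodes for LOEO-CV")
    engine = AxonRenderEngine(axon_map, grid) if model == "axon_map" else None

    fold_params, fold_costs = [], []
    rng = np.random.default_rng(seed)
    for held in names:
        train = [e for e in names if e != held]
        try:
            ev_train = CostEvaluator(
                model, ds, axon_map, grid,
                electrodes=train, threshold=threshold, engine=engine,
            )
            params, _ = pso_fit(
                model, ds, axon_map, grid,
                bounds=bounds,
                seed=int(rng.integers(2**31 - 1)),
                evaluator=ev_train,
                threshold=threshold,
            )
            ev_test = CostEvaluator(
                model, ds, axon_map, grid,
                electrodes=[held], threshold=threshold, engine=engine,
            )
            vec = [params.rho] if model == "scoreboard" else [params.rho, params.lam]
            c = float(ev_test.costs(np.asarray([vec]), msd_override=ev_train.msd)[0])
        except Exception as exc:  # keep remaining folds alive
            warnings.warn(f"fold {held} failed: {exc}", stacklevel=2)
            params, c = None, math.nan
        fold_params.append(params)
        fold_costs.append(c)

    summary = {}
    for key in ("rho", "lam"):
        vals = np.asarray(
            [getattr(p, key) for p in fold_params if p is not None and getattr(p, key) is not None],
            dtype=float,
        )
        if vals.size:
            sem = float(np.std(vals, ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else 0.0
            summary[key] = (float(vals.mean()), sem)
    return FitResult(
        model=model,
        fold_electrodes=list(names),
        fold_params=fold_params,
        fold_costs=fold_costs,
        summary=summary,
        pso_config=dict(PSO_CONFIG),
    )


def compare_models(fit_a: FitResult, fit_b: FitResult):
    """Two-tailed Wilcoxon signed-rank test on paired per-electrode log errors.

    Returns ``(statistic, p, diffs)`` where ``statistic`` is the signed rank
    sum (positive when ``fit_a`` has larger errors) and ``diffs`` the paired
    log-error differences ``log(err_a) - log(err_b)`` for plotting.
    Swapping the inputs flips the sign of the statistic.
    """
    if fit_a.fold_electrodes != fit_b.fold_electrodes:
        raise ValueError("fits cover different electrodes")
    diffs = fit_a.log_errors() - fit_b.log_errors()
    nz = diffs[diffs != 0]
    if nz.size == 0:
        return 0.0, 1.0, diffs
    ranks = sps.rankdata(np.abs(nz))
    signed = float(np.sum(np.sign(nz) * ranks))
    method = "exact" if nz.size < 6 else "auto"
    p = float(sps.wilcoxon(nz, alternative="two-sided", method=method).pvalue)
    return signed, p, diffs
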