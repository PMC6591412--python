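import math

import numpy as np
import pytest

from phosphenes.axon_map import BundleTrajectory, assemble_axon_map
from phosphenes.geometry import Grid, MICRONS_PER_DEGREE
from phosphenes.render import (
    AxonRenderEngine,
    ModelParams,
    _render_axon_generic,
    render_axon,
    render_scoreboard,
    scoreboard_intensity_at,
    simulate_distance_series,
    threshold_percept,
)
from phosphenes.shapes import describe


def straight_horizontal_map(geometry, ys_um, x_step_um=50.0, extent_um=6000.0):
    """Idealized map: straight parallel horizontal bundles, disc toward +x.

    Placing bundle rows on the rendering grid's pixel-center rows makes
    every pixel an exact soma location (no nearest-bundle snap).
    """
    bundles = []
    xs = np.arange(-extent_um, extent_um + x_step_um, x_step_um, dtype=float)
    for y in ys_um:
        pts = np.column_stack([xs, np.full_like(xs, y)])
        arclen = (xs[-1] - xs)  # distance to disc-ward (+x) end
        bundles.append(BundleTrajectory(0.0, pts, arclen))
    return assemble_axon_map(bundles, geometry)


class TestModelParams:
    @pytest.mark.parametrize("kw", [dict(rho=-1), dict(rho=300, lam=0),
                                    dict(rho=300, threshold=1.5)])
    def test_validation(self, kw):
        with pytest.raises(ValueError):
            ModelParams(**kw)


class TestScoreboard:
    def test_peak_at_electrode(self):
        assert scoreboard_intensity_at((100.0, -50.0), (100.0, -50.0), 300.0) == 1.0

    def test_value_at_rho_is_inv_sqrt_e(self):
        v = scoreboard_intensity_at((300.0, 0.0), (0.0, 0.0), 300.0)
        assert v == pytest.approx(1.0 / math.sqrt(math.e))

    def test_radial_symmetry(self, rng):
        grid = Grid((-6, 6), (-6, 6), 0.1)
        img = render_scoreboard((0.0, 0.0), ModelParams(400.0), grid)
        assert np.allclose(img.data, img.data[::-1, :], atol=1e-12)
        assert np.allclose(img.data, img.data[:, ::-1], atol=1e-12)

    def test_thresholded_percept_is_disc_of_radius_rho(self):
        rho = 437.0
        grid = Grid((-6, 6), (-6, 6), 0.05)
        img = render_scoreboard((0.0, 0.0), ModelParams(rho), grid)
        percept = threshold_percept(img)
        xx, yy = grid.pixel_centers_um()
        d = np.hypot(xx, yy)
        px_um = grid.pixel_size_um
        assert d[percept.data].max() <= rho + px_um
        outside = ~percept.data
        assert d[outside].min() >= rho - px_um
        area_um2 = percept.data.sum() * px_um**2
        assert area_um2 == pytest.approx(math.pi * rho**2, rel=0.03)

    def test_warns_when_electrode_off_grid(self):
        grid = Grid((-2, 2), (-2, 2), 0.2)
        with pytest.warns(UserWarning):
            render_scoreboard((5000.0, 0.0), ModelParams(300.0), grid)


class TestThreshold:
    def test_higher_threshold_is_subset(self):
        grid = Grid((-4, 4), (-4, 4), 0.1)
        img = render_scoreboard((0.0, 0.0), ModelParams(300.0), grid)
        lo = threshold_percept(img, 0.4).data
        hi = threshold_percept(img, 0.8).data
        assert np.all(hi <= lo)
        assert hi.sum() < lo.sum()

    def test_near_one_keeps_only_peak(self):
        grid = Grid((-4, 4), (-4, 4), 0.1)
        # electrode exactly on a pixel center so the peak value 1 is attained
        e = (0.05 * MICRONS_PER_DEGREE, 0.05 * MICRONS_PER_DEGREE)
        img = render_scoreboard(e, ModelParams(300.0), grid)
        peak = threshold_percept(img, 1.0 - 1e-12).data
        assert peak.sum() == 1

    def test_invalid_threshold(self):
        grid = Grid((-1, 1), (-1, 1), 0.5)
        img = render_scoreboard((0.0, 0.0), ModelParams(300.0), grid)
        with pytest.raises(ValueError):
            threshold_percept(img, 0.0)


class TestAxonRender:
    def test_fast_engine_matches_generic(self, small_map, fit_grid):
        params = ModelParams(437.0, 1420.0)
        engine = AxonRenderEngine(small_map, fit_grid)
        for e in [(-1800.0, 400.0), (-3000.0, -800.0), (-500.0, 1500.0)]:
            fast = engine.render(e, params).data
            ref = _render_axon_generic(
                e, params, small_map, fit_grid, "arclength", "max"
            ).data
            assert np.abs(fast - ref).max() < 1e-12

    def test_normalized_to_peak_one(self, small_map, fit_grid):
        img = render_axon((-1800.0, 400.0), ModelParams(200.0, 600.0), small_map, fit_grid)
        assert img.data.max() == pytest.approx(1.0)
        assert img.data.min() >= 0.0

    def test_requires_lam(self, small_map, fit_grid):
        with pytest.raises(ValueError):
            render_axon((0.0, 0.0), ModelParams(300.0), small_map, fit_grid)

    def test_lambda_infinity_is_max_over_path_scoreboard(self, small_map, fit_grid):
        # with no decay along the axon, a pixel lights up according to its
        # path's closest approach to the electrode
        e = (-2000.0, 300.0)
        rho = 400.0
        img = render_axon(e, ModelParams(rho, 1e9), small_map, fit_grid)
        amap = small_map
        xx, yy = fit_grid.pixel_centers_um()
        pix = np.column_stack([xx.ravel(), yy.ravel()])
        vidx = amap.nearest_vertex(pix)
        expected = np.empty(len(pix))
        g2 = (amap.points[:, 0] - e[0]) ** 2 + (amap.points[:, 1] - e[1]) ** 2
        for p, k in enumerate(vidx):
            end = amap.bundle_ptr[amap.bundle_index[k] + 1]
            expected[p] = np.exp(-g2[k:end].min() / (2 * rho**2))
        expected = (expected / expected.max()).reshape(fit_grid.shape)
        assert np.abs(img.data - expected).max() < 1e-9

    def test_straight_bundle_closed_form(self, subject4):
        # max-over-path of the product decay has a closed form for straight
        # horizontal bundles: exp(-t²/2ρ²) · exp(-d²/(2(ρ²+λ²))) for a soma
        # d peripheral of the electrode at orthogonal offset t
        grid = Grid((-10, 10), (-6, 6), 0.25)
        ys_um = grid.ys * MICRONS_PER_DEGREE
        amap = straight_horizontal_map(subject4, ys_um, x_step_um=10.0)
        rho, lam = 300.0, 500.0
        e = (1000.0, 0.0)
        img = render_axon(e, ModelParams(rho, lam), amap, grid)
        u, v = 1 / (2 * rho**2), 1 / (2 * lam**2)
        xx, yy = grid.pixel_centers_um()
        # somas snap to the nearest bundle vertex (10 µm grid along x)
        xs = np.round((xx + 6000.0) / 10.0) * 10.0 - 6000.0
        t = yy - e[1]
        # peripheral somas (x < xe): optimum drive point between soma and electrode
        d = np.clip(e[0] - xs, 0.0, None)
        expected = np.exp(-(t**2) * u - d**2 * (u * v) / (u + v))
        # central somas (x > xe): the path never comes back to the electrode
        central = xs > e[0]
        expected[central] = np.exp(
            -(t**2)[central] * u - ((xs - e[0]) ** 2)[central] * u
        )
        expected /= expected.max()
        assert np.abs(img.data - expected).max() < 1e-3

    def test_euclidean_metric_equals_arclength_for_straight_bundles(self, subject4):
        grid = Grid((-8, 8), (-4, 4), 0.5)
        amap = straight_horizontal_map(subject4, grid.ys * MICRONS_PER_DEGREE,
                                       x_step_um=5.0, extent_um=4000.0)
        params = ModelParams(300.0, 500.0)
        e = (500.0, 0.0)
        a = _render_axon_generic(e, params, amap, grid, "arclength", "max").data
        b = _render_axon_generic(e, params, amap, grid, "euclidean", "max").data
        # along a straight bundle the soma-to-vertex arclength equals the
        # euclidean distance up to the sub-vertex snap of the soma position
        assert np.abs(a - b).max() < 0.01

    def test_sum_aggregation_runs_and_differs(self, small_map, fit_grid):
        params = ModelParams(300.0, 800.0)
        e = (-1800.0, 400.0)
        mx = _render_axon_generic(e, params, small_map, fit_grid, "arclength", "max").data
        sm = _render_axon_generic(e, params, small_map, fit_grid, "arclength", "sum").data
        assert sm.max() == pytest.approx(1.0)
        assert not np.allclose(mx, sm)

    def test_papillomacular_electrode_percept_near_horizontal(self, dense_map):
        # bundles between fovea and disc run horizontally; with lam > rho the
        # percept elongates along them
        grid = Grid((-2, 12), (-5, 7), 0.2)
        img = render_axon((2200.0, 80.0), ModelParams(200.0, 1000.0), dense_map, grid)
        d = describe(threshold_percept(img).data)
        assert abs(d.orientation) < 10.0


class TestDistanceSeries:
    def test_equal_rho_gives_identical_percepts(self, small_map, fit_grid):
        out = simulate_distance_series(
            (-1800.0, 300.0), [500.0, 500.0], 500.0, small_map, fit_grid
        )
        assert np.array_equal(out[0].data, out[1].data)

    def test_elongation_decreases_with_electrode_lift(self, dense_map):
        grid = Grid((-24, 10), (-16, 16), 0.2)
        out = simulate_distance_series(
            (-1600.0, 500.0), [300.0, 500.0, 800.0, 1600.0], 500.0, dense_map, grid
        )
        elong = [describe(p.data).elongation for p in out]
        assert all(a >= b - 1e-9 for a, b in zip(elong, elong[1:]))

    def test_provenance_recorded(self, small_map, fit_grid):
        out = simulate_distance_series(
            (-1800.0, 300.0), [400.0], 500.0, small_map, fit_grid
        )
        assert out[0].provenance["rho"] == 400.0
        assert out[0].provenance["model"] == "axon_map"
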