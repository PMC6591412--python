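import math

import numpy as np
import pandas as pd
import pytest

from phosphenes.geometry import Grid, build_array
from phosphenes.render import PerceptImage
from phosphenes.stats import (
    DrawingSet,
    axial_mean,
    axial_residuals,
    elongation_area_correlation,
    orientation_alignment_test,
    orientation_variance_explained,
    sem_consistency_test,
)


def disc_image(grid, r_px, cx, cy):
    ny, nx = grid.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    return PerceptImage((xx - cx) ** 2 + (yy - cy) ** 2 <= r_px**2, grid)


def bar_image(grid, angle_deg, cx, cy, half_len=14, half_w=2):
    ny, nx = grid.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    t = math.radians(angle_deg)
    u = (xx - cx) * math.cos(t) + (yy - cy) * math.sin(t)
    v = -(xx - cx) * math.sin(t) + (yy - cy) * math.cos(t)
    return PerceptImage((np.abs(u) <= half_len) & (np.abs(v) <= half_w), grid)


@pytest.fixture
def toy_grid():
    return Grid((-8, 8), (-8, 8), 0.2)


def table_drawing_set(geometry, electrodes, orientations_by_el, grid=None):
    """DrawingSet with an injected descriptor table (no rasters needed)."""
    rows = []
    for el, os_ in zip(electrodes, orientations_by_el):
        for t, o in enumerate(os_):
            rows.append(dict(electrode=el, trial=t, area=100.0,
                             orientation=float(o), elongation=0.5,
                             centroid_x=0.0, centroid_y=0.0))
    return DrawingSet(
        subject_id="toy",
        grid=grid or Grid((-8, 8), (-8, 8), 0.5),
        drawings={el: [] for el in electrodes},
        geometry=geometry,
        _table=pd.DataFrame(rows),
    )


class TestAxialHelpers:
    def test_axial_mean_wraps(self):
        assert axial_mean([85.0, -85.0]) == pytest.approx(90.0) or \
            axial_mean([85.0, -85.0]) == pytest.approx(-90.0)

    def test_axial_mean_plain(self):
        assert axial_mean([10.0, 20.0]) == pytest.approx(15.0)

    def test_residuals_in_range(self, rng):
        r = axial_residuals(rng.uniform(-90, 90, 100), rng.uniform(-90, 90))
        assert np.all(r >= -90) and np.all(r < 90)


class TestSemConsistency:
    def test_identical_within_distinct_across(self, toy_grid):
        ds = DrawingSet(
            "s", toy_grid,
            {
                "A1": [disc_image(toy_grid, 6, 30, 30)] * 5,
                "B2": [disc_image(toy_grid, 12, 45, 45)] * 5,
                "C3": [bar_image(toy_grid, 40.0, 40, 40)] * 5,
            },
        )
        r = sem_consistency_test(ds, "area", iters=200, seed=0)
        assert r.observed == 0.0
        assert r.p <= 1.0 / 200.0 + 1e-12
        assert r.null.size == 200

    def test_pooled_identical_gives_p_one(self, toy_grid):
        img = disc_image(toy_grid, 6, 30, 30)
        ds = DrawingSet("s", toy_grid, {"A1": [img] * 5, "B2": [img] * 5})
        r = sem_consistency_test(ds, "elongation", iters=100, seed=0)
        assert r.observed == 0.0
        assert r.p == 1.0

    def test_reproducible_given_seed(self, toy_grid):
        ds = DrawingSet(
            "s", toy_grid,
            {
                "A1": [disc_image(toy_grid, 4 + k, 30, 30) for k in range(5)],
                "B2": [disc_image(toy_grid, 9 + k, 45, 45) for k in range(5)],
            },
        )
        r1 = sem_consistency_test(ds, "area", iters=100, seed=7)
        r2 = sem_consistency_test(ds, "area", iters=100, seed=7)
        assert np.array_equal(r1.null, r2.null)
        assert r1.p == r2.p

    def test_unknown_descriptor(self, toy_grid):
        ds = DrawingSet("s", toy_grid, {"A1": [disc_image(toy_grid, 4, 30, 30)] * 2})
        with pytest.raises(ValueError):
            sem_consistency_test(ds, "perimeter")


class TestOrientationAlignment:
    def test_tangent_generated_orientations_give_tiny_p(self, subject4, small_map):
        arr = build_array(subject4)
        names = [n for n in arr.names][:10]
        idx = small_map.nearest_vertex(np.asarray([arr[n] for n in names]))
        tangents = small_map.tangents[idx]
        ds = table_drawing_set(subject4, names, [[t] * 5 for t in tangents])
        r = orientation_alignment_test(ds, small_map, "NM1", iters=200, seed=0)
        assert r.observed == pytest.approx(0.0, abs=1e-9)
        assert r.p <= 1.0 / 200.0 + 1e-12

    def test_nm1_null_mean_is_45_degrees(self, subject4, small_map, rng):
        # |uniform axial mismatch| has mean 45 deg regardless of tangents
        arr = build_array(subject4)
        names = [n for n in arr.names][:12]
        ds = table_drawing_set(
            subject4, names, [rng.uniform(-90, 90, 5) for _ in names]
        )
        r = orientation_alignment_test(ds, small_map, "NM1", iters=1000, seed=1)
        assert r.null.mean() == pytest.approx(45.0, abs=2.0)

    def test_nm2_contract(self, subject4, small_map, rng):
        arr = build_array(subject4)
        names = [n for n in arr.names][:6]
        ds = table_drawing_set(
            subject4, names, [rng.uniform(-90, 90, 5) for _ in names]
        )
        r = orientation_alignment_test(ds, small_map, "NM2", iters=50, seed=3)
        assert r.null.size == 50
        assert 0.0 <= r.p <= 1.0

    def test_unknown_null_model(self, subject4, small_map):
        ds = table_drawing_set(subject4, ["A1"], [[10.0] * 5])
        with pytest.raises(ValueError):
            orientation_alignment_test(ds, small_map, "NM3")


class TestVarianceExplained:
    def test_perfect_alignment_gives_one(self, subject4, small_map):
        arr = build_array(subject4)
        names = [n for n in arr.names][:10]
        idx = small_map.nearest_vertex(np.asarray([arr[n] for n in names]))
        tangents = small_map.tangents[idx]
        ds = table_drawing_set(subject4, names, [[t] * 5 for t in tangents])
        assert orientation_variance_explained(ds, small_map) == pytest.approx(1.0)

    def test_constant_prediction_near_zero(self, subject4, small_map, rng):
        # when drawn orientations carry no tangent signal, R² <= ~0
        arr = build_array(subject4)
        names = [n for n in arr.names][:12]
        ds = table_drawing_set(
            subject4, names, [rng.uniform(-50, 50, 5) for _ in names]
        )
        r2 = orientation_variance_explained(ds, small_map)
        assert r2 < 0.3

    def test_noisy_alignment_matches_analytic_r2(self, subject4, small_map):
        # s_i = tangent + N(0, sigma): analytic R² = 1 - sigma² / total var
        rng = np.random.default_rng(99)
        arr = build_array(subject4)
        names = list(arr.names)
        idx = small_map.nearest_vertex(np.asarray([arr[n] for n in names]))
        tangents = small_map.tangents[idx]
        sigma = 10.0
        obs = [t + rng.normal(0, sigma, 20) for t in tangents]
        ds = table_drawing_set(subject4, names, obs)
        s = np.concatenate(obs)
        expected = 1.0 - sigma**2 / np.mean(axial_residuals(s, axial_mean(s)) ** 2)
        assert orientation_variance_explained(ds, small_map) == pytest.approx(
            expected, abs=0.1
        )

    def test_per_electrode_mean_mode(self, subject4, small_map, rng):
        arr = build_array(subject4)
        names = [n for n in arr.names][:10]
        ds = table_drawing_set(subject4, names, [rng.uniform(-80, 80, 5) for _ in names])
        r2 = orientation_variance_explained(ds, small_map, per_trial=False)
        assert math.isfinite(r2)


class TestElongationAreaCorrelation:
    def test_exact_linear_relation(self, subject4):
        rows = []
        for i, a in enumerate(np.linspace(50, 400, 12)):
            rows.append(dict(electrode=f"E{i}", trial=0, area=a,
                             orientation=0.0, elongation=1.0 - 0.002 * a,
                             centroid_x=0, centroid_y=0))
        ds = DrawingSet("s", Grid((-4, 4), (-4, 4), 0.5),
                        {f"E{i}": [] for i in range(12)}, subject4,
                        _table=pd.DataFrame(rows))
        r, p = elongation_area_correlation(ds)
        assert r == pytest.approx(-1.0)
        assert p < 1e-6

    def test_constant_elongation_flagged(self, subject4):
        rows = [dict(electrode=f"E{i}", trial=0, area=50.0 + i,
                     orientation=0.0, elongation=0.5, centroid_x=0, centroid_y=0)
                for i in range(5)]
        ds = DrawingSet("s", Grid((-4, 4), (-4, 4), 0.5),
                        {f"E{i}": [] for i in range(5)}, subject4,
                        _table=pd.DataFrame(rows))
        with pytest.warns(UserWarning):
            r, p = elongation_area_correlation(ds)
        assert math.isnan(r)

    def test_shuffled_pairing_decorrelates(self, subject4, rng):
        area = rng.uniform(50, 400, 300)
        elong = rng.permutation(1.0 - 0.002 * area)
        rows = [dict(electrode="E0", trial=t, area=a, orientation=0.0,
                     elongation=e, centroid_x=0, centroid_y=0)
                for t, (a, e) in enumerate(zip(area, elong))]
        ds = DrawingSet("s", Grid((-4, 4), (-4, 4), 0.5), {"E0": []},
                        subject4, _table=pd.DataFrame(rows))
        r, p = elongation_area_correlation(ds)
        assert abs(r) < 0.15
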