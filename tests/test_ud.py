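import itertools
import math

import numpy as np
import pytest

from udshift.grids import GridSpec, Raster, master_grid
from udshift.ud import (BandwidthPair, KernelUD, baseline_ud, isopleth, kde_ud,
                        plugin_bandwidth, population_ud, scale01, to_density,
                        to_mass)

from conftest import random_mass_raster


def brute_force_kde(points, bw, xs, ys):
    """Independent double-loop Gaussian product-kernel density."""
    out = np.zeros((len(ys), len(xs)))
    for i, y in enumerate(ys):
        for j, x in enumerate(xs):
            s = 0.0
            for px, py in points:
                s += (math.exp(-0.5 * ((x - px) / bw.h_x) ** 2)
                      * math.exp(-0.5 * ((y - py) / bw.h_y) ** 2))
            out[i, j] = s / (len(points) * 2 * math.pi * bw.h_x * bw.h_y)
    return out


class TestPluginBandwidth:
    def test_close_to_normal_reference_on_gaussian_data(self, rng):
        pts = rng.normal(0.0, 1000.0, size=(1000, 2))
        bw = plugin_bandwidth(pts)
        ref = 1.06 * 1000.0 * 1000 ** (-0.2)  # ~265 m
        assert abs(bw.h_x - ref) / ref < 0.15
        assert abs(bw.h_y - ref) / ref < 0.15

    def test_axis_swap_symmetry(self, rng):
        pts = rng.normal(0, [300.0, 900.0], size=(200, 2))
        bw = plugin_bandwidth(pts)
        sw = plugin_bandwidth(pts[:, ::-1])
        assert (bw.h_x, bw.h_y) == (sw.h_y, sw.h_x)

    def test_duplication_shrinks_bandwidth_by_n_scaling(self, rng):
        pts = rng.normal(0, 500.0, size=(400, 2))
        bw1 = plugin_bandwidth(pts)
        bw2 = plugin_bandwidth(np.vstack([pts, pts]))
        ratio = bw2.h_x / bw1.h_x
        assert ratio == pytest.approx(2 ** (-0.2), rel=0.05)

    def test_matches_reference_dpik_on_frozen_fixture(self):
        # KernSmooth::dpik(x, scalest="minim", level=2, gridsize=50001)
        # on this exact sequence returns 5.41238764 (fine-grid -> exact)
        rng = np.random.default_rng(42)
        x = np.round(rng.normal(50, 12, 40) + 6 * np.sin(np.arange(40)), 6)
        from udshift.ud import _dpik_1d
        assert _dpik_1d(x) == pytest.approx(5.41238764, rel=1e-6)

    def test_degenerate_inputs_rejected(self, rng):
        with pytest.raises(ValueError, match="zero variance"):
            plugin_bandwidth(np.column_stack([np.ones(50), rng.normal(size=50)]))
        with pytest.raises(ValueError, match=">= 10 points"):
            plugin_bandwidth(rng.normal(size=(5, 2)))


class TestKdeUD:
    def test_mode_value_closed_form_for_colocated_points(self, rng):
        pts = rng.normal(0.0, 1.0, size=(50, 2))  # 1-m jitter around origin
        bw = BandwidthPair(400.0, 400.0)
        grid = GridSpec(-5125.0, -5125.0, 250.0, 41, 41)
        ud = kde_ud(pts, bw, grid)
        expected = 1.0 / (2 * math.pi * bw.h_x * bw.h_y)
        assert ud.values.max() == pytest.approx(expected, rel=1e-3)

    def test_mass_normalization(self, rng):
        pts = rng.uniform(0, 10_000, size=(200, 2))
        bw = plugin_bandwidth(pts)
        grid = master_grid(pts[:, 0], pts[:, 1], 250.0, 4 * bw.h_max)
        ud = kde_ud(pts, bw, grid)
        assert ud.values.sum() * grid.cell_area == pytest.approx(1.0, abs=1e-3)

    def test_matches_double_loop_oracle_at_probe_cells(self, rng):
        pts = rng.uniform(0, 10_000, size=(200, 2))
        bw = BandwidthPair(700.0, 900.0)
        grid = master_grid(pts[:, 0], pts[:, 1], 250.0, 4 * bw.h_max)
        ud = kde_ud(pts, bw, grid, truncate=np.inf)
        ii = rng.integers(0, grid.n_rows, 100)
        jj = rng.integers(0, grid.n_cols, 100)
        oracle = brute_force_kde(pts, bw, grid.x_centers[jj], grid.y_centers[ii])
        got = ud.values[np.ix_(ii, jj)]
        np.testing.assert_allclose(np.diag(got), np.diag(oracle), rtol=1e-12)

    def test_refuses_fewer_than_50_locations(self, rng):
        pts = rng.normal(0, 100, size=(49, 2))
        with pytest.raises(ValueError, match="<50 locations"):
            kde_ud(pts, BandwidthPair(100, 100), GridSpec(-5000, -5000, 250, 40, 40))

    def test_grid_must_cover_padded_points(self, rng):
        pts = rng.normal(0, 100, size=(60, 2))
        with pytest.raises(ValueError, match="cover"):
            kde_ud(pts, BandwidthPair(500, 500), GridSpec(0, 0, 250, 4, 4))


class TestRepresentations:
    def test_density_mass_roundtrip(self, rng, small_grid):
        m = random_mass_raster(small_grid, rng)
        d = to_density(m)
        assert d.values.sum() * small_grid.cell_area == pytest.approx(1.0)
        again = to_mass(d)
        np.testing.assert_allclose(again.values, m.values, rtol=1e-12)

    def test_scale01_idempotent_and_preserves_ratios(self, small_grid, rng):
        r = random_mass_raster(small_grid, rng)
        s = scale01(r)
        assert s.values.max() == 1.0
        np.testing.assert_allclose(s.values / s.values.sum(), r.values, rtol=1e-12)
        np.testing.assert_allclose(scale01(s).values, s.values)

    def test_all_zero_rejected(self, small_grid):
        with pytest.raises(ValueError):
            scale01(Raster(small_grid, np.zeros((10, 10)), "density"))


class TestPopulationUD:
    def _scaled(self, grid, rng):
        v = rng.random(grid.shape)
        return Raster(grid, v / v.max(), "scaled01")

    def test_two_identical_inputs_renormalized(self, small_grid, rng):
        u = self._scaled(small_grid, rng)
        pop = population_ud([u, Raster(small_grid, u.values.copy(), "scaled01")])
        np.testing.assert_allclose(pop.values, u.values / u.values.sum(), rtol=1e-12)
        assert pop.values.sum() == pytest.approx(1.0, abs=1e-9)

    def test_disjoint_uniform_supports_split_mass_evenly(self, small_grid):
        a = np.zeros((10, 10)); a[:5] = 1.0
        b = np.zeros((10, 10)); b[5:] = 1.0
        pop = population_ud([Raster(small_grid, a, "scaled01"),
                             Raster(small_grid, b, "scaled01")])
        assert pop.values[:5].sum() == pytest.approx(0.5)

    def test_cellwise_mean_against_loop_oracle(self, small_grid, rng):
        uds = [self._scaled(small_grid, rng) for _ in range(3)]
        pop = population_ud(uds)
        oracle = np.zeros((10, 10))
        for i in range(10):
            for j in range(10):
                oracle[i, j] = sum(u.values[i, j] for u in uds) / 3
        oracle /= oracle.sum()
        np.testing.assert_allclose(pop.values, oracle, rtol=1e-12)

    def test_permutation_invariance(self, small_grid, rng):
        uds = [self._scaled(small_grid, rng) for _ in range(4)]
        a = population_ud(uds)
        b = population_ud(uds[::-1])
        np.testing.assert_allclose(a.values, b.values)

    def test_single_ud_stratum_refused(self, small_grid, rng):
        with pytest.raises(ValueError, match="one UD"):
            population_ud([self._scaled(small_grid, rng)])

    def test_baseline_pools_era_years_only(self, small_grid, rng):
        by_year = {1998: [self._scaled(small_grid, rng)],
                   2000: [self._scaled(small_grid, rng)],
                   2010: [self._scaled(small_grid, rng) for _ in range(5)]}
        base = baseline_ud(by_year, era=(1998, 2005))
        direct = population_ud(by_year[1998] + by_year[2000])
        np.testing.assert_allclose(base.values, direct.values)
        assert base.values.sum() == pytest.approx(1.0, abs=1e-9)


class TestIsopleth:
    def test_four_cell_example_selects_three_cells(self):
        grid = GridSpec(0, 0, 1000.0, 2, 2)
        ud = Raster(grid, np.array([[0.5, 0.3], [0.15, 0.05]]), "mass")
        hr = isopleth(ud, 0.95)
        assert hr.n_cells == 3
        # exhaustive check: no smaller subset reaches 0.95
        vals = ud.values.ravel()
        for size in range(1, 3):
            assert all(sum(c) < 0.95 for c in itertools.combinations(vals, size))

    def test_uniform_mass_selects_exact_fraction(self):
        grid = GridSpec(0, 0, 1000.0, 10, 10)
        ud = Raster(grid, np.full((10, 10), 0.01), "mass")
        assert isopleth(ud, 0.95).n_cells == 95
        assert isopleth(ud, 0.95, ties="include").n_cells == 100

    def test_level_near_one_takes_all_nonzero(self, small_grid, rng):
        m = random_mass_raster(small_grid, rng)
        hr = isopleth(m, 0.999999)
        assert hr.n_cells == 100

    def test_area_monotone_in_level(self, small_grid, rng):
        m = random_mass_raster(small_grid, rng)
        areas = [isopleth(m, lv).area_km2 for lv in (0.5, 0.75, 0.9, 0.95, 0.99)]
        assert areas == sorted(areas)

    def test_matches_exhaustive_smallest_prefix_on_random_rasters(self, rng):
        grid = GridSpec(0, 0, 500.0, 10, 10)
        for _ in range(5):
            m = random_mass_raster(grid, rng)
            hr = isopleth(m, 0.95)
            flat = np.sort(m.values.ravel())[::-1]
            k = int(np.argmax(np.cumsum(flat) >= 0.95)) + 1
            assert hr.n_cells == k
            assert m.values[hr.mask].sum() >= 0.95 - 1e-12


class TestKernelUDEstimator:
    def test_fit_sets_fitted_attributes(self, rng):
        est = KernelUD().fit(rng.normal(0, 800, size=(120, 2)))
        assert est.bandwidth_.h_x > 0
        assert est.density_.representation == "density"
        assert est.grid_.cell == 250.0

    def test_score_samples_matches_grid_values(self, rng):
        pts = rng.normal(0, 800, size=(120, 2))
        est = KernelUD(bandwidth=(300.0, 300.0)).fit(pts)
        g = est.grid_
        probe = np.array([[g.x_centers[10], g.y_centers[12]]])
        assert est.score_samples(probe)[0] == pytest.approx(
            est.density_.values[12, 10], rel=1e-9)

    def test_get_set_params_roundtrip(self):
        est = KernelUD(cell=100.0)
        est.set_params(**est.get_params())
        assert est.get_params()["cell"] == 100.0
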