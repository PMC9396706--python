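"""Niche-overlap ordination: climate extraction, PCA, kernel occupancy
grids, and the D and I overlap indices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nichetrack.niche import (EnvPCA, NicheGrid, NicheOverlap, extract_climate,
                              hellinger_I, kernel_density_grid, occupancy_grid,
                              schoener_D, variable_overlap_1d)
from nichetrack.synthdata import (CLIMATE_VARS, ClimateRaster,
                                  identical_climate_config,
                                  simulate_climate_fields)


def constant_raster(value=10.0, n=20):
    vals = {"tmin": np.full((n, n), value), "tmax": np.full((n, n), value + 5),
            "precip": np.full((n, n), 50.0), "wind": np.full((n, n), 3.0)}
    return ClimateRaster(west=-95.0, south=30.0, cell_size=0.5, values=vals,
                         season="winter")


class TestExtractClimate:
    def test_cell_centre_returns_cell_value(self):
        w, _ = simulate_climate_fields(seed=1)
        lon, lat = w.cell_centres()
        loc = pd.DataFrame({"lon": [lon[3]], "lat": [lat[5]]})
        env = extract_climate(loc, w)
        for var in CLIMATE_VARS:
            assert env[var].iloc[0] == w.values[var][5, 3]

    def test_constant_raster_gives_identical_rows(self):
        r = constant_raster()
        rng = np.random.default_rng(0)
        loc = pd.DataFrame({"lon": rng.uniform(-94.9, -85.2, 30),
                            "lat": rng.uniform(30.1, 39.9, 30)})
        env = extract_climate(loc, r)
        assert (env[list(CLIMATE_VARS)].nunique() == 1).all()

    def test_lookup_matches_brute_force_nearest_cell(self):
        w, _ = simulate_climate_fields(seed=3)
        rng = np.random.default_rng(4)
        west, south, east, north = w.bbox
        lon = rng.uniform(west, east - 1e-9, 100)
        lat = rng.uniform(south, north - 1e-9, 100)
        env = extract_climate(pd.DataFrame({"lon": lon, "lat": lat}), w)
        clon, clat = w.cell_centres()
        for i in range(100):
            col = int(np.argmin(np.abs(clon - lon[i])))
            row = int(np.argmin(np.abs(clat - lat[i])))
            for var in CLIMATE_VARS:
                assert env[var].iloc[i] == w.values[var][row, col]

    def test_out_of_bounds_location_rejected_with_count(self):
        r = constant_raster()
        loc = pd.DataFrame({"lon": [-94.0, -200.0 + 160.0], "lat": [31.0, 5.0]})
        with pytest.raises(ValueError, match="1 location"):
            extract_climate(loc, r)


class TestEnvPCA:
    def test_explained_fractions_sum_to_100(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(200, 4)), columns=CLIMATE_VARS)
        pca = EnvPCA().fit(df)
        assert pca.explained_pct_.sum() == pytest.approx(100.0, abs=1e-9)

    def test_zero_variance_column_named_in_error(self):
        df = pd.DataFrame({"tmin": [1.0, 2.0, 3.0], "tmax": [5.0, 5.0, 5.0],
                           "precip": [1.0, 2.0, 1.5], "wind": [3.0, 3.1, 2.9]})
        with pytest.raises(ValueError, match="tmax"):
            EnvPCA().fit(df)

    def test_known_covariance_eigenstructure_recovered(self):
        # 4-D Gaussian: after unit-variance scaling the explained fractions
        # are the correlation-matrix eigenvalues over 4
        rng = np.random.default_rng(2)
        corr = np.array([[1.0, 0.8, 0.2, 0.0],
                         [0.8, 1.0, 0.1, 0.0],
                         [0.2, 0.1, 1.0, 0.3],
                         [0.0, 0.0, 0.3, 1.0]])
        x = rng.multivariate_normal(np.zeros(4), corr, size=100_000)
        df = pd.DataFrame(x, columns=CLIMATE_VARS)
        pca = EnvPCA().fit(df)
        expected = 100.0 * np.sort(np.linalg.eigvalsh(corr))[::-1] / 4.0
        np.testing.assert_allclose(pca.explained_pct_, expected, atol=1.0)


class TestOccupancyGrid:
    def test_point_mass_occupancy(self):
        occ = np.zeros((50, 2))
        bg = np.random.default_rng(0).uniform(-5, 5, size=(500, 2))
        g = occupancy_grid(occ, bg, R=51, bandwidth=(0.01, 0.01),
                           extent_scores=bg, correction=False)
        i, j = np.unravel_index(np.argmax(g.z), g.z.shape)
        assert g.z[i, j] == 1.0
        mask = np.ones_like(g.z, dtype=bool)
        mask[i - 1:i + 2, j - 1:j + 2] = False
        assert g.z[mask].max() < 1e-6

    def test_density_matches_brute_force_kernel_sum(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(200, 2))
        bg = rng.normal(size=(300, 2))
        g = occupancy_grid(pts, bg, R=40)
        bw = g.bandwidth_occ
        probe = [(3, 7), (10, 20), (39, 0), (25, 25), (0, 39),
                 (5, 30), (33, 12), (17, 3), (8, 8), (20, 39)]
        for (iy, ix) in probe:
            x, y = g.x_centres[ix], g.y_centres[iy]
            dens = np.mean(
                np.exp(-0.5 * (((x - pts[:, 0]) / bw[0]) ** 2
                               + ((y - pts[:, 1]) / bw[1]) ** 2))
            ) / (2 * np.pi * bw[0] * bw[1])
            assert g.occ_density[iy, ix] == pytest.approx(dens, abs=1e-8)

    def test_correction_with_matching_background_is_flat(self):
        # occurrences drawn as the background itself: o = e cellwise, so the
        # corrected occupancy is 1 across the support
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(400, 2))
        g = occupancy_grid(pts, pts, R=30)
        support = g.z > 0
        assert support.sum() > 50
        np.testing.assert_allclose(g.z[support], 1.0, rtol=1e-9)

    def test_too_few_occurrences_rejected(self):
        with pytest.raises(ValueError, match="5 occurrences"):
            occupancy_grid(np.zeros((3, 2)), np.zeros((10, 2)))

    def test_nonpositive_bandwidth_rejected(self):
        pts = np.random.default_rng(0).normal(size=(20, 2))
        with pytest.raises(ValueError, match="bandwidth"):
            occupancy_grid(pts, pts, bandwidth=(0.0, 0.1))


def grid_from_z(z):
    z = np.asarray(z, dtype=float)
    return NicheGrid(x_centres=np.arange(z.shape[1], dtype=float),
                     y_centres=np.arange(z.shape[0], dtype=float),
                     occ_density=z, env_density=np.ones_like(z), z=z,
                     corrected=False)


class TestOverlapIndices:
    def test_identical_grids_give_one(self):
        g = grid_from_z([[0.2, 0.8], [0.5, 0.0]])
        assert schoener_D(g, g) == pytest.approx(1.0)
        assert hellinger_I(g, g) == pytest.approx(1.0)

    def test_disjoint_supports_give_zero(self):
        g1 = grid_from_z([[1.0, 0.0]])
        g2 = grid_from_z([[0.0, 1.0]])
        assert schoener_D(g1, g2) == 0.0
        assert hellinger_I(g1, g2) == pytest.approx(0.0, abs=1e-12)

    def test_three_cell_hand_computed_D(self):
        g1 = grid_from_z([[0.5, 0.5, 0.0]])
        g2 = grid_from_z([[0.0, 0.5, 0.5]])
        assert schoener_D(g1, g2) == pytest.approx(0.5)

    def test_two_cell_hand_computed_I(self):
        g1 = grid_from_z([[1.0, 0.0]])
        g2 = grid_from_z([[0.5, 0.5]])
        expected = 1.0 - 0.5 * ((1 - np.sqrt(0.5)) ** 2 + 0.5)
        assert hellinger_I(g1, g2) == pytest.approx(expected, abs=1e-12)
        assert round(expected, 4) == 0.7071

    def test_geometry_mismatch_rejected(self):
        g1 = grid_from_z([[1.0, 0.0]])
        g2 = grid_from_z([[1.0, 0.0, 0.0]])
        with pytest.raises(ValueError, match="geometry"):
            schoener_D(g1, g2)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0.0, 1.0), min_size=4, max_size=4),
           st.lists(st.floats(0.0, 1.0), min_size=4, max_size=4))
    def test_indices_bounded_in_unit_interval(self, z1, z2):
        if sum(z1) == 0 or sum(z2) == 0:
            return
        g1, g2 = grid_from_z([z1]), grid_from_z([z2])
        for v in (schoener_D(g1, g2), hellinger_I(g1, g2)):
            assert -1e-12 <= v <= 1.0 + 1e-12

    def test_overlap_decreases_with_niche_separation(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=(400, 2))
        bg = rng.normal(scale=2.0, size=(2000, 2))
        prev_D, prev_I = 1.1, 1.1
        for shift in (0.0, 1.0, 2.5, 4.0):
            occ2 = base + np.array([shift, 0.0])
            ext = np.vstack([base, occ2, bg])
            g1 = occupancy_grid(base, bg, R=60, extent_scores=ext)
            g2 = occupancy_grid(occ2, bg, R=60, extent_scores=ext)
            D, I = schoener_D(g1, g2), hellinger_I(g1, g2)
            assert D <= prev_D + 1e-9 and I <= prev_I + 1e-9
            prev_D, prev_I = D, I

    def test_grid_resolution_stability(self):
        rng = np.random.default_rng(8)
        occ1 = rng.normal(size=(500, 2))
        occ2 = rng.normal(size=(500, 2)) + 0.5
        bg = rng.normal(scale=2.0, size=(3000, 2))
        ext = np.vstack([occ1, occ2, bg])
        Ds = []
        for R in (100, 200):
            g1 = occupancy_grid(occ1, bg, R=R, extent_scores=ext)
            g2 = occupancy_grid(occ2, bg, R=R, extent_scores=ext)
            Ds.append(schoener_D(g1, g2))
        assert abs(Ds[0] - Ds[1]) < 0.02


class TestVariableOverlap1D:
    def test_identical_samples_overlap_one(self):
        v = np.random.default_rng(0).normal(3.3, 0.4, size=500)
        assert variable_overlap_1d(v, v) == pytest.approx(1.0, abs=1e-6)

    def test_far_separated_samples_overlap_zero(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.0, 1.0, 200)
        b = rng.normal(100.0, 1.0, 200)
        assert variable_overlap_1d(a, b) < 1e-6

    def test_wind_speed_overlap_near_closed_form(self):
        # closed-form overlap of N(3.33, 0.4^2) and N(3.26, 0.34^2) ~ 0.90
        from scipy.stats import norm
        x = np.linspace(1.0, 6.0, 4001)
        oracle = np.trapezoid(np.minimum(norm.pdf(x, 3.33, 0.4),
                                         norm.pdf(x, 3.26, 0.34)), x)
        rng = np.random.default_rng(2)
        a = rng.normal(3.33, 0.4, size=10_000)
        b = rng.normal(3.26, 0.34, size=10_000)
        got = variable_overlap_1d(a, b)
        assert got > 0.85
        assert got == pytest.approx(oracle, abs=0.05)


class TestEndToEnd:
    def test_separated_climates_have_zero_overlap(self):
        ov = _overlap_for(None, seed=1)
        assert round(ov.D_, 2) == 0.0
        assert round(ov.I_, 2) == 0.0

    def test_identical_climates_have_high_overlap(self):
        ov = _overlap_for(identical_climate_config(), seed=1)
        assert ov.D_ > 0.8


def _overlap_for(cfg, seed, n_occ=2000):
    w, s = simulate_climate_fields(cfg, seed=seed)
    bw, bs = w.table(), s.table()
    rng = np.random.default_rng(seed + 77)
    occ_w = bw.iloc[rng.integers(len(bw), size=n_occ)].reset_index(drop=True)
    occ_s = bs.iloc[rng.integers(len(bs), size=n_occ)].reset_index(drop=True)
    return NicheOverlap().fit(occ_w, occ_s, bw, bs)
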