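"""Landscape and used-point generation: determinism, range contracts,
spatial-correlation calibration, and selection-weighted sampling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from riskscape.covariates import match_covariates
from riskscape.raster import bilinear
from riskscape.rsf import SealRSF, build_rsf_table
from riskscape.synthetic import (TruthParams, WorldConfig, make_landscape,
                                 simulate_bear_use, simulate_seal_used_points,
                                 smooth_field, expected_smoothing_corr,
                                 true_risk_rasters, bear_linear_field,
                                 sample_weighted_points)


class TestLandscape:
    def test_same_seed_bit_identical(self):
        cfg = WorldConfig(seed=7, n_days=4, extent=(0, 200, 0, 200))
        a = make_landscape(cfg)
        b = make_landscape(cfg)
        assert np.array_equal(a.bathymetry.values, b.bathymetry.values)
        assert all(np.array_equal(a.ice[d].values, b.ice[d].values)
                   for d in a.ice)
        for sp in a.prey_biomass:
            for y in a.prey_biomass[sp]:
                assert np.array_equal(a.prey_biomass[sp][y].values,
                                      b.prey_biomass[sp][y].values)

    def test_ice_always_in_percent_range(self):
        for seed in range(20):
            cfg = WorldConfig(seed=seed, n_days=3, extent=(0, 150, 0, 150))
            stack = make_landscape(cfg)
            for f in stack.ice.values():
                assert f.values.min() >= 0.0 and f.values.max() <= 100.0

    def test_fields_finite_and_water_depth_positive(self, small_world):
        cfg, stack = small_world
        water = ~stack.land
        assert np.isfinite(stack.bathymetry.values).all()
        assert (stack.bathymetry.values[water] > 0).all()
        for y, f in stack.prey_diversity.items():
            assert np.isfinite(f.values).all()
            assert ((f.values >= 0) & (f.values < 1)).all()

    def test_degenerate_extent_rejected(self):
        with pytest.raises(ValueError, match="extent"):
            make_landscape(WorldConfig(extent=(0, 0, 0, 100)))

    def test_spatial_correlation_matches_kernel_theory(self):
        """Empirical lag correlation of the smoothed fields vs the stated
        Gaussian-kernel correlation, averaged over seeds, within 20%."""
        range_cells = 4.0
        lag = 4
        target = expected_smoothing_corr(lag, range_cells)
        cors = []
        for seed in range(50):
            f = smooth_field(np.random.default_rng(seed), (40, 40), range_cells)
            a, b = f[:, :-lag].ravel(), f[:, lag:].ravel()
            cors.append(np.corrcoef(a, b)[0, 1])
        assert abs(np.mean(cors) - target) < 0.2 * target


class TestUsedPointSampling:
    def test_zero_coefficients_give_uniform_water_use(self, small_world):
        cfg, stack = small_world
        lin = stack.bathymetry.like(np.zeros_like(stack.bathymetry.values))
        pts = sample_weighted_points(stack, lin, 20000,
                                     np.random.default_rng(0))
        geo = stack.geometry
        ii = np.rint((pts[:, 1] - geo.y0) / geo.cell_size).astype(int)
        jj = np.rint((pts[:, 0] - geo.x0) / geo.cell_size).astype(int)
        # chi-square over interior water nodes (uniform catchment areas)
        interior = np.zeros_like(stack.land)
        interior[1:-1, 1:-1] = True
        water_int = (~stack.land) & interior
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                water_int[1:-1, 1:-1] &= ~stack.land[1 + di:stack.land.shape[0]
                                                     - 1 + di,
                                                     1 + dj:stack.land.shape[1]
                                                     - 1 + dj]
        counts = np.zeros(stack.land.shape)
        np.add.at(counts, (ii, jj), 1)
        obs = counts[water_int]
        stat, p = stats.chisquare(obs)
        assert p > 0.01

    def test_no_used_points_on_land(self, small_world):
        cfg, stack = small_world
        pts = simulate_bear_use(stack, cfg.truth, 2000, 3)
        geo = stack.geometry
        ii = np.rint((pts["y"] - geo.y0) / geo.cell_size).astype(int)
        jj = np.rint((pts["x"] - geo.x0) / geo.cell_size).astype(int)
        assert not stack.land[ii, jj].any()

    def test_seeded_determinism(self, small_world):
        cfg, stack = small_world
        a = simulate_bear_use(stack, cfg.truth, 500, 11)
        b = simulate_bear_use(stack, cfg.truth, 500, 11)
        pd.testing.assert_frame_equal(a, b)

    def test_single_dominant_coefficient_monotone_use(self, small_world):
        """Use frequency rises across covariate deciles when one large
        coefficient drives selection."""
        cfg, stack = small_world
        truth = TruthParams(bear_beta=(0.08, 0.0, 0.0))  # ice only, strong
        pts = simulate_bear_use(stack, truth, 8000, 5)
        vals = np.concatenate([
            bilinear(stack.ice[int(d)], g["x"].to_numpy(), g["y"].to_numpy())
            for d, g in pts.groupby("day")])
        # decile edges from the availability frame (water nodes, all days)
        water = ~stack.land
        avail_vals = np.concatenate([stack.ice[d].values[water]
                                     for d in stack.ice])
        deciles = np.quantile(avail_vals, np.linspace(0, 1, 11))
        deciles[0], deciles[-1] = -np.inf, np.inf
        counts = np.histogram(vals, deciles)[0]
        rho = stats.spearmanr(np.arange(10), counts).statistic
        assert rho > 0.9

    def test_all_land_domain_rejected(self, small_world):
        cfg, stack = small_world
        import copy
        s = copy.copy(stack)
        s.land = np.ones_like(stack.land)
        lin = stack.bathymetry.like(np.zeros_like(stack.bathymetry.values))
        with pytest.raises(ValueError, match="land"):
            sample_weighted_points(s, lin, 10, np.random.default_rng(0))

    def test_unpenalised_refit_recovers_bear_beta(self):
        """Generative/inferential duality for the predator stage."""
        from riskscape.predator import build_bear_design
        import statsmodels.api as sm
        hits = 0
        for rep in range(5):
            cfg = WorldConfig(seed=300 + rep, n_days=30,
                              extent=(0, 400, 0, 400))
            stack = make_landscape(cfg)
            bears = simulate_bear_use(stack, cfg.truth, 3000, 400 + rep)
            design = build_bear_design(bears, stack, ratio=10, seed=rep)
            X = np.column_stack([np.ones(len(design)),
                                 design[["ice", "bathymetry",
                                         "dist_coast"]].to_numpy()])
            fit = sm.GLM(design["response"].to_numpy(float), X,
                         family=sm.families.Binomial()).fit()
            ci = fit.conf_int()
            ok = all(ci[k + 1][0] <= cfg.truth.bear_beta[k] <= ci[k + 1][1]
                     for k in range(3))
            hits += ok
        assert hits >= 4

    def test_seal_points_tag_ids_and_days(self, small_world):
        cfg, stack = small_world
        pts = simulate_seal_used_points(stack, cfg.truth, 4, 9)
        assert pts["animal_id"].str.startswith("seal_").all()
        assert set(pts["day"]).issubset(set(stack.risk))
        # expected total: n_seals x n_days
        assert len(pts) == 4 * cfg.n_days
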