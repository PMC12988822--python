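"""Seal RSF stage: thinning, availability geometry, AICc, candidate
ranking, prediction maps and Boyce cross-validation mechanics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import box

from riskscape.model_selection import aicc, candidate_set, rank_models
from riskscape.rsf import (SealRSF, boyce_spearman, build_availability_domain,
                           build_rsf_table, fit_candidate_set, predict_map,
                           sample_available, thin_one_per_day,
                           coefficient_stabilization)
from riskscape.validation import build_world, rsf_table_from_world


class TestThinning:
    def _points(self, per_day, n_days=3):
        t0 = pd.Timestamp("2011-01-01")
        rows = []
        for d in range(n_days):
            for k in range(per_day):
                rows.append({"animal_id": "a",
                             "datetime": t0 + pd.Timedelta(days=d, hours=2 * k),
                             "x": float(k), "y": float(d)})
        return pd.DataFrame(rows)

    def test_one_location_per_seal_day(self):
        out = thin_one_per_day(self._points(12), seed=0)
        assert len(out) == 3
        days = pd.to_datetime(out["datetime"]).dt.floor("D")
        assert days.is_unique

    def test_deterministic_under_seed(self):
        a = thin_one_per_day(self._points(12), seed=5)
        b = thin_one_per_day(self._points(12), seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_within_day_selection_uniform(self):
        counts = np.zeros(6)
        pts = self._points(6, n_days=1)
        for seed in range(3000):
            out = thin_one_per_day(pts, seed=seed)
            counts[int(out["x"].iloc[0])] += 1
        from scipy.stats import chisquare
        assert chisquare(counts).pvalue > 0.01


class TestAvailabilityDomain:
    def test_square_buffer_area_matches_geometry(self):
        side = 100.0
        pts = np.array([[0, 0], [side, 0], [side, side], [0, side]])
        dom = build_availability_domain(pts, buffer_km=30.0)
        exact = (side + 60) ** 2 - (4 - np.pi) * 30 ** 2
        assert dom.area == pytest.approx(exact, rel=1e-3)

    def test_collinear_points_buffer_the_line(self):
        pts = np.array([[0, 0], [50, 0], [100, 0]])
        dom = build_availability_domain(pts, buffer_km=10.0)
        assert dom.area == pytest.approx(100 * 20 + np.pi * 100, rel=1e-3)

    def test_fully_land_covered_rejected(self):
        pts = np.array([[0, 0], [10, 0], [10, 10]])
        land = box(-100, -100, 100, 100)
        with pytest.raises(ValueError, match="water"):
            build_availability_domain(pts, 5.0, land=land)

    def test_sample_count_and_containment(self, rng):
        pts = np.array([[0, 0], [80, 0], [80, 80], [0, 80]])
        dom = build_availability_domain(pts, 20.0)
        import shapely
        av = sample_available(dom, 40, ratio=25, seed=rng)
        assert len(av) == 1000
        assert shapely.contains_xy(dom.polygon, av[:, 0], av[:, 1]).all()

    def test_sample_uniformity(self):
        from scipy.stats import chisquare
        pts = np.array([[0, 0], [100, 0], [100, 100], [0, 100]])
        dom = build_availability_domain(pts, 0.5)
        av = sample_available(dom, 800, ratio=25, seed=1)
        inside = av[(av[:, 0] > 0) & (av[:, 0] < 100)
                    & (av[:, 1] > 0) & (av[:, 1] < 100)]
        h = np.histogram2d(inside[:, 0], inside[:, 1],
                           bins=[5, 5], range=[[0, 100], [0, 100]])[0]
        assert chisquare(h.ravel()).pvalue > 0.01


class TestAicc:
    def test_hand_computed_value(self):
        # -2(-100) + 2*3 + 2*3*4/(50-3-1) = 206.5217...
        assert aicc(-100.0, 3, 50) == pytest.approx(206.52173913043478)

    def test_undefined_for_tiny_n(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 6)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.floats(-500, -1), st.integers(1, 6), st.integers(20, 500))
    def test_exceeds_plain_aic(self, ll, k, n):
        assert aicc(ll, k, n) >= -2 * ll + 2 * k

    def test_parsimony_rule_prefers_smaller_within_two(self):
        class F:
            def __init__(s, name, k, a): s.name, s.k, s.aicc = name, k, a
        fits = [F("big", 5, 100.0), F("small", 2, 101.5), F("bad", 3, 130.0)]
        tab = rank_models(fits)
        assert tab.loc[tab["selected"], "model"].iloc[0] == "small"


class TestCandidateSet:
    def test_structure(self):
        cands = candidate_set()
        assert len(cands) == 10
        names = {c.name for c in cands}
        assert "null" in names
        assert "prey*risk" in names and "ice+prey*risk" in names

    def test_ranking_invariant_to_standardization(self):
        cfg, stack = build_world(404, n_seals=6, n_days=20)
        data = rsf_table_from_world(cfg, stack, 405)
        raw, _ = fit_candidate_set(data, standardize_covariates=False)
        std, _ = fit_candidate_set(data, standardize_covariates=True)
        merged = raw.merge(std, on="model", suffixes=("_raw", "_std"))
        assert np.allclose(merged["delta_aicc_raw"],
                           merged["delta_aicc_std"], atol=1e-6)

    def test_missing_class_rejected(self):
        df = pd.DataFrame({"response": [1, 1], "bathymetry": [1.0, 2.0],
                           "animal_id": "a"})
        with pytest.raises(ValueError):
            SealRSF(df, ())


@pytest.fixture(scope="module")
def fitted_world():
    cfg, stack = build_world(42, n_seals=10, n_days=30)
    data = rsf_table_from_world(cfg, stack, 43)
    fit = SealRSF(data, ("ice", "prey", "risk", "prey:risk")).fit()
    return cfg, stack, data, fit


class TestPredictionMap:
    def test_core_mask_quarter_of_water(self, fitted_world):
        cfg, stack, data, fit = fitted_world
        raster, core = predict_map(fit, stack, day=5, contour_q=0.75)
        water = ~stack.land
        frac = core[water].mean()
        assert 0.2 < frac < 0.3

    def test_core_mask_invariant_to_intercept_shift(self, fitted_world):
        cfg, stack, data, fit = fitted_world
        _, core1 = predict_map(fit, stack, day=5)
        fit.params["intercept"] += 3.0
        try:
            _, core2 = predict_map(fit, stack, day=5)
        finally:
            fit.params["intercept"] -= 3.0
        assert np.array_equal(core1, core2)

    def test_interaction_map_ranks_differently_from_prey_only(self, fitted_world):
        from scipy.stats import spearmanr
        cfg, stack, data, fit = fitted_world
        prey_fit = SealRSF(data, ("prey",)).fit()
        r_int, _ = predict_map(fit, stack, day=5)
        r_prey, _ = predict_map(prey_fit, stack, day=5)
        water = ~stack.land
        rho = spearmanr(r_int.values[water], r_prey.values[water]).statistic
        assert rho < 0.999


class TestBoyce:
    def test_monotone_scores_give_perfect_rho(self, rng):
        # used scores stochastically dominate available ones, fine-grained
        sa = rng.uniform(0, 1, 20000)
        keep = rng.random(20000) < sa ** 2
        su = sa[keep]
        rho = boyce_spearman(su, sa, 10)
        assert rho == pytest.approx(1.0)

    def test_permuted_scores_average_zero(self, rng):
        scores = rng.uniform(0, 1, 5000)
        rhos = []
        for _ in range(100):
            p = rng.permutation(scores)
            rhos.append(boyce_spearman(p[:500], p[500:], 10))
        assert abs(np.mean(rhos)) < 0.1

    def test_degenerate_scores_return_zero(self):
        assert boyce_spearman(np.ones(10), np.ones(100)) == 0.0


class TestStabilization:
    def test_monotone_ratio_grid_enforced(self, fitted_world):
        cfg, stack, data, fit = fitted_world
        with pytest.raises(ValueError, match="increasing"):
            coefficient_stabilization(None, None, None, ratios=(5, 1, 10))

    def test_coefficients_stabilise_at_large_ratio(self):
        from riskscape.covariates import match_covariates
        from riskscape.rsf import land_polygon_from_mask
        from riskscape.synthetic import simulate_seal_used_points
        cfg, stack = build_world(77, n_seals=8, n_days=30)
        used = simulate_seal_used_points(stack, cfg.truth, 8, 78)

        def match(df):
            return match_covariates(df, stack).rename(
                columns={"prey_diversity": "prey"})

        used_m = match(used)
        geo = stack.geometry
        dom = build_availability_domain(
            used_m[["x", "y"]].to_numpy(), 30.0,
            land=land_polygon_from_mask(geo, stack.land),
            clip_to=box(geo.x0, geo.y0, geo.x_max, geo.y_max))
        tab = coefficient_stabilization(used_m, dom, match,
                                        ratios=(1, 10, 30, 40), seed=79)
        # successive change of the structural coefficient shrinks
        d_small = abs(tab.loc[10, "bathymetry"] - tab.loc[1, "bathymetry"])
        d_large = abs(tab.loc[40, "bathymetry"] - tab.loc[30, "bathymetry"])
        assert d_large < d_small
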