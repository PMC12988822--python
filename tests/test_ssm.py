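"""CTCRW state-space model: segmentation rules, likelihood vs the dense
joint-Gaussian reference, smoothing, prediction, residual calibration and
posterior track draws."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.diagnostic import acorr_ljungbox

from riskscape.ssm import (CtcrwModel, CtcrwParams, TrackSegment,
                           split_segments)
from riskscape.synthetic import WorldConfig, simulate_ctcrw_track
from riskscape.validation import dense_ctcrw_nll, random_segment


def make_obs(times_h, animal_id="a", lc="3"):
    t0 = pd.Timestamp("2011-01-01")
    return pd.DataFrame({
        "animal_id": animal_id,
        "datetime": [t0 + pd.Timedelta(hours=h) for h in times_h],
        "lc": lc, "x": np.random.default_rng(0).normal(0, 1, len(times_h)),
        "y": 0.0})


class TestSplitSegments:
    def test_gap_cut_and_short_remainder_dropped(self):
        # 150 hourly obs with a 13-h gap after the 120th
        t = np.concatenate([np.arange(120), 119 + 13 + np.arange(30)])
        segs = split_segments(make_obs(t))
        assert len(segs) == 1
        assert len(segs[0]) == 120

    def test_below_min_length_dropped(self):
        segs = split_segments(make_obs(np.arange(99)))
        assert segs == []

    def test_gap_at_boundary_not_cut(self):
        t = np.concatenate([np.arange(100), 99 + 11.9 + np.arange(50)])
        segs = split_segments(make_obs(t))
        assert len(segs) == 1
        assert len(segs[0]) == 150

    def test_empty_input_gives_empty_list(self):
        assert split_segments(make_obs([])) == []

    def test_duplicate_timestamps_keep_first(self):
        t = np.concatenate([np.arange(120), [119.0]])
        segs = split_segments(make_obs(t))
        assert len(segs[0]) == 120


class TestLikelihood:
    def test_matches_dense_joint_gaussian(self, rng):
        worst = 0.0
        for _ in range(60):
            seg = random_segment(rng)
            p = CtcrwParams(float(rng.uniform(0.1, 2)),
                            float(rng.uniform(0.5, 3)),
                            float(rng.uniform(0.5, 2)))
            worst = max(worst, abs(CtcrwModel(seg).nloglik(p)
                                   - dense_ctcrw_nll(seg, p)))
        assert worst < 1e-6

    def test_doubling_error_sds_tracks_reference(self, rng):
        seg = random_segment(rng, 6)
        p1 = CtcrwParams(0.5, 1.0, 1.0)
        p2 = CtcrwParams(0.5, 1.0, 2.0)
        m = CtcrwModel(seg)
        assert m.nloglik(p2) - m.nloglik(p1) == pytest.approx(
            dense_ctcrw_nll(seg, p2) - dense_ctcrw_nll(seg, p1), abs=1e-8)

    def test_unsorted_times_rejected(self, rng):
        seg = random_segment(rng, 6)
        seg.t_hours = seg.t_hours[::-1].copy()
        with pytest.raises(ValueError, match="increasing"):
            CtcrwModel(seg)

    def test_invalid_params_rejected(self, rng):
        seg = random_segment(rng, 5)
        with pytest.raises(ValueError):
            CtcrwModel(seg).nloglik(CtcrwParams(-0.5, 1.0))


@pytest.fixture(scope="module")
def fitted():
    cfg = WorldConfig(seed=5, long_gap_rate=0.0)
    tru, obs = simulate_ctcrw_track(cfg.truth, 40, cfg, 6)
    seg = split_segments(obs)[0]
    return cfg, tru, seg, CtcrwModel(seg).fit()


class TestFitAndPredict:
    def test_fit_converges_near_truth(self, fitted):
        cfg, tru, seg, res = fitted
        assert res.converged
        assert abs(res.params.beta_mov - cfg.truth.ctcrw_beta_mov) \
            / cfg.truth.ctcrw_beta_mov < 0.5
        assert abs(res.params.sigma_mov - cfg.truth.ctcrw_sigma_mov) \
            / cfg.truth.ctcrw_sigma_mov < 0.5

    def test_init_at_truth_and_default_agree(self, fitted):
        cfg, tru, seg, res = fitted
        res2 = CtcrwModel(seg).fit(start=CtcrwParams(
            cfg.truth.ctcrw_beta_mov, cfg.truth.ctcrw_sigma_mov, 1.0))
        assert res2.nll == pytest.approx(res.nll, abs=1e-3)

    def test_prediction_count_arithmetic(self, fitted):
        cfg, tru, seg, res = fitted
        pred = res.predict_regular(2.0)
        span = seg.t_hours[-1] - seg.t_hours[0]
        assert len(pred) == int(np.floor(span / 2.0)) + 1
        assert np.allclose(np.diff(pred["t_hours"]), 2.0)

    def test_interior_variance_not_above_edges(self, fitted):
        cfg, tru, seg, res = fitted
        pred = res.predict_regular(2.0)
        v = pred["var_x"].to_numpy()
        inner = v[len(v) // 4: -len(v) // 4]
        assert inner.mean() <= max(v[0], v[-1]) + 1e-9

    def test_smoother_never_above_filter_variance(self, fitted):
        cfg, tru, seg, res = fitted
        times, dts, miss, (nll, fm, fP, pm, pP, *_ ) = \
            res.model._moments(res.params)
        from riskscape.ssm import _rts_pass
        sm_, sP = _rts_pass(dts, res.params.beta_mov, fm, fP, pm, pP)
        assert (sP[:, 0] <= fP[:, 0] + 1e-9).all()

    def test_noiseless_predictions_interpolate_observations(self):
        cfg = WorldConfig(seed=8, argos_class_sds={c: 0.0 for c in "3210AB"},
                          long_gap_rate=0.0)
        tru, obs = simulate_ctcrw_track(cfg.truth, 12, cfg, 3,
                                        regular_gap=2.0)
        seg = split_segments(obs)[0]
        res = CtcrwModel(seg, class_sds={c: 1e-6 for c in "3210AB"},
                         estimate_error_scale=False).fit()
        pred = res.predict_regular(2.0)
        assert np.allclose(pred[["x", "y"]].to_numpy()[:len(seg)],
                           seg.xy, atol=1e-3)


class TestResidualsAndDraws:
    def test_one_step_residual_calibration(self):
        cfg = WorldConfig(seed=2, long_gap_rate=0.0)
        tru, obs = simulate_ctcrw_track(cfg.truth, 60, cfg, 11)
        seg = split_segments(obs)[0]
        res = CtcrwModel(seg, estimate_error_scale=False).fit()
        r = res.one_step_ahead_residuals()
        z = np.concatenate([r["resid_x"], r["resid_y"]])
        assert abs(z.mean()) < 0.1
        assert abs(z.var() - 1.0) < 0.15

    def test_residuals_pass_ljung_box_under_true_model(self):
        cfg = WorldConfig(seed=2, long_gap_rate=0.0)
        rng = np.random.default_rng(21)
        passed = 0
        n_rep = 20
        for _ in range(n_rep):
            _, obs = simulate_ctcrw_track(cfg.truth, 15, cfg, rng)
            segs = split_segments(obs)
            if not segs:
                n_rep -= 1
                continue
            res = CtcrwModel(segs[0], estimate_error_scale=False).fit()
            r = res.one_step_ahead_residuals()
            p = min(acorr_ljungbox(r["resid_x"], lags=[10])["lb_pvalue"].iloc[0],
                    acorr_ljungbox(r["resid_y"], lags=[10])["lb_pvalue"].iloc[0])
            passed += p > 0.01
        assert passed >= 0.85 * n_rep

    def test_outliers_inflate_residual_kurtosis(self):
        from scipy.stats import kurtosis
        cfg = WorldConfig(seed=2, long_gap_rate=0.0)
        tru, obs = simulate_ctcrw_track(cfg.truth, 40, cfg, 13)
        seg_clean = split_segments(obs)[0]
        obs2 = obs.copy()
        rng = np.random.default_rng(5)
        hit = rng.random(len(obs2)) < 0.03
        obs2.loc[hit, ["x", "y"]] += rng.standard_t(1, (int(hit.sum()), 2)) * 20
        seg_dirty = split_segments(obs2)[0]
        k_clean = kurtosis(np.concatenate(
            CtcrwModel(seg_clean).fit().one_step_ahead_residuals()
            [["resid_x", "resid_y"]].to_numpy().T.tolist()))
        k_dirty = kurtosis(np.concatenate(
            CtcrwModel(seg_dirty).fit().one_step_ahead_residuals()
            [["resid_x", "resid_y"]].to_numpy().T.tolist()))
        assert k_dirty > k_clean + 1.0

    def test_draw_moments_match_smoother(self, fitted):
        cfg, tru, seg, res = fitted
        draws = res.simulate_posterior_tracks(600, seed=1)
        pred = res.predict_regular(2.0)
        sample_var = draws[:, :, 0].var(axis=0)
        ratio = sample_var[5:-5] / pred["var_x"].to_numpy()[5:-5]
        assert abs(np.median(ratio) - 1.0) < 0.15
        # joint draws: consecutive grid points strongly dependent
        centred = draws[:, :, 0] - draws[:, :, 0].mean(axis=0)
        lag_cov = (centred[:, :-1] * centred[:, 1:]).mean()
        assert lag_cov > 0

    def test_zero_noise_draws_identical(self):
        cfg = WorldConfig(seed=8, argos_class_sds={c: 0.0 for c in "3210AB"},
                          long_gap_rate=0.0)
        tru, obs = simulate_ctcrw_track(cfg.truth, 12, cfg, 3,
                                        regular_gap=2.0)
        seg = split_segments(obs)[0]
        res = CtcrwModel(seg, class_sds={c: 1e-9 for c in "3210AB"},
                         estimate_error_scale=False).fit()
        draws = res.simulate_posterior_tracks(10, seed=4)
        assert np.allclose(draws.std(axis=0), 0.0, atol=1e-4)

    def test_nonconverged_fit_refuses_downstream_use(self, fitted):
        cfg, tru, seg, res = fitted
        from riskscape.ssm import CtcrwResults
        bad = CtcrwResults(res.model, res.params, res.nll, False, np.nan)
        with pytest.raises(RuntimeError, match="converge"):
            bad.predict_regular()
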