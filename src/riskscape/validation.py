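"""Parameter-recovery and calibration experiments on synthetic worlds.

Each experiment regenerates data from the synthetic-world generator with
known truth, runs the corresponding inference stage, and measures recovery,
coverage or calibration.  Brute-force reference computations (dense
joint-Gaussian densities) are kept here as independent checks of the
recursive likelihoods.  Problem sizes are arguments with desk-scale
defaults.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import multivariate_normal
from shapely.geometry import box

from .covariates import match_covariates
from .dive import Ar1MixedModel, _ar1_corr
from .persistence import MovePersistenceModel
from .raster import CovariateStack
from .rsf import (SealRSF, build_availability_domain, build_rsf_table,
                  fit_candidate_set, land_polygon_from_mask,
                  loio_cross_validate, boyce_spearman, propagate_location_error,
                  sample_available, uniform_day_datetimes)
from .ssm import CtcrwModel, CtcrwParams, TrackSegment, ou_transition, split_segments
from .synthetic import (TruthParams, WorldConfig, make_landscape,
                        simulate_ctcrw_track, simulate_dive_metrics,
                        simulate_mpm_track, simulate_seal_used_points,
                        true_risk_rasters)

__all__ = [
    "dense_ctcrw_nll", "random_segment", "ssm_oracle_battery", "ssm_recovery",
    "dense_ar1_lmm_nll", "ar1_lmm_oracle_battery", "ar1_lmm_recovery",
    "rsf_recovery", "model_selection_operating_characteristics",
    "boyce_experiment", "error_propagation_experiment", "mpm_recovery",
    "build_world", "rsf_table_from_world",
]

SEAL_TRUTH_NAMES = {"bathymetry": 0, "ice": 1, "prey": 2, "risk": 3,
                    "prey:risk": 4}


# ---------------------------------------------------------------------------
# dense reference densities (independent of the recursive filters)

def dense_ctcrw_nll(segment: TrackSegment, params: CtcrwParams,
                    prior_pos_sd: float = 50.0) -> float:
    """CTCRW marginal NLL by building the full joint-Gaussian observation
    covariance (state process integrated analytically); O(n^3), for small
    segments only."""
    t = segment.t_hours
    n = len(t)
    sds = segment.error_sds() * params.error_scale
    beta, sigma = params.beta_mov, params.sigma_mov
    V = [np.diag([prior_pos_sd ** 2, sigma ** 2 / (2 * beta)])]
    Ts = []
    for k in range(1, n):
        T, Q = ou_transition(beta, sigma, t[k] - t[k - 1])
        Ts.append(T)
        V.append(T @ V[-1] @ T.T + Q)
    P = np.zeros((2 * n, 2 * n))
    for i in range(n):
        P[2 * i:2 * i + 2, 2 * i:2 * i + 2] = V[i]
        A = np.eye(2)
        for j in range(i + 1, n):
            A = Ts[j - 1] @ A
            C = V[i] @ A.T
            P[2 * i:2 * i + 2, 2 * j:2 * j + 2] = C
            P[2 * j:2 * j + 2, 2 * i:2 * i + 2] = C.T
    H = np.zeros((n, 2 * n))
    H[np.arange(n), 2 * np.arange(n)] = 1.0
    S = H @ P @ H.T + np.diag(sds ** 2)
    nll = 0.0
    for c in range(2):
        mu = np.full(n, segment.xy[0, c])
        nll -= multivariate_normal.logpdf(segment.xy[:, c], mu, S)
    return float(nll)


def random_segment(rng: np.random.Generator, n: int | None = None) -> TrackSegment:
    n = int(rng.integers(3, 9)) if n is None else n
    t = np.cumsum(rng.uniform(0.5, 4.0, n))
    t -= t[0]
    xy = rng.normal(0.0, 5.0, (n, 2))
    lc = rng.choice(list("3210AB"), n)
    times = np.datetime64("2011-01-01") + (t * 3.6e12).astype("timedelta64[ns]")
    return TrackSegment("fx", "a", times, t, xy, lc)


def ssm_oracle_battery(n_segments: int = 200, seed: int = 0) -> float:
    """Max |filter NLL - dense joint-Gaussian NLL| over random fixtures."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_segments):
        seg = random_segment(rng)
        p = CtcrwParams(float(rng.uniform(0.1, 2.0)), float(rng.uniform(0.5, 3.0)),
                        float(rng.uniform(0.5, 2.0)))
        worst = max(worst, abs(CtcrwModel(seg).nloglik(p) - dense_ctcrw_nll(seg, p)))
    return worst


def ssm_recovery(n_tracks: int = 50, n_obs: int = 500, seed: int = 0) -> dict:
    """Denoising and movement-parameter recovery on simulated tracks."""
    cfg = WorldConfig(seed=seed, long_gap_rate=0.0)
    rng = np.random.default_rng(seed)
    duration_days = n_obs * cfg.mean_obs_gap / 24.0
    denoise_wins = 0
    rel_beta, rel_sigma = [], []
    n_done = 0
    while n_done < n_tracks:
        tru, obs = simulate_ctcrw_track(cfg.truth, duration_days, cfg, rng)
        segs = split_segments(obs)
        if not segs:
            continue
        seg = segs[0]
        # the generative class SDs are known by design; estimating a
        # redundant scale would only blur the movement parameters
        fit = CtcrwModel(seg, estimate_error_scale=False).fit()
        rel_beta.append(abs(fit.params.beta_mov - cfg.truth.ctcrw_beta_mov)
                        / cfg.truth.ctcrw_beta_mov)
        rel_sigma.append(abs(fit.params.sigma_mov - cfg.truth.ctcrw_sigma_mov)
                         / cfg.truth.ctcrw_sigma_mov)
        sm = fit.smoothed_states()
        idx = np.searchsorted(np.round(tru["t_hours"].to_numpy(), 9),
                              np.round(seg.t_hours + (seg.times[0] - tru["datetime"]
                                       .to_numpy()[0]) / np.timedelta64(1, "h"), 9))
        true_xy = tru[["x", "y"]].to_numpy()[idx]
        raw = np.sqrt(((seg.xy - true_xy) ** 2).sum(1).mean())
        smo = np.sqrt(((sm[["x", "y"]].to_numpy() - true_xy) ** 2).sum(1).mean())
        denoise_wins += smo < raw
        n_done += 1
    return {"denoise_fraction": denoise_wins / n_tracks,
            "median_rel_err_beta": float(np.median(rel_beta)),
            "median_rel_err_sigma": float(np.median(rel_sigma)),
            "median_rel_err_movement": float(np.median(rel_beta + rel_sigma))}


def dense_ar1_lmm_nll(model: Ar1MixedModel, beta, phi, sigma_b, sigma_e) -> float:
    """AR1 LMM marginal NLL via dense per-seal covariance matrices."""
    total = 0.0
    for _, y, X in model.groups:
        n = len(y)
        V = sigma_b ** 2 * np.ones((n, n)) + sigma_e ** 2 * _ar1_corr(n, phi)
        total -= multivariate_normal.logpdf(y, X @ np.asarray(beta, float), V)
    return float(total)


def ar1_lmm_oracle_battery(n_sets: int = 20, seed: int = 0) -> float:
    """Max |O(n) likelihood - dense MVN| over random toy row sets."""
    rng = np.random.default_rng(seed)
    truth = TruthParams()
    worst = 0.0
    for _ in range(n_sets):
        rows = []
        for i in range(3):
            m = int(rng.integers(2, 7))
            df = pd.DataFrame({"animal_id": f"s{i}",
                               "ice": rng.uniform(0, 100, m),
                               "prey": rng.uniform(0.2, 0.9, m),
                               "risk": rng.uniform(0, 1, m)})
            rows.append(simulate_dive_metrics(df, truth, rng,
                                              bathymetry=rng.uniform(50, 250, m)))
        model = Ar1MixedModel(pd.concat(rows, ignore_index=True), "duration_s",
                              ("ice", "prey"))
        beta = rng.normal(0, 1, model.p)
        phi = float(rng.uniform(-0.8, 0.8))
        sb, se = float(rng.uniform(1, 20)), float(rng.uniform(5, 40))
        worst = max(worst, abs(model.nloglik(beta, phi, sb, se)
                               - dense_ar1_lmm_nll(model, beta, phi, sb, se)))
    return worst


def ar1_lmm_recovery(n_reps: int = 80, n_seals: int = 26, n_rows: int = 200,
                     seed: int = 0) -> dict:
    """Median relative error of (phi, sigma_b, interaction beta).

    REML is used here: the variance components are themselves the recovery
    target, and REML removes the fixed-effect degrees-of-freedom bias.
    """
    truth = TruthParams()
    rng = np.random.default_rng(seed)
    b_true = truth.dive_beta["duration"][5]
    err_phi, err_sb, err_b = [], [], []
    for _ in range(n_reps):
        rows = []
        for i in range(n_seals):
            df = pd.DataFrame({"animal_id": f"s{i:02d}",
                               "ice": rng.uniform(0, 100, n_rows),
                               "prey": rng.uniform(0.2, 0.9, n_rows),
                               "risk": rng.uniform(0, 1, n_rows)})
            rows.append(simulate_dive_metrics(df, truth, rng,
                                              bathymetry=rng.uniform(50, 250, n_rows)))
        fit = Ar1MixedModel(pd.concat(rows, ignore_index=True), "duration_s",
                            ("ice", "prey", "risk", "prey:risk")).fit(reml=True)
        err_phi.append(abs(fit.phi - truth.dive_phi) / truth.dive_phi)
        err_sb.append(abs(fit.sigma_b - truth.dive_sigma_b["duration"])
                      / truth.dive_sigma_b["duration"])
        err_b.append(abs(fit.params["prey:risk"] - b_true) / abs(b_true))
    return {"median_rel_err_phi": float(np.median(err_phi)),
            "median_rel_err_sigma_b": float(np.median(err_sb)),
            "median_rel_err_beta": float(np.median(err_b)),
            "median_rel_err_pooled": float(np.median(err_phi + err_sb + err_b))}


# ---------------------------------------------------------------------------
# habitat-selection experiments

def build_world(seed: int, n_seals: int = 26, n_days: int = 90,
                truth: TruthParams | None = None) -> tuple[WorldConfig, CovariateStack]:
    kw = {} if truth is None else {"truth": truth}
    cfg = WorldConfig(seed=seed, n_seals=n_seals, n_days=n_days, **kw)
    stack = make_landscape(cfg)
    true_risk_rasters(stack, cfg.truth)
    return cfg, stack


def rsf_table_from_world(cfg: WorldConfig, stack: CovariateStack, seed: int,
                         ratio: int = 25) -> pd.DataFrame:
    """Used points from the generative RSF + matched availability sample."""
    used = simulate_seal_used_points(stack, cfg.truth, cfg.n_seals, seed)

    def match(df):
        return match_covariates(df, stack).rename(columns={"prey_diversity": "prey"})

    used_m = match(used)
    geo = stack.geometry
    land_poly = land_polygon_from_mask(geo, stack.land)
    bounds = box(geo.x0, geo.y0, geo.x_max, geo.y_max)
    dom = build_availability_domain(used_m[["x", "y"]].to_numpy(), 30.0,
                                   land=land_poly, clip_to=bounds)
    rng = np.random.default_rng(seed + 1)
    av = sample_available(dom, len(used_m), ratio, rng)
    avail = match(pd.DataFrame({
        "x": av[:, 0], "y": av[:, 1],
        "datetime": uniform_day_datetimes(used_m["datetime"], len(av), rng),
        "animal_id": "avail"}))
    return build_rsf_table(used_m, avail)


def rsf_recovery(n_worlds: int = 60, n_seals: int = 26, n_days: int = 90,
                 seed: int = 0) -> dict:
    """95% Wald-CI coverage per coefficient and interaction-sign agreement."""
    covered = {t: 0 for t in SEAL_TRUTH_NAMES}
    sign_ok = 0
    for w in range(n_worlds):
        cfg, stack = build_world(seed * 100003 + w, n_seals, n_days)
        data = rsf_table_from_world(cfg, stack, seed * 7919 + w)
        fit = SealRSF(data, ("ice", "prey", "risk", "prey:risk")).fit()
        ci = fit.conf_int()
        for term, k in SEAL_TRUTH_NAMES.items():
            tv = cfg.truth.seal_beta[k]
            if ci.loc[term, "lower"] <= tv <= ci.loc[term, "upper"]:
                covered[term] += 1
        sign_ok += np.sign(fit.params["prey:risk"]) == np.sign(cfg.truth.seal_beta[4])
    return {"coverage": {t: c / n_worlds for t, c in covered.items()},
            "min_coverage": min(covered.values()) / n_worlds,
            "interaction_sign_rate": sign_ok / n_worlds}


def model_selection_operating_characteristics(
        n_interaction: int = 60, n_null: int = 100, n_seals: int = 13,
        n_days: int = 45, seed: int = 0) -> dict:
    """Top-rank rate of the interaction model under interaction truth and
    null-within-2-delta-AICc rate under null truth."""
    interaction_top = 0
    null_ok = 0
    null_truth = TruthParams(seal_beta=(-0.008, 0.0, 0.0, 0.0, 0.0))
    for w in range(n_interaction):
        cfg, stack = build_world(seed * 90001 + w, n_seals, n_days)
        data = rsf_table_from_world(cfg, stack, seed * 6007 + w)
        ranking, _ = fit_candidate_set(data)
        interaction_top += "prey*risk" in ranking.iloc[0]["model"]
    for w in range(n_null):
        cfg0, stack0 = build_world(seed * 81001 + w, n_seals, n_days,
                                   truth=null_truth)
        data0 = rsf_table_from_world(cfg0, stack0, seed * 5003 + w)
        ranking0, _ = fit_candidate_set(data0)
        null_ok += bool(ranking0.loc[ranking0["model"] == "null",
                                     "delta_aicc"].iloc[0] <= 2.0)
    return {"interaction_top_rate": interaction_top / max(n_interaction, 1),
            "null_within_two_rate": null_ok / max(n_null, 1)}


def boyce_experiment(seed: int = 0, n_seals: int = 26, n_days: int = 90,
                     n_permutations: int = 100) -> dict:
    """Boyce LOIO on a well-specified world + permutation null."""
    cfg, stack = build_world(seed + 17, n_seals, n_days)
    data = rsf_table_from_world(cfg, stack, seed + 18)
    cv = loio_cross_validate(data, ("ice", "prey", "risk", "prey:risk"))
    fit = SealRSF(data, ("ice", "prey", "risk", "prey:risk")).fit()
    su = fit.linear_predictor(data[data["response"] == 1])
    sa = fit.linear_predictor(data[data["response"] == 0])
    rng = np.random.default_rng(seed)
    allscores = np.concatenate([su, sa])
    nu = len(su)
    perm_rhos = []
    for _ in range(n_permutations):
        p = rng.permutation(allscores)
        perm_rhos.append(boyce_spearman(p[:nu], p[nu:]))
    return {"mean_rho": float(cv["rho"].mean()),
            "perm_mean_rho": float(np.mean(perm_rhos))}


def error_propagation_experiment(seed: int = 0, n_draws: int = 50,
                                 n_seals: int = 5, n_days: int = 30,
                                 error_scales=(0.0, 1.0, 2.5)) -> dict:
    """Propagated-CI widths across increasing Argos error levels.

    Level 0 has zero measurement error and observations on the 2-h
    prediction grid itself, so every grid state is pinned exactly: all
    posterior draws coincide and the propagated CI has zero width.  Higher
    levels scale the Argos class SDs up, widening the coefficient CIs.
    """
    widths = {}
    for level, scale in enumerate(error_scales):
        cfg, stack = build_world(seed + 23, n_seals, n_days)
        sds = {k: max(v * scale, 1e-9) for k, v in cfg.argos_class_sds.items()}
        cfg.argos_class_sds = sds
        rng = np.random.default_rng(seed + 31)
        draws_by_seal = []
        for i in range(n_seals):
            tru, obs = simulate_ctcrw_track(
                cfg.truth, n_days, cfg, rng,
                start=(350.0 + 20 * rng.standard_normal(),
                       300.0 + 20 * rng.standard_normal()),
                animal_id=f"seal_{i:02d}",
                regular_gap=2.0 if scale == 0.0 else None)
            segs = split_segments(obs)
            if not segs:
                continue
            seg = segs[0]
            if scale == 0.0:
                fit = CtcrwModel(seg, class_sds={k: 1e-6 for k in sds},
                                 estimate_error_scale=False).fit()
            else:
                fit = CtcrwModel(seg, class_sds=sds,
                                 estimate_error_scale=False).fit()
            d = fit.simulate_posterior_tracks(n_draws, seed=rng, step_hours=2.0)
            pred = fit.predict_regular(2.0)
            draws_by_seal.append((pred, d))
        track_draws = []
        for j in range(n_draws):
            pts = []
            for pred, d in draws_by_seal:
                t = pred.copy()
                t["x"] = d[j, :, 0]
                t["y"] = d[j, :, 1]
                pts.append(t)
            track_draws.append(pd.concat(pts, ignore_index=True))

        def match(df):
            return match_covariates(df, stack).rename(
                columns={"prey_diversity": "prey"})

        geo = stack.geometry
        land_poly = land_polygon_from_mask(geo, stack.land)
        bounds = box(geo.x0, geo.y0, geo.x_max, geo.y_max)
        ci = propagate_location_error(track_draws, match, land=land_poly,
                                      clip_to=bounds, seed=seed + 41)
        widths[level] = float((ci["upper"] - ci["lower"]).mean())
    return {"widths": widths, "zero_error_width": widths[0],
            "monotone": all(widths[i] < widths[i + 1]
                            for i in range(len(widths) - 1))}


def mpm_recovery(n_reps: int = 40, n_seals: int = 20, n_steps: int = 300,
                 seed: int = 0) -> dict:
    """Sign agreement and relative error for the persistence risk effect."""
    truth = TruthParams()
    rng = np.random.default_rng(seed)
    b_true = truth.mpm_beta[2]
    signs = 0
    rel = []
    for _ in range(n_reps):
        rows = []
        for i in range(n_seals):
            cov = pd.DataFrame({"bathymetry": rng.uniform(50, 250, n_steps),
                                "risk": rng.uniform(0, 1, n_steps),
                                "prey": rng.uniform(0.2, 0.9, n_steps)})
            tr = simulate_mpm_track(truth, cov, rng)
            tr["animal_id"] = f"s{i:02d}"
            rows.append(tr)
        fit = MovePersistenceModel(pd.concat(rows, ignore_index=True),
                                   ("bathymetry", "risk", "prey")).fit()
        signs += np.sign(fit.params["risk"]) == np.sign(b_true)
        rel.append(abs(fit.params["risk"] - b_true) / abs(b_true))
    return {"sign_rate": signs / n_reps,
            "median_rel_err": float(np.median(rel))}
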