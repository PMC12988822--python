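"""End-to-end orchestration: simulate -> fit-ssm -> build-risk -> match ->
fit-rsf (+CV) -> fit-mpm -> fit-dive, with a reproducible run manifest.

Every stochastic stage draws from a seed recorded in the manifest, so every
output is reproducible from the manifest alone.  A stage failure raises
:class:`PipelineError` naming the stage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .covariates import match_covariates, screen_correlations
from .dive import (daily_frequency_table, derive_dive_metrics,
                   fit_dive_candidates, thin_every_kth)
from .persistence import rank_mpm_models
from .predator import LassoRSF, build_bear_design, predict_daily_risk
from .raster import CovariateStack
from .rsf import (build_availability_domain, build_rsf_table, fit_candidate_set,
                  land_polygon_from_mask, loio_cross_validate, sample_available,
                  thin_one_per_day)
from .ssm import CtcrwModel, split_segments
from .synthetic import (WorldConfig, make_landscape,
                        simulate_bear_use, simulate_ctcrw_track,
                        simulate_dives, true_risk_rasters)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Desk-scale pipeline configuration; every stage seed is explicit."""

    out_dir: str = "runs/demo"
    seed: int = 1
    n_seals: int = 5
    n_days: int = 30
    n_bear_points: int = 1500
    dive_rate_per_hour: float = 1.0
    step_hours: float = 2.0
    max_gap_hours: float = 12.0
    min_segment_len: int = 100
    availability_ratio: int = 25
    thin_k: int = 10
    run_cv: bool = True
    world: dict = field(default_factory=dict)

    def seeds(self) -> dict:
        base = int(self.seed)
        return {name: base + i for i, name in enumerate(
            ["world", "bears", "tracks", "dives", "thin", "avail", "lasso"])}


def _matcher(stack: CovariateStack, prey_var: str = "prey_diversity"):
    def match(df: pd.DataFrame) -> pd.DataFrame:
        out = match_covariates(df, stack, prey_var)
        return out.rename(columns={prey_var: "prey"})
    return match


def run_pipeline(config: RunConfig) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.seeds()
    manifest = {"config": asdict(config), "seeds": seeds, "stages": {},
                "row_drops": {}}
    results: dict = {"manifest": manifest}

    def stage(name):
        def deco(fn):
            try:
                info = fn() or {}
            except Exception as e:  # halt with named stage
                raise PipelineError(name, e) from e
            manifest["stages"][name] = info
            return info
        return deco

    @stage("simulate")
    def _simulate():
        wc = WorldConfig(seed=seeds["world"], n_seals=config.n_seals,
                         n_days=config.n_days, **config.world)
        stack = make_landscape(wc)
        true_risk_rasters(stack, wc.truth)
        results["world_config"] = wc
        results["stack"] = stack
        bears = simulate_bear_use(stack, wc.truth, config.n_bear_points,
                                  seeds["bears"], n_bears=wc.n_bears)
        results["bears"] = bears
        rng = np.random.default_rng(seeds["tracks"])
        obs_all, truth_all = [], []
        for i in range(config.n_seals):
            tru, obs = simulate_ctcrw_track(
                wc.truth, config.n_days, wc, rng,
                start=(350.0 + 30 * rng.standard_normal(),
                       300.0 + 30 * rng.standard_normal()),
                animal_id=f"seal_{i:02d}")
            obs_all.append(obs)
            truth_all.append(tru)
        results["observations"] = pd.concat(obs_all, ignore_index=True)
        results["true_tracks"] = pd.concat(truth_all, ignore_index=True)
        rio.write_tracks(results["observations"], out / "argos_tracks.csv")
        rio.write_raster_stack(stack, out / "stack.nc")
        rio.write_truth_json(wc.truth, out / "truth.json")
        return {"n_obs": len(results["observations"]), "n_bears": len(bears)}

    @stage("fit_ssm")
    def _fit_ssm():
        segs = split_segments(results["observations"], config.max_gap_hours,
                              config.min_segment_len)
        if not segs:
            raise ValueError("no usable segments after splitting")
        preds = []
        for seg in segs:
            fit = CtcrwModel(seg).fit()
            preds.append(fit.predict_regular(config.step_hours))
        results["predicted"] = pd.concat(preds, ignore_index=True)
        rio.write_tracks(results["predicted"].assign(lc="G"),
                         out / "predicted_tracks.csv")
        return {"n_segments": len(segs),
                "n_predicted": len(results["predicted"])}

    @stage("build_risk")
    def _build_risk():
        stack = results["stack"]
        design = build_bear_design(results["bears"], stack, ratio=10,
                                   seed=seeds["lasso"])
        lasso = LassoRSF(design).fit(lam="cv", seed=seeds["lasso"])
        results["bear_fit"] = lasso
        fitted_risk = {d: predict_daily_risk(lasso, stack, d)
                       for d in stack.ice}
        results["fitted_risk"] = fitted_risk
        # downstream stages consume the fitted risk layer
        stack.risk = fitted_risk
        return {"lambda": lasso.lam,
                "coefficients": lasso.coefficients.to_dict()}

    @stage("match_and_rsf")
    def _rsf():
        stack = results["stack"]
        match = _matcher(stack)
        used = thin_one_per_day(results["predicted"], seeds["thin"])
        used = match(used)
        land_poly = land_polygon_from_mask(stack.geometry, stack.land)
        from shapely.geometry import box
        geo = stack.geometry
        bounds = box(geo.x0, geo.y0, geo.x_max, geo.y_max)
        dom = build_availability_domain(used[["x", "y"]].to_numpy(), 30.0,
                                        land=land_poly, clip_to=bounds)
        av = sample_available(dom, len(used), config.availability_ratio,
                              np.random.default_rng(seeds["avail"]))
        from .rsf import uniform_day_datetimes
        avail = match(pd.DataFrame({
            "x": av[:, 0], "y": av[:, 1],
            "datetime": uniform_day_datetimes(
                used["datetime"], len(av), np.random.default_rng(seeds["avail"])),
            "animal_id": "avail"}))
        data = build_rsf_table(used, avail)
        results["rsf_data"] = data
        corr, flagged = screen_correlations(
            data, ["bathymetry", "ice", "prey", "risk"])
        ranking, fits = fit_candidate_set(data)
        results["rsf_ranking"] = ranking
        results["rsf_fits"] = fits
        best = ranking.loc[ranking["selected"], "model"].iloc[0]
        ranking.to_csv(out / "rsf_ranking.csv", index=False)
        info = {"n_used": len(used), "n_available": len(avail),
                "best_model": best, "correlation_flags": flagged}
        if config.run_cv and best != "null":
            cv = loio_cross_validate(data, fits[best].model.terms)
            results["rsf_cv"] = cv
            info["cv_mean_rho"] = float(cv["rho"].mean())
        return info

    @stage("fit_mpm")
    def _mpm():
        match = _matcher(results["stack"])
        pred = match(results["predicted"])
        ranking, fits = rank_mpm_models(pred)
        results["mpm_ranking"] = ranking
        results["mpm_fits"] = fits
        ranking.to_csv(out / "mpm_ranking.csv", index=False)
        return {"best_model": ranking.loc[ranking["selected"], "model"].iloc[0]}

    @stage("fit_dive")
    def _dive():
        wc = results["world_config"]
        match = _matcher(results["stack"])
        rows = []
        for aid, tr in results["predicted"].groupby("animal_id"):
            dives = simulate_dives(tr.reset_index(drop=True), match, wc.truth,
                                   config.dive_rate_per_hour, seeds["dives"])
            rows.append(dives)
        dives = pd.concat(rows, ignore_index=True)
        metrics = derive_dive_metrics(dives)
        thinned = thin_every_kth(metrics, config.thin_k)
        results["dive_rows"] = thinned
        info = {}
        for response in ("duration_s", "ascent_speed"):
            ranking, fits = fit_dive_candidates(thinned, response)
            results[f"dive_ranking_{response}"] = ranking
            info[response] = ranking.loc[ranking["selected"], "model"].iloc[0]
        freq = daily_frequency_table(metrics)
        results["dive_frequency"] = freq
        return {"n_dives": len(metrics), "best": info}

    manifest_str = json.dumps(manifest, indent=2, sort_keys=True, default=str)
    manifest["manifest_sha256"] = hashlib.sha256(manifest_str.encode()).hexdigest()
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return results
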