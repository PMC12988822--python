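"""Dive generation: Poisson dive times along a track, AR1 mixed-model dive
metrics, and transmitted-style five-point dive profiles.

Metric construction guarantees the derived quantities round-trip exactly:
the last intermediate depth point and its elapsed-percentage are chosen so
that (last depth) / (time from last point to surfacing) equals the
generated ascent speed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import TruthParams

__all__ = ["simulate_dive_times", "simulate_dive_metrics", "simulate_dives"]

_PCTS = (10.0, 22.0, 30.0, 38.0)  # first four elapsed-% points


def simulate_dive_times(track: pd.DataFrame, rate_per_hour: float, seed) -> pd.DataFrame:
    """Homogeneous Poisson dive start times along a track's time span,
    positions linearly interpolated between track points."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = track["t_hours"].to_numpy(float)
    span = t[-1] - t[0]
    n = rng.poisson(rate_per_hour * span)
    times = np.sort(rng.uniform(t[0], t[-1], n))
    out = pd.DataFrame({
        "animal_id": track["animal_id"].iloc[0],
        "t_hours": times,
        "x": np.interp(times, t, track["x"].to_numpy(float)),
        "y": np.interp(times, t, track["y"].to_numpy(float)),
    })
    if "datetime" in track:
        t0 = pd.to_datetime(track["datetime"].iloc[0])
        out["datetime"] = t0 + pd.to_timedelta((times - t[0]) * 3600, unit="s")
    return out


def _ar1_series(n: int, phi: float, sigma_e: float, rng) -> np.ndarray:
    e = np.zeros(n)
    if n == 0:
        return e
    e[0] = rng.normal(0.0, sigma_e)
    innov_sd = sigma_e * np.sqrt(1 - phi * phi)
    for k in range(1, n):
        e[k] = phi * e[k - 1] + rng.normal(0.0, innov_sd)
    return e


def _metric_values(X: np.ndarray, beta, b: float, phi: float, sigma_e: float,
                   rng, floor: float) -> np.ndarray:
    """x'beta + b + AR1 noise, resampling innovations on positivity violations."""
    mu = X @ np.asarray(beta, float) + b
    n = len(mu)
    e = _ar1_series(n, phi, sigma_e, rng)
    vals = mu + e
    innov_sd = sigma_e * np.sqrt(1 - phi * phi)
    for k in range(n):
        tries = 0
        while vals[k] <= floor and tries < 100:
            prev = e[k - 1] if k else 0.0
            sd = innov_sd if k else sigma_e
            e[k] = phi * prev + rng.normal(0.0, sd) if k else rng.normal(0.0, sigma_e)
            vals[k] = mu[k] + e[k]
            tries += 1
        if vals[k] <= floor:
            vals[k] = floor + abs(rng.normal(0.0, 0.1 * max(floor, 1.0)))
    return vals


def simulate_dive_metrics(dives: pd.DataFrame, truth: TruthParams, seed,
                          bathymetry=None) -> pd.DataFrame:
    """Generate duration, depth, ascent speed and the five-point profile.

    ``dives`` needs per-dive covariate columns ``ice``, ``prey``, ``risk``
    (zeros substituted when absent) and ``animal_id``; ``bathymetry``
    (column or array) bounds the maximum depth.  Per-seal random intercepts
    and AR1 residuals follow the truth parameters.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = dives.reset_index(drop=True).copy()
    n = len(out)
    if bathymetry is None:
        bathymetry = out["bathymetry"].to_numpy(float) if "bathymetry" in out \
            else np.full(n, 150.0)
    bath = np.asarray(bathymetry, float)
    depth = np.clip(rng.uniform(0.2, 0.8, n) * bath, 3.0, None)
    out["max_depth"] = depth

    cov = {c: (out[c].to_numpy(float) if c in out else np.zeros(n))
           for c in ("ice", "prey", "risk")}
    X = np.column_stack([np.ones(n), depth, cov["ice"], cov["prey"], cov["risk"],
                         cov["risk"] * cov["prey"]])

    dur = np.empty(n)
    asc = np.empty(n)
    for aid, idx in out.groupby("animal_id", sort=False).indices.items():
        b_dur = rng.normal(0.0, truth.dive_sigma_b["duration"])
        b_asc = rng.normal(0.0, truth.dive_sigma_b["ascent_speed"])
        dur[idx] = _metric_values(X[idx], truth.dive_beta["duration"], b_dur,
                                  truth.dive_phi, truth.dive_sigma_e["duration"],
                                  rng, floor=20.0)
        asc[idx] = _metric_values(X[idx], truth.dive_beta["ascent_speed"], b_asc,
                                  truth.dive_phi, truth.dive_sigma_e["ascent_speed"],
                                  rng, floor=0.05)
    out["duration_s"] = dur
    out["true_ascent_speed"] = asc

    # five-point profile consistent with the generated ascent speed
    for i, p in enumerate(_PCTS, start=1):
        frac = {1: 0.55, 2: 0.85, 3: 1.0, 4: 0.95}[i]
        out[f"d{i}"] = frac * depth
        out[f"p{i}"] = p
    d5 = np.minimum(0.9 * depth, 0.6 * asc * dur)
    p5 = 100.0 * (1.0 - d5 / (asc * dur))
    out["d5"] = d5
    out["p5"] = p5
    return out


def simulate_dives(track: pd.DataFrame, covariate_lookup, truth: TruthParams,
                   rate_per_hour: float, seed) -> pd.DataFrame:
    """Compose dive times, covariate matching and metric generation.

    ``covariate_lookup(points_df) -> df`` must attach ``ice``, ``prey``,
    ``risk`` and ``bathymetry`` columns (e.g. a closure over
    :func:`riskscape.covariates.match_covariates`).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pts = simulate_dive_times(track, rate_per_hour, rng)
    pts = covariate_lookup(pts)
    return simulate_dive_metrics(pts, truth, rng)
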