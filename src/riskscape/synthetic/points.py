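"""Weighted used-point generation for predator and mesopredator selection.

Points are drawn from the continuous water domain by rejection sampling
against exp(linear predictor), where the linear predictor is evaluated by
the same bilinear interpolation the fitting pipeline uses.  The fitted
resource selection function is therefore exactly well-specified and
recovery tests are sharp.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..raster import CovariateStack, RasterField, bilinear
from .config import TruthParams

__all__ = ["simulate_bear_use", "simulate_seal_used_points",
           "bear_linear_field", "seal_linear_field", "sample_weighted_points"]


def bear_linear_field(stack: CovariateStack, truth: TruthParams, day: int) -> RasterField:
    b_ice, b_bath, b_d2c = truth.bear_beta
    lin = (b_ice * stack.ice[day].values + b_bath * stack.bathymetry.values
           + b_d2c * stack.dist_coast.values)
    return stack.bathymetry.like(lin, stamp=day, name="bear_lin")


def seal_linear_field(stack: CovariateStack, truth: TruthParams, day: int,
                      year: int) -> RasterField:
    b_bath, b_ice, b_prey, b_risk, b_int = truth.seal_beta
    prey = _prey_on_geometry(stack, year)
    risk = stack.risk[day].values
    lin = (b_bath * stack.bathymetry.values + b_ice * stack.ice[day].values
           + b_prey * prey + b_risk * risk + b_int * risk * prey)
    return stack.bathymetry.like(lin, stamp=day, name="seal_lin")


def _prey_on_geometry(stack: CovariateStack, year: int) -> np.ndarray:
    from ..covariates import prey_on_geometry
    return prey_on_geometry(stack, year)


def sample_weighted_points(stack: CovariateStack, lin: RasterField, n: int,
                           rng: np.random.Generator,
                           max_tries: int = 500) -> np.ndarray:
    """Rejection-sample ``n`` water points with density prop. to exp(lin).

    Candidates are uniform over the node bounding box; a candidate is kept
    if its nearest node is water and U < exp(lin(x) - max_node_lin).  The
    node maximum bounds the bilinear interpolant, so the envelope is valid.
    """
    water = ~stack.land
    if not water.any():
        raise ValueError("domain is entirely land")
    geo = stack.geometry
    lmax = lin.values[water].max()
    out = np.empty((0, 2))
    for _ in range(max_tries):
        m = max(4 * (n - len(out)), 64)
        x = rng.uniform(geo.x0, geo.x_max, m)
        y = rng.uniform(geo.y0, geo.y_max, m)
        ii = np.rint((y - geo.y0) / geo.cell_size).astype(int)
        jj = np.rint((x - geo.x0) / geo.cell_size).astype(int)
        ok = water[ii, jj]
        if ok.any():
            xw, yw = x[ok], y[ok]
            acc = rng.random(len(xw)) < np.exp(bilinear(lin, xw, yw) - lmax)
            out = np.vstack([out, np.column_stack([xw[acc], yw[acc]])])
        if len(out) >= n:
            return out[:n]
    raise RuntimeError("rejection sampling failed to reach the requested count")


def _sample_spacetime(stack: CovariateStack, lin_by_day: dict, n: int,
                      rng: np.random.Generator,
                      max_tries: int = 500) -> pd.DataFrame:
    """Joint (day, location) rejection sampling with density prop. to
    exp(lin_day(x, y)) over water x days — the generative inverse of a
    pooled used/available RSF with a single normalising constant."""
    water = ~stack.land
    if not water.any():
        raise ValueError("domain is entirely land")
    geo = stack.geometry
    days = np.array(sorted(lin_by_day))
    gmax = max(f.values[water].max() for f in lin_by_day.values())
    rows = []
    have = 0
    for _ in range(max_tries):
        m = max(4 * (n - have), 256)
        d = rng.choice(days, m)
        x = rng.uniform(geo.x0, geo.x_max, m)
        y = rng.uniform(geo.y0, geo.y_max, m)
        ii = np.rint((y - geo.y0) / geo.cell_size).astype(int)
        jj = np.rint((x - geo.x0) / geo.cell_size).astype(int)
        ok = water[ii, jj]
        d, x, y = d[ok], x[ok], y[ok]
        lin = np.empty(len(d))
        for dv in np.unique(d):
            sel = d == dv
            lin[sel] = bilinear(lin_by_day[int(dv)], x[sel], y[sel])
        acc = rng.random(len(d)) < np.exp(lin - gmax)
        if acc.any():
            rows.append(pd.DataFrame({"x": x[acc], "y": y[acc],
                                      "day": d[acc].astype(int)}))
            have += int(acc.sum())
        if have >= n:
            out = pd.concat(rows, ignore_index=True).iloc[:n]
            return out.sort_values(["day"]).reset_index(drop=True)
    raise RuntimeError("rejection sampling failed to reach the requested count")


def simulate_bear_use(stack: CovariateStack, truth: TruthParams, n_points: int,
                      seed, days=None, n_bears: int = 1) -> pd.DataFrame:
    """Predator used points: (day, location) sampled jointly with density
    prop. to exp(x' bear_beta) over water x days."""
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    rng = _rng(seed)
    days = sorted(stack.ice.keys()) if days is None else list(days)
    lin_by_day = {int(d): bear_linear_field(stack, truth, int(d)) for d in days}
    out = _sample_spacetime(stack, lin_by_day, n_points, rng)
    out["animal_id"] = [f"bear_{i % n_bears:02d}" for i in range(len(out))]
    out["datetime"] = stack.time_origin + out["day"].to_numpy() * np.timedelta64(1, "D") \
        + np.timedelta64(12, "h")
    return out


def simulate_seal_used_points(stack: CovariateStack, truth: TruthParams,
                              n_seals: int, seed, days=None,
                              n_per_seal_day: int = 1, year=None) -> pd.DataFrame:
    """Mesopredator used points including the risk x prey interaction term.

    (day, location) pairs are drawn jointly with density prop. to
    exp(x' seal_beta); the expected total is n_seals x n_days x
    n_per_seal_day and seal ids are assigned round-robin within day.
    """
    if n_per_seal_day < 1:
        raise ValueError("n_per_seal_day must be >= 1")
    rng = _rng(seed)
    days = sorted(stack.risk.keys()) if days is None else list(days)
    year = year if year is not None else sorted(stack.prey_diversity)[0]
    lin_by_day = {int(d): seal_linear_field(stack, truth, int(d), year)
                  for d in days}
    total = n_seals * n_per_seal_day * len(days)
    out = _sample_spacetime(stack, lin_by_day, total, rng)
    ids = np.empty(len(out), dtype=object)
    for _, idx in out.groupby("day").indices.items():
        ids[idx] = [f"seal_{i % n_seals:02d}" for i in range(len(idx))]
    out["animal_id"] = ids
    hours = rng.integers(0, 24, len(out))
    out["datetime"] = stack.time_origin + out["day"].to_numpy() * np.timedelta64(1, "D") \
        + hours * np.timedelta64(1, "h")
    return out


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
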