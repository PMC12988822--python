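"""Space/time matching of point data to the covariate stack.

Points (track locations or dives) are matched to daily fields (ice,
predator selection) by calendar day, to annual fields (prey biomass,
prey diversity) by calendar year, and to static fields (bathymetry)
directly; every spatial lookup is bilinear.  Calendar days are UTC.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .raster import CovariateStack, bilinear

logger = logging.getLogger(__name__)

__all__ = [
    "match_covariates",
    "prey_on_geometry",
    "interpolate_dive_locations",
    "screen_correlations",
    "standardize",
    "apply_standardization",
]


def match_covariates(points: pd.DataFrame, stack: CovariateStack,
                     prey_var: str = "prey_diversity") -> pd.DataFrame:
    """Attach covariate columns to a point table.

    ``points`` needs columns ``x``, ``y`` and ``datetime``.  Returns a copy
    with ``bathymetry``, ``ice``, ``risk`` and the prey metric named by
    ``prey_var`` (``"prey_diversity"``, ``"prey_total"`` or a species name).
    Rows whose day/year layer is missing are dropped, with the count logged.
    """
    pts = points.reset_index(drop=True).copy()
    when = pd.to_datetime(pts["datetime"], utc=True).dt.tz_localize(None)
    days = ((when.values - stack.time_origin) // np.timedelta64(1, "D")).astype(int)
    years = when.dt.year.to_numpy()
    x = pts["x"].to_numpy(float)
    y = pts["y"].to_numpy(float)

    pts["bathymetry"] = bilinear(stack.bathymetry, x, y)
    ice = np.full(len(pts), np.nan)
    risk = np.full(len(pts), np.nan)
    prey = np.full(len(pts), np.nan)
    for d in np.unique(days):
        m = days == d
        if d in stack.ice:
            ice[m] = bilinear(stack.ice[d], x[m], y[m])
        if d in stack.risk:
            risk[m] = bilinear(stack.risk[d], x[m], y[m])
    for yr in np.unique(years):
        m = years == yr
        fld = _prey_field(stack, prey_var, int(yr))
        if fld is not None:
            # coarse annual grids: nearest-edge extension at the margin
            cx = np.clip(x[m], fld.x0, fld.x_max)
            cy = np.clip(y[m], fld.y0, fld.y_max)
            prey[m] = bilinear(fld, cx, cy)
    pts["ice"] = ice
    pts["risk"] = risk
    pts[prey_var] = prey
    bad = ~np.isfinite(pts[["bathymetry", "ice", "risk", prey_var]].to_numpy()).all(axis=1)
    if bad.any():
        logger.warning("match_covariates: dropped %d/%d rows with missing layers",
                       int(bad.sum()), len(pts))
    return pts.loc[~bad].reset_index(drop=True)


def _prey_field(stack: CovariateStack, var: str, year: int):
    if var == "prey_diversity":
        return stack.prey_diversity.get(year)
    if var == "prey_total":
        series = [s.get(year) for s in stack.prey_biomass.values()]
        series = [f for f in series if f is not None]
        if not series:
            return None
        return series[0].like(np.sum([f.values for f in series], axis=0),
                              stamp=year, name="prey_total")
    sp = stack.prey_biomass.get(var)
    return None if sp is None else sp.get(year)


def prey_on_geometry(stack: CovariateStack, year: int,
                     var: str = "prey_diversity") -> np.ndarray:
    """Annual prey metric resampled bilinearly onto the analysis grid."""
    geo = stack.geometry
    fld = _prey_field(stack, var, int(year))
    if fld is None:
        raise KeyError(f"no {var} layer for year {year}")
    gx, gy = np.meshgrid(geo.node_x(), geo.node_y())
    cx = np.clip(gx, fld.x0, fld.x_max)
    cy = np.clip(gy, fld.y0, fld.y_max)
    return bilinear(fld, cx.ravel(), cy.ravel()).reshape(gx.shape)


def interpolate_dive_locations(dives: pd.DataFrame,
                               tracks: pd.DataFrame) -> pd.DataFrame:
    """Place dives on the regular predicted track by linear time interpolation.

    ``tracks`` is a predicted-track table (``animal_id``, ``datetime``, ``x``,
    ``y``); dives outside every segment's time span for their animal are
    dropped (count logged), since they cannot be located.
    """
    out = []
    n_drop = 0
    for aid, dv in dives.groupby("animal_id", sort=False):
        tr = tracks[tracks["animal_id"] == aid].sort_values("datetime")
        if tr.empty:
            n_drop += len(dv)
            continue
        tt = pd.to_datetime(tr["datetime"]).astype("int64").to_numpy() / 1e9
        dt = pd.to_datetime(dv["datetime"]).astype("int64").to_numpy() / 1e9
        ok = (dt >= tt[0]) & (dt <= tt[-1])
        n_drop += int((~ok).sum())
        dv = dv.loc[ok].copy()
        dv["x"] = np.interp(dt[ok], tt, tr["x"].to_numpy())
        dv["y"] = np.interp(dt[ok], tt, tr["y"].to_numpy())
        out.append(dv)
    if n_drop:
        logger.warning("interpolate_dive_locations: dropped %d dives outside track spans", n_drop)
    if not out:
        return dives.iloc[0:0].assign(x=[], y=[])
    return pd.concat(out, ignore_index=True)


def screen_correlations(df: pd.DataFrame, covariates=None,
                        threshold: float = 0.6):
    """Pairwise Pearson correlations among model covariates.

    Returns ``(corr_table, flagged)`` where ``flagged`` lists pairs with
    ``|r| > threshold`` (strict).  Flagging is a report; nothing is dropped.
    """
    cols = list(covariates) if covariates is not None else [
        c for c in df.columns if df[c].dtype.kind == "f"]
    corr = df[cols].corr(method="pearson")
    flagged = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            r = corr.loc[a, b]
            if np.isfinite(r) and abs(r) > threshold:
                flagged.append((a, b, float(r)))
    return corr, flagged


def standardize(df: pd.DataFrame, columns):
    """Z-score ``columns`` by their own mean/SD; returns (frame, transform).

    The transform (per-column mean and SD) is stored with fits so that
    predictions on new data reuse the training-scale.
    """
    out = df.copy()
    transform = {}
    for c in columns:
        mu = float(df[c].mean())
        sd = float(df[c].std(ddof=0))
        if sd == 0:
            sd = 1.0
        out[c] = (df[c] - mu) / sd
        transform[c] = (mu, sd)
    return out, transform


def apply_standardization(df: pd.DataFrame, transform) -> pd.DataFrame:
    out = df.copy()
    for c, (mu, sd) in transform.items():
        if c in out.columns:
            out[c] = (out[c] - mu) / sd
    return out
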