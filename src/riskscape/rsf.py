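"""Mesopredator (ringed seal) habitat selection: the used/available RSF.

Pipeline: thin predicted locations to one per seal-day, build the
availability domain (minimum convex polygon of all locations, buffered
30 km, land-clipped), sample 25 available points per used point, match
covariates, fit the 9+null candidate logistic models, rank by AICc with
the parsimony rule, cross-validate leave-one-individual-out with
Boyce-style binning, and propagate location error through posterior track
draws.

The fitting table uses canonical covariate names ``bathymetry``, ``ice``,
``prey``, ``risk``; ``prey:risk`` denotes their product.  Bathymetry is in
every candidate, including the null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
import statsmodels.api as sm
from scipy.stats import spearmanr
from shapely.geometry import MultiPoint, box

from .covariates import standardize, apply_standardization
from .model_selection import aicc, candidate_set, rank_models
from .raster import CovariateStack, RasterField

__all__ = [
    "thin_one_per_day", "build_availability_domain", "sample_available",
    "land_polygon_from_mask", "SealRSF", "RsfResults", "fit_candidate_set",
    "coefficient_stabilization", "predict_map", "loio_cross_validate",
    "propagate_location_error", "build_rsf_table",
]


# ---------------------------------------------------------------------------
# design construction

def thin_one_per_day(points: pd.DataFrame, seed) -> pd.DataFrame:
    """One uniformly chosen location per animal per UTC calendar day."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pts = points.reset_index(drop=True)
    day = pd.to_datetime(pts["datetime"]).dt.floor("D")
    keep = []
    for _, idx in pts.groupby([pts["animal_id"], day], sort=True).indices.items():
        keep.append(idx[rng.integers(len(idx))])
    return pts.loc[sorted(keep)].reset_index(drop=True)


def land_polygon_from_mask(geo: RasterField, land: np.ndarray):
    """Union of cell squares for land nodes (synthetic-world convenience)."""
    cs = geo.cell_size
    iy, ix = np.where(land)
    if len(iy) == 0:
        return None
    boxes = [box(geo.x0 + (j - 0.5) * cs, geo.y0 + (i - 0.5) * cs,
                 geo.x0 + (j + 0.5) * cs, geo.y0 + (i + 0.5) * cs)
             for i, j in zip(iy, ix)]
    return shapely.unary_union(boxes)


@dataclass
class AvailabilityDomain:
    polygon: shapely.Geometry
    area: float


def build_availability_domain(points_xy: np.ndarray, buffer_km: float = 30.0,
                              land=None, clip_to=None) -> AvailabilityDomain:
    """MCP of all locations, buffered, land-clipped.

    Degenerate hulls (collinear points) are handled by buffering the
    line/point directly.  A fully land-covered result is an error.
    """
    hull = MultiPoint([tuple(p) for p in np.asarray(points_xy)]).convex_hull
    poly = hull.buffer(buffer_km)
    if clip_to is not None:
        poly = poly.intersection(clip_to)
    if land is not None:
        poly = poly.difference(land)
    if poly.is_empty or poly.area <= 0:
        raise ValueError("availability domain has no water area")
    return AvailabilityDomain(poly, float(poly.area))


def sample_available(domain: AvailabilityDomain, n_used: int, ratio: int = 25,
                     seed=None) -> np.ndarray:
    """Uniform points over the domain polygon; count = ratio * n_used."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = ratio * n_used
    minx, miny, maxx, maxy = domain.polygon.bounds
    pts = np.empty((0, 2))
    while len(pts) < n:
        m = max(int(1.6 * (n - len(pts)) * (maxx - minx) * (maxy - miny)
                    / max(domain.area, 1e-9)), 256)
        x = rng.uniform(minx, maxx, m)
        y = rng.uniform(miny, maxy, m)
        ok = shapely.contains_xy(domain.polygon, x, y)
        pts = np.vstack([pts, np.column_stack([x[ok], y[ok]])])
    return pts[:n]


def uniform_day_datetimes(used_datetimes, n: int, rng) -> np.ndarray:
    """Datetimes uniform over the study's observed calendar days (the
    availability sampling frame is uniform over water x days)."""
    days = pd.DatetimeIndex(pd.to_datetime(pd.Series(used_datetimes))
                            .dt.floor("D").unique())
    pick = rng.integers(0, len(days), n)
    return days[pick].to_numpy().astype("datetime64[ns]") + np.timedelta64(12, "h")


def build_rsf_table(used: pd.DataFrame, available: pd.DataFrame) -> pd.DataFrame:
    """Stack used (1) and available (0) rows into one modelling table."""
    u = used.copy()
    u["response"] = 1
    a = available.copy()
    a["response"] = 0
    return pd.concat([u, a], ignore_index=True)


# ---------------------------------------------------------------------------
# model

_CANONICAL = ("bathymetry", "ice", "prey", "risk")


def _design(df: pd.DataFrame, terms) -> tuple[np.ndarray, list]:
    cols = ["intercept", "bathymetry"] + list(terms)
    X = np.empty((len(df), len(cols)))
    X[:, 0] = 1.0
    X[:, 1] = df["bathymetry"].to_numpy(float)
    for j, t in enumerate(terms, start=2):
        if ":" in t:
            a, b = t.split(":")
            X[:, j] = df[a].to_numpy(float) * df[b].to_numpy(float)
        else:
            X[:, j] = df[t].to_numpy(float)
    return X, cols


class SealRSF:
    """Used/available logistic RSF (GLM, binomial, logit link).

    Parameters
    ----------
    data : DataFrame with ``response`` (0/1), ``animal_id`` and the
        canonical covariates.
    terms : iterable of extra terms beyond the always-present bathymetry,
        e.g. ``("ice", "prey", "risk", "prey:risk")``.
    standardize : bool
        Z-score continuous covariates by the table's own mean/SD; the
        transform is stored with the fit for prediction.
    """

    def __init__(self, data: pd.DataFrame, terms=("ice", "prey", "risk", "prey:risk"),
                 standardize_covariates: bool = False):
        if set(np.unique(data["response"])) != {0, 1}:
            raise ValueError("both used (1) and available (0) rows are required")
        self.terms = tuple(terms)
        self.standardize = standardize_covariates
        base_cols = [c for c in _CANONICAL if c in data.columns]
        if standardize_covariates:
            self.data, self.transform = standardize(data, base_cols)
        else:
            self.data, self.transform = data, {}

    def fit(self) -> "RsfResults":
        X, cols = _design(self.data, self.terms)
        y = self.data["response"].to_numpy(float)
        glm = sm.GLM(y, X, family=sm.families.Binomial())
        res = glm.fit()
        return RsfResults(self, res, cols)


class RsfResults:
    """Fitted RSF: coefficients, Wald CIs, AICc, prediction."""

    def __init__(self, model: SealRSF, res, cols, name: str | None = None):
        self.model = model
        self._res = res
        self.names = cols
        self.params = pd.Series(res.params, index=cols)
        self.bse = pd.Series(res.bse, index=cols)
        self.loglik = float(res.llf)
        self.k = len(cols)
        self.n = int(res.nobs)
        self.aicc = aicc(self.loglik, self.k, self.n)
        if name is not None:
            self.name = name
        else:
            self.name = "+".join(model.terms) if model.terms else "null"

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        ci = self._res.conf_int(alpha)
        return pd.DataFrame(np.asarray(ci), index=self.names, columns=["lower", "upper"])

    def linear_predictor(self, df: pd.DataFrame) -> np.ndarray:
        d = apply_standardization(df, self.model.transform) if self.model.transform else df
        X, _ = _design(d, self.model.terms)
        return X @ self.params.to_numpy()

    def selection_score(self, df: pd.DataFrame) -> np.ndarray:
        """exp(linear predictor): relative selection intensity."""
        return np.exp(self.linear_predictor(df))

    def summary(self) -> str:
        lines = [f"Resource selection function ({self.name})",
                 f"  n={self.n}  k={self.k}  logLik={self.loglik:.2f}  AICc={self.aicc:.2f}",
                 f"  {'term':<12}{'coef':>10}{'se':>10}{'2.5%':>10}{'97.5%':>10}"]
        ci = self.conf_int()
        for t in self.names:
            lines.append(f"  {t:<12}{self.params[t]:>10.4f}{self.bse[t]:>10.4f}"
                         f"{ci.loc[t, 'lower']:>10.4f}{ci.loc[t, 'upper']:>10.4f}")
        return "\n".join(lines)


def fit_candidate_set(data: pd.DataFrame, standardize_covariates: bool = False):
    """Fit the 10 candidate models and rank them (parsimony rule).

    Returns ``(ranking_table, fits_by_name)``.
    """
    fits = {}
    for cand in candidate_set():
        res = SealRSF(data, cand.terms, standardize_covariates).fit()
        res.name = cand.name
        fits[cand.name] = res
    table = rank_models(list(fits.values()))
    return table, fits


def coefficient_stabilization(used: pd.DataFrame, domain: AvailabilityDomain,
                              matcher, ratios=(1, 5, 10, 15, 20, 25, 30, 35, 40),
                              terms=("ice", "prey", "risk", "prey:risk"),
                              seed=None) -> pd.DataFrame:
    """Refit the full model at each used:available ratio.

    ``matcher(points_df) -> df`` attaches covariates to sampled available
    points.  Returns one coefficient row per ratio for visual assessment of
    stabilisation.
    """
    if list(ratios) != sorted(set(ratios)):
        raise ValueError("ratios must be strictly increasing")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for r in ratios:
        pts = sample_available(domain, len(used), int(r), rng)
        avail = matcher(pd.DataFrame({
            "x": pts[:, 0], "y": pts[:, 1],
            "datetime": uniform_day_datetimes(used["datetime"], len(pts), rng),
            "animal_id": "avail"}))
        fit = SealRSF(build_rsf_table(used, avail), terms).fit()
        row = fit.params.to_dict()
        row["ratio"] = int(r)
        rows.append(row)
    return pd.DataFrame(rows).set_index("ratio")


def predict_map(fit: RsfResults, stack: CovariateStack, day: int,
                year: int | None = None, contour_q: float = 0.75,
                prey_var: str = "prey_diversity"):
    """Selection raster over water for one day, min-max normalised, plus the
    core-area mask of cells above the ``contour_q`` quantile."""
    from .covariates import prey_on_geometry
    geo = stack.geometry
    year = year if year is not None else sorted(stack.prey_diversity)[0]
    df = pd.DataFrame({
        "bathymetry": stack.bathymetry.values.ravel(),
        "ice": stack.ice[day].values.ravel(),
        "risk": stack.risk[day].values.ravel(),
        "prey": prey_on_geometry(stack, year).ravel(),
    })
    w = fit.selection_score(df).reshape(geo.values.shape)
    water = ~stack.land
    lo, hi = w[water].min(), w[water].max()
    vals = np.where(water, (w - lo) / (hi - lo) if hi > lo else 0.5, np.nan)
    thresh = np.nanquantile(vals[water], contour_q)
    core = np.where(water, vals > thresh, False)
    return geo.like(vals, stamp=day, name="seal_selection"), core


def loio_cross_validate(data: pd.DataFrame, terms=("ice", "prey", "risk", "prey:risk"),
                        n_bins: int = 10, score_scale: str = "link") -> pd.DataFrame:
    """Leave-one-individual-out Boyce-style validation.

    For each seal: refit on the others, score that seal's used points and
    the availability sample with the predicted RSF value, cut scores into
    ``n_bins`` even-increment bins of the realised score range, compute the
    area-adjusted frequency (used share / available share) per bin, and the
    Spearman correlation of bin rank vs frequency.  Scores default to the
    link (log) scale, where even-increment bins partition the prediction
    range evenly; ``score_scale="exp"`` bins the exponentiated intensity
    instead.  Empty bins are dropped from the correlation.
    """
    rows = []
    seals = [s for s in data.loc[data["response"] == 1, "animal_id"].unique()]
    for seal in seals:
        train = data[(data["animal_id"] != seal) | (data["response"] == 0)]
        test_used = data[(data["animal_id"] == seal) & (data["response"] == 1)]
        if test_used.empty:
            continue
        fit = SealRSF(train, terms).fit()
        avail = data[data["response"] == 0]
        if score_scale == "exp":
            su = fit.selection_score(test_used)
            sa = fit.selection_score(avail)
        else:
            su = fit.linear_predictor(test_used)
            sa = fit.linear_predictor(avail)
        rho = boyce_spearman(su, sa, n_bins)
        rows.append({"animal_id": seal, "rho": rho, "n_used": len(test_used)})
    return pd.DataFrame(rows)


def boyce_spearman(scores_used: np.ndarray, scores_available: np.ndarray,
                   n_bins: int = 10) -> float:
    """Spearman rho of bin rank vs area-adjusted frequency over even-increment
    score bins."""
    allscores = np.concatenate([scores_used, scores_available])
    lo, hi = allscores.min(), allscores.max()
    if hi <= lo:
        return 0.0
    edges = np.linspace(lo, hi, n_bins + 1)
    edges[-1] += 1e-12
    bu = np.clip(np.digitize(scores_used, edges) - 1, 0, n_bins - 1)
    ba = np.clip(np.digitize(scores_available, edges) - 1, 0, n_bins - 1)
    used_share = np.bincount(bu, minlength=n_bins) / max(len(scores_used), 1)
    avail_share = np.bincount(ba, minlength=n_bins) / max(len(scores_available), 1)
    ok = avail_share > 0
    freq = used_share[ok] / avail_share[ok]
    ranks = np.arange(n_bins)[ok]
    if len(freq) < 3:
        return np.nan
    return float(spearmanr(ranks, freq).statistic)


def propagate_location_error(track_draws, matcher, land=None, clip_to=None,
                             terms=("ice", "prey", "risk", "prey:risk"),
                             ratio: int = 25, buffer_km: float = 30.0,
                             seed: int = 0) -> pd.DataFrame:
    """Full thin/match/sample/fit pipeline per posterior track draw.

    ``track_draws`` is a list of point tables (``animal_id``, ``datetime``,
    ``x``, ``y``), one per draw.  Thinning and availability sampling reuse
    the same seed across draws, so the spread of the resulting coefficient
    distribution reflects location uncertainty alone.  Returns per-term
    mean and 2.5/97.5 percentiles.
    """
    coef_rows = []
    for pts in track_draws:
        used = thin_one_per_day(pts, np.random.default_rng(seed))
        used = matcher(used)
        dom = build_availability_domain(used[["x", "y"]].to_numpy(), buffer_km,
                                        land=land, clip_to=clip_to)
        av = sample_available(dom, len(used), ratio, np.random.default_rng(seed + 1))
        avail = matcher(pd.DataFrame({
            "x": av[:, 0], "y": av[:, 1],
            "datetime": uniform_day_datetimes(
                used["datetime"], len(av), np.random.default_rng(seed + 2)),
            "animal_id": "avail"}))
        fit = SealRSF(build_rsf_table(used, avail), terms).fit()
        coef_rows.append(fit.params)
    coefs = pd.DataFrame(coef_rows)
    return pd.DataFrame({
        "mean": coefs.mean(),
        "lower": coefs.quantile(0.025),
        "upper": coefs.quantile(0.975),
    })
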