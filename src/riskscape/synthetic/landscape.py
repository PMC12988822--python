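"""Landscape generation: coast, bathymetry, ice, prey and true risk fields."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..raster import CovariateStack, RasterField, simpson_diversity_fields
from .config import WorldConfig, TruthParams

__all__ = ["make_landscape", "true_risk_rasters", "smooth_field", "expected_smoothing_corr"]

PREY_SPECIES = ("arctic_cod", "capelin", "sand_lance")


def smooth_field(rng: np.random.Generator, shape, range_cells: float,
                 sd: float = 1.0) -> np.ndarray:
    """Stationary Gaussian random field with Gaussian correlation.

    White noise smoothed with a Gaussian kernel of scale ``sigma =
    range_cells / 2`` then rescaled to marginal SD ``sd``.  Correlation at
    lag h cells is exp(-h^2 / (4 sigma^2)) (kernel self-convolution).
    """
    sigma = range_cells / 2.0
    w = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(w, sigma, mode="wrap")
    s = f.std()
    return f * (sd / s) if s > 0 else f


def expected_smoothing_corr(lag_cells: float, range_cells: float) -> float:
    sigma = range_cells / 2.0
    return float(np.exp(-lag_cells ** 2 / (4.0 * sigma ** 2)))


def make_landscape(config: WorldConfig) -> CovariateStack:
    """Build the full covariate stack for one synthetic world.

    Bathymetry is a smooth positive-depth gradient away from a sinuous
    western coastline; ice follows a seasonal freeze-up trajectory with
    spatially correlated day-to-day noise, clipped to [0, 100]; prey biomass
    is log-Gaussian per species on a coarse annual grid.
    """
    config.validate()
    x0, x1, y0, y1 = config.extent
    cs = config.cell_size
    nc = int(round((x1 - x0) / cs))
    nr = int(round((y1 - y0) / cs))
    xs = x0 + cs / 2 + np.arange(nc) * cs
    ys = y0 + cs / 2 + np.arange(nr) * cs
    X, Y = np.meshgrid(xs, ys)
    rng = config.rng("landscape")

    # sinuous western coastline; land strip on the left
    coast_x = x0 + 0.1 * (x1 - x0) + 25.0 * np.sin(2 * np.pi * (ys - y0) / (y1 - y0))
    land = X < coast_x[:, None]

    d2c = ndimage.distance_transform_edt(~land) * cs
    bath_noise = smooth_field(rng, (nr, nc), 5.0, sd=12.0)
    depth = np.where(land, 0.0, np.clip(0.6 * d2c + bath_noise, 5.0, None))

    def fld(v, stamp="static", name=""):
        return RasterField(v, float(xs[0]), float(ys[0]), cs, stamp=stamp, name=name)

    stack = CovariateStack(
        bathymetry=fld(depth, name="bathymetry"),
        dist_coast=fld(d2c, name="dist_coast"),
        land=land,
        time_origin=config.time_origin,
    )

    # seasonal freeze-up: concentration climbs from ~30% to ~95% over the season
    season = 30.0 + 65.0 * np.clip(np.arange(config.n_days) / max(config.n_days - 1, 1), 0, 1)
    ice_range_cells = config.ice_noise_range / cs
    base = smooth_field(rng, (nr, nc), ice_range_cells, sd=12.0)
    for d in range(config.n_days):
        daily = smooth_field(rng, (nr, nc), ice_range_cells, sd=6.0)
        vals = np.clip(season[d] + base + daily, 0.0, 100.0)
        stack.ice[d] = fld(vals, stamp=d, name="ice")

    # coarse annual prey surfaces (log-Gaussian, >= 0)
    pcs = config.prey_cell_size
    pnc = max(int(round((x1 - x0) / pcs)), 4)
    pnr = max(int(round((y1 - y0) / pcs)), 4)
    pxs = x0 + pcs / 2
    pys = y0 + pcs / 2
    prey_range_cells = config.prey_range / pcs
    for sp_i, sp in enumerate(PREY_SPECIES):
        series = {}
        mu = {"arctic_cod": 1.2, "capelin": 0.5, "sand_lance": 0.0}[sp]
        g = smooth_field(rng, (pnr, pnc), prey_range_cells, sd=1.4)
        series[config.year] = RasterField(np.exp(mu + g), pxs, pys, pcs,
                                          stamp=config.year, name=sp)
        stack.prey_biomass[sp] = series
    stack.prey_diversity[config.year] = simpson_diversity_fields(
        {sp: stack.prey_biomass[sp][config.year] for sp in PREY_SPECIES},
        stamp=config.year)
    return stack


def true_risk_rasters(stack: CovariateStack, truth: TruthParams) -> None:
    """Fill ``stack.risk`` with the generative predator-selection surface.

    Daily linear predictor over (ice, bathymetry, distance-to-coast) through
    exp(), min-max normalised to [0, 1] over water nodes; land nodes get 0.
    This is the known "truth" counterpart of the fitted predator layer.
    """
    b_ice, b_bath, b_d2c = truth.bear_beta
    water = ~stack.land
    for d, ice in stack.ice.items():
        lin = b_ice * ice.values + b_bath * stack.bathymetry.values \
            + b_d2c * stack.dist_coast.values
        w = np.exp(lin - lin[water].max())
        lo, hi = w[water].min(), w[water].max()
        vals = np.where(water, (w - lo) / (hi - lo) if hi > lo else 0.5, 0.0)
        stack.risk[d] = ice.like(vals, stamp=d, name="risk")
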