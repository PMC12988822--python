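"""Lightweight planar raster fields and the covariate stack.

All geometry is planar, in projected kilometres.  A :class:`RasterField` is a
regular rectangular grid of cell-centre node values; interpolation between
nodes is bilinear.  A :class:`CovariateStack` bundles the static, daily and
annual fields that every downstream model draws its covariates from:
bathymetry (static), sea-ice concentration and predator selection (daily),
and per-species prey biomass plus prey diversity (annual).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "RasterField",
    "CovariateStack",
    "bilinear",
    "simpson_diversity",
]


@dataclass
class RasterField:
    """A regular grid of values at cell-centre nodes.

    ``values[i, j]`` sits at ``(x0 + j*cell_size, y0 + i*cell_size)``;
    row 0 is the smallest y.  ``stamp`` records validity: the string
    ``"static"``, a day index, or a year.
    """

    values: np.ndarray
    x0: float
    y0: float
    cell_size: float
    stamp: object = "static"
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def x_max(self) -> float:
        return self.x0 + (self.n_cols - 1) * self.cell_size

    @property
    def y_max(self) -> float:
        return self.y0 + (self.n_rows - 1) * self.cell_size

    def node_x(self) -> np.ndarray:
        return self.x0 + np.arange(self.n_cols) * self.cell_size

    def node_y(self) -> np.ndarray:
        return self.y0 + np.arange(self.n_rows) * self.cell_size

    def like(self, values: np.ndarray, stamp=None, name: str = "") -> "RasterField":
        return RasterField(values, self.x0, self.y0, self.cell_size,
                           stamp=self.stamp if stamp is None else stamp,
                           name=name or self.name)


def bilinear(fld: RasterField, x, y):
    """Bilinear interpolation of ``fld`` at planar points.

    Standard 4-neighbour interpolation on the cell-centre nodes; exact for
    affine surfaces.  Queries outside the node bounding box raise
    ``ValueError`` — no extrapolation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    scalar = x.ndim == 0 and y.ndim == 0
    x, y = np.atleast_1d(x), np.atleast_1d(y)
    eps = 1e-9 * fld.cell_size
    if (np.any(x < fld.x0 - eps) or np.any(x > fld.x_max + eps)
            or np.any(y < fld.y0 - eps) or np.any(y > fld.y_max + eps)):
        raise ValueError("bilinear query outside raster bounds")
    fx = np.clip((x - fld.x0) / fld.cell_size, 0.0, fld.n_cols - 1 - 1e-12)
    fy = np.clip((y - fld.y0) / fld.cell_size, 0.0, fld.n_rows - 1 - 1e-12)
    j0 = fx.astype(int)
    i0 = fy.astype(int)
    tx = fx - j0
    ty = fy - i0
    v = fld.values
    out = (v[i0, j0] * (1 - tx) * (1 - ty)
           + v[i0, j0 + 1] * tx * (1 - ty)
           + v[i0 + 1, j0] * (1 - tx) * ty
           + v[i0 + 1, j0 + 1] * tx * ty)
    return float(out[0]) if scalar else out


def simpson_diversity(biomass) -> float:
    """Gini–Simpson diversity, ``D = 1 - sum(p_i^2)``, in [0, 1).

    ``biomass`` is a non-negative per-species vector; proportions are taken
    over its sum.  Larger values mean a more even community.  An all-zero
    (or negative) vector is rejected.
    """
    b = np.asarray(biomass, dtype=float)
    if np.any(b < 0):
        raise ValueError("biomass must be non-negative")
    tot = b.sum()
    if tot <= 0:
        raise ValueError("at least one species must have positive biomass")
    p = b / tot
    return float(1.0 - np.sum(p * p))


def simpson_diversity_fields(species_fields: Mapping[str, RasterField],
                             stamp=None, name: str = "prey_diversity") -> RasterField:
    """Cellwise Gini–Simpson diversity across co-registered species fields."""
    flds = list(species_fields.values())
    stack = np.stack([np.clip(f.values, 0.0, None) for f in flds])
    tot = stack.sum(axis=0)
    tot = np.where(tot > 0, tot, np.nan)
    p = stack / tot
    div = 1.0 - np.nansum(p * p, axis=0)
    div = np.where(np.isfinite(tot), div, 0.0)
    return flds[0].like(div, stamp=stamp, name=name)


@dataclass
class CovariateStack:
    """Static, daily and annual covariate fields over one analysis domain.

    ``ice`` and ``risk`` are day-indexed, ``prey_biomass`` maps species name
    to a year-indexed series, ``prey_diversity`` is year-indexed.  ``land``
    is a boolean node mask (True = land).  ``time_origin`` anchors day 0.
    """

    bathymetry: RasterField
    dist_coast: RasterField
    land: np.ndarray
    ice: dict = field(default_factory=dict)
    risk: dict = field(default_factory=dict)
    prey_biomass: dict = field(default_factory=dict)
    prey_diversity: dict = field(default_factory=dict)
    time_origin: np.datetime64 = np.datetime64("2011-01-01")

    @property
    def geometry(self) -> RasterField:
        return self.bathymetry

    def day_of(self, when) -> int:
        t = np.datetime64(when)
        return int((t - self.time_origin) // np.timedelta64(1, "D"))

    def year_of(self, when) -> int:
        return int(np.datetime64(when, "Y").astype(int)) + 1970

    def water_nodes(self):
        """(x, y) coordinates of all water nodes."""
        geo = self.geometry
        iy, ix = np.where(~self.land)
        return geo.x0 + ix * geo.cell_size, geo.y0 + iy * geo.cell_size
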