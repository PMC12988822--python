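"""Configuration and ground-truth parameters for the synthetic world.

The generator emulates an ice-season Arctic study system: a coastal shelf
with smooth bathymetry, seasonal sea-ice fields, coarse annual prey-biomass
surfaces, predator (polar bear) habitat use driven by a known selection
function, mesopredator (ringed seal) tracks and dives driven by known
selection, persistence and dive-metric parameters.  Every downstream model
can therefore be tested by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = ["TruthParams", "WorldConfig", "DEFAULT_CLASS_SDS", "DEFAULT_CLASS_FREQS"]

# Conventional Argos location-class error SDs (km); configurable, not
# estimated from any particular dataset.
DEFAULT_CLASS_SDS = {"3": 0.25, "2": 0.5, "1": 1.5, "0": 4.0, "A": 6.0, "B": 10.0}
DEFAULT_CLASS_FREQS = {"3": 0.10, "2": 0.15, "1": 0.20, "0": 0.15, "A": 0.20, "B": 0.20}


@dataclass
class TruthParams:
    """Generative parameters mirrored by every estimated quantity.

    Covariates enter on their natural scales: ice concentration in %,
    bathymetry in m (positive depth), distance-to-coast in km, predator
    selection ("risk") in [0, 1], prey diversity in [0, 1).
    """

    # predator selection: (ice, bathymetry, dist_coast); magnitudes chosen so
    # the normalised daily selection surface spans [0, 1] with broad spatial
    # variation rather than collapsing onto a few hotspot cells
    bear_beta: tuple = (0.015, -0.003, -0.004)
    # seal selection: (bathymetry, ice, prey, risk, risk x prey); the
    # interaction is sized so risk tolerance reverses sign across the
    # realised prey-diversity range ("hazardous duty pay" regime)
    seal_beta: tuple = (-0.008, 0.025, 2.0, -4.0, 8.0)
    # move persistence, logit scale: (intercept, bathymetry, risk, prey)
    mpm_beta: tuple = (0.2, 0.002, 2.0, -0.8)
    mpm_sigma_b: float = 0.3
    mpm_step_sd: float = 0.8           # km, per-2h displacement innovation SD
    # dive metrics: coefficient maps, each (intercept, depth, ice, prey, risk, risk x prey)
    dive_beta: dict = field(default_factory=lambda: {
        "duration": (180.0, 0.5, 0.3, -40.0, -60.0, 120.0),
        "ascent_speed": (1.2, 0.004, 0.0, 0.0, 0.0, 0.0),
    })
    dive_phi: float = 0.4
    dive_sigma_b: dict = field(default_factory=lambda: {"duration": 20.0, "ascent_speed": 0.12})
    dive_sigma_e: dict = field(default_factory=lambda: {"duration": 30.0, "ascent_speed": 0.18})
    # continuous-time correlated random walk (velocity OU process)
    ctcrw_beta_mov: float = 0.5        # 1/h reversion rate
    ctcrw_sigma_mov: float = 1.0       # km/sqrt(h) velocity noise scale

    def validate(self) -> None:
        if not -1 < self.dive_phi < 1:
            raise ValueError("dive_phi must lie in (-1, 1)")
        if self.ctcrw_beta_mov <= 0 or self.ctcrw_sigma_mov <= 0:
            raise ValueError("CTCRW parameters must be positive")
        if self.mpm_sigma_b < 0 or any(v < 0 for v in self.dive_sigma_b.values()) \
                or any(v <= 0 for v in self.dive_sigma_e.values()):
            raise ValueError("variance components must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class WorldConfig:
    """Shape and observation-process settings of one synthetic world."""

    extent: tuple = (0.0, 600.0, 0.0, 600.0)   # x_min, x_max, y_min, y_max (km)
    cell_size: float = 10.0                    # km
    prey_cell_size: float = 50.0               # km, coarse annual prey grid
    n_days: int = 90
    n_seals: int = 26
    n_bears: int = 39
    year: int = 2011
    seed: int = 0
    argos_class_sds: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_SDS))
    argos_class_freqs: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_FREQS))
    mean_obs_gap: float = 1.3                  # hours
    long_gap_rate: float = 0.02                # probability of an inserted >12 h gap
    ice_noise_range: float = 80.0              # km, spatial correlation range scale
    prey_range: float = 100.0                  # km
    truth: TruthParams = field(default_factory=TruthParams)

    def validate(self) -> None:
        x0, x1, y0, y1 = self.extent
        if x1 <= x0 or y1 <= y0:
            raise ValueError("degenerate world extent")
        if self.cell_size <= 0 or self.n_days < 1:
            raise ValueError("cell_size must be > 0 and n_days >= 1")
        if any(sd < 0 for sd in self.argos_class_sds.values()):
            raise ValueError("Argos class SDs must be non-negative")
        if self.mean_obs_gap <= 0 or not 0 <= self.long_gap_rate < 1:
            raise ValueError("invalid observation-gap settings")
        self.truth.validate()

    @property
    def time_origin(self) -> np.datetime64:
        return np.datetime64(f"{self.year}-01-01")

    def rng(self, *stream) -> np.random.Generator:
        """Independent substream keyed by (seed, *stream)."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, *map(_key, stream)]))


def _key(s) -> int:
    if isinstance(s, (int, np.integer)):
        return int(s) & 0x7FFFFFFF
    return sum(ord(c) * 31 ** i for i, c in enumerate(str(s))) & 0x7FFFFFFF
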