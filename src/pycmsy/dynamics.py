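"""Schaefer surplus production dynamics with a low-biomass correction.

The production function is the classic Schaefer parabola r·B·(1 − B/k),
linearly damped below one quarter of carrying capacity to avoid the
well-known overestimation of productivity at very low stock sizes:

    P(B) = r·B·(1 − B/k)                  for B ≥ k/4
    P(B) = (4·B/k) · r·B·(1 − B/k)        for B < k/4

The two branches agree at B = k/4. Annual projection is discrete:
catch in year t is removed within the t → t+1 transition, biomass is
start-of-year, and lognormal process error multiplies the post-production
state. Reference points follow the Schaefer identities MSY = r·k/4,
Bmsy = k/2, Fmsy = r/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import CatchSeries

__all__ = [
    "StockParams",
    "BiomassTrajectory",
    "ReferencePoints",
    "BIOMASS_FLOOR_FRACTION",
    "surplus_production",
    "project_step",
    "project_trajectory",
    "reference_points",
    "exploitation_rate",
]

#: Biomass floor as a fraction of k. When catch exceeds available biomass the
#: state is clamped here (and flagged) so log-scale likelihoods stay finite;
#: implausible parameter draws are then penalized by the data, not by a crash.
BIOMASS_FLOOR_FRACTION = 1e-3


@dataclass(frozen=True)
class StockParams:
    """Schaefer stock parameters.

    r : intrinsic growth rate (1/yr); k : carrying capacity (kt);
    q : catchability scalars (index units per kt), one per abundance index.
    """

    r: float
    k: float
    q: tuple[float, ...] = ()

    def __post_init__(self):
        if not (self.r > 0 and np.isfinite(self.r)):
            raise ValueError(f"r must be positive, got {self.r}")
        if not (self.k > 0 and np.isfinite(self.k)):
            raise ValueError(f"k must be positive, got {self.k}")
        if any(qi <= 0 for qi in self.q):
            raise ValueError("every catchability q must be positive")
        object.__setattr__(self, "q", tuple(float(qi) for qi in self.q))


@dataclass(frozen=True)
class ReferencePoints:
    """Schaefer reference points: msy (kt/yr), bmsy (kt), fmsy (1/yr)."""

    msy: float
    bmsy: float
    fmsy: float


@dataclass(frozen=True)
class BiomassTrajectory:
    """Annual biomass path with depletion (B/k) and collapse flags."""

    years: np.ndarray
    biomass: np.ndarray
    k: float
    collapsed: np.ndarray = None  # True where the floor clamp was hit

    def __post_init__(self):
        years = np.asarray(self.years, dtype=int)
        biomass = np.asarray(self.biomass, dtype=float)
        if years.size != biomass.size:
            raise ValueError("years and biomass differ in length")
        collapsed = self.collapsed
        if collapsed is None:
            collapsed = np.zeros(years.size, dtype=bool)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "biomass", biomass)
        object.__setattr__(self, "collapsed", np.asarray(collapsed, dtype=bool))

    @property
    def depletion(self) -> np.ndarray:
        return self.biomass / self.k

    def __len__(self) -> int:
        return self.years.size

    def at_year(self, year: int) -> float:
        pos = int(year) - int(self.years[0])
        if pos < 0 or pos >= self.years.size:
            raise ValueError(f"year {year} outside trajectory span")
        return float(self.biomass[pos])


def surplus_production(b, params: StockParams):
    """Annual surplus production (kt/yr) at biomass ``b`` (kt).

    Accepts scalars or arrays; the hockey-stick damping applies below k/4.
    """
    b_arr = np.asarray(b, dtype=float)
    if np.any(b_arr < 0):
        raise ValueError("biomass must be non-negative")
    core = params.r * b_arr * (1.0 - b_arr / params.k)
    damp = np.where(b_arr < params.k / 4.0, 4.0 * b_arr / params.k, 1.0)
    out = damp * core
    return float(out) if np.isscalar(b) or b_arr.ndim == 0 else out


def project_step(b_t, catch_t, params: StockParams, logdev: float = 0.0):
    """One annual transition: B_{t+1} = max(B_t + P(B_t) − C_t, floor)·e^logdev.

    The floor is ``BIOMASS_FLOOR_FRACTION``·k. ``logdev = 0`` gives the
    deterministic expectation. Returns (biomass, collapsed flag) when given
    scalars; vectorized inputs return arrays.
    """
    if np.any(np.asarray(b_t) < 0) or np.any(np.asarray(catch_t) < 0):
        raise ValueError("biomass and catch must be non-negative")
    floor = BIOMASS_FLOOR_FRACTION * params.k
    raw = np.asarray(b_t, dtype=float) + surplus_production(b_t, params) - np.asarray(catch_t, dtype=float)
    clamped = np.maximum(raw, floor)
    out = clamped * np.exp(logdev)
    if np.isscalar(b_t):
        return float(out)
    return out


def project_trajectory(
    b_start: float,
    catches: CatchSeries,
    params: StockParams,
    logdevs: np.ndarray | None = None,
) -> BiomassTrajectory:
    """Iterate :func:`project_step` across the catch series.

    ``logdevs`` holds one process deviation per transition (``len(catches)-1``);
    ``None`` means deterministic. Biomass is start-of-year: element t+1 is the
    state after removing catch in year t.
    """
    if b_start <= 0:
        raise ValueError("b_start must be positive")
    n = len(catches)
    if logdevs is None:
        logdevs = np.zeros(n - 1)
    logdevs = np.asarray(logdevs, dtype=float)
    if logdevs.size != n - 1:
        raise ValueError(f"need {n - 1} process deviations, got {logdevs.size}")

    floor = BIOMASS_FLOOR_FRACTION * params.k
    biomass = np.empty(n)
    collapsed = np.zeros(n, dtype=bool)
    biomass[0] = b_start
    for t in range(n - 1):
        raw = biomass[t] + surplus_production(biomass[t], params) - catches.catch[t]
        if raw < floor:
            raw = floor
            collapsed[t + 1] = True
        biomass[t + 1] = raw * np.exp(logdevs[t])
    return BiomassTrajectory(catches.years, biomass, params.k, collapsed)


def reference_points(params: StockParams) -> ReferencePoints:
    """MSY = r·k/4, Bmsy = k/2, Fmsy = r/2."""
    return ReferencePoints(
        msy=params.r * params.k / 4.0,
        bmsy=params.k / 2.0,
        fmsy=params.r / 2.0,
    )


def exploitation_rate(catch_t, b_t):
    """Annual exploitation F = catch/biomass (1/yr); NaN where biomass is 0."""
    c = np.asarray(catch_t, dtype=float)
    b = np.asarray(b_t, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(b > 0, c / np.where(b > 0, b, 1.0), np.nan)
    if np.isscalar(catch_t) and np.isscalar(b_t):
        return float(f)
    return f
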