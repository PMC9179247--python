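"""Synthetic catch and CPUE data with the structure the assessment assumes.

An operating model iterates the damped Schaefer dynamics under a harvest
schedule (an explicit F-by-year vector or a linear F ramp), with
lognormal process error on the states. Observations are then generated
as reported catch = true catch · lognormal error (CV 0.2 by default) and
per-fleet indices = q · B · lognormal error (CV 0.15) on each fleet's
covered years only — so fragmented, short and full-span index series all
arise naturally.

``study_fixture`` builds a canned study system: a 1971–2020 rising
harvest history over a low-resilience stock sized so the catch-only
posterior MSY lands in the few-tens-of-kt range, with six fleet indices
of differing catchability and coverage (one spanning the whole horizon),
plus a 1992-truncated variant of the same underlying truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dynamics import (BIOMASS_FLOOR_FRACTION, BiomassTrajectory, StockParams,
                       reference_points, surplus_production)
from .series import CatchSeries, IndexSeries

__all__ = ["FleetDesign", "SimulationDesign", "simulate_truth",
           "simulate_observations", "study_fixture", "recovery_design"]


@dataclass(frozen=True)
class FleetDesign:
    """One CPUE fleet: catchability, coverage span and missing years."""

    label: str
    q: float
    start_year: int
    end_year: int
    missing_years: tuple[int, ...] = ()


@dataclass(frozen=True)
class SimulationDesign:
    """Complete specification of one simulated stock and its observation."""

    params: StockParams
    initial_depletion: float
    start_year: int
    end_year: int
    f_ramp: tuple[float, float] | None = None   # linear F from f0 to f1
    f_by_year: tuple[float, ...] | None = None  # explicit schedule (overrides ramp)
    process_sigma: float = 0.05
    catch_cv: float = 0.2
    cpue_cv: float = 0.15
    fleets: tuple[FleetDesign, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.f_by_year is None and self.f_ramp is None:
            raise ValueError("provide f_ramp or f_by_year")
        if not (0 < self.initial_depletion <= 1):
            raise ValueError("initial depletion must lie in (0, 1]")
        for fl in self.fleets:
            if fl.start_year < self.start_year or fl.end_year > self.end_year:
                raise ValueError(f"fleet {fl.label}: coverage outside the year span")

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year + 1

    def f_schedule(self) -> np.ndarray:
        if self.f_by_year is not None:
            f = np.asarray(self.f_by_year, dtype=float)
            if f.size != self.n_years:
                raise ValueError(f"f_by_year needs {self.n_years} values, got {f.size}")
        else:
            f = np.linspace(self.f_ramp[0], self.f_ramp[1], self.n_years)
        if np.any(f < 0):
            raise ValueError("F values must be non-negative")
        return f


def simulate_truth(design: SimulationDesign) -> tuple[BiomassTrajectory, CatchSeries]:
    """True biomass path and true (pre-observation-error) catches.

    Catch in year t is F_t·B_t taken before the t → t+1 update; process
    deviations are drawn N(0, process_sigma). Fully reproducible from
    ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    p = design.params
    f = design.f_schedule()
    n = design.n_years
    years = np.arange(design.start_year, design.end_year + 1)
    devs = design.process_sigma * rng.standard_normal(n - 1)

    floor = BIOMASS_FLOOR_FRACTION * p.k
    b = np.empty(n)
    catch = np.empty(n)
    collapsed = np.zeros(n, dtype=bool)
    b[0] = design.initial_depletion * p.k
    for t in range(n):
        catch[t] = f[t] * b[t]
        if t < n - 1:
            raw = b[t] + surplus_production(b[t], p) - catch[t]
            if raw < floor:
                raw = floor
                collapsed[t + 1] = True
            b[t + 1] = raw * np.exp(devs[t])
    if collapsed.mean() > 0.5:
        warnings.warn("harvest schedule drives the stock to the floor in most years",
                      stacklevel=2)
    traj = BiomassTrajectory(years, b, p.k, collapsed)
    return traj, CatchSeries(years, catch, label="true_catch")


def simulate_observations(
    truth: tuple[BiomassTrajectory, CatchSeries],
    design: SimulationDesign,
) -> tuple[CatchSeries, list[IndexSeries]]:
    """Observed (reported) catches and per-fleet CPUE indices.

    Multiplicative lognormal errors use log-sd sqrt(ln(1+cv²)); a CV of 0
    reproduces the truth exactly. Fleets whose coverage mask hides every
    year yield an empty (but valid) series.
    """
    traj, true_catch = truth
    rng = np.random.default_rng(design.seed + 1)
    sd_c = np.sqrt(np.log1p(design.catch_cv**2))
    sd_i = np.sqrt(np.log1p(design.cpue_cv**2))

    reported = true_catch.catch * np.exp(sd_c * rng.standard_normal(len(true_catch)))
    catches = CatchSeries(true_catch.years, reported, label="reported_catch")

    indices = []
    for fl in design.fleets:
        cover = ((traj.years >= fl.start_year) & (traj.years <= fl.end_year)
                 & ~np.isin(traj.years, fl.missing_years))
        b = traj.biomass[cover]
        vals = fl.q * b * np.exp(sd_i * rng.standard_normal(b.size))
        indices.append(IndexSeries(traj.years[cover], vals, label=fl.label))
    return catches, indices


def recovery_design(seed: int, r: float = 0.21, k: float = 2000.0) -> SimulationDesign:
    """The canonical parameter-recovery experiment.

    A 50-year, single full-coverage-index stock at the study error levels
    (process sd 0.05, catch CV 0.2, CPUE CV 0.15). The harvest schedule
    runs two fish-down/rebuild cycles that keep depletion above the
    depensation zone (B > k/4): surplus production per unit biomass there
    is r·(1 − B/k), so observed rebuild rates at two different depletion
    levels are what identifies r separately from k. One-way-trip
    histories leave r–k confounded along r·k ≈ const and recover poorly
    regardless of sampler — by design this experiment does not test that.
    """
    params = StockParams(r=r, k=k)
    fmsy = reference_points(params).fmsy
    f = np.concatenate([
        np.linspace(0.3 * fmsy, 2.2 * fmsy, 18),   # fish down
        np.full(9, 0.3 * fmsy),                    # rebuild 1
        np.linspace(0.5 * fmsy, 2.4 * fmsy, 12),   # fish down again
        np.full(11, 0.2 * fmsy),                   # rebuild 2
    ])
    return SimulationDesign(
        params=params,
        initial_depletion=0.65,
        start_year=1971,
        end_year=2020,
        f_by_year=tuple(f),
        fleets=(FleetDesign("idx", q=1.0e-3, start_year=1971, end_year=2020),),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Canned study system

_FIXTURE_SEED = 12386

# Truth chosen for a low-resilience pelagic shark stock: r in the "Low"
# resilience band, k sized so MSY = r·k/4 ≈ 37 kt/yr; harvest ramps from
# 0.2·Fmsy to 1.3·Fmsy across 1971-2020, giving the rise-then-pressure
# catch shape (peak near the MSY scale) with end-year depletion near 0.5.
_FIXTURE_PARAMS = StockParams(r=0.072, k=2065.0)
_FIXTURE_FLEETS = (
    FleetDesign("JP", q=1.0e-3, start_year=1971, end_year=2020),     # full span
    FleetDesign("UR", q=2.4e-3, start_year=1993, end_year=2020),
    FleetDesign("BR", q=0.7e-3, start_year=1997, end_year=2020,
                missing_years=(2003, 2004, 2011)),
    FleetDesign("ESP", q=3.1e-3, start_year=1990, end_year=2020),
    FleetDesign("CHTP", q=1.6e-3, start_year=1995, end_year=2020,
                missing_years=(1999,)),
    FleetDesign("JCPUE", q=1.2e-3, start_year=1971, end_year=2020),  # combined
)


def fixture_design() -> SimulationDesign:
    """The design behind :func:`study_fixture` (importable for tests)."""
    fmsy = reference_points(_FIXTURE_PARAMS).fmsy
    return SimulationDesign(
        params=_FIXTURE_PARAMS,
        initial_depletion=0.72,
        start_year=1971,
        end_year=2020,
        f_ramp=(0.2 * fmsy, 1.3 * fmsy),
        fleets=_FIXTURE_FLEETS,
        seed=_FIXTURE_SEED,
    )


def study_fixture(which: str = "reconstructed") -> tuple[CatchSeries, dict[str, IndexSeries]]:
    """Canned catch series plus a six-fleet index library.

    ``which='reconstructed'`` spans 1971–2020; ``which='nominal'`` is the
    same underlying truth truncated to 1992–2020 (identical catches on the
    overlap). The index library is shared.
    """
    design = fixture_design()
    truth = simulate_truth(design)
    catches, index_list = simulate_observations(truth, design)
    library = {idx.label: idx for idx in index_list}
    if which == "reconstructed":
        return catches, library
    if which == "nominal":
        return catches.truncate(start_year=1992), library
    raise ValueError(f"unknown fixture {which!r}; use 'reconstructed' or 'nominal'")
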