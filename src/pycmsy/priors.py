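"""Prior elicitation for the state-space Schaefer assessment.

Categorical resilience classes map to ranges of the intrinsic growth rate
r, and qualitative depletion classes map to ranges of relative biomass
B/k. A [low, high] range is interpreted as the central 95% interval of a
lognormal, which yields the multivariate normal prior on (log r, log k)
used by both the catch-only and catch+CPUE modes. Relative-biomass
windows at the start, an intermediate year, and the end of the series
are hard (uniform, truncated) constraints on depletion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .series import CatchSeries

__all__ = [
    "RangePrior",
    "DepletionWindow",
    "PriorSet",
    "RESILIENCE_R_RANGES",
    "DEPLETION_BK_RANGES",
    "r_range_from_resilience",
    "bk_range_from_depletion",
    "default_k_range",
    "rk_log_prior_density",
]

# Categorical prior table: resilience class -> r range (1/yr)
RESILIENCE_R_RANGES: dict[str, tuple[float, float]] = {
    "high": (0.6, 1.5),
    "medium": (0.2, 0.8),
    "low": (0.05, 0.5),
    "very low": (0.015, 0.1),
}

# Depletion class -> relative biomass (B/k) range
DEPLETION_BK_RANGES: dict[str, tuple[float, float]] = {
    "very strong depletion": (0.01, 0.2),
    "strong depletion": (0.01, 0.4),
    "medium depletion": (0.2, 0.6),
    "low depletion": (0.4, 0.8),
    "nearly unexploited": (0.75, 1.0),
}


@dataclass(frozen=True)
class RangePrior:
    """A positive [low, high] range read as a 95% lognormal interval."""

    low: float
    high: float

    def __post_init__(self):
        if not (0 < self.low < self.high):
            raise ValueError(f"need 0 < low < high, got ({self.low}, {self.high})")

    @property
    def log_mid(self) -> float:
        return 0.5 * (np.log(self.low) + np.log(self.high))

    @property
    def log_sd(self) -> float:
        # [low, high] spans ±1.96 sd in log space
        return (np.log(self.high) - np.log(self.low)) / (2.0 * 1.96)

    @property
    def mid(self) -> float:
        """Geometric midpoint (the prior median)."""
        return float(np.exp(self.log_mid))


@dataclass(frozen=True)
class DepletionWindow:
    """Hard B/k window at an anchor year (None = series start or end)."""

    low: float
    high: float
    year: int | None = None

    def __post_init__(self):
        if not (0 <= self.low < self.high <= 1):
            raise ValueError(f"need 0 <= low < high <= 1, got ({self.low}, {self.high})")

    def contains(self, depletion) -> np.ndarray:
        d = np.asarray(depletion, dtype=float)
        return (d >= self.low) & (d <= self.high)


@dataclass(frozen=True)
class PriorSet:
    """Complete prior specification for one assessment run.

    process_sigma is the lognormal sd of annual process deviations;
    catch_cv and cpue_cv are observation-error coefficients of variation,
    converted to log-scale sds as sqrt(ln(1+cv²)) by the observation model.
    """

    r_range: RangePrior
    k_range: RangePrior
    start_window: DepletionWindow
    intermediate_window: DepletionWindow
    end_window: DepletionWindow
    rk_log_correlation: float = 0.0
    process_sigma: float = 0.05
    catch_cv: float = 0.2
    cpue_cv: float = 0.15

    def __post_init__(self):
        if not (-1.0 < self.rk_log_correlation < 1.0):
            raise ValueError("rk_log_correlation must lie in (-1, 1)")
        if self.intermediate_window.year is None:
            raise ValueError("intermediate window needs an explicit year")
        for cv in (self.process_sigma, self.catch_cv, self.cpue_cv):
            if cv < 0:
                raise ValueError("error magnitudes must be non-negative")

    def validate_years(self, catches: CatchSeries) -> None:
        y = self.intermediate_window.year
        if not (catches.start_year < y < catches.end_year):
            raise ValueError(
                f"intermediate year {y} outside catch span "
                f"({catches.start_year}–{catches.end_year})"
            )


def _lookup(table: dict[str, tuple[float, float]], category: str, what: str):
    key = " ".join(category.strip().lower().replace("-", " ").split())
    # allow the bare class word ("low") as well as "low depletion"
    if key not in table:
        for full in table:
            if full.startswith(key) and what == "depletion":
                key = full
                break
    if key not in table:
        valid = ", ".join(sorted(table))
        raise ValueError(f"unknown {what} category {category!r}; valid: {valid}")
    return table[key]


def r_range_from_resilience(category: str) -> RangePrior:
    """Prior r range for a resilience class (High/Medium/Low/Very low)."""
    return RangePrior(*_lookup(RESILIENCE_R_RANGES, category, "resilience"))


def bk_range_from_depletion(category: str) -> tuple[float, float]:
    """Prior B/k range for a depletion class (e.g. 'Strong depletion')."""
    return _lookup(DEPLETION_BK_RANGES, category, "depletion")


def default_k_range(
    catches: CatchSeries,
    r_range: RangePrior | tuple[float, float],
    end_window: DepletionWindow | None = None,
) -> RangePrior:
    """Carrying-capacity range from maximum catch and the r prior.

    Uses the catch-only heuristic k ∈ [max(C)/r_high, 12·max(C)/r_low]: a
    stock cannot have sustained its peak catch unless k·r covers it, while
    the upper bound keeps the prior proper. ``r_range`` may be a plain
    (low, high) tuple, including a degenerate low == high point value.
    ``end_window`` is accepted for interface symmetry; the heuristic does
    not use it.
    """
    if isinstance(r_range, RangePrior):
        r_lo, r_hi = r_range.low, r_range.high
    else:
        r_lo, r_hi = r_range
        if not (0 < r_lo <= r_hi):
            raise ValueError(f"need 0 < low <= high, got ({r_lo}, {r_hi})")
    cmax = float(np.max(catches.catch))
    if cmax <= 0:
        raise ValueError("all-zero catch series cannot inform a k range")
    return RangePrior(cmax / r_hi, 12.0 * cmax / r_lo)


def rk_log_prior_density(r, k, priors: PriorSet):
    """Bivariate normal log-density of (log r, log k).

    Means sit at the log-midpoints of the ranges, sds make each range a 95%
    interval, and the correlation is ``priors.rk_log_correlation`` (0 unless
    configured). The density is over (log r, log k); no Jacobian to the
    (r, k) scale is included here.
    """
    r = np.asarray(r, dtype=float)
    k = np.asarray(k, dtype=float)
    if np.any(r <= 0) or np.any(k <= 0):
        raise ValueError("r and k must be positive")
    rho = priors.rk_log_correlation
    sr, sk = priors.r_range.log_sd, priors.k_range.log_sd
    zr = (np.log(r) - priors.r_range.log_mid) / sr
    zk = (np.log(k) - priors.k_range.log_mid) / sk
    quad = (zr * zr - 2.0 * rho * zr * zk + zk * zk) / (1.0 - rho * rho)
    logdet = np.log(sr) + np.log(sk) + 0.5 * np.log(1.0 - rho * rho)
    out = -0.5 * quad - logdet - np.log(2.0 * np.pi)
    return float(out) if out.ndim == 0 else out


def sample_rk(priors: PriorSet, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw (log r, log k) pairs from the joint prior; shape (size, 2)."""
    rho = priors.rk_log_correlation
    mean = [priors.r_range.log_mid, priors.k_range.log_mid]
    sr, sk = priors.r_range.log_sd, priors.k_range.log_sd
    cov = [[sr * sr, rho * sr * sk], [rho * sr * sk, sk * sk]]
    return stats.multivariate_normal.rvs(mean, cov, size=size, random_state=rng).reshape(size, 2)
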