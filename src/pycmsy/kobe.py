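"""Stock-status outputs: Kobe quadrants, trajectory bands, process deviations.

The Kobe plane classifies joint stock status from relative biomass
B/Bmsy and relative exploitation F/Fmsy:

* green  — B/Bmsy ≥ 1 and F/Fmsy ≤ 1 (healthy, sustainably fished)
* orange — B/Bmsy ≥ 1 and F/Fmsy > 1 (healthy but undergoing overfishing)
* yellow — B/Bmsy < 1 and F/Fmsy ≤ 1 (overfished, pressure reduced)
* red    — B/Bmsy < 1 and F/Fmsy > 1 (overfished and undergoing overfishing)

Ties at exactly 1 go to the better status; posterior draws put
essentially zero mass there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import PosteriorEnsemble

__all__ = [
    "KobeProbabilities",
    "ProcessDeviationSummary",
    "kobe_classify",
    "kobe_probabilities",
    "status_trajectories",
    "process_deviation_series",
]

QUADRANTS = ("green", "yellow", "orange", "red")


@dataclass(frozen=True)
class KobeProbabilities:
    """Fractions of posterior draws per quadrant at one year (sum to 1)."""

    year: int
    p_green: float
    p_yellow: float
    p_orange: float
    p_red: float

    def as_dict(self) -> dict[str, float]:
        return {q: getattr(self, f"p_{q}") for q in QUADRANTS}


@dataclass(frozen=True)
class ProcessDeviationSummary:
    """Per-transition process-deviation bands plus a flatness statistic.

    ``max_abs_median`` — the largest |median deviation| across years; small
    values mean biomass changes track the Schaefer expectation.
    """

    table: pd.DataFrame
    max_abs_median: float


def kobe_classify(b_ratio, f_ratio):
    """Quadrant label(s) for relative biomass and exploitation.

    Vectorized; scalar inputs return a scalar string.
    """
    b = np.asarray(b_ratio, dtype=float)
    f = np.asarray(f_ratio, dtype=float)
    if np.any(b < 0) or np.any(f < 0):
        raise ValueError("status ratios must be non-negative")
    healthy = b >= 1.0
    fished_ok = f <= 1.0
    out = np.where(
        healthy, np.where(fished_ok, "green", "orange"),
        np.where(fished_ok, "yellow", "red"),
    )
    if np.isscalar(b_ratio) and np.isscalar(f_ratio):
        return str(out)
    return out


def kobe_probabilities(ensemble: PosteriorEnsemble, year: int) -> KobeProbabilities:
    """Quadrant probabilities: per-draw status at ``year``, tallied."""
    pos = ensemble.year_pos(year)
    labels = kobe_classify(ensemble.b_over_bmsy()[:, pos], ensemble.f_over_fmsy()[:, pos])
    n = labels.size
    counts = {q: float(np.sum(labels == q)) / n for q in QUADRANTS}
    return KobeProbabilities(year=int(year), **{f"p_{q}": counts[q] for q in QUADRANTS})


def kobe_table(ensemble: PosteriorEnsemble) -> pd.DataFrame:
    """Quadrant probabilities for every year of the assessment horizon."""
    rows = [kobe_probabilities(ensemble, int(y)) for y in ensemble.years]
    return pd.DataFrame(
        [{"year": p.year, **{f"p_{q}": getattr(p, f"p_{q}") for q in QUADRANTS}} for p in rows]
    )


def status_trajectories(ensemble: PosteriorEnsemble) -> pd.DataFrame:
    """Per-year median and 2.5/97.5 percentile bands of B/Bmsy and F/Fmsy."""
    if ensemble.n_draws == 0:
        raise ValueError("empty ensemble")
    bb = ensemble.b_over_bmsy()
    ff = ensemble.f_over_fmsy()
    qs = [2.5, 50.0, 97.5]
    bq = np.percentile(bb, qs, axis=0)
    fq = np.percentile(ff, qs, axis=0)
    return pd.DataFrame({
        "year": ensemble.years,
        "b_bmsy_lo": bq[0], "b_bmsy": bq[1], "b_bmsy_hi": bq[2],
        "f_fmsy_lo": fq[0], "f_fmsy": fq[1], "f_fmsy_hi": fq[2],
    })


def process_deviation_series(ensemble: PosteriorEnsemble) -> ProcessDeviationSummary:
    """Median and 2.5/97.5 bands of the latent process deviations per year.

    A deterministic (all-zero-deviation) fit yields an all-zero series.
    """
    devs = ensemble.process_logdevs
    qs = np.percentile(devs, [2.5, 50.0, 97.5], axis=0)
    table = pd.DataFrame({
        "year": ensemble.years[1:],
        "dev_lo": qs[0], "dev": qs[1], "dev_hi": qs[2],
    })
    return ProcessDeviationSummary(table=table, max_abs_median=float(np.max(np.abs(qs[1]))))
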