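"""Catch and relative-abundance (CPUE) time series containers.

Units follow the assessment convention: catch and biomass in kt
(thousand tonnes), abundance indices in arbitrary index units assumed
proportional to biomass through a catchability scalar q.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CatchSeries", "IndexSeries"]


@dataclass(frozen=True)
class CatchSeries:
    """Annual catch observations over a contiguous span of years.

    Parameters
    ----------
    years
        Calendar years, strictly consecutive (no gaps, no duplicates).
    catch
        Catch in kt per year, non-negative, same length as ``years``.
    label
        Free-form tag (e.g. the catch-series name used in run labels).
    """

    years: np.ndarray
    catch: np.ndarray
    label: str = "catch"

    def __post_init__(self):
        years = np.asarray(self.years, dtype=int)
        catch = np.asarray(self.catch, dtype=float)
        if years.size == 0:
            raise ValueError("catch series is empty")
        if years.size != catch.size:
            raise ValueError("years and catch differ in length")
        gaps = np.flatnonzero(np.diff(years) != 1)
        if gaps.size:
            y = int(years[gaps[0]])
            raise ValueError(f"catch years must be consecutive; gap/duplicate after {y}")
        if np.any(catch < 0) or not np.all(np.isfinite(catch)):
            raise ValueError("catch values must be finite and non-negative")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "catch", catch)

    def __len__(self) -> int:
        return self.years.size

    @property
    def start_year(self) -> int:
        return int(self.years[0])

    @property
    def end_year(self) -> int:
        return int(self.years[-1])

    def truncate(self, start_year: int | None = None, end_year: int | None = None) -> "CatchSeries":
        """Restrict to [start_year, end_year] without altering retained values."""
        lo = self.start_year if start_year is None else int(start_year)
        hi = self.end_year if end_year is None else int(end_year)
        keep = (self.years >= lo) & (self.years <= hi)
        if not keep.any():
            raise ValueError(f"no catch years inside [{lo}, {hi}]")
        return CatchSeries(self.years[keep], self.catch[keep], self.label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "catch": self.catch})


@dataclass(frozen=True)
class IndexSeries:
    """A relative-abundance (CPUE) series, possibly short or fragmented.

    Years need not be consecutive; missing years simply contribute no
    likelihood term. Index values must be strictly positive because the
    observation model is lognormal.
    """

    years: np.ndarray
    index: np.ndarray
    label: str = "index"

    def __post_init__(self):
        years = np.asarray(self.years, dtype=int)
        index = np.asarray(self.index, dtype=float)
        if years.size != index.size:
            raise ValueError("years and index differ in length")
        if years.size and np.any(np.diff(years) <= 0):
            raise ValueError("index years must be strictly increasing")
        if np.any(index <= 0) or not np.all(np.isfinite(index)):
            raise ValueError("index values must be finite and positive (lognormal likelihood)")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "index", index)

    def __len__(self) -> int:
        return self.years.size

    def overlap(self, years: np.ndarray) -> np.ndarray:
        """Positions of this series' years inside a full year vector."""
        pos = np.searchsorted(years, self.years)
        ok = (pos < years.size) & (np.take(years, pos, mode="clip") == self.years)
        return pos[ok]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "index": self.index})
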