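"""CSV readers/writers and the run manifest.

Dialect: comma-separated, UTF-8, mandatory header row, '.' decimal.
Catch files have columns ``year,catch`` (kt); index files ``year,index``.
A run manifest (JSON, written atomically) records input digests, the
config snapshot, the seed, the package version and per-run diagnostics —
enough to re-execute a run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import os
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .series import CatchSeries, IndexSeries

__all__ = [
    "read_catch_csv", "write_catch_csv",
    "read_index_csv", "write_index_csv",
    "RunManifest", "write_manifest", "read_manifest",
]


def _read_table(path, required: tuple[str, str]) -> pd.DataFrame:
    frame = pd.read_csv(path)
    frame.columns = [c.strip().lower() for c in frame.columns]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
    return frame


def read_catch_csv(path) -> CatchSeries:
    """Load an annual catch file; years must be consecutive.

    Errors name the offending rows (2-based, counting the header as row 1).
    """
    frame = _read_table(path, ("year", "catch"))
    years = frame["year"].to_numpy()
    if not np.issubdtype(years.dtype, np.number):
        raise ValueError(f"{path}: non-numeric year column")
    years = years.astype(int)
    dup = pd.Series(years).duplicated()
    if dup.any():
        rows = ", ".join(str(i + 2) for i in np.flatnonzero(dup))
        raise ValueError(f"{path}: duplicate year at row(s) {rows}")
    gaps = np.flatnonzero(np.diff(years) != 1)
    if gaps.size:
        i = gaps[0]
        raise ValueError(
            f"{path}: year gap {years[i]}→{years[i + 1]} at rows {i + 2}–{i + 3}")
    bad = frame["catch"].to_numpy() < 0
    if bad.any():
        rows = ", ".join(str(i + 2) for i in np.flatnonzero(bad))
        raise ValueError(f"{path}: negative catch at row(s) {rows}")
    return CatchSeries(years, frame["catch"].to_numpy(float), label=Path(path).stem)


def write_catch_csv(catches: CatchSeries, path) -> None:
    catches.to_frame().to_csv(path, index=False)


def read_index_csv(path) -> IndexSeries:
    """Load a CPUE file; gaps are allowed, non-positive values are not."""
    frame = _read_table(path, ("year", "index"))
    if len(frame) == 0:
        warnings.warn(f"{path}: empty index file", stacklevel=2)
        return IndexSeries(np.array([], int), np.array([]), label=Path(path).stem)
    vals = frame["index"].to_numpy(float)
    bad = ~(vals > 0)
    if bad.any():
        rows = ", ".join(str(i + 2) for i in np.flatnonzero(bad))
        raise ValueError(f"{path}: non-positive index at row(s) {rows}")
    return IndexSeries(frame["year"].to_numpy(int), vals, label=Path(path).stem)


def write_index_csv(index: IndexSeries, path) -> None:
    index.to_frame().to_csv(path, index=False)


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record for one run or batch."""

    seed: int
    package_version: str
    input_digests: dict[str, str] = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    diagnostics: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True, default=float)


def write_manifest(manifest: RunManifest, path) -> None:
    """Atomic write: temp file in the same directory, then rename."""
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(manifest.to_json() + "\n")
    os.replace(tmp, path)


def read_manifest(path) -> RunManifest:
    return RunManifest(**json.loads(Path(path).read_text()))
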