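"""Sensitivity-scenario driver: configure, run and summarize assessment runs.

A scenario table (YAML) holds one row per run with the conventional
CMSY column names (``r.low``/``r.hi``, ``stb.low``/``stb.hi``,
``intb.yr``/``intb.low``/``intb.hi``, ``endb.low``/``endb.hi``,
``btype``, ``force.cmsy``, ``process.error``). Each run truncates the
catch series to its year span, fits in CMSY or BSM mode, and emits a
summary row of posterior medians (r, K, MSY, Bmsy, final-year B,
B/Bmsy, F, Fmsy, F/Fmsy). Ratio columns are medians of per-draw ratios,
not ratios of medians.

The packaged 14-run sensitivity design (two catch-only runs, twelve
catch+index runs across six abundance indices and two start years) ships
as ``pycmsy/configs/sensitivity_14.yaml``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .inference import PosteriorEnsemble, SamplerSettings, fit
from .priors import DepletionWindow, PriorSet, RangePrior, default_k_range
from .series import CatchSeries, IndexSeries

__all__ = [
    "ScenarioConfig",
    "SummaryRow",
    "SUMMARY_COLUMNS",
    "load_scenarios",
    "packaged_scenarios",
    "run_scenario",
    "run_all",
    "summarize_ensemble",
    "write_summary_table",
    "read_summary_table",
    "format_summary_table",
]

_REQUIRED_KEYS = (
    "r.low", "r.hi", "stb.low", "stb.hi", "intb.yr", "intb.low", "intb.hi",
    "endb.low", "endb.hi", "btype", "force.cmsy",
)

SUMMARY_COLUMNS = [
    "run", "label", "start_year", "end_year", "mode", "converged",
    "r", "K", "MSY", "Bmsy", "B", "B_Bmsy", "F", "Fmsy", "F_Fmsy",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """One scenario row: prior choices plus data selection."""

    run_id: int
    label: str
    start_year: int
    end_year: int
    r_range: RangePrior
    start_window: DepletionWindow
    intermediate_window: DepletionWindow
    end_window: DepletionWindow
    btype: str = "None"            # "None" (catch-only) or "CPUE"
    force_cmsy: bool = False
    index: str | None = None       # label into the index library
    process_sigma: float = 0.05
    catch_cv: float = 0.2
    cpue_cv: float = 0.15
    k_range: RangePrior | None = None

    def __post_init__(self):
        if not (self.start_year < self.intermediate_window.year < self.end_year):
            raise ValueError(
                f"run {self.run_id}: need start_year < intb.yr < end_year, got "
                f"{self.start_year} < {self.intermediate_window.year} < {self.end_year}")
        if self.btype == "None" and not self.force_cmsy:
            raise ValueError(f"run {self.run_id}: btype None requires force.cmsy true")
        if self.btype == "CPUE" and not self.force_cmsy and self.index is None:
            raise ValueError(f"run {self.run_id}: btype CPUE needs an index selection")

    def prior_set(self, catches: CatchSeries) -> PriorSet:
        k_range = self.k_range or default_k_range(catches, self.r_range, self.end_window)
        return PriorSet(
            r_range=self.r_range,
            k_range=k_range,
            start_window=self.start_window,
            intermediate_window=self.intermediate_window,
            end_window=self.end_window,
            process_sigma=self.process_sigma,
            catch_cv=self.catch_cv,
            cpue_cv=self.cpue_cv,
        )


@dataclass(frozen=True)
class SummaryRow:
    """Posterior-median summary of one run (the assessment-table row)."""

    run: int
    label: str
    start_year: int
    end_year: int
    mode: str
    converged: bool
    r: float
    K: float
    MSY: float
    Bmsy: float
    B: float
    B_Bmsy: float
    F: float
    Fmsy: float
    F_Fmsy: float

    def as_dict(self) -> dict:
        return {c: getattr(self, c) for c in SUMMARY_COLUMNS}


def _parse_row(row: dict, position: int) -> ScenarioConfig:
    missing = [c for c in _REQUIRED_KEYS if c not in row]
    if missing:
        raise ValueError(f"scenario row {position}: missing column(s) {', '.join(missing)}")
    for c in ("start.yr", "end.yr"):
        if c not in row and c.replace(".yr", "_year") not in row:
            raise ValueError(f"scenario row {position}: missing column(s) {c}")
    start = int(row.get("start.yr", row.get("start_year")))
    end = int(row.get("end.yr", row.get("end_year")))
    btype = str(row["btype"])
    force = row["force.cmsy"]
    if isinstance(force, str):
        force = force.strip().upper() in {"T", "TRUE", "1", "Y"}
    k_range = None
    if "k.low" in row and "k.hi" in row:
        k_range = RangePrior(float(row["k.low"]), float(row["k.hi"]))
    return ScenarioConfig(
        run_id=int(row.get("run", position)),
        label=str(row.get("label", f"run{position}")),
        start_year=start,
        end_year=end,
        r_range=RangePrior(float(row["r.low"]), float(row["r.hi"])),
        start_window=DepletionWindow(float(row["stb.low"]), float(row["stb.hi"]), year=None),
        intermediate_window=DepletionWindow(
            float(row["intb.low"]), float(row["intb.hi"]), year=int(row["intb.yr"])),
        end_window=DepletionWindow(float(row["endb.low"]), float(row["endb.hi"]), year=None),
        btype=btype,
        force_cmsy=bool(force),
        index=row.get("index") or None,
        process_sigma=float(row.get("process.error", 0.05)),
        catch_cv=float(row.get("catch.cv", 0.2)),
        cpue_cv=float(row.get("cpue.cv", 0.15)),
        k_range=k_range,
    )


def load_scenarios(source) -> list[ScenarioConfig]:
    """Parse a scenario document (YAML path, text, or parsed mapping/list)."""
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        doc = yaml.safe_load(Path(source).read_text())
    elif isinstance(source, str):
        doc = yaml.safe_load(source)
    else:
        doc = source
    rows = doc["runs"] if isinstance(doc, dict) else doc
    if rows is None:
        return []
    return [_parse_row(row, i + 1) for i, row in enumerate(rows)]


def packaged_scenarios() -> list[ScenarioConfig]:
    """The bundled 14-run sensitivity design."""
    text = importlib.resources.files("pycmsy").joinpath(
        "configs/sensitivity_14.yaml").read_text()
    return load_scenarios(yaml.safe_load(text))


def summarize_ensemble(ensemble: PosteriorEnsemble, config: ScenarioConfig) -> SummaryRow:
    """Posterior medians for the summary table; ratios are per-draw medians."""
    med = lambda x: float(np.median(x))
    b_final = ensemble.biomass[:, -1]
    f_final = ensemble.catch_effective[:, -1] / b_final
    return SummaryRow(
        run=config.run_id,
        label=config.label,
        start_year=int(ensemble.years[0]),
        end_year=int(ensemble.years[-1]),
        mode=ensemble.mode,
        converged=ensemble.converged,
        r=med(ensemble.r),
        K=med(ensemble.k),
        MSY=med(ensemble.r * ensemble.k / 4.0),
        Bmsy=med(ensemble.k / 2.0),
        B=med(b_final),
        B_Bmsy=med(b_final / (ensemble.k / 2.0)),
        F=med(f_final),
        Fmsy=med(ensemble.r / 2.0),
        F_Fmsy=med(f_final / (ensemble.r / 2.0)),
    )


def run_scenario(
    config: ScenarioConfig,
    catches: CatchSeries,
    indices: dict[str, IndexSeries] | None = None,
    settings: SamplerSettings | None = None,
    seed: int | None = None,
) -> tuple[PosteriorEnsemble, SummaryRow]:
    """Execute one scenario: truncate, fit, summarize."""
    if settings is None:
        if seed is None:
            raise ValueError("provide settings or a seed")
        settings = SamplerSettings(seed=seed)
    catches_run = catches.truncate(config.start_year, config.end_year)
    chosen: list[IndexSeries] = []
    if config.btype == "CPUE" and not config.force_cmsy:
        library = indices or {}
        if config.index not in library:
            raise ValueError(
                f"run {config.run_id}: index {config.index!r} not in library "
                f"({', '.join(sorted(library)) or 'empty'})")
        chosen = [library[config.index]]
    ensemble = fit(catches_run, chosen, config.prior_set(catches_run),
                   settings, force_cmsy=config.force_cmsy)
    return ensemble, summarize_ensemble(ensemble, config)


def _per_run_seed(base_seed: int, run_id: int) -> int:
    return int((base_seed + 10007 * run_id) % (2**31 - 1))


def run_all(
    configs: list[ScenarioConfig],
    catches: CatchSeries,
    indices: dict[str, IndexSeries] | None = None,
    seed: int = 1,
    settings_factory=None,
) -> pd.DataFrame:
    """Run every scenario; failing runs are reported in-table, not fatal.

    Per-run seeds derive deterministically from ``seed`` and the run id, so
    results are invariant to config ordering.
    """
    rows, errors = [], []
    for config in configs:
        run_seed = _per_run_seed(seed, config.run_id)
        settings = (settings_factory(run_seed) if settings_factory
                    else SamplerSettings(seed=run_seed))
        try:
            _, row = run_scenario(config, catches, indices, settings=settings)
            rows.append(row.as_dict())
        except Exception as exc:  # noqa: BLE001 - a bad run must not kill the batch
            errors.append({"run": config.run_id, "label": config.label, "error": str(exc)})
    table = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    table.attrs["errors"] = errors
    return table.sort_values("run", ignore_index=True) if len(table) else table


def write_summary_table(table: pd.DataFrame, path) -> None:
    """Full-precision tab-separated table (round-trips exactly)."""
    table.to_csv(path, sep="\t", index=False)


def read_summary_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def format_summary_table(table: pd.DataFrame) -> pd.DataFrame:
    """Printing convention: 3 significant figures for ratios and rates,
    whole numbers for biomass-scale columns at or above 1000 kt."""
    def sig3(x):
        return float(f"{x:.3g}")

    out = table.copy()
    for col in ("r", "F", "Fmsy", "B_Bmsy", "F_Fmsy", "MSY"):
        out[col] = out[col].map(sig3)
    for col in ("K", "B", "Bmsy"):
        out[col] = out[col].map(lambda x: round(x) if x >= 1000 else sig3(x))
    return out
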