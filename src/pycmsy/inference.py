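"""Posterior sampling for the state-space Schaefer model.

Two modes share one joint density:

* **CMSY** (catch-only): priors on (r, k), hard relative-biomass windows
  at the start, an intermediate year and the end of the series, and
  lognormal process deviations — no abundance likelihood.
* **BSM** (catch + CPUE): adds, for every index series and every observed
  year, a lognormal likelihood of the index around q·B. Short and
  fragmented index series are handled naturally: missing years simply
  contribute no term.

The joint log-density factorizes as

    log p = log N₂(log r, log k)                      (r–k prior)
          + log Unif(B₀/k | start window)             (initial depletion)
          + Σ_t log N(η_t | 0, σ_proc)                (process deviations)
          + Σ_t log N(ξ_t | 0, σ_catch)               (catch-error deviations)
          + Σ_j log N(log q_j | log q̂_j, 1)           (diffuse catchability prior)
          + Σ_{j,t} log N(log I_{jt} | log q_j B_t, σ_cpue)
          + hard windows on depletion at the intermediate and final years,

where η_t is the deviation of the realized state from the damped-Schaefer
expectation, B_{t+1} = max(B_t + P(B_t) − C_t, floor)·exp(η_t).

Sampling runs in *centered* state-space coordinates — the log-depletion
path log(B_t/k) is sampled directly and the process deviations are
derived (the change of variables is volume-preserving: the map from
(log d₀, η) to the log-depletion path is triangular with unit diagonal).
With a small process sd the posterior over the path is tightly
data-shaped, and this centering gives the ensemble sampler well-
conditioned geometry where deviation coordinates produce an
unexplorable funnel. Moves are a differential-evolution mixture;
walkers are split into groups to compute split-R̂ and effective sample
sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import dynamics
from .dynamics import BIOMASS_FLOOR_FRACTION, StockParams
from .priors import PriorSet, rk_log_prior_density, sample_rk
from .series import CatchSeries, IndexSeries

__all__ = [
    "ObservationModel",
    "LatentState",
    "SamplerSettings",
    "PosteriorEnsemble",
    "log_posterior",
    "fit",
    "marginal_q_estimate",
]

RHAT_THRESHOLD = 1.05
_LOG2PI = np.log(2.0 * np.pi)
# hard numeric bounds on log-depletion states (depletion 1e-6 .. 2)
_LOGD_MIN, _LOGD_MAX = np.log(1e-6), np.log(2.0)


def _cv_to_log_sd(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv * cv)))


@dataclass(frozen=True)
class ObservationModel:
    """Log-scale error sds derived from the configured CVs."""

    catch_sd_log: float
    cpue_sd_log: float
    process_sd_log: float

    @classmethod
    def from_priors(cls, priors: PriorSet) -> "ObservationModel":
        return cls(
            catch_sd_log=_cv_to_log_sd(priors.catch_cv),
            cpue_sd_log=_cv_to_log_sd(priors.cpue_cv),
            process_sd_log=float(priors.process_sigma),
        )


@dataclass(frozen=True)
class LatentState:
    """Latent variables of one draw: initial depletion and deviation vectors."""

    log_initial_depletion: float
    process_logdevs: np.ndarray
    catch_logdevs: np.ndarray | None = None


@dataclass(frozen=True)
class SamplerSettings:
    """Ensemble-sampler configuration.

    ``n_walkers=None`` picks an even count ≥ max(2·ndim+2, 64). Walkers are
    grouped into ``n_chain_groups`` pseudo-chains for convergence
    diagnostics. ``fixed_catch=True`` drops the latent catch-error
    deviations (treat reported catch as exact) — lower-dimensional and
    faster; the full model carries one catch multiplier per year.
    """

    seed: int
    n_walkers: int | None = None
    n_steps: int = 4000
    burn_fraction: float = 0.5
    thin: int = 1
    min_draws: int = 1000
    fixed_catch: bool = False
    n_chain_groups: int = 4

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory; no silent global randomness")
        if not (0 < self.burn_fraction < 1):
            raise ValueError("burn_fraction must be in (0, 1)")

    @classmethod
    def fast(cls, seed: int, **kw) -> "SamplerSettings":
        """Small preset for tests/examples: fixed catch, short run."""
        kw.setdefault("n_steps", 1500)
        kw.setdefault("fixed_catch", True)
        kw.setdefault("min_draws", 500)
        return cls(seed=seed, **kw)


def _propagate(r, k, log_d0, devs, catch):
    """Forward simulation in deviation coordinates (draws vectorized).

    Arguments are (W,) or (W, n)-shaped; returns biomass (W, n) and
    collapse flags. Used to rebuild trajectories from stored draws.
    """
    r, k, log_d0 = np.atleast_1d(r, k, log_d0)
    devs = np.atleast_2d(devs)
    catch = np.atleast_2d(catch)
    W, n = catch.shape
    b = np.empty((W, n))
    collapsed = np.zeros((W, n), dtype=bool)
    b[:, 0] = np.exp(log_d0) * k
    floor = BIOMASS_FLOOR_FRACTION * k
    for t in range(n - 1):
        bt = b[:, t]
        prod = r * bt * (1.0 - bt / k)
        prod *= np.where(bt < 0.25 * k, 4.0 * bt / k, 1.0)
        raw = bt + prod - catch[:, t]
        hit = raw < floor
        collapsed[:, t + 1] = hit
        b[:, t + 1] = np.where(hit, floor, raw) * np.exp(devs[:, t])
    return b, collapsed


class _Model:
    """Precomputed pieces of the joint density for one (catches, indices, priors).

    Coordinate layout: [log r, log k, log q_1..m, log d_0..d_{n-1},
    (catch logdevs)] with d_t = B_t/k the sampled depletion path.
    """

    def __init__(self, catches: CatchSeries, indices: list[IndexSeries],
                 priors: PriorSet, fixed_catch: bool):
        priors.validate_years(catches)
        self.catches = catches
        self.indices = list(indices)
        self.priors = priors
        self.fixed_catch = fixed_catch
        self.obs = ObservationModel.from_priors(priors)
        self.n_years = len(catches)
        self.n_idx = len(self.indices)

        years = catches.years
        self.i_int = int(priors.intermediate_window.year - years[0])
        self.obs_pos, self.obs_log = [], []
        for idx in self.indices:
            pos = idx.overlap(years)
            if pos.size == 0:
                raise ValueError(f"index {idx.label!r} has no years overlapping the catch series")
            keep = np.isin(idx.years, years[pos])
            self.obs_pos.append(pos)
            self.obs_log.append(np.log(idx.index[keep]))

        self.i_q = 2
        self.i_d = 2 + self.n_idx
        self.i_catch = self.i_d + self.n_years
        self.ndim = self.i_catch + (0 if fixed_catch else self.n_years)

        self.log_d0_lo = np.log(max(priors.start_window.low, 1e-12))
        self.log_d0_hi = np.log(priors.start_window.high)

        # catchability anchor: geometric-mean q of each index against the
        # deterministic prior-median trajectory
        ref_params = StockParams(priors.r_range.mid, priors.k_range.mid)
        ref_b0 = 0.5 * (priors.start_window.low + priors.start_window.high) * ref_params.k
        ref_traj = dynamics.project_trajectory(max(ref_b0, 1e-6), catches, ref_params)
        self.log_q0 = np.array(
            [np.log(marginal_q_estimate(ref_traj, idx)) for idx in self.indices]
        )
        self.q_prior_sd = 1.0

    # --- vectorized joint density -------------------------------------
    def log_prob(self, theta: np.ndarray) -> np.ndarray:
        """Joint log-density for a (W, ndim) matrix of walker positions."""
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            return self._log_prob(theta)

    def _log_prob(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        W = theta.shape[0]
        log_r, log_k = theta[:, 0], theta[:, 1]
        r, k = np.exp(log_r), np.exp(log_k)
        log_d = theta[:, self.i_d:self.i_d + self.n_years]

        lp = rk_log_prior_density(r, k, self.priors)

        # hard support: numeric state bounds, start window, intermediate and
        # end depletion windows — all directly on the sampled coordinates
        w_int, w_end = self.priors.intermediate_window, self.priors.end_window
        ok = (
            np.all((log_d > _LOGD_MIN) & (log_d < _LOGD_MAX), axis=1)
            & (log_d[:, 0] >= self.log_d0_lo) & (log_d[:, 0] <= self.log_d0_hi)
            & (log_d[:, self.i_int] >= np.log(max(w_int.low, 1e-12)))
            & (log_d[:, self.i_int] <= np.log(w_int.high))
            & (log_d[:, -1] >= np.log(max(w_end.low, 1e-12)))
            & (log_d[:, -1] <= np.log(w_end.high))
        )
        # initial depletion uniform on B/k: Jacobian of the log coordinate
        lp = np.where(ok, lp + log_d[:, 0], -np.inf)

        if self.fixed_catch:
            catch = np.broadcast_to(self.catches.catch, (W, self.n_years))
        else:
            cdev = theta[:, self.i_catch:]
            sc = self.obs.catch_sd_log
            lp = lp - 0.5 * np.sum((cdev / sc) ** 2, axis=1) \
                - self.n_years * (np.log(sc) + 0.5 * _LOG2PI)
            catch = self.catches.catch[None, :] * np.exp(cdev)

        # process deviations derived from consecutive states (unit-Jacobian
        # triangular map, so the N(0, σ) density applies unchanged)
        b = np.exp(log_d) * k[:, None]
        bt = b[:, :-1]
        prod = r[:, None] * bt * (1.0 - bt / k[:, None])
        prod *= np.where(bt < 0.25 * k[:, None], 4.0 * bt / k[:, None], 1.0)
        raw = np.maximum(bt + prod - catch[:, :-1], BIOMASS_FLOOR_FRACTION * k[:, None])
        devs = np.log(b[:, 1:]) - np.log(raw)
        sp = self.obs.process_sd_log
        lp = lp - 0.5 * np.sum((devs / sp) ** 2, axis=1) \
            - (self.n_years - 1) * (np.log(sp) + 0.5 * _LOG2PI)

        # CPUE likelihood (BSM); fragmented years contribute no term
        si = self.obs.cpue_sd_log
        for j in range(self.n_idx):
            log_q = theta[:, self.i_q + j]
            lp = lp - 0.5 * ((log_q - self.log_q0[j]) / self.q_prior_sd) ** 2 \
                - np.log(self.q_prior_sd) - 0.5 * _LOG2PI
            pred = log_q[:, None] + np.log(b[:, self.obs_pos[j]])
            resid = (self.obs_log[j][None, :] - pred) / si
            lp = lp - 0.5 * np.sum(resid * resid, axis=1) \
                - self.obs_pos[j].size * (np.log(si) + 0.5 * _LOG2PI)

        return np.where(np.isfinite(lp), lp, -np.inf)

    # --- helpers -------------------------------------------------------
    def states_and_devs(self, theta: np.ndarray):
        """Biomass paths, derived process devs, effective catches, collapse flags."""
        theta = np.atleast_2d(theta)
        W = theta.shape[0]
        r, k = np.exp(theta[:, 0]), np.exp(theta[:, 1])
        log_d = theta[:, self.i_d:self.i_d + self.n_years]
        if self.fixed_catch:
            catch = np.broadcast_to(self.catches.catch, (W, self.n_years)).copy()
        else:
            catch = self.catches.catch[None, :] * np.exp(theta[:, self.i_catch:])
        b = np.exp(log_d) * k[:, None]
        bt = b[:, :-1]
        prod = r[:, None] * bt * (1.0 - bt / k[:, None])
        prod *= np.where(bt < 0.25 * k[:, None], 4.0 * bt / k[:, None], 1.0)
        raw = bt + prod - catch[:, :-1]
        floor = BIOMASS_FLOOR_FRACTION * k[:, None]
        collapsed = np.zeros((W, self.n_years), dtype=bool)
        collapsed[:, 1:] = raw < floor
        devs = np.log(b[:, 1:]) - np.log(np.maximum(raw, floor))
        return b, devs, catch, collapsed

    def theta_from_deviations(self, params: StockParams, state: LatentState) -> np.ndarray:
        """Assemble a coordinate vector from the deviation representation."""
        if len(params.q) != self.n_idx:
            raise ValueError(f"need {self.n_idx} catchability value(s), got {len(params.q)}")
        catch = self.catches.catch
        if state.catch_logdevs is not None and not self.fixed_catch:
            catch = catch * np.exp(np.asarray(state.catch_logdevs))
        b, _ = _propagate(params.r, params.k, state.log_initial_depletion,
                          np.asarray(state.process_logdevs)[None, :], catch[None, :])
        theta = np.empty(self.ndim)
        theta[0], theta[1] = np.log(params.r), np.log(params.k)
        theta[self.i_q:self.i_q + self.n_idx] = np.log(params.q) if params.q else []
        theta[self.i_d:self.i_d + self.n_years] = np.log(b[0] / params.k)
        if not self.fixed_catch:
            theta[self.i_catch:] = (np.asarray(state.catch_logdevs)
                                    if state.catch_logdevs is not None
                                    else np.zeros(self.n_years))
        return theta


def log_posterior(
    params: StockParams,
    state: LatentState,
    catches: CatchSeries,
    indices: list[IndexSeries],
    priors: PriorSet,
) -> float:
    """Joint log-density of one (parameters, latent state) point.

    Window violations return −∞, never raise. ``state.catch_logdevs=None``
    evaluates the fixed-catch variant of the density.
    """
    fixed = state.catch_logdevs is None
    model = _Model(catches, list(indices), priors, fixed_catch=fixed)
    theta = model.theta_from_deviations(params, state)
    return float(model.log_prob(theta)[0])


def marginal_q_estimate(trajectory: dynamics.BiomassTrajectory, index: IndexSeries) -> float:
    """Closed-form catchability: geometric mean of index/biomass over observed years."""
    pos = index.overlap(trajectory.years)
    if pos.size == 0:
        raise ValueError("index and trajectory share no years")
    keep = np.isin(index.years, trajectory.years[pos])
    return float(np.exp(np.mean(np.log(index.index[keep]) - np.log(trajectory.biomass[pos]))))


@dataclass
class PosteriorEnsemble:
    """Retained posterior draws with implied biomass trajectories.

    Arrays are (n_draws,) or (n_draws, n_years)-shaped; ``q`` is
    (n_draws, n_indices). ``chain_id`` records the walker-group each draw
    came from (used by the split-R̂ diagnostic).
    """

    years: np.ndarray
    catch_reported: np.ndarray
    r: np.ndarray
    k: np.ndarray
    q: np.ndarray
    log_initial_depletion: np.ndarray
    process_logdevs: np.ndarray
    catch_logdevs: np.ndarray | None
    biomass: np.ndarray
    catch_effective: np.ndarray
    collapsed: np.ndarray
    chain_id: np.ndarray
    mode: str
    seed: int
    settings: SamplerSettings
    diagnostics: pd.DataFrame
    converged: bool
    index_labels: tuple[str, ...] = ()

    @property
    def n_draws(self) -> int:
        return self.r.size

    # --- derived per-draw quantities ----------------------------------
    def b_over_bmsy(self) -> np.ndarray:
        """(n_draws, n_years) relative biomass B/(k/2)."""
        return self.biomass / (0.5 * self.k[:, None])

    def f_over_fmsy(self) -> np.ndarray:
        """(n_draws, n_years) relative exploitation (C/B)/(r/2)."""
        f = self.catch_effective / self.biomass
        return f / (0.5 * self.r[:, None])

    def year_pos(self, year: int) -> int:
        pos = int(year) - int(self.years[0])
        if pos < 0 or pos >= self.years.size:
            raise ValueError(f"year {year} outside assessment horizon")
        return pos

    def to_frame(self) -> pd.DataFrame:
        """One row per retained draw, named columns (serializable as TSV)."""
        cols = {"chain": self.chain_id, "r": self.r, "k": self.k}
        for j, lab in enumerate(self.index_labels):
            cols[f"q_{lab}"] = self.q[:, j]
        cols["log_initial_depletion"] = self.log_initial_depletion
        for t in range(self.process_logdevs.shape[1]):
            cols[f"procdev_{self.years[t + 1]}"] = self.process_logdevs[:, t]
        if self.catch_logdevs is not None:
            for t, y in enumerate(self.years):
                cols[f"catchdev_{y}"] = self.catch_logdevs[:, t]
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, catches: CatchSeries,
                   mode: str = "CMSY", seed: int = 0,
                   settings: SamplerSettings | None = None) -> "PosteriorEnsemble":
        """Rebuild an ensemble (with trajectories) from its serialized form."""
        qcols = [c for c in frame.columns if c.startswith("q_")]
        ccols = [c for c in frame.columns if c.startswith("catchdev_")]
        pcols = [c for c in frame.columns if c.startswith("procdev_")]
        n = len(frame)
        r = frame["r"].to_numpy()
        k = frame["k"].to_numpy()
        devs = frame[pcols].to_numpy()
        catch = np.broadcast_to(catches.catch, (n, len(catches))).copy()
        catch_logdevs = None
        if ccols:
            catch_logdevs = frame[ccols].to_numpy()
            catch = catch * np.exp(catch_logdevs)
        biomass, collapsed = _propagate(
            r, k, frame["log_initial_depletion"].to_numpy(), devs, catch)
        return cls(
            years=catches.years, catch_reported=catches.catch,
            r=r, k=k,
            q=frame[qcols].to_numpy() if qcols else np.empty((n, 0)),
            log_initial_depletion=frame["log_initial_depletion"].to_numpy(),
            process_logdevs=devs,
            catch_logdevs=catch_logdevs,
            biomass=biomass, catch_effective=catch, collapsed=collapsed,
            chain_id=frame["chain"].to_numpy() if "chain" in frame else np.zeros(n, int),
            mode=mode, seed=seed,
            settings=settings or SamplerSettings(seed=seed),
            diagnostics=pd.DataFrame(), converged=True,
            index_labels=tuple(c[2:] for c in qcols),
        )


def _initial_walkers(model: _Model, n_walkers: int, rng: np.random.Generator) -> np.ndarray:
    """Feasible overdispersed starts.

    Stage 1 draws (r, k) from the joint prior, initial depletion from the
    start window and q around its anchor, builds each candidate's
    deterministic depletion path clipped into the windows, and keeps the
    highest-density candidates; stage 2 jitters them into distinct walkers.
    """
    w_int, w_end = model.priors.intermediate_window, model.priors.end_window

    def clip_windows(log_d: np.ndarray) -> np.ndarray:
        # clip anchors into their windows (implied devs absorb the kink)
        log_d[:, 0] = np.clip(log_d[:, 0], model.log_d0_lo + 1e-9, model.log_d0_hi - 1e-9)
        log_d[:, model.i_int] = np.clip(
            log_d[:, model.i_int], np.log(max(w_int.low, 1e-12)) + 1e-9,
            np.log(w_int.high) - 1e-9)
        log_d[:, -1] = np.clip(
            log_d[:, -1], np.log(max(w_end.low, 1e-12)) + 1e-9,
            np.log(w_end.high) - 1e-9)
        return np.clip(log_d, _LOGD_MIN + 1e-9, _LOGD_MAX - 1e-9)

    def candidates(M: int, shrink: float) -> np.ndarray:
        theta = np.zeros((M, model.ndim))
        rk = sample_rk(model.priors, M, rng)
        if shrink < 1.0:
            center = np.array([model.priors.r_range.log_mid, model.priors.k_range.log_mid])
            rk = center + shrink * (rk - center)
        theta[:, :2] = rk
        for j in range(model.n_idx):
            theta[:, model.i_q + j] = model.log_q0[j] + 0.7 * rng.standard_normal(M)
        log_d0 = rng.uniform(model.log_d0_lo + 1e-9, model.log_d0_hi - 1e-9, M)
        b, _ = _propagate(np.exp(rk[:, 0]), np.exp(rk[:, 1]), log_d0,
                          np.zeros((M, model.n_years - 1)),
                          np.broadcast_to(model.catches.catch, (M, model.n_years)))
        log_d = np.log(b) - rk[:, 1][:, None]
        if model.n_idx:
            # for half the candidates anchor the path to the first index
            # (states the data favor for that candidate's q and k), so the
            # walker cloud spans both data-led and dynamics-led basins
            half = M // 2
            pos = model.obs_pos[0]
            anchored = np.interp(
                np.arange(model.n_years), pos,
                model.obs_log[0], left=model.obs_log[0][0], right=model.obs_log[0][-1])
            log_d[:half] = (anchored[None, :] - theta[:half, model.i_q:model.i_q + 1]
                            - rk[:half, 1][:, None])
        theta[:, model.i_d:model.i_d + model.n_years] = clip_windows(log_d)
        return theta

    best: np.ndarray | None = None
    for attempt in range(6):
        theta = candidates(max(4000, 12 * n_walkers), shrink=1.0 if attempt < 3 else 0.4)
        lp = model.log_prob(theta)
        finite = np.flatnonzero(np.isfinite(lp))
        if finite.size >= n_walkers:
            # top-ranked candidates for density, random feasible ones for spread
            n_top = (3 * n_walkers) // 4
            order = finite[np.argsort(lp[finite])]
            top = theta[order[-n_top:]]
            rest = theta[rng.choice(order[:-n_top] if order.size > n_top else order,
                                    size=n_walkers - n_top)]
            best = np.vstack([top, rest])
            break
        if finite.size and best is None:
            best = theta[finite]
    if best is None:
        raise RuntimeError(
            "could not find any parameter draw satisfying the depletion windows; "
            "check that the priors and catch series are compatible")
    while best.shape[0] < n_walkers:
        best = np.vstack([best, best[: n_walkers - best.shape[0]]])
    # jitter into distinct walkers, keeping feasibility
    p0 = best.copy()
    for _ in range(20):
        jit = p0 + 0.01 * rng.standard_normal(p0.shape)
        ok = np.isfinite(model.log_prob(jit))
        p0[ok] = jit[ok]
    return p0


def _diagnostics(chains: np.ndarray, names: list[str], n_groups: int) -> pd.DataFrame:
    """Split-R̂ and bulk ESS per scalar, walkers grouped into pseudo-chains.

    ``chains`` has shape (n_walkers, n_steps, n_scalars).
    """
    import arviz as az

    n_walkers, n_steps, _ = chains.shape
    g = max(2, n_groups)
    per = n_walkers // g
    grouped = chains[: per * g].reshape(g, per, n_steps, -1)
    # concatenate walkers within a group along the draw axis
    grouped = grouped.transpose(0, 2, 1, 3).reshape(g, per * n_steps, -1)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, name in enumerate(names):
            data = az.convert_to_dataset(grouped[:, :, i])
            rows.append({
                "parameter": name,
                "rhat": float(az.rhat(data)["x"].values),
                "ess_bulk": float(az.ess(data)["x"].values),
            })
    return pd.DataFrame(rows)


def fit(
    catches: CatchSeries,
    indices: list[IndexSeries] | None,
    priors: PriorSet,
    settings: SamplerSettings,
    force_cmsy: bool = False,
) -> PosteriorEnsemble:
    """Sample the posterior in CMSY (catch-only) or BSM (catch+CPUE) mode.

    ``force_cmsy=True`` ignores any supplied indices, reproducing the
    catch-only analysis even when abundance data exist. Identical seed and
    inputs give an identical ensemble. Convergence failure (split-R̂ above
    1.05 on any of r, k, q) sets ``converged=False`` and warns; it never
    raises.
    """
    import emcee

    indices = list(indices or [])
    if force_cmsy:
        indices = []
    mode = "CMSY" if not indices else "BSM"
    model = _Model(catches, indices, priors, fixed_catch=settings.fixed_catch)

    ndim = model.ndim
    n_walkers = settings.n_walkers or max(2 * ndim + 2, 64)
    if n_walkers % 2:
        n_walkers += 1
    rng = np.random.default_rng(settings.seed)
    p0 = _initial_walkers(model, n_walkers, rng)

    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(n_walkers, ndim, model.log_prob,
                                    vectorize=True, moves=moves)
    sampler.random_state = np.random.RandomState(
        rng.integers(0, 2**31 - 1)).get_state()
    sampler.run_mcmc(p0, settings.n_steps, progress=False, skip_initial_state_check=True)

    burn = int(settings.burn_fraction * settings.n_steps)
    chain = sampler.get_chain(discard=burn, thin=settings.thin)  # (steps, walkers, ndim)
    kept_steps = chain.shape[0]
    if kept_steps * n_walkers < settings.min_draws:
        raise ValueError(
            f"only {kept_steps * n_walkers} retained draws < min_draws={settings.min_draws}; "
            "increase n_steps or decrease thinning")

    names = ["r", "k"] + [f"q_{idx.label}" for idx in indices] + ["log_initial_depletion"]
    scalars = np.concatenate([
        np.exp(chain[:, :, :2]),                      # r, k
        np.exp(chain[:, :, model.i_q:model.i_q + model.n_idx]),
        chain[:, :, model.i_d:model.i_d + 1],         # log initial depletion
    ], axis=2).transpose(1, 0, 2)                     # (walkers, steps, scalars)
    diag = _diagnostics(scalars, names, settings.n_chain_groups)
    converged = bool((diag["rhat"] <= RHAT_THRESHOLD).all())
    if not converged:
        warnings.warn(
            f"potential scale reduction above {RHAT_THRESHOLD} for "
            f"{', '.join(diag.loc[diag.rhat > RHAT_THRESHOLD, 'parameter'])}; "
            "treat results with caution", stacklevel=2)

    flat = chain.reshape(kept_steps * n_walkers, ndim)
    chain_id = np.tile(np.arange(n_walkers) * settings.n_chain_groups // n_walkers, kept_steps)
    biomass, devs, catch_eff, collapsed = model.states_and_devs(flat)

    return PosteriorEnsemble(
        years=catches.years,
        catch_reported=catches.catch,
        r=np.exp(flat[:, 0]),
        k=np.exp(flat[:, 1]),
        q=np.exp(flat[:, model.i_q:model.i_q + model.n_idx]),
        log_initial_depletion=flat[:, model.i_d],
        process_logdevs=devs,
        catch_logdevs=None if settings.fixed_catch else flat[:, model.i_catch:],
        biomass=biomass,
        catch_effective=catch_eff,
        collapsed=collapsed,
        chain_id=chain_id,
        mode=mode,
        seed=settings.seed,
        settings=settings,
        diagnostics=diag,
        converged=converged,
        index_labels=tuple(idx.label for idx in indices),
    )
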