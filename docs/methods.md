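# Methods

## Population dynamics

The stock is modeled by a discrete-annual Schaefer surplus-production model.
Biomass is a start-of-year quantity in kt; catch taken in year *t* is removed
within the *t* → *t*+1 transition:

```
B[t+1] = max(B[t] + P(B[t]) − C[t], floor) · exp(η[t]),   η[t] ~ N(0, σ_proc²)
```

Surplus production is the Schaefer parabola `r·B·(1 − B/k)`, multiplied by
`4B/k` when `B < k/4`. Production models notoriously overestimate
productivity at very low stock sizes; the linear damping below one quarter of
carrying capacity removes that artifact while keeping the curve continuous at
the breakpoint. Reference points are the Schaefer identities `MSY = r·k/4`,
`Bmsy = k/2`, `Fmsy = r/2`; exploitation is `F[t] = C[t]/B[t]`.

**Biomass floor.** When catch exceeds available biomass the state is clamped
at `10⁻³·k` and the year is flagged as a collapse. The floor keeps log-scale
likelihoods finite for implausible parameter draws — those draws are then
rejected by the data rather than by a crash. The specific fraction only
matters for draws the posterior discards anyway.

**Process error placement.** The lognormal deviation multiplies the
post-production, post-catch state. With σ_proc = 0.05 the multiplicative and
additive conventions are numerically close; multiplicative is the convention
consistent with a lognormal state equation and keeps biomass positive.

## Priors

* **r** — a categorical resilience table maps High/Medium/Low/Very-low to
  ranges (0.6–1.5, 0.2–0.8, 0.05–0.5, 0.015–0.1 yr⁻¹). A range `[lo, hi]` is
  read as the central 95% interval of a lognormal: mean at the log-midpoint,
  sd `(ln hi − ln lo)/3.92`.
* **k** — default range `[max(C)/r_hi, 12·max(C)/r_lo]` (kt): a stock cannot
  have sustained its peak catch unless `r·k` covers it; the upper factor
  keeps the prior proper but weak. Overridable per run.
* **(log r, log k)** jointly bivariate normal. The correlation defaults to 0
  and is configurable; no documented value exists for it here, so none is
  invented.
* **Depletion windows** — hard uniform constraints on `B/k` at the series
  start, one intermediate year and the final year. Trajectories violating a
  window have −∞ posterior density (truncation, not penalty). The
  intermediate window is treated as hard for symmetry with the others.
* **q** — diffuse lognormal per index, sd 1.0 in log space, centered on the
  geometric-mean ratio of the index to the deterministic prior-median
  trajectory. This anchors the scale without informing the trend.
* **Catch error** — reported catch enters through latent per-year lognormal
  multipliers with CV 0.2 (`true = reported · exp(ξ[t])`). A `fixed_catch`
  mode drops these 50 extra latent dimensions and treats reported catch as
  exact; tests and quick looks use it, and side-by-side runs show it moves
  posterior medians by far less than their credible widths.

Error CVs convert to log-scale sds as `sqrt(ln(1 + cv²))`; defaults are 0.2
(catch), 0.15 (CPUE), σ_proc = 0.05 — the error levels conventionally used in
state-space production-model assessments of pelagic sharks.

## Posterior and sampler

The joint density is the product of the r–k prior, the start-window prior on
initial depletion, N(0, σ_proc) process deviations, N(0, σ_catch) catch
deviations (when enabled), the q priors, and the lognormal index likelihood
`log I[j,t] ~ N(log(q_j·B[t]), σ_cpue)` over observed years only. Catch-only
(CMSY) runs simply have no index terms; `force_cmsy` drops supplied indices
to reproduce a catch-only analysis on data-rich inputs.

Sampling uses the emcee affine-invariant ensemble with a differential-
evolution move mixture, **in centered state-space coordinates**: the sampled
vector is `(log r, log k, log q, log-depletion path, catch deviations)` and
the process deviations are derived from consecutive states. The map from
(initial depletion, deviations) to the path is triangular with unit diagonal,
so the N(0, σ) deviation density applies unchanged. This matters: with small
process sd the posterior concentrates near a deterministic manifold, and in
deviation coordinates high-r solutions live in a funnel that ensemble moves
cannot enter (a prior-draw calibration experiment showed systematic
under-coverage concentrated at high-r truths). In state coordinates each
index observation constrains one coordinate directly and the same experiment
is calibrated. The density is fully vectorized across walkers; a 50-year BSM
fit takes seconds on one CPU.

Initialization draws `(r, k)` from their joint prior, filters candidates
through a cheap zero-deviation profile (deterministic paths clipped into the
windows, plus index-anchored paths when an index exists), keeps the
highest-density three quarters and random feasible candidates for the rest,
and jitters into distinct walkers. Defaults: walkers = max(2·dim+2, 64),
4000 steps, 50% burn-in, no thinning; the `fast` preset (1500 steps,
fixed catch) is used in tests. Walkers are split into 4 groups playing the
role of independent chains for split-R̂ and bulk ESS (ArviZ); R̂ > 1.05 on any
of r, k, q sets a non-converged flag and a warning, never an exception. All
randomness flows from the mandatory integer seed; identical seeds and inputs
give bit-identical ensembles.

## Scenario driver and outputs

A YAML scenario table (one row per run, columns named in the conventional
CMSY style: `r.low/r.hi`, `stb/intb/endb` windows, `btype`, `force.cmsy`,
`process.error`) drives batches. Each run truncates the catch series to its
year span before fitting, so start-year experiments never alter retained
catch values. Summary rows report posterior medians; **B/Bmsy and F/Fmsy are
medians of per-draw ratios**, not ratios of medians — the two differ
noticeably in skewed posteriors, which is why printed assessment tables do
not close exactly under the Schaefer identities. Per-run seeds derive from
the batch seed and the run id, making batch results order-invariant. A
failing run is reported in the output table's error list and skipped.

Kobe classification: green (`B/Bmsy ≥ 1, F/Fmsy ≤ 1`), orange (`≥ 1, > 1`),
yellow (`< 1, ≤ 1`), red (`< 1, > 1`). Boundary ties go to the better
status; posterior draws put measure ≈ 0 there. Quadrant probabilities are
straight tallies of per-draw classifications. Status trajectories report
per-year medians and 2.5/97.5 percentiles of the per-draw ratios. The
process-deviation diagnostic summarizes the latent η per transition with a
flatness statistic (max |median|); medians near zero mean biomass changes
track the Schaefer expectation — large excursions point at an index the
dynamics cannot explain or mis-specified priors.

## Synthetic data

The operating model iterates the same dynamics under an F-by-year schedule
(`C[t] = F[t]·B[t]` before the update) and observes them with the lognormal
error model. Per-fleet coverage masks produce full-span, short and
fragmented CPUE series.

`study_fixture` is the canned study system: a low-resilience stock
(r = 0.072, k = 2065 kt, so MSY ≈ 37 kt/yr) harvested along a ramp from
0.2·Fmsy to 1.3·Fmsy over 1971–2020 from initial depletion 0.72 — a long
rising catch history peaking near the MSY scale with end-year depletion
near 0.5 — observed by six fleets with distinct catchabilities and coverage
(one spanning the whole horizon, others starting 1990–1997, some with
missing years). The `nominal` variant truncates the same truth to
1992–2020. The fixture emulates the *shape* of a reconstructed-vs-nominal
bycatch data situation: it does not emulate fleet targeting changes, CPUE
standardization artifacts, or non-stationary catchability, so passing tests
show the estimator works when its assumptions hold, not that any real
stock's published numbers are reproduced.

`recovery_design` is the canonical parameter-recovery experiment: 50 years,
truth r = 0.21, k = 2000 kt, study error levels, one full-coverage index,
and a **two-cycle** fish-down/rebuild harvest schedule that keeps depletion
above k/4. Rebuild rates observed at two depletion levels are what identify
r separately from k; one-way-trip histories leave the pair confounded along
`r·k ≈ const`, where the posterior legitimately follows the prior — a
documented property of this model class, visible in published assessments as
index-dependent scatter of posterior r. The r prior for the experiment is
the Low-resilience category (0.05–0.5), the correct category for a stock
with r = 0.21.

## Numerical choices and limitations

* Depletion states are hard-bounded to (10⁻⁶, 2); the initial-depletion
  coordinate is log-depletion with the uniform-on-depletion Jacobian.
* Table printing: 3 significant figures for rates and ratios, whole numbers
  for biomass-scale columns ≥ 1000 kt; serialized tables keep full precision
  and round-trip exactly.
* Problem sizes in tests (1500–3000 sampler steps, 20-replicate coverage
  runs) were chosen as the smallest giving stable split-R̂ below 1.05 on the
  scalar parameters.
* Catch-only posteriors are strongly prior-driven — that is intrinsic to the
  method, not a defect of the implementation; treat CMSY-mode medians as a
  prior-informed plausibility band, not a measurement.
* One q per index: catchability is assumed constant over each series.
  Time-varying q, Pella–Tomlinson shape parameters and age structure are out
  of scope.
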