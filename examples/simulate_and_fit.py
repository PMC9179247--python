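"""Catch-only (CMSY) assessment of a synthetic shark-like stock.

Builds the canned 1971-2020 catch history, fits the Bayesian state-space
Schaefer model using catch data plus priors only, and prints the
posterior-median stock status. Everything is seeded and reproducible.
"""

import numpy as np

import pycmsy as pc
from pycmsy.scenarios import packaged_scenarios, run_scenario

catches, index_library = pc.study_fixture("reconstructed")
print(f"catch series {catches.start_year}-{catches.end_year}, "
      f"peak {catches.catch.max():.1f} kt")

config = next(c for c in packaged_scenarios() if c.label == "BSH_ATS")  # catch-only
ensemble, row = run_scenario(config, catches, index_library,
                             settings=pc.SamplerSettings.fast(seed=1))

print(f"\nmode {row.mode}; {ensemble.n_draws} posterior draws; "
      f"converged: {row.converged}")
print(f"r    = {row.r:.3f} /yr    k   = {row.K:.0f} kt")
print(f"MSY  = {row.MSY:.1f} kt/yr  Bmsy = {row.Bmsy:.0f} kt")
print(f"B/Bmsy (final year) = {row.B_Bmsy:.2f}   F/Fmsy = {row.F_Fmsy:.2f}")

probs = pc.kobe_probabilities(ensemble, int(ensemble.years[-1]))
print(f"\nKobe probabilities in {probs.year}: "
      f"green {probs.p_green:.1%}, yellow {probs.p_yellow:.1%}, "
      f"orange {probs.p_orange:.1%}, red {probs.p_red:.1%}")
print("these are posterior fractions of draws in each joint-status quadrant;")
print("B/Bmsy > 1 with F/Fmsy > 1 (orange) warns of incipient overfishing.")
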