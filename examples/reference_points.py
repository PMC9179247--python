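"""Schaefer reference points and Kobe status from point estimates.

Given an intrinsic growth rate r and carrying capacity k, the Schaefer
model fixes the management quantities algebraically: MSY = r·k/4 is the
largest sustainable harvest, taken at biomass Bmsy = k/2 under fishing
mortality Fmsy = r/2. The Kobe quadrant then summarizes joint stock
status from B/Bmsy and F/Fmsy.
"""

import pycmsy as pc

# posterior medians of a catch-only assessment of a low-resilience shark stock
params = pc.StockParams(r=0.074, k=2027.0)
rp = pc.reference_points(params)

print(f"r = {params.r}  k = {params.k} kt")
print(f"MSY  = {rp.msy:.1f} kt/yr   (largest sustainable annual harvest)")
print(f"Bmsy = {rp.bmsy:.0f} kt     (biomass that produces MSY)")
print(f"Fmsy = {rp.fmsy:.3f} /yr    (fishing mortality at MSY)")

# final-year status: biomass above Bmsy, fishing below Fmsy -> green quadrant
b_ratio, f_ratio = 1.16, 0.823
quadrant = pc.kobe_classify(b_ratio, f_ratio)
print(f"\nB/Bmsy = {b_ratio}, F/Fmsy = {f_ratio} -> Kobe quadrant: {quadrant}")
print("green means a healthy stock under sustainable fishing pressure.")
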