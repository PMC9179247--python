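"""A slice of the 14-run sensitivity design.

Runs the two catch-only configurations (1971 and 1992 start years) and
one catch+CPUE configuration from the bundled scenario table, then
prints the assessment-style summary. Comparing rows shows how the start
year and an abundance index move the posterior medians.
"""

import pycmsy as pc
from pycmsy.scenarios import format_summary_table, packaged_scenarios, run_all

catches, index_library = pc.study_fixture("reconstructed")
configs = [c for c in packaged_scenarios() if c.run_id in (1, 8, 4)]

table = run_all(configs, catches, index_library, seed=1,
                settings_factory=lambda s: pc.SamplerSettings.fast(seed=s))

print(format_summary_table(table).to_string(index=False))
print("\nrun 1 and run 8 are catch-only (CMSY) with different start years;")
print("run 4 adds the full-span CPUE index (BSM). Close r and K across the")
print("two start years means the truncation matters little; the index run")
print("shifts the medians by weighting the abundance trend.")
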