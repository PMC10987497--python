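"""Score fly sleep and quantify the cooling-induced evening-peak advance.

Generates paired activity days for 32 flies (18 degC cold day vs 24 degC
control), scores sleep with the 5-min immobility rule, and computes the
E-peak-advance index next to its analytic expectation.
"""

import numpy as np

from circatemp import sleep, synth
from circatemp.synth import SynthConfig, TempEffect

effects = {"24C": TempEffect(), "18C": TempEffect(evening_rate_factor=1.3)}
cfg = SynthConfig(master_seed=1, temp_effects=effects)

cold = synth.gen_activity(cfg, "18C", n_flies=32)
ctrl = synth.gen_activity(cfg, "24C", n_flies=32)

sleep_min = [sleep.score_sleep(r).total_sleep_min for r in ctrl]
print(f"control flies sleep {np.mean(sleep_min):.0f} +- "
      f"{np.std(sleep_min):.0f} min/day (5-min immobility rule)")

res = sleep.epeak_advance_index(cold, ctrl)
oracle = (synth.expected_window_mean(cfg, "18C", (6, 12)).value
          / synth.expected_window_mean(cfg, "24C", (6, 12)).value - 1)
print(f"E-peak advance index: {res.mean:.3f} +- {res.sem:.3f} (n={len(res.per_fly)})")
print(f"generator expectation: {oracle:.3f}")
print("-> a positive index means evening locomotion rises under cooling; the")
print("   planted +30% ZT6-12 rate effect is recovered within sampling error.")
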