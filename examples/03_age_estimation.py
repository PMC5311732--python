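"""Insertion-age estimation from LTR-pair divergence, T = K / (2r).

Simulates a family under a uniform molecular clock with known insertion
ages, aligns each element's two LTRs, corrects the p-distance (JC69) and
converts divergence to years with r = 1.3e-8 substitutions/site/year.
"""

import numpy as np

from tesrna import synthetic_data as sd
from tesrna import te_annotation as ta

spec = sd.FamilySpec("clock", 60, ltr_length=1000, int_length=100,
                     age_law="uniform", age_params=(2e5, 1.8e6),
                     hotspot_rate_factor=1.0, hotspot_variant_divergence=0.0)
elements = sd.simulate_family(spec, seed=3)

rel_err = []
for el in elements[:5]:
    est = ta.age_ltr_pair(el.sequence[slice(*el.ltr5)],
                          el.sequence[slice(*el.ltr3)], model="JC69")
    print(f"{el.element_id}: true {el.age/1e6:.2f} My, "
          f"K = {est.K:.4f}, estimated {est.T/1e6:.2f} My")
for el in elements:
    est = ta.age_ltr_pair(el.sequence[slice(*el.ltr5)],
                          el.sequence[slice(*el.ltr3)], model="JC69")
    rel_err.append((est.T - el.age) / el.age)
print(f"mean relative bias over {len(elements)} elements: "
      f"{100 * float(np.mean(rel_err)):+.1f}%")
print(f"anchor: K = 0.0026 at r = 1.3e-8  ->  T = "
      f"{ta.estimate_age(0.0026, 1.3e-8):,.0f} years")
# Per-element estimates scatter (a 1 kb LTR gives few substitutions at young
# ages) but the estimator is essentially unbiased in the low-divergence regime.
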