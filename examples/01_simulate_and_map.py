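"""Simulate a TE-rich genome with an sRNA library and map it back.

Builds two LTR retrotransposon families (20 copies each) on a random
background, generates a 21/22/24-nt sRNA library whose production decays
with element age, maps every distinct read sequence (species) to the genome
with zero mismatches and all hits reported, and tags species as uniquely (U)
or multiply (M) mapping.
"""

from tesrna import pipelines as pl
from tesrna import quantification as qt
from tesrna import synthetic_data as sd

families = [
    sd.FamilySpec("famA", 20, ltr_length=400, int_length=1200),
    sd.FamilySpec("famB", 20, ltr_length=400, int_length=1200),
]
study = pl.simulate_study(families, background_length=150_000, seed=42)

um = qt.um_ratio(study.genome_hits.values())
print(f"elements annotated : {len(study.annotations)}")
print(f"sRNA species       : {len(study.species)}")
print(f"mapped species     : {um['mapped']}  (U: {um['U']}, M: {um['M']})")
print(f"U proportion       : {um['U_proportion']:.1%}")
x_multi = [hs.x for hs in study.genome_hits.values() if hs.x >= 2]
print(f"median x of M_sRNAs: {sorted(x_multi)[len(x_multi) // 2]}")
# The U proportion is small because TE copies of a family share sequence:
# most TE-derived species hit several copies, so their location count x > 1.
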