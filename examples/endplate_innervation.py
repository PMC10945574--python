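"""Endplate counting and innervation fractions.

Detects α-BTx endplates in a phantom volume, classifies each by GFP/ChAT
colocalization, and reports the graft-innervated fraction — the same
calculation that yields 10.5% for the published whole-muscle counts
(364 YFP-colocalized of 3482 detected endplates).
"""

from collections import Counter

from nmquant import innervation
from nmquant import synthetic_data as sd

spec = sd.MusclePhantomSpec(
    n_fibers=15,
    class_fractions={"graft": 0.3, "endogenous": 0.2, "denervated": 0.3, "unconfirmed": 0.2},
    seed=12,
)
vol, truth = sd.generate_muscle_phantom(spec)
records = innervation.detect_endplates(vol)
print(f"detected {len(records)} endplates (truth: {len(truth.endplates)})")
print("categories:", dict(Counter(r.category for r in records)))

n_graft = innervation.count_innervated(records)
frac = innervation.innervation_fraction(n_graft, len(records))
print(f"graft-innervated fraction in phantom: {n_graft}/{len(records)} = {frac}%")

print("\npublished whole-muscle worked example:")
print(f"  innervation_fraction(364, 3482) = {innervation.innervation_fraction(364, 3482)}%")
print("Only a small minority of endplates are reinnervated by the engrafted "
      "motor neurons; the fraction is the key denominator for force recovery.")
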