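"""Synthetic patient cohorts with realistic metaboliser frequencies.

Samples 10,000 patients and prints the CYP2D6 class fractions: around 10%
poor metabolisers (codeine gives little analgesia) and 2% ultra-rapid
(morphine toxicity risk) — the population figures that motivate routing
prescribing decisions through PGx data in the first place. Each class maps
to a guideline recommendation code per drug.
"""

from collections import Counter

from pgxledger import sample_patients
from pgxledger.synth import guideline_recommendations

cohort = sample_patients(10_000, seed=2024)
counts = Counter(p.cyp2d6 for p in cohort)
for cls in ("poor", "ultra_rapid", "normal"):
    print(f"CYP2D6 {cls:12s}: {counts[cls]:5d}  ({100 * counts[cls] / len(cohort):.2f}%)")

poor = next(p for p in cohort if p.cyp2d6 == "poor")
print("\nguideline recommendations for one poor metaboliser:")
for rec in guideline_recommendations(poor):
    print(f"  {rec['drug']:13s} ({rec['gene']:7s} {rec['phenotype']:12s})"
          f" -> {rec['recommendation']}")
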