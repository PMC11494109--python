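"""Effect barcodes and the addition rule.

Derives the hypertension effect barcode from a synthetic cohort study, the
barcode of a VWF-side inhibitor from a paired drug test, and combines them
with the sign-saturating addition rule.
"""

import numpy as np

from thromboprofile import synth
from thromboprofile.barcode import (
    DIMENSIONS,
    Barcode,
    add_barcodes,
    derive_effect_barcode,
)
from thromboprofile.pipeline import measure_profiles

design = synth.StudyDesign()
subjects = synth.generate_study(design, seed=42)
rng = np.random.default_rng(42)
measured = measure_profiles(subjects, measurement_cv=0.1, rng=rng)

healthy = measured[measured.cohort == "healthy_young"][list(DIMENSIONS)]
hypertensive = measured[measured.cohort.str.startswith("htn")][list(DIMENSIONS)]
htn_code = derive_effect_barcode(healthy, hypertensive)
print(f"hypertension effect barcode : {htn_code}")

# paired drug test: 5 hypertensive subjects, without vs with the inhibitor at IC50
inhibitor = synth.InhibitorSpec(
    name="vwf_blocker", ic50=1.0, effect_barcode=Barcode.from_string("-0--0--")
)
truth = subjects[subjects.cohort.str.startswith("htn")][list(DIMENSIONS)].to_numpy()[:5]
treated = np.array([synth.apply_inhibitor(row, inhibitor, 1.0) for row in truth])
sigma = np.sqrt(np.log1p(0.1**2))
drug_code = derive_effect_barcode(
    truth * rng.lognormal(-sigma**2 / 2, sigma, truth.shape),
    treated * rng.lognormal(-sigma**2 / 2, sigma, truth.shape),
    paired=True,
)
print(f"inhibitor effect barcode    : {drug_code}")

combined = add_barcodes(htn_code, drug_code)
print(f"disease + drug (addition)   : {combined}")

# Dimensions order: [size, Fg, VWF, P-sel, PS, E+, Act]. '+'/'-' mark
# significant increases/decreases; the addition rule predicts the
# drug-disease interaction barcode from the two individual codes.
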