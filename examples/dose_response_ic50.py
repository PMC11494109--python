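"""Fitting an inhibitor's dose-response and extracting its IC50.

Simulates residue-size measurements from a known Hill curve with 5%
multiplicative assay noise and fits them back.
"""

import numpy as np

from thromboprofile.doseresponse import (
    DoseResponseData,
    fit_hill,
    predict_residue_params,
)

rng = np.random.default_rng(7)
doses = np.logspace(-1.5, 1.5, 8)  # µg/mL, three decades
truth = predict_residue_params(doses, ic50=1.0, hill_slope=1.5, floor_R=10.0)
observed = truth * rng.lognormal(0.0, 0.05, doses.size)

fit = fit_hill(DoseResponseData(doses, observed))

print("dose (µg/mL)   residue (%)")
for c, r in zip(doses, observed):
    print(f"  {c:8.3f}     {r:6.1f}")
print(f"\nIC50       : {fit.ic50:.3f} µg/mL  (truth 1.0)")
print(f"Hill slope : {fit.hill_slope:.2f}      (truth 1.5)")
print(f"floor R    : {fit.floor_R:.1f} %     (truth 10)")

# Residue size is 100% without drug and decays to the floor R at saturating
# dose; the IC50 is the concentration at the (100 + R)/2 midpoint.
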