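"""Maximin-LHS uncertainty analysis with the plausibility filter.

Samples the joint prior with a 500-point maximin Latin hypercube, simulates
a 0.738 mg/kg oral dose for every design point, and counts how many runs
give a blood-MPHP profile consistent with the biomonitoring data: a peak
between 0.025 and 0.3 mg/L and at most 0.025 mg/L left in blood at 48 h.
"""

import numpy as np

from dphpkin.uasa import run_uncertainty_analysis

res = run_uncertainty_analysis(n=500, seed=1)

peaks = res["peak_CBlood_MPHP"]
c48 = res["CBlood_MPHP_48h"]
n = len(peaks)
print(f"design points            : {n}")
print(f"retained by the filter   : {len(res['retained'])}")
print(f"rejected, peak < 0.025   : {(peaks < 0.025).sum()}")
print(f"rejected, peak > 0.3     : {(peaks > 0.3).sum()}")
print(f"rejected, 48-h > 0.025   : {(c48 > 0.025).sum()} (overlaps possible)")
print(f"median peak blood MPHP   : {np.median(peaks):.3f} mg/L")
# Roughly half to two-thirds of the prior-consistent parameterisations
# produce plausible monoester kinetics; the rest are screened out before
# any calibration is attempted.
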