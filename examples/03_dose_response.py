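"""Cellular dose-response: normalization, EC50 fitting and censoring.

Normalizes a raw reporter readout against its assay controls, fits a 4PL
on log dose, and shows how an inactive compound propagates as a censored
">50" potency into the cell/target ratio.
"""

import numpy as np

from helixscan import cell_target_ratio, fit_ec50, normalize_reporter
from helixscan.dose_response import DoseResponseCurve
from helixscan.simulate import GeneratorConfig, gen_dose_response

# raw signal -> percent of the saturating-control activity
raw = np.array([210.0, 400.0, 900.0, 1600.0, 1980.0])
pct = normalize_reporter(raw, max_control=2000.0, background=200.0)
print("normalized response (%):", np.round(pct, 1))

# fit a simulated active compound (planted EC50 0.54 uM)
curve, truth = gen_dose_response(ec50_uM=0.54, hill=1.5,
                                 cfg=GeneratorConfig(seed=3, sigma_response=3.0))
res = fit_ec50(curve)
print(f"EC50 = {res.ec50:.2f} uM (truth {truth['ec50_uM']}), hill = {res.hill:.2f}")
print(f"cell/target ratio at Kd 18.6 nM: {cell_target_ratio(res.ec50, 18.6)}")

# an inactive compound: flat response up to the 50 uM ceiling
flat = DoseResponseCurve(dose=np.geomspace(0.05, 50, 8), response=np.zeros(8))
censored = fit_ec50(flat, max_tested=50.0)
print(f"inactive compound: EC50 {censored.ec50}, "
      f"ratio at Kd 6485 nM: {cell_target_ratio(censored.ec50, 6485.0)}")
# ">8" means the true ratio is at least 8-fold; no activity was seen up to 50 uM.
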