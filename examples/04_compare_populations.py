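"""Compare parameter distributions between two calibrated populations.

Builds two synthetic populations with a known -40% shift in gKur, then runs
the per-parameter Mann-Whitney comparison used to read electrical remodeling
out of stratified data, and the median-model construction.
"""

import numpy as np

from pomcal import analysis
from pomcal.refine import PopulationOfModels

rng = np.random.default_rng(7)
Y = np.tile([10.0, 150.0, 280.0, 105.0, -74.0, -5.0, 200.0], (300, 1))

theta_sr = rng.normal(1.0, 0.15, size=(300, 11))
theta_caf = rng.normal(1.0, 0.15, size=(300, 11))
theta_caf[:, 2] *= 0.6   # gKur down-regulated by 40%

pom_sr = PopulationOfModels(theta=theta_sr, biomarkers=Y)
pom_caf = PopulationOfModels(theta=theta_caf, biomarkers=Y)

report = analysis.compare_parameter_distributions(pom_sr, pom_caf)
print(report.to_string(index=False,
                       float_format=lambda v: f"{v:.3g}"))

med = analysis.median_model(pom_caf)
print(f"\nmedian model gKur multiplier: {med.gKur:.3f} (truth ~0.6)")
print("\nThe shifted parameter is flagged significant with the correct")
print("magnitude; unshifted parameters show no significant change.")
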