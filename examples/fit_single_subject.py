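"""Fit the four growth models to one subject's scan series.

A subject whose tumor shrinks and then regrows is built from the additive
decay+growth (gd) model; all admissible models are fitted and the AIC /
p-value selection rule picks the class, from which the g-score and tumor
doubling time follow.
"""

import numpy as np

import tumorkinetics as tk
from tumorkinetics.fitting import fit_single_model

# sum of target-lesion diameters (mm) at 6-weekly scans
days = np.array([0, 42, 85, 126, 170, 210, 252])
f = tk.evaluate("gd", days.astype(float), g=0.0025, d=0.015)
rng = np.random.default_rng(2)
sod = np.round(48.0 * f * np.exp(rng.normal(0, 0.05, f.shape)), 1)
sod[0] = 48.0

traj = tk.TumorTrajectory("patient-001", days, sod)
print("day:", traj.days.astype(int).tolist())
print("SOD (mm):", traj.sod_mm.tolist())

for model in ("dx", "gx", "gd", "gdphi"):
    fit = fit_single_model(traj, model)
    print(f"{model:>6}: RSS={fit.rss:.5f}  AIC={fit.aic:7.2f}  "
          f"p={ {k: round(v, 4) for k, v in fit.pvalues.items()} }")

result = tk.classify_subject(traj)
print(f"\nselected class: {result.classification}")
print(f"g-score: {result.g:.5f}/day, d: {result.d:.5f}/day")
print(f"tumor doubling time: {result.tdt_days:.0f} days")
print("\nThe g-score is the regrowth rate of the resistant disease; the")
print("doubling time ln(2)/g expresses the same rate as time to doubling.")
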