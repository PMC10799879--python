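"""Calibration and concentration of risk for a screening program.

Calibration tables compare observed event fractions per score stratum with
the probability the logistic score implies; concentration of risk is the
event rate in a top score stratum divided by the overall rate — the number
a screening program multiplies against its outreach capacity.
"""

import numpy as np

from riskpipe import calibration, concentration_of_risk


def sigmoid(x):
    return 1 / (1 + np.exp(-x))


rng = np.random.default_rng(9)
n = 60_000
scores = rng.normal(-3.0, 1.4, n)          # log-odds, ~5% prevalence
labels = rng.random(n) < sigmoid(scores)   # well-specified by construction

tab = calibration(scores, labels)
print("calibration (well-specified score): bin center / n / observed / expected")
for _, r in tab[tab["n"] > 500].iterrows():
    print(f"  {r['bin_center']:+.2f}  {int(r['n']):>6}  "
          f"{r['observed']:.4f}  {r['expected']:.4f}")
print("observed tracks expected across the score range -> well calibrated")

cor = concentration_of_risk(scores, labels, [0.01, 0.001])
print("\nconcentration of risk (top strata):")
for _, r in cor.iterrows():
    print(f"  top {100 * r['q']:g}%: {int(r['n_events'])} events in "
          f"{int(r['n_stratum'])} patients, event rate {r['stratum_fraction']:.3f}"
          f" = {r['concentration']:.1f}x the overall rate")
print("\na ratio of R means screening the top stratum finds R times as many "
      "events\nper patient screened as screening at random")
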