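"""Generate a synthetic EMR population and look at what it contains.

The generator draws patients with dates of birth spanning 1930-1985, gives
each a yearly visit intensity from a log-normal distribution, emits coded
diagnosis/medication events at visits, and draws suicide / attempt /
overdose events from a known logistic hazard that depends on the patient's
trailing 8-year feature state, age, and healthcare utilization.
"""

import numpy as np

from riskpipe import PopulationConfig, generate_population, ground_truth

cfg = PopulationConfig(n_patients=2000, seed=1)
pop = generate_population(cfg)

print(f"patients: {len(pop.patients)}")
print(f"visits:   {len(pop.visits)} "
      f"(mean {len(pop.visits) / len(pop.patients):.1f} per patient over 22 y)")
print(f"coded events: {len(pop.events)} across {len(pop.variable_list)} variables")
print(f"lab/vital/survey records: {len(pop.labs)}")
print(f"deaths: {len(pop.deaths)}")

n_suicide = int((pop.truth["suicide_year"] >= 0).sum())
n_attempt = int(pop.truth["attempt_events"].any(axis=1).sum())
n_od = int(pop.truth["overdose_events"].any(axis=1).sum())
print(f"\nground-truth outcomes: {n_suicide} suicides, "
      f"{n_attempt} patients with attempts, {n_od} with overdoses")
print("(the suicide count is sub-1% of patients, the attempt/overdose counts "
      "a few percent — the rare-outcome regime the matched design exists for)")

gt = ground_truth(cfg, pop)
lp = gt.linear_predictors["suicide"]
print(f"\nmean annual suicide linear predictor: {np.nanmean(lp.to_numpy()):.2f} "
      "(log-odds; the sigmoid of this is the annual hazard)")
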