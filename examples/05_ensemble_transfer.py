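"""Ensemble transfer learning end to end at a small scale.

Base models trained on the matched case-control cohort score a later
calendar cohort without refitting (cross-prediction works because every
design shares the 8-bin layout); an unpenalized logistic fine-tuning then
stacks the base scores with ten design-sensitive covariates.
"""

import warnings

import numpy as np

warnings.simplefilter("ignore")

from riskpipe import (PopulationConfig, RccConfig, assign_dob_partitions,
                      build_calendar_cohort, build_rcc, classify_events,
                      encode_cohort, even_odd_protocol, fit_ensemble,
                      generate_population, score_base_models, auroc)
from riskpipe.cohorts import compute_outcomes
from riskpipe.ensemble import default_finetune_frame
from riskpipe.models import LearnerConfig

cfg = PopulationConfig(n_patients=6000, seed=6)
pop = generate_population(cfg)
parts = assign_dob_partitions(pop.patients, k=20)
outcomes = compute_outcomes(pop)
comp = classify_events(pop.events, pop.deaths)

rcc = build_rcc(pop, outcomes, RccConfig(seed=7), partitions=parts,
                calendar_range=cfg.calendar_range)
fm_rcc = encode_cohort(rcc, pop)
y_rcc = rcc["is_case"].to_numpy()
lc = LearnerConfig(rf_trees=200, glm_cv_folds=3, glm_n_lambda=12)

res_glm = even_odd_protocol("glm-lasso", fm_rcc, y_rcc, rcc["even"].to_numpy(),
                            lc, seed=8)
res_rf = even_odd_protocol("random-forest", fm_rcc, y_rcc,
                           rcc["even"].to_numpy(), lc, seed=8)
print(f"matched-cohort out-of-half AUROC: glm {auroc(res_glm.scores, y_rcc):.3f}"
      f", rf {auroc(res_rf.scores, y_rcc):.3f}")
print("(matching absorbs age/utilization signal, so these look modest)")

c17 = build_calendar_cohort(pop, comp, "2017-01-01", partitions=parts,
                            design_tag="C17")
fm17 = encode_cohort(c17, pop)
y17 = c17["is_case"].to_numpy()
S = score_base_models([("rcc_glm", res_glm.final_model),
                       ("rcc_rf", res_rf.final_model)], fm17)
print(f"\ncross-predicted on the 2017 calendar cohort "
      f"({y17.sum()} cases / {len(y17)}):")
for name in S:
    print(f"  {name}: AUROC {auroc(S[name], y17):.3f}")

ft = default_finetune_frame(fm17, pop)
model, oof = fit_ensemble(S, ft, y17, c17["even"].to_numpy())
print(f"  ensemble (fine-tuned, out-of-half): AUROC {auroc(oof, y17):.3f}")
print("\nfine-tuning coefficients (base weights then the ten covariates):")
print(model.coefficients.round(2).to_string())
print("\nfine-tuning restores the age/utilization and outcome-definition "
      "signal the\nmatched design deliberately removed; with only a few "
      "hundred target-cohort\ncases the gain over the best base is small — "
      "it grows with the case count")
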