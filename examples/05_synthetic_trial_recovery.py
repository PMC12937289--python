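"""Validate the estimators on simulated trials with known ground truth.

Simulates the replicated 11-diet x 3-period balance experiment (22 pigs,
six replicates per diet, intake at 4% of body weight) at realistic assay
noise and checks how well the difference method recovers the true
ingredient energies.
"""

import numpy as np

from feedval import (
    estimate_ingredient_energies,
    generate_design,
    recovery_report,
    simulate_balance_trial,
    treatment_energy_summary,
)
from feedval.synthetic import BASAL_DIET_ID, NoiseModel, default_energy_truth

truth = default_energy_truth()
plan = generate_design(
    22, 11, 3, 6, seed=1, diet_ids=[BASAL_DIET_ID, *sorted(truth.true_de)]
)
print(f"Design: {len(plan.pigs)} pigs x {plan.periods} periods, "
      f"{len(plan.diets)} diets, replicate counts "
      f"{set(plan.replicate_counts().values())}")

# Zero noise: the forward model inverts exactly.
records = simulate_balance_trial(truth, plan, NoiseModel(0, 0, 0), seed=1)
summary = treatment_energy_summary(
    estimate_ingredient_energies(records, BASAL_DIET_ID)
)
est = {i: summary.loc[i, "de"] for i in truth.true_de}
print("Zero-noise recovery:", recovery_report(est, dict(truth.true_de)).round(12).to_dict())

# 2% energy-assay noise, 200 replicate trials.
errors = []
for seed in range(200):
    records = simulate_balance_trial(
        truth, plan, NoiseModel(2.0, 2.0, 5.0), seed=1000 + seed
    )
    s = treatment_energy_summary(
        estimate_ingredient_energies(records, BASAL_DIET_ID)
    )
    errors.append(np.mean([s.loc[i, "de"] - truth.true_de[i]
                           for i in truth.true_de]))
print(f"Bias of ingredient DE over 200 noisy trials: "
      f"{np.mean(errors):+.4f} MJ/kg (SD of the trial mean {np.std(errors):.4f})")
print("A bias within a few hundredths of an MJ/kg shows the difference")
print("method is unbiased at the assay precision a balance trial achieves.")
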