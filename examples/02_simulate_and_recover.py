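"""Mass-balance simulation with known truth, and its exact inversion.

Simulates a two-line trial with assay noise switched off and runs the DC
pipeline on each bird: because the generator constructs manure by the
exact inverse of the digestibility equations, the recovered coefficients
equal the latent truths to machine precision.
"""

import numpy as np

from layerdig import compute_all_dcs, simulate_trial
from layerdig.synthetic import default_sim_config

config = default_sim_config(seed=1, assay_noise_cv=0.0)
dataset, truth = simulate_trial(config)
truth = truth.set_index("bird_id")

worst = 0.0
for bird in dataset.birds:
    dcs = compute_all_dcs(bird, dataset.assays[bird.bird_id], dataset.feed)
    row = truth.loc[bird.bird_id]
    worst = max(
        worst,
        abs(dcs.dc_dm - row.true_dc_dm), abs(dcs.dc_fat - row.true_dc_fat),
        abs(dcs.dc_n - row.true_dc_n), abs(dcs.dc_org - row.true_dc_org),
    )

first = dataset.birds[0]
dcs = compute_all_dcs(first, dataset.assays[first.bird_id], dataset.feed)
print(f"simulated {len(dataset)} birds in lines {sorted(truth.line.unique())}")
print(f"bird {first.bird_id}: recovered DC_DM {dcs.dc_dm:.6f} % "
      f"vs latent {truth.loc[first.bird_id].true_dc_dm:.6f} %")
print(f"worst absolute recovery error over all birds and DCs: {worst:.2e} points")
print()
print("The ~1e-14 error is pure floating-point roundoff: the estimator is")
print("the exact inverse of the generator's nutrient mass balance.")
print(f"line-mean latent DC_DM: "
      f"A {truth[truth.line == 'A'].true_dc_dm.mean():.1f} %, "
      f"B {truth[truth.line == 'B'].true_dc_dm.mean():.1f} %")
print(f"(np {np.__version__}; rerun with any seed, the property is seed-free)")
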