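"""Differential Jacobian between two metabolic states.

Simulates the 13-pool compartmented carbohydrate model under control rates
and with the vacuolar fructose export doubled, then ranks the differential
Jacobian: the perturbed transport should surface near the top.
"""

import numpy as np

from metajac import (
    analytic_jacobian,
    build_toy_network,
    covariance_from_replicates,
    differential_jacobian,
    entry_significance,
    find_steady_state,
    normalize_ensemble,
    run_ensemble,
    simulate_replicates,
)
from metajac.synthetic import CARB13_RATES

control = build_toy_network("carb13")
perturbed = build_toy_network(
    "carb13", rates={"tonoplast_frc_out": 2 * CARB13_RATES["tonoplast_frc_out"]}
)
mask = analytic_jacobian(control, find_steady_state(control)).structure_mask

ensembles = []
for i, model in enumerate((control, perturbed)):
    sim = simulate_replicates(model, 100_000, noise_scale=0.05, rng_seed=40 + i)
    cov = covariance_from_replicates(sim.replicates)
    # paired design: both conditions share the fluctuation-matrix stream
    ensembles.append(run_ensemble(cov, mask, 1000, seed=99, pool_ids=model.pools))

dj = differential_jacobian(*[normalize_ensemble(e) for e in ensembles])
sig = entry_significance(*ensembles, alpha=0.05)

print("top 5 differential-Jacobian entries (effect_pool <- wrt_pool):")
for rank, (i, j, v) in enumerate(dj.ranked_entries()[:5], start=1):
    star = "*" if sig.significant[i, j] else " "
    print(f"  {rank}. dJ={v:5.2f}{star}  {control.pools[i]:20s} <- {control.pools[j]}")
print("(* = significant at alpha 0.05, Welch test on 100 batch medians)")
# dJ is |log2| of the normalized-Jacobian ratio: 1.0 means a two-fold
# change of the inferred interaction strength between conditions.
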