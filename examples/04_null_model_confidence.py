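"""Assigning confidence to epistasis estimates with the Poisson null model.

How much apparent epistasis does sequencing-sampling noise alone create?
The experiment is re-simulated 1000 times under a no-epistasis
assumption (Poisson resampling of counts, deterministic selection with
multiplicative fitness), and each observed epsilon is compared against
its simulated null distribution. Run on the sign-epistasis preset, the
injected negative V315A x A321G interaction should be flagged at 99%.
"""

import numpy as np

from epifit import (
    assign_confidence,
    filter_for_epistasis,
    focal_mutations,
    make_benchmark,
    marginal_fitness,
    pairwise_epistasis,
    simulate_null,
)

exp = make_benchmark("sign-epistasis", seed=3)
table = filter_for_epistasis(exp.table)
singles = [marginal_fitness(table, p, r) for p, r in focal_mutations(table.panel)]

eps = pairwise_epistasis(table)
null = simulate_null(table, singles, n_sims=1000, seed=30)
results = assign_confidence(eps, null)

flagged = results[results["sig_0.95"]]
print(f"pairs flagged at 95% confidence: {len(flagged)} / {len(results)}")
print(
    flagged[["locus_i", "res_i", "locus_j", "res_j", "epsilon", "confidence"]]
    .to_string(index=False)
)
# confidence is one-sided: the fraction of the 1000 no-epistasis
# simulations on the null side of the observed epsilon; under a true
# null the 95% flag fires for ~10% of pairs (both tails), so a seed may
# show a few false positives besides the injected pair

row = results[(results.locus_i == 315) & (results.locus_j == 321)].iloc[0]
print(f"\ninjected pair V315A x A321G: eps = {row.epsilon:+.3f}, "
      f"confidence = {row.confidence:.3f} (truth eps = -1.2)")
# the estimate is attenuated relative to the injected value because both
# single-mutation fitnesses are themselves averages over backgrounds that
# include the interacting partner — but the sign and significance survive
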