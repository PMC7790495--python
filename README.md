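# epifit

Fitness and pairwise-epistasis inference for combinatorial mutant
libraries under selection, from long-read enrichment sequencing.

## The problem

Directed-evolution experiments on the integron integrase IntI1 combine a
set of beneficial amino-acid substitutions to recover the enzyme's
ancestral double-strand (attI x attI) recombination activity. Combining
mutations rarely pays off multiplicatively: negative epistasis makes
stacked mutants far less active than their single-mutant effects
predict. To map these interactions, a combinatorial library carrying all
combinations of 13 focal substitutions (24,576 theoretical alleles — 11
binary loci plus degenerate codons GRM at position 319 and RRT at 320)
is subjected to selection cycles and sequenced with long reads at each
timepoint. `epifit` implements the complete analysis of such an
experiment for anyone running enrichment-sequencing screens over
designed combinatorial libraries.

## What it computes

Each read is aligned to the reference ORF, indels are repaired against
the reference (they are overwhelmingly technical artifacts of the
long-read chemistry), and the residues at the 13 focal codons are
translated into a 13-letter *allele-ID* per read. From allele-ID counts
at consecutive timepoints, the per-cycle **marginal fitness** of a focal
mutation *i* is the background-averaged log enrichment

W_i = ln[(mut_i^t1 / wt_i^t1) / (mut_i^t0 / wt_i^t0)],

where mut_i^t / wt_i^t are read counts of alleles carrying the mutation
vs the WT residue at that locus. **Pairwise epistasis** is the deviation
from log-additivity,

eps_ij = W_ij − (W_i + W_j),

with W_ij computed from double-carriers vs double-WT alleles. Because
sequencing depth alone creates apparent epistasis, significance comes
from a **Poisson-resampling null model**: the experiment is re-simulated
1000 times under multiplicative (no-epistasis) fitness, and each
observed eps_ij receives a one-sided empirical confidence against its
simulated null distribution. A separate module handles the
recombination-assay arm: fold changes from colony counts, the
multiplicative expectation E = prod(x_i) for combined mutations, and
delta-method error propagation for the expected-minus-observed epistasis.

A ground-truthed synthetic-data generator (`epifit.simulate`) emulates
the whole experiment — library composition with degenerate-codon draws
and ~40% off-target clones, deterministic selection, 0.3% per-base
sequencing error with indels — so every stage is testable against known
truth.

## Worked example

```python
import epifit as ef

exp = ef.make_benchmark("sign-epistasis", seed=3)     # synthetic, known truth
table = ef.filter_for_epistasis(exp.table)            # WT at 319/320, expected elsewhere
singles = [ef.marginal_fitness(table, p, r)
           for p, r in ef.focal_mutations(table.panel)]
eps = ef.pairwise_epistasis(table)                    # 55 pairs, t0 -> c1
null = ef.simulate_null(table, singles, n_sims=1000, seed=30)
res = ef.assign_confidence(eps, null)
row = res[(res.locus_i == 315) & (res.locus_j == 321)].iloc[0]
print(f"V315A x A321G: eps = {row.epsilon:+.3f}, confidence = {row.confidence:.3f}")
```

prints

```
V315A x A321G: eps = -0.265, confidence = 1.000
```

i.e. the injected sign-epistasis pair (V315A beneficial alone,
deleterious together with A321G) is recovered as significant negative
epistasis at >99.9% confidence; the magnitude is attenuated relative to
the injected −1.2 because single-mutation fitnesses are averaged over
backgrounds that include the interacting partner. The scripts under
`examples/` walk through each capability (library design, read curation,
fitness/epistasis estimation, null-model confidence, assay fold
changes) and print annotated output.

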