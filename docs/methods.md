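# Methods

This note documents the models and procedures implemented in `epifit`,
the parameter choices that matter, and what the synthetic-data tests do
and do not demonstrate about real data.

## Panel model and allele-IDs

A library is described by an ordered panel of focal loci (1-based
protein positions, strictly increasing). Each locus carries a WT residue
and one or more mutant residues; a locus may additionally record the
IUPAC degenerate codon used in the library primers, in which case the
codon's expansion must translate exactly to the allowed residue set
(stop codons are rejected at panel construction). The default panel is
the 13-substitution integrase set E103K, T118S, D161G, H162Q, S173R,
K219R, Y220N, D299E, V315A, G319E, G320D/N, A321G, A329T; positions 319
and 320 use the degenerate codons GRM and RRT, whose expansions include
the unintended residues D (319) and S (320). These unintended residues
are part of the designed alphabet — they count toward the
2^11 x 3 x 4 = 24,576 theoretical allele space — and the `unexpected`
flag is reserved for residues outside the codon design. Codon *i*
occupies ORF nucleotides 3i−2..3i; the reference ORF is 338 codons
(1014 bp) including the stop. An optional 14th locus (A234V) expresses
the off-target hotspot in the same machinery; the default panel omits
it.

The bundled reference ORF is synthetic: it carries the correct WT
residue at every focal codon (with GRM/RRT-compatible codons at
319/320) and fixed arbitrary sense codons elsewhere. Only the focal
codons and the reading frame matter to any computation; a real ORF can
be supplied as FASTA.

## Read curation

Reads are aligned to the reference with edlib (edit-distance alignment,
free end gaps on the reference, both orientations tried; identity
threshold 0.8 below which a read is `unalignable`). Unit-cost alignment
has a known failure mode here: a substitution can be represented as an
equal-cost insertion+deletion pair, and the subsequent indel repair
would then silently revert a real mutation to reference. Any read whose
edit path contains both insertions and deletions is therefore realigned
under scores that make gaps dearer than mismatches (match +1, mismatch
−1, gap open −2, gap extend −1, end gaps free), which restores the
substitution interpretation wherever one exists. This keeps the fast
aligner on the ~60% of reads where no ambiguity is possible.

Reads whose aligned reference span does not cover the first through
last focal codon are `too_short` and discarded. Indels are repaired
against the reference — extra read bases dropped, missing reference
bases filled in — justified by the persistence of indels even after
strong selection for an active enzyme (a frameshifted integrase would
not survive the cycles), which marks them as technical. Focal codons
containing repaired deletions consequently read as reference; the
curation report tracks indel incidence per timepoint. Quality scores
are ignored by default (consensus long reads carry little per-base
information at the ~0.3% residual error level); an optional
minimum-mean-quality filter exists for FASTQ input. Counting is per
read, with no duplicate/UMI logic.

Off-target codon mismatches are counted at the amino-acid level over
the covered ORF (silent changes excluded). The hotspot detector flags
positions whose substitution rate exceeds 5x the per-position median.
The default multiple is set by the arithmetic of the error background:
at 0.3% per-base error the per-codon background substitution rate is
~0.6–0.9% with ~2x Poisson scatter at usual depths, while a systematic
artifact carried by a few percent of clones sits at 5–10x the median.

## Fitness estimation

Read coverage is far too low to estimate full-haplotype fitness, so
mutation effects are marginal: aggregated over all genetic backgrounds.
This is valid when carrier and non-carrier background compositions are
similar — true in the initial library by construction (verified by the
`background_profile` total-variation check) and progressively violated
as selection reshapes backgrounds, which is why epistasis uses only the
first cycle; requesting a later interval emits a warning rather than an
error.

Before estimation, the table is filtered to alleles that are WT at loci
319/320 (their extra variability is a primer artifact, not biology) and
WT-or-expected-mutant everywhere else, leaving 11 focal mutations and
55 pairs on the default panel. W is the log ratio-of-ratios of mutant
to WT counts across the cycle; pair estimates use double-carriers vs
double-WT with mixed alleles in neither group. Aggregate counts receive
a pseudocount (default 0.5, added to each of the four aggregates)
before the log; with pseudocount 0, any zero aggregate yields a
flagged NaN rather than a silent drop. W is invariant to per-timepoint
depth rescaling. No multiple-testing correction is applied to the
per-pair confidences by default, matching the per-pair reporting
convention; users can correct downstream.

## Null model

Significance of eps_ij is assessed against sequencing-sampling noise
only: selection-step drift is neglected (enrichment populations are
large relative to library diversity) and off-target mutations are
invisible to allele-IDs, so confidences are upper bounds. Each of the
(default) 1000 replicates: (1) Poisson-resamples the observed t0 counts
(mean = observed count) to produce simulated true t0 frequencies;
(2) propagates one cycle with multiplicative fitness built from the
real single-mutation estimates, f' = f·w/mean(w); (3) Poisson-samples
t1 counts at the real t1 depth; (4) re-estimates all singles, pairs and
eps with the real t0 counts plus the simulated t1 counts, under the
same pseudocount policy as the real estimator. Replicate r draws from
an independent child stream of the run seed, so results are independent
of execution order. Replicates with undefined estimates are excluded
and counted, with a warning above 5%.

Confidence is the one-sided empirical tail in the direction of the
observed sign: for eps > 0 the fraction of simulated values below it,
for eps < 0 the fraction above; ties count half. Two consequences worth
stating plainly: confidence is confined to (0.5, 1] under a symmetric
null, and a flag at level c has a two-tailed nominal false-positive
rate of 2(1−c) — the 95% flag fires for ~10% of truly non-epistatic
pairs, the 99% flag for ~2%. The calibration tests verify exactly these
rates (measured 0.100 and 0.022 over 55 pairs x 20 synthetic
experiments).

## Assay arm

Recombination frequencies are recombinant/total colony ratios; fold
changes are ratios of replicate means with quotient-rule (delta-method)
standard errors. The no-epistasis expectation for combined mutations is
the product of single fold increases, E = prod(x_i), with first-order
error sigma_E = E·sqrt(sum (s_i/x_i)^2) — accurate while relative
errors stay below ~20% (verified against Monte-Carlo propagation).
Epistasis is expected minus observed fold, with
sigma_eps = sqrt(sigma_E^2 + s_O^2); the significance threshold is
k = 2 standard errors by default. On the log scale this epistasis is
consistent with the count-based definition: ln E − ln O = −eps when
fold changes are the linear counterparts of the log fitnesses (tested
identity). Bootstrap over replicates is available but not default —
with three replicates the delta method is the less noisy choice.

## Synthetic data

The generator emulates the study conditions end to end. Library: clones
drawn locus-independently, binary loci 50/50 WT/mutant at the codon
level, degenerate loci uniform over their codon expansions (so 319 is
G:1/2, E:1/4, D:1/4 and 320 is G/D/N/S each 1/4); 40% of clones carry
one off-target coding substitution at a uniform non-focal codon; an
optional hotspot parameter plants a systematic artifact (used to test
A234V-style detection). Fitness: ln w is additive in per-mutation
selection coefficients plus any injected pairwise terms. The preset
coefficients span −0.4..+0.9 per cycle with D161G, D299E and A321G
deleterious, matching the qualitative outcome of the experiment; the
sign-epistasis preset injects eps = −1.2 on V315A x A321G, enough to
make the double less fit than the A321G single. Selection: exact
deterministic propagation f' = f·w/mean(w) (no bottleneck noise, per
the large-population assumption); an optional multinomial bottleneck is
deliberately absent from presets. Sequencing: multinomial read draws at
the study's usable-read depths (67,179 / 21,622 / 31,694 / 18,907 for
t0/c1/c3/c6, used as configuration), 0.3% uniform per-base
substitution error (~3 errors per 1014 bp read), indels at 5x10^-4 per
base, random orientation.

Two fidelity levels: `sample_counts` draws allele-ID count tables
directly (exact, fast — the input the estimators consume), and
`sequence_reads` emits erroneous full-length reads for the curation
stage. Statistical studies (calibration, recovery, detection) run at
count level; read-level tests cover the curation round trip at hundreds
to thousands of reads per timepoint, a deliberate scale-down that
leaves per-read behaviour fully exercised.

What passing synthetic tests do *not* show about real data: the
generator has no 5'-UTR variation (UTR mutations in the study were
hitchhikers), no clone-identity error correlation beyond one off-target
per affected clone, no PCR chimeras, no quality-score structure, and
its selection is noiseless — so real-data confidences inherit the
upper-bound caveat of the null model rather than the near-exact
calibration seen here.

## Numerical choices and degenerate inputs

Pseudocount 0.5 on aggregates (0 = flagged NaN); identity threshold 0.8
for unalignable reads; frequency vectors validated to sum to 1 within
1e-9; empty timepoints, empty panels, zero totals and zero reference
frequencies raise errors naming the offender; confidence for eps
exactly 0 is 0.5 by symmetry; boundary confidence 1.0 is reported as-is
with n_sims recorded so users can read it as "> 1 − 1/n_sims".

## Known limitations

Marginal (background-averaged) epistasis estimates are attenuated when
the interaction partner segregates in the background (the recovered
V315A x A321G effect is ~−0.27 for an injected −1.2); sign and
significance are robust, magnitudes are conservative. Only pairwise
interactions are modelled; higher-order terms fold into the background
average. The null model conditions on observed t0 counts, which makes
mid-range p-values mildly conservative while leaving tail flag rates at
nominal.
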