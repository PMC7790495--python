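"""Panel definition, degenerate codons and the theoretical allele space.

The combinatorial library mixes 13 focal substitutions of the integrase.
Two loci were built with degenerate primers (GRM at 319, RRT at 320),
which widen the residue alphabet beyond the intended mutations and set
the size of the theoretical allele space.
"""

from epifit import allele_distance, default_panel, enumerate_allele_space, expand_degenerate_codon

panel = default_panel()
print(f"panel: {len(panel)} loci at positions {panel.positions}")
print(f"WT allele-ID: {panel.wt_allele_id}")

for codon in ("GRM", "RRT"):
    pairs = sorted(expand_degenerate_codon(codon))
    residues = sorted({r for _, r in pairs})
    print(f"{codon} expands to {[c for c, _ in pairs]} -> residues {residues}")

count, alleles = enumerate_allele_space(panel)
print(f"theoretical allele space: {count} allele-IDs")
# 2^11 binary loci x 3 residues at 319 x 4 at 320 = 24,576: every
# combination the degenerate-primer design can physically produce.

example = next(a for a in alleles if a != panel.wt_allele_id)
d = allele_distance(panel.wt_allele_id, example)
print(f"first non-WT allele {example} is {d} mutation(s) away from WT")
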