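"""Reference ORF handling.

The analysis needs the integrase coding sequence so that focal codons can
be located and reads compared codon-by-codon. Any 1014 bp ORF can be
supplied as FASTA; for self-contained simulation and testing this module
builds a synthetic ORF that carries the correct WT residue at every focal
codon (with GRM/RRT-compatible codons at 319/320) and arbitrary but fixed
codons elsewhere. Codon *i* (1-based) occupies ORF nucleotides
``3i-2 .. 3i``; the ORF is 338 codons = 1014 bp including the stop.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .panel import LociPanel, default_panel

__all__ = [
    "ORF_CODONS",
    "ORF_LENGTH",
    "synthetic_reference_orf",
    "load_reference",
    "write_reference",
    "codon_slice",
    "preferred_codon",
]

ORF_CODONS = 338  # includes the stop codon
ORF_LENGTH = 3 * ORF_CODONS  # 1014 bp

_SENSE_CODONS = [
    "".join(c)
    for c in __import__("itertools").product("ACGT", repeat=3)
    if str(Seq("".join(c)).translate()) != "*"
]

# Fixed WT codons at the focal loci of the default panel. 319/320 use
# codons from the degenerate-primer expansions (GRM, RRT).
_FOCAL_WT_CODONS = {
    103: "GAA",  # E
    118: "ACT",  # T
    161: "GAT",  # D
    162: "CAT",  # H
    173: "AGC",  # S
    219: "AAA",  # K
    220: "TAT",  # Y
    234: "GCA",  # A (off-target hotspot position)
    299: "GAC",  # D
    315: "GTT",  # V
    319: "GGC",  # G, within GRM
    320: "GGT",  # G, within RRT
    321: "GCT",  # A
    329: "GCC",  # A
}


def codon_slice(protein_position: int) -> slice:
    """0-based ORF slice of the codon at a 1-based protein position."""
    if not 1 <= protein_position <= ORF_CODONS:
        raise ValueError(f"protein position {protein_position} outside ORF")
    start = 3 * (protein_position - 1)
    return slice(start, start + 3)


def synthetic_reference_orf(panel: LociPanel | None = None) -> str:
    """Deterministic synthetic 1014 bp ORF consistent with the panel.

    Synthetic stand-in for the real integrase gene: codon identities away
    from the focal loci are arbitrary (fixed RNG), only the focal codons
    and the reading frame matter to the pipeline.
    """
    panel = panel or default_panel()
    rng = np.random.default_rng(10141)
    codons = ["ATG"]
    codons += [_SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), ORF_CODONS - 2)]
    codons.append("TAA")
    for pos, codon in _FOCAL_WT_CODONS.items():
        codons[pos - 1] = codon
    orf = "".join(codons)
    for locus in panel:
        expected = locus.wt_residue
        got = str(Seq(orf[codon_slice(locus.protein_position)]).translate())
        if got != expected:
            raise AssertionError(
                f"synthetic ORF codon {locus.protein_position} translates to "
                f"{got}, panel expects {expected}"
            )
    return orf


def preferred_codon(protein_position: int, residue: str, reference: str) -> str:
    """A codon for `residue` minimising nucleotide changes vs the reference codon."""
    ref_codon = reference[codon_slice(protein_position)]
    candidates = [c for c in _SENSE_CODONS if str(Seq(c).translate()) == residue]
    if not candidates:
        raise ValueError(f"no sense codon encodes residue {residue!r}")
    return min(candidates, key=lambda c: (sum(a != b for a, b in zip(c, ref_codon)), c))


def load_reference(path: str | Path) -> tuple[str, str]:
    """Read the first record of a FASTA file; returns (id, sequence)."""
    record = next(SeqIO.parse(str(path), "fasta"))
    return record.id, str(record.seq).upper()


def write_reference(path: str | Path, sequence: str, name: str = "reference") -> None:
    SeqIO.write([SeqRecord(Seq(sequence), id=name, description="")], str(path), "fasta")
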