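"""Focal-mutation panel: loci, degenerate codons, and the allele-ID alphabet.

A combinatorial mutant library is described by an ordered panel of focal
loci on the protein. Each locus has a wild-type residue and one or more
allowed mutant residues, optionally realised through a degenerate codon in
the library primers. The residues observed at the focal loci of a single
haplotype, concatenated in panel order, form its *allele-ID* — the central
observable of the whole analysis.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

__all__ = [
    "LocusSpec",
    "LociPanel",
    "AlleleID",
    "expand_degenerate_codon",
    "enumerate_allele_space",
    "allele_distance",
    "default_panel",
    "FLAG_WT",
    "FLAG_MUT",
    "FLAG_UNEXPECTED",
]

FLAG_WT = "expected_wt"
FLAG_MUT = "expected_mut"
FLAG_UNEXPECTED = "unexpected"


def expand_degenerate_codon(codon: str) -> set[tuple[str, str]]:
    """Expand an IUPAC degenerate codon into (DNA codon, residue) pairs.

    Returns the full Cartesian expansion under the standard genetic code.
    Stop codons are included in the expansion (residue ``*``); callers that
    forbid them must check.

    >>> sorted(expand_degenerate_codon("GRM"))
    [('GAA', 'E'), ('GAC', 'D'), ('GGA', 'G'), ('GGC', 'G')]
    """
    codon = codon.upper()
    if len(codon) != 3:
        raise ValueError(f"codon must have length 3, got {codon!r}")
    try:
        choices = [ambiguous_dna_values[b] for b in codon]
    except KeyError as exc:
        raise ValueError(f"non-IUPAC symbol in codon {codon!r}") from exc
    return {
        ("".join(bases), str(Seq("".join(bases)).translate()))
        for bases in itertools.product(*choices)
    }


@dataclass(frozen=True)
class LocusSpec:
    """One focal locus: 1-based protein position, WT and mutant residues.

    If ``degenerate_codon`` is given, its expansion must translate exactly
    to ``{wt_residue} | mutant_residues`` with no stop codons.
    """

    protein_position: int
    wt_residue: str
    mutant_residues: frozenset[str]
    degenerate_codon: str | None = None

    def __post_init__(self) -> None:
        if self.protein_position < 1:
            raise ValueError("protein_position is 1-based and must be >= 1")
        muts = frozenset(self.mutant_residues)
        object.__setattr__(self, "mutant_residues", muts)
        if not muts:
            raise ValueError("at least one mutant residue is required")
        if self.wt_residue in muts:
            raise ValueError(
                f"WT residue {self.wt_residue} listed among mutants at "
                f"position {self.protein_position}"
            )
        if self.degenerate_codon is not None:
            residues = {res for _, res in expand_degenerate_codon(self.degenerate_codon)}
            if "*" in residues:
                raise ValueError(
                    f"degenerate codon {self.degenerate_codon} at position "
                    f"{self.protein_position} expands to a stop codon"
                )
            if residues != self.allowed_residues:
                raise ValueError(
                    f"degenerate codon {self.degenerate_codon} expands to "
                    f"{sorted(residues)}, panel allows {sorted(self.allowed_residues)}"
                )

    @property
    def allowed_residues(self) -> frozenset[str]:
        return self.mutant_residues | {self.wt_residue}

    def classify(self, residue: str) -> str:
        if residue == self.wt_residue:
            return FLAG_WT
        if residue in self.mutant_residues:
            return FLAG_MUT
        return FLAG_UNEXPECTED


@dataclass(frozen=True)
class LociPanel:
    """Ordered panel of focal loci; defines the allele-ID string.

    Loci are kept in ascending protein position so that string index i of
    an allele-ID always refers to ``loci[i]``.
    """

    loci: tuple[LocusSpec, ...]
    reference_id: str = "reference"

    def __post_init__(self) -> None:
        object.__setattr__(self, "loci", tuple(self.loci))
        if not self.loci:
            raise ValueError("panel must contain at least one locus")
        positions = [l.protein_position for l in self.loci]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError("loci must be strictly increasing in protein position")

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self) -> Iterator[LocusSpec]:
        return iter(self.loci)

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(l.protein_position for l in self.loci)

    @property
    def wt_allele_id(self) -> str:
        return "".join(l.wt_residue for l in self.loci)

    def index_of(self, protein_position: int) -> int:
        for i, l in enumerate(self.loci):
            if l.protein_position == protein_position:
                return i
        raise KeyError(f"position {protein_position} not in panel")

    def locus(self, protein_position: int) -> LocusSpec:
        return self.loci[self.index_of(protein_position)]

    def flags(self, allele_id: str) -> tuple[str, ...]:
        """Per-locus flag (expected_wt / expected_mut / unexpected)."""
        if len(allele_id) != len(self.loci):
            raise ValueError(
                f"allele-ID length {len(allele_id)} != panel size {len(self.loci)}"
            )
        return tuple(l.classify(r) for l, r in zip(self.loci, allele_id))

    def is_expected(self, allele_id: str) -> bool:
        return FLAG_UNEXPECTED not in self.flags(allele_id)

    # ---- config file round trip -------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        lines = ["position\twt\tmutants\tcodon"]
        for l in self.loci:
            lines.append(
                f"{l.protein_position}\t{l.wt_residue}\t"
                f"{','.join(sorted(l.mutant_residues))}\t{l.degenerate_codon or ''}"
            )
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path, reference_id: str = "reference") -> "LociPanel":
        loci = []
        lines = Path(path).read_text().splitlines()
        header = lines[0].rstrip("\n").split("\t")
        cols = {name: i for i, name in enumerate(header)}
        for line in lines[1:]:
            if not line.strip():
                continue
            fields = line.split("\t")
            loci.append(
                LocusSpec(
                    protein_position=int(fields[cols["position"]]),
                    wt_residue=fields[cols["wt"]],
                    mutant_residues=frozenset(fields[cols["mutants"]].split(",")),
                    degenerate_codon=fields[cols["codon"]].strip() or None
                    if "codon" in cols and len(fields) > cols["codon"]
                    else None,
                )
            )
        return cls(loci=tuple(loci), reference_id=reference_id)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "reference_id": self.reference_id,
            "loci": [
                {
                    "position": l.protein_position,
                    "wt": l.wt_residue,
                    "mutants": sorted(l.mutant_residues),
                    "codon": l.degenerate_codon,
                }
                for l in self.loci
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "LociPanel":
        payload = json.loads(Path(path).read_text())
        return cls(
            loci=tuple(
                LocusSpec(
                    protein_position=d["position"],
                    wt_residue=d["wt"],
                    mutant_residues=frozenset(d["mutants"]),
                    degenerate_codon=d.get("codon"),
                )
                for d in payload["loci"]
            ),
            reference_id=payload.get("reference_id", "reference"),
        )


@dataclass(frozen=True)
class AlleleID:
    """An allele-ID string with its per-locus flags resolved against a panel.

    Most APIs accept and return plain strings; this wrapper is for when
    the expected/unexpected classification needs to travel with the ID.
    """

    residues: str
    flags: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.residues) != len(self.flags):
            raise ValueError("one flag per residue is required")

    def __str__(self) -> str:
        return self.residues

    @property
    def is_expected(self) -> bool:
        return FLAG_UNEXPECTED not in self.flags

    @classmethod
    def from_string(cls, residues: str, panel: "LociPanel") -> "AlleleID":
        return cls(residues=residues, flags=panel.flags(residues))


def enumerate_allele_space(panel: LociPanel) -> tuple[int, Iterator[str]]:
    """Count and lazily enumerate every allele-ID the panel allows.

    The count is the product over loci of |{WT} ∪ mutants|; the iterator
    yields each allele-ID exactly once, in lexicographic order of the
    per-locus residue choices.
    """
    alphabets = [sorted(l.allowed_residues) for l in panel]
    count = 1
    for a in alphabets:
        count *= len(a)
    iterator = ("".join(combo) for combo in itertools.product(*alphabets))
    return count, iterator


def allele_distance(a: str, b: str) -> int:
    """Hamming distance between two allele-IDs over the same panel."""
    if len(a) != len(b):
        raise ValueError(f"allele-ID length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


# The 13 focal substitutions combined in the integrase library. Loci 319
# and 320 were built with degenerate primers (GRM, RRT) whose expansions
# include the unintended D (at 319) and S (at 320); those residues are part
# of the designed alphabet and count toward the 24,576-allele space.
_DEFAULT_LOCI = (
    (103, "E", "K", None),
    (118, "T", "S", None),
    (161, "D", "G", None),
    (162, "H", "Q", None),
    (173, "S", "R", None),
    (219, "K", "R", None),
    (220, "Y", "N", None),
    (299, "D", "E", None),
    (315, "V", "A", None),
    (319, "G", "ED", "GRM"),
    (320, "G", "DNS", "RRT"),
    (321, "A", "G", None),
    (329, "A", "T", None),
)

# Off-target hotspot seen late in selection; not part of the default panel
# but expressible with the same machinery.
A234V_LOCUS = LocusSpec(protein_position=234, wt_residue="A", mutant_residues=frozenset("V"))


def default_panel(include_a234v: bool = False, reference_id: str = "intI1_synthetic") -> LociPanel:
    """The 13-locus integrase panel (optionally with the A234V hotspot).

    WT allele-ID is ``ETDHSKYDVGGAA``; the theoretical allele space is
    2^11 x 3 x 4 = 24,576.
    """
    loci = [
        LocusSpec(pos, wt, frozenset(muts), codon)
        for pos, wt, muts, codon in _DEFAULT_LOCI
    ]
    if include_a234v:
        loci.append(A234V_LOCUS)
        loci.sort(key=lambda l: l.protein_position)
    return LociPanel(loci=tuple(loci), reference_id=reference_id)
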