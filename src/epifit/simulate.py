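"""Ground-truthed synthetic selection-sequencing experiments.

Emulates the combinatorial-library experiment end to end so every
pipeline stage can be tested against known truth:

* a pre-selection library with an even WT/mutant draw at each binary
  locus and uniform degenerate-codon draws at loci 319 (GRM) and 320
  (RRT), with ~40% of clones carrying one off-target coding mutation;
* multiplicative genotype fitness from per-mutation selection
  coefficients (ln scale), with optional injected pairwise epistasis —
  including a sign-epistasis preset in which V315A is beneficial alone
  but deleterious together with A321G;
* deterministic frequency propagation across selection cycles (the
  enrichment population is large relative to library diversity, so
  selection-step drift is neglected);
* sequencing as multinomial read sampling at configured per-timepoint
  depths, with ~0.3% per-base substitution error plus rare indels and
  random read orientation.

Two fidelity levels are offered: :func:`sample_counts` draws allele-ID
count tables directly (exact, fast — what the estimators and null model
consume), and :func:`sequence_reads` emits full-length erroneous reads
for exercising the curation stage.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .counts import CountTable
from .curation import ReadRecord
from .panel import LociPanel, default_panel, expand_degenerate_codon
from .reference import codon_slice, preferred_codon, synthetic_reference_orf, write_reference

__all__ = [
    "TruthModel",
    "SyntheticExperiment",
    "design_frequencies",
    "generate_library",
    "assign_true_fitness",
    "run_selection",
    "sample_counts",
    "sequence_reads",
    "make_benchmark",
    "PRESETS",
]

# Per-cycle selection coefficients (ln scale) used by the presets. Signs
# follow the qualitative outcome of the experiment: most focal mutations
# are beneficial across backgrounds; D161G, D299E and A321G are not.
DEFAULT_SELECTION: dict[tuple[int, str], float] = {
    (103, "K"): 0.8,
    (118, "S"): 0.5,
    (161, "G"): -0.2,
    (162, "Q"): 0.4,
    (173, "R"): 0.9,
    (219, "R"): 0.3,
    (220, "N"): 0.6,
    (299, "E"): -0.1,
    (315, "A"): 0.5,
    (319, "E"): 0.4,
    (319, "D"): 0.0,
    (320, "D"): 0.3,
    (320, "N"): 0.6,
    (320, "S"): 0.0,
    (321, "G"): -0.4,
    (329, "T"): 0.2,
}

# Usable-read depths of the real experiment, used as preset configuration.
STUDY_TIMEPOINTS: dict[str, tuple[int, int]] = {
    "t0": (0, 67179),
    "c1": (1, 21622),
    "c3": (3, 31694),
    "c6": (6, 18907),
}

SIGN_EPISTASIS_PAIR = ((315, "A"), (321, "G"))


@dataclass(frozen=True)
class TruthModel:
    """Complete generative description of a synthetic experiment."""

    panel: LociPanel
    #: per locus: residue -> design frequency in the pre-selection library
    design: dict[int, dict[str, float]]
    #: (position, residue) -> selection coefficient, ln scale per cycle
    selection: dict[tuple[int, str], float]
    #: ((pos_i, res_i), (pos_j, res_j)) -> injected pairwise epistasis (ln)
    epistasis: dict[tuple[tuple[int, str], tuple[int, str]], float] = field(default_factory=dict)
    #: label -> (cycle index, read depth)
    timepoints: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(STUDY_TIMEPOINTS)
    )
    offtarget_rate: float = 0.4  # fraction of clones with one off-target mutation
    per_base_error: float = 0.003  # residual consensus substitution rate
    indel_rate: float = 0.0005  # per-base indel rate in raw reads
    #: optional systematic artifact: (protein position, mutant codon, clone fraction)
    hotspot: tuple[int, str, float] | None = None

    def __post_init__(self) -> None:
        for pos, freqs in self.design.items():
            if not np.isclose(sum(freqs.values()), 1.0):
                raise ValueError(f"design frequencies at locus {pos} do not sum to 1")
        for rate in (self.offtarget_rate, self.per_base_error, self.indel_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")

    @property
    def n_cycles(self) -> int:
        return max(cycle for cycle, _ in self.timepoints.values())


def _default_design(panel: LociPanel) -> dict[int, dict[str, float]]:
    """Even WT/mutant split per binary locus; uniform codon draw at 319/320."""
    design: dict[int, dict[str, float]] = {}
    for locus in panel:
        if locus.degenerate_codon:
            codons = sorted(expand_degenerate_codon(locus.degenerate_codon))
            freqs: dict[str, float] = {}
            for _, res in codons:
                freqs[res] = freqs.get(res, 0.0) + 1.0 / len(codons)
            design[locus.protein_position] = freqs
        else:
            muts = sorted(locus.mutant_residues)
            freqs = {locus.wt_residue: 0.5}
            for m in muts:
                freqs[m] = 0.5 / len(muts)
            design[locus.protein_position] = freqs
    return design


def design_frequencies(truth: TruthModel) -> pd.Series:
    """Expected pre-selection frequency of every allele-ID (locus independence)."""
    alphabets = [sorted(l.allowed_residues) for l in truth.panel]
    positions = truth.panel.positions
    ids = []
    freqs = []
    for combo in itertools.product(*alphabets):
        ids.append("".join(combo))
        f = 1.0
        for pos, res in zip(positions, combo):
            f *= truth.design[pos].get(res, 0.0)
        freqs.append(f)
    s = pd.Series(freqs, index=ids)
    return s / s.sum()


def assign_true_fitness(truth: TruthModel, allele_id: str) -> float:
    """Linear-scale fitness: ln w = sum of member coefficients + member-pair epistasis."""
    members = {
        (pos, res)
        for pos, res in zip(truth.panel.positions, allele_id)
        if res != truth.panel.locus(pos).wt_residue
    }
    ln_w = sum(truth.selection.get(m, 0.0) for m in members)
    for (mi, mj), eps in truth.epistasis.items():
        if mi in members and mj in members:
            ln_w += eps
    return float(np.exp(ln_w))


def true_fitness_vector(truth: TruthModel, allele_ids: pd.Index) -> pd.Series:
    return pd.Series([assign_true_fitness(truth, a) for a in allele_ids], index=allele_ids)


def run_selection(
    f0: pd.Series, truth: TruthModel, n_cycles: int | None = None
) -> pd.DataFrame:
    """Deterministic frequency trajectories over selection cycles.

    Columns are cycles 0..n; each column sums to 1. No bottleneck noise
    is applied (large enrichment populations), so the update is exactly
    f_{c+1} = f_c w / mean(w).
    """
    n_cycles = truth.n_cycles if n_cycles is None else n_cycles
    w = true_fitness_vector(truth, f0.index).to_numpy()
    freqs = [f0 / f0.sum()]
    for _ in range(n_cycles):
        fw = freqs[-1].to_numpy() * w
        freqs.append(pd.Series(fw / fw.sum(), index=f0.index))
    return pd.DataFrame({c: f for c, f in enumerate(freqs)})


def generate_library(
    truth: TruthModel, n_clones: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw the physical pre-selection library, clone by clone.

    Each clone's focal codons are drawn locus-independently from the
    design (codon-level at degenerate loci); with probability
    ``offtarget_rate`` the clone additionally carries one off-target
    coding substitution at a uniformly chosen non-focal codon. Returns a
    clone table with columns allele_id, codons (tuple, one per locus),
    offtarget_position (0 when absent), offtarget_codon.
    """
    if n_clones <= 0:
        raise ValueError("n_clones must be positive")
    panel = truth.panel
    reference = synthetic_reference_orf(panel)
    # per-locus codon pools and probabilities
    pools: list[tuple[list[str], list[str], np.ndarray]] = []
    for locus in panel:
        pos = locus.protein_position
        if locus.degenerate_codon:
            expansion = sorted(expand_degenerate_codon(locus.degenerate_codon))
            codons = [c for c, _ in expansion]
            residues = [r for _, r in expansion]
            probs = np.full(len(codons), 1.0 / len(codons))
        else:
            codons, residues, p = [], [], []
            for res, f in sorted(truth.design[pos].items()):
                codons.append(
                    reference[codon_slice(pos)]
                    if res == locus.wt_residue
                    else preferred_codon(pos, res, reference)
                )
                residues.append(res)
                p.append(f)
            probs = np.asarray(p)
        pools.append((codons, residues, probs))

    choices = np.column_stack(
        [rng.choice(len(c), size=n_clones, p=p) for c, _, p in pools]
    )
    allele_ids = [
        "".join(pools[i][1][choices[k, i]] for i in range(len(pools)))
        for k in range(n_clones)
    ]
    codon_tuples = [
        tuple(pools[i][0][choices[k, i]] for i in range(len(pools)))
        for k in range(n_clones)
    ]

    focal = set(panel.positions)
    non_focal = [p for p in range(2, 338) if p not in focal]  # skip start/stop codons
    off_pos = np.zeros(n_clones, dtype=int)
    off_codon = [""] * n_clones
    has_off = rng.random(n_clones) < truth.offtarget_rate
    sense = _sense_codon_table()
    for k in np.flatnonzero(has_off):
        pos = int(rng.choice(non_focal))
        ref_codon = reference[codon_slice(pos)]
        ref_res = sense[ref_codon]
        alternatives = [c for c, r in sense.items() if r not in (ref_res, "*")]
        off_pos[k] = pos
        off_codon[k] = alternatives[int(rng.integers(len(alternatives)))]
    if truth.hotspot is not None:
        pos, codon, fraction = truth.hotspot
        hot = rng.random(n_clones) < fraction
        off_pos[hot] = pos
        for k in np.flatnonzero(hot):
            off_codon[k] = codon
    return pd.DataFrame(
        {
            "allele_id": allele_ids,
            "codons": codon_tuples,
            "offtarget_position": off_pos,
            "offtarget_codon": off_codon,
        }
    )


def _sense_codon_table() -> dict[str, str]:
    from Bio.Seq import Seq

    return {
        "".join(c): str(Seq("".join(c)).translate())
        for c in itertools.product("ACGT", repeat=3)
    }


def sample_counts(
    truth: TruthModel,
    rng: np.random.Generator,
    f0: pd.Series | None = None,
) -> tuple[CountTable, pd.DataFrame]:
    """Multinomial allele-ID counts at every configured timepoint.

    The sequencing of each timepoint is a multinomial draw at its depth
    from the deterministic true frequencies of that cycle. Returns the
    count table and the true frequency trajectory. This is the exact
    count-level view (zero sequencing error), suitable for estimator and
    null-model studies.
    """
    f0 = design_frequencies(truth) if f0 is None else f0 / f0.sum()
    traj = run_selection(f0, truth)
    counts = {}
    for label, (cycle, depth) in truth.timepoints.items():
        drawn = rng.multinomial(depth, traj[cycle].to_numpy())
        nz = drawn > 0
        counts[label] = dict(zip(traj.index[nz], drawn[nz]))
    return CountTable.from_counts(counts, panel=truth.panel), traj


def _clone_sequence(
    clone: pd.Series, truth: TruthModel, reference: str
) -> str:
    seq = list(reference)
    for locus, codon in zip(truth.panel, clone["codons"]):
        seq[codon_slice(locus.protein_position)] = codon
    if clone["offtarget_position"]:
        seq[codon_slice(int(clone["offtarget_position"]))] = clone["offtarget_codon"]
    return "".join(seq)


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def sequence_reads(
    library: pd.DataFrame,
    truth: TruthModel,
    rng: np.random.Generator,
) -> dict[str, list[ReadRecord]]:
    """Simulate sequencing reads for every timepoint from a clone library.

    Clone frequencies are propagated through the selection cycles using
    each clone's true allele-ID fitness, then reads are drawn multinomially
    at each timepoint's depth. Substitutions are injected per base at
    ``per_base_error``, indels at ``indel_rate`` (equal insertion and
    deletion probability), and each read has a random orientation. Read
    ids encode the source clone for truth tracking: ``<tp>_<n>/<clone>``.
    """
    reference = synthetic_reference_orf(truth.panel)
    sequences = [_clone_sequence(c, truth, reference) for _, c in library.iterrows()]
    w = np.array([assign_true_fitness(truth, a) for a in library["allele_id"]])
    f = np.full(len(library), 1.0 / len(library))
    freq_by_cycle = {0: f}
    for cycle in range(1, truth.n_cycles + 1):
        fw = freq_by_cycle[cycle - 1] * w
        freq_by_cycle[cycle] = fw / fw.sum()

    out: dict[str, list[ReadRecord]] = {}
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for label, (cycle, depth) in truth.timepoints.items():
        reads: list[ReadRecord] = []
        clone_draws = rng.multinomial(depth, freq_by_cycle[cycle])
        n = 0
        for clone_idx in np.flatnonzero(clone_draws):
            template = np.frombuffer(sequences[clone_idx].encode(), dtype=np.uint8)
            for _ in range(clone_draws[clone_idx]):
                seq = template.copy()
                # substitutions
                hits = np.flatnonzero(rng.random(len(seq)) < truth.per_base_error)
                for h in hits:
                    seq[h] = rng.choice(bases[bases != seq[h]])
                read = seq.tobytes().decode()
                # indels
                n_indel = rng.poisson(truth.indel_rate * len(read))
                for _ in range(n_indel):
                    at = int(rng.integers(len(read)))
                    if rng.random() < 0.5:
                        read = read[:at] + "ACGT"[rng.integers(4)] + read[at:]
                    else:
                        read = read[:at] + read[at + 1 :]
                if rng.random() < 0.5:
                    read = read.translate(_COMPLEMENT)[::-1]
                reads.append(ReadRecord(read_id=f"{label}_{n}/{clone_idx}", sequence=read))
                n += 1
        out[label] = reads
    return out


@dataclass(frozen=True)
class SyntheticExperiment:
    """A complete benchmark: truth model, trajectories, counts, truth tables."""

    truth: TruthModel
    trajectory: pd.DataFrame  # true allele frequencies per cycle
    table: CountTable  # sampled allele-ID counts per timepoint
    true_single_W: pd.DataFrame  # per focal mutation: truth coefficient
    true_epistasis: pd.DataFrame  # per injected pair: epsilon_true

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.table.to_tsv(outdir / "counts.tsv")
        self.truth.panel.to_tsv(outdir / "panel.tsv")
        self.true_single_W.to_csv(outdir / "truth_singles.tsv", sep="\t", index=False)
        self.true_epistasis.to_csv(outdir / "truth_epistasis.tsv", sep="\t", index=False)
        write_reference(
            outdir / "reference.fa",
            synthetic_reference_orf(self.truth.panel),
            name=self.truth.panel.reference_id,
        )


def _preset_truth(name: str) -> TruthModel:
    panel = default_panel()
    base = dict(
        panel=panel,
        design=_default_design(panel),
        selection=dict(DEFAULT_SELECTION),
        timepoints={"t0": STUDY_TIMEPOINTS["t0"], "c1": STUDY_TIMEPOINTS["c1"]},
    )
    if name == "null":
        return TruthModel(**base)
    if name == "sign-epistasis":
        return TruthModel(**base, epistasis={SIGN_EPISTASIS_PAIR: -1.2})
    if name == "study-like":
        return TruthModel(**{**base, "timepoints": dict(STUDY_TIMEPOINTS)})
    raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")


PRESETS = ("null", "study-like", "sign-epistasis")


def make_benchmark(
    preset: str, seed: int, outdir: str | Path | None = None
) -> SyntheticExperiment:
    """Build a fully reproducible synthetic experiment from a named preset.

    Presets: ``null`` (multiplicative truth, t0/c1 at the real usable-read
    depths), ``study-like`` (all four timepoints), ``sign-epistasis``
    (``null`` plus an injected negative V315A x A321G interaction strong
    enough to invert the sign of V315A in the A321G background). The same
    (preset, seed) always yields identical outputs.
    """
    truth = _preset_truth(preset)
    rng = np.random.default_rng(seed)
    table, traj = sample_counts(truth, rng)
    singles = pd.DataFrame(
        [
            {"locus": pos, "residue": res, "W_true": s}
            for (pos, res), s in sorted(truth.selection.items())
        ]
    )
    eps = pd.DataFrame(
        [
            {
                "locus_i": mi[0], "res_i": mi[1],
                "locus_j": mj[0], "res_j": mj[1],
                "epsilon_true": e,
            }
            for (mi, mj), e in truth.epistasis.items()
        ],
        columns=["locus_i", "res_i", "locus_j", "res_j", "epsilon_true"],
    )
    experiment = SyntheticExperiment(
        truth=truth, trajectory=traj, table=table,
        true_single_W=singles, true_epistasis=eps,
    )
    if outdir is not None:
        experiment.write(outdir)
    return experiment
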