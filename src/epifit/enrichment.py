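"""Marginal fitness and pairwise epistasis from enrichment counts.

Read coverage of a combinatorial library is far too low to estimate the
fitness of complete haplotypes, so mutation effects are measured
*marginally*: the fitness of a focal mutation is the log change, across
one enrichment cycle, of the ratio between all reads carrying the
mutation and all reads carrying the WT residue at that locus,

    W_i = ln[(mut_i^t1 / wt_i^t1) / (mut_i^t0 / wt_i^t0)],

with counts aggregated over all genetic backgrounds. This is valid when
the background composition of carriers and non-carriers is the same —
true in the initial library by construction, and increasingly violated as
selection reshapes backgrounds, which is why only the first cycle
(t0 -> t1) is used for epistasis. Pair fitness W_ij uses alleles carrying
both mutations vs alleles WT at both loci (mixed alleles belong to
neither group), and pairwise epistasis is

    eps_ij = W_ij - (W_i + W_j).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counts import CountTable
from .panel import FLAG_MUT, FLAG_WT, LociPanel

__all__ = [
    "MarginalFitness",
    "filter_for_epistasis",
    "focal_mutations",
    "marginal_fitness",
    "pair_fitness",
    "pairwise_epistasis",
    "background_profile",
    "position_composition",
    "diversity_trajectory",
    "mutation_masks",
    "batch_fitness",
]

DEFAULT_PSEUDOCOUNT = 0.5
#: loci whose unintended degenerate-primer variability forces a WT-only filter
DEFAULT_WT_ONLY_POSITIONS = (319, 320)


@dataclass(frozen=True)
class MarginalFitness:
    """W for a focal mutation (or mutation pair) with its count support."""

    locus: tuple[int, ...]
    residue: tuple[str, ...]
    W: float  # natural-log relative fitness; NaN when undefined
    mut_t0: int
    wt_t0: int
    mut_t1: int
    wt_t1: int
    pseudocount: float

    @property
    def defined(self) -> bool:
        return bool(np.isfinite(self.W))


def filter_for_epistasis(
    table: CountTable,
    wt_only_positions: tuple[int, ...] = DEFAULT_WT_ONLY_POSITIONS,
) -> CountTable:
    """Restrict to alleles usable for the epistasis analysis.

    Keeps alleles that are WT at ``wt_only_positions`` (loci whose extra
    residues are degenerate-primer artifacts) and WT-or-expected-mutant
    everywhere else. With the default 13-locus panel this leaves 11 focal
    mutations, hence 55 unordered pairs.
    """
    panel = table.panel
    wt_only = {panel.index_of(p) for p in wt_only_positions}
    keep = []
    for allele in table.df.index:
        flags = panel.flags(allele)
        ok = all(
            f == FLAG_WT if i in wt_only else f in (FLAG_WT, FLAG_MUT)
            for i, f in enumerate(flags)
        )
        if ok:
            keep.append(allele)
    if not keep:
        raise ValueError("no alleles left after the epistasis filter")
    return table.subset(keep)


def focal_mutations(
    panel: LociPanel,
    exclude_positions: tuple[int, ...] = DEFAULT_WT_ONLY_POSITIONS,
) -> list[tuple[int, str]]:
    """(position, mutant residue) for every focal mutation kept in the analysis."""
    out = []
    for locus in panel:
        if locus.protein_position in exclude_positions:
            continue
        for res in sorted(locus.mutant_residues):
            out.append((locus.protein_position, res))
    return out


# ---------------------------------------------------------------------
# vectorised core, shared with the null-model simulator


def mutation_masks(
    allele_ids: pd.Index,
    panel: LociPanel,
    mutations: list[tuple],
) -> tuple[np.ndarray, np.ndarray]:
    """Carrier / WT-reference masks per mutation (or mutation pair).

    ``mutations`` items are ((pos, res)) singles or ((pos_i, res_i),
    (pos_j, res_j)) pairs. Returns boolean arrays of shape
    (n_alleles, n_mutations): carrier requires the mutant residue at every
    member locus, reference requires the WT residue at every member locus;
    mixed alleles are in neither.
    """
    residues = np.array([list(a) for a in allele_ids])
    mut_mask = np.ones((len(allele_ids), len(mutations)), dtype=bool)
    wt_mask = np.ones_like(mut_mask)
    for g, members in enumerate(mutations):
        if isinstance(members[0], int):  # a bare (pos, res) single
            members = (members,)
        for pos, res in members:
            i = panel.index_of(pos)
            mut_mask[:, g] &= residues[:, i] == res
            wt_mask[:, g] &= residues[:, i] == panel.loci[i].wt_residue
    return mut_mask, wt_mask


def batch_fitness(
    counts_t0: np.ndarray,
    counts_t1: np.ndarray,
    mut_mask: np.ndarray,
    wt_mask: np.ndarray,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> np.ndarray:
    """W per mutation group from count vectors (vectorised over replicates).

    ``counts_t0``/``counts_t1`` have shape (..., n_alleles); masks come
    from :func:`mutation_masks`. The pseudocount is added to each of the
    four aggregates; with pseudocount 0 any zero aggregate yields NaN.
    """
    m0 = counts_t0 @ mut_mask + pseudocount
    w0 = counts_t0 @ wt_mask + pseudocount
    m1 = counts_t1 @ mut_mask + pseudocount
    w1 = counts_t1 @ wt_mask + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        W = np.log((m1 / w1) / (m0 / w0))
    return np.where(
        (m0 > 0) & (w0 > 0) & (m1 > 0) & (w1 > 0), W, np.nan
    )


def _single_fitness(
    table: CountTable,
    members: tuple[tuple[int, str], ...],
    t_from: str,
    t_to: str,
    pseudocount: float,
) -> MarginalFitness:
    mut_mask, wt_mask = mutation_masks(table.df.index, table.panel, [members])
    n0 = table.counts(t_from).to_numpy(dtype=float)
    n1 = table.counts(t_to).to_numpy(dtype=float)
    W = batch_fitness(n0, n1, mut_mask, wt_mask, pseudocount)[0]
    return MarginalFitness(
        locus=tuple(p for p, _ in members),
        residue=tuple(r for _, r in members),
        W=float(W),
        mut_t0=int(n0 @ mut_mask[:, 0]),
        wt_t0=int(n0 @ wt_mask[:, 0]),
        mut_t1=int(n1 @ mut_mask[:, 0]),
        wt_t1=int(n1 @ wt_mask[:, 0]),
        pseudocount=pseudocount,
    )


def marginal_fitness(
    table: CountTable,
    locus: int,
    residue: str,
    t_from: str | None = None,
    t_to: str | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> MarginalFitness:
    """W for one focal mutation, aggregated over genetic backgrounds."""
    t_from = t_from or table.timepoints[0]
    t_to = t_to or table.timepoints[1]
    return _single_fitness(table, ((locus, residue),), t_from, t_to, pseudocount)


def pair_fitness(
    table: CountTable,
    locus_i: int,
    residue_i: str,
    locus_j: int,
    residue_j: str,
    t_from: str | None = None,
    t_to: str | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> MarginalFitness:
    """W for a mutation pair: double carriers vs double-WT alleles."""
    t_from = t_from or table.timepoints[0]
    t_to = t_to or table.timepoints[1]
    return _single_fitness(
        table, ((locus_i, residue_i), (locus_j, residue_j)), t_from, t_to, pseudocount
    )


def pairwise_epistasis(
    table: CountTable,
    pairs: list[tuple[tuple[int, str], tuple[int, str]]] | None = None,
    t_from: str | None = None,
    t_to: str | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """eps_ij = W_ij - (W_i + W_j) for every requested pair.

    Valid only over the first cycle: later intervals are computable but
    the background-similarity assumption no longer holds, so a warning is
    raised when ``t_from`` is not the first timepoint. Confidence columns
    are filled by the null model.
    """
    t_from = t_from or table.timepoints[0]
    t_to = t_to or table.timepoints[1]
    if t_from != table.timepoints[0] or t_to != table.timepoints[1]:
        warnings.warn(
            "epistasis outside the first cycle: background profiles of focal "
            "mutations diverge over time, estimates may be biased",
            stacklevel=2,
        )
    if pairs is None:
        singles = focal_mutations(table.panel)
        pairs = list(itertools.combinations(singles, 2))
    rows = []
    for (pi, ri), (pj, rj) in pairs:
        Wi = marginal_fitness(table, pi, ri, t_from, t_to, pseudocount)
        Wj = marginal_fitness(table, pj, rj, t_from, t_to, pseudocount)
        Wij = pair_fitness(table, pi, ri, pj, rj, t_from, t_to, pseudocount)
        rows.append(
            {
                "locus_i": pi, "res_i": ri, "locus_j": pj, "res_j": rj,
                "W_i": Wi.W, "W_j": Wj.W, "W_ij": Wij.W,
                "epsilon": Wij.W - (Wi.W + Wj.W),
                "mut_t0": Wij.mut_t0, "wt_t0": Wij.wt_t0,
                "mut_t1": Wij.mut_t1, "wt_t1": Wij.wt_t1,
                "confidence": np.nan, "n_sims": 0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# composition summaries


def position_composition(table: CountTable, timepoint: str) -> pd.DataFrame:
    """Count-weighted residue frequencies per focal locus (logo table).

    Rows are protein positions, columns residues; each row sums to 1.
    """
    counts = table.counts(timepoint)
    residues = np.array([list(a) for a in table.df.index])
    rows = {}
    for i, locus in enumerate(table.panel):
        s = pd.Series(counts.to_numpy(), index=residues[:, i]).groupby(level=0).sum()
        rows[locus.protein_position] = s / s.sum()
    return pd.DataFrame(rows).T.fillna(0.0).rename_axis("position")


def background_profile(
    table: CountTable,
    locus: int,
    residue: str,
    timepoint: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Residue composition at the *other* loci for carriers and WT reference.

    Returns (carrier profile, WT-reference profile); comparing profiles
    across focal mutations is the validity check for background-averaged
    fitness. Empty carrier or reference sets yield empty frames.
    """
    timepoint = timepoint or table.timepoints[0]
    panel = table.panel
    i = panel.index_of(locus)
    wt_res = panel.loci[i].wt_residue

    def _profile(mask: pd.Series) -> pd.DataFrame:
        sub = table.df.loc[mask.to_numpy(), [timepoint]]
        if sub[timepoint].sum() == 0:
            return pd.DataFrame()
        sub_table = CountTable(df=sub, panel=panel)
        comp = position_composition(sub_table, timepoint)
        return comp.drop(index=locus)

    at_locus = pd.Series([a[i] for a in table.df.index], index=table.df.index)
    return _profile(at_locus == residue), _profile(at_locus == wt_res)


def diversity_trajectory(table: CountTable) -> pd.DataFrame:
    """Allele richness and Shannon entropy (nats) per timepoint.

    Selection purges variation, so entropy is expected to fall across
    enrichment cycles.
    """
    rows = []
    for t in table.timepoints:
        counts = table.counts(t)
        nz = counts[counts > 0]
        f = nz / nz.sum()
        rows.append(
            {
                "timepoint": t,
                "richness": int((counts > 0).sum()),
                "entropy": float(-(f * np.log(f)).sum()),
            }
        )
    return pd.DataFrame(rows)
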