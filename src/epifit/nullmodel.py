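"""Poisson-resampling null model for pairwise epistasis confidence.

How much apparent epistasis does pure sequencing-sampling noise create?
To answer that, the selection-sequencing experiment is simulated under a
no-epistasis (multiplicative) assumption:

1. each allele gets a linear-scale fitness w_a = prod exp(W_i) over the
   single-mutation fitness estimates it carries;
2. the observed t0 counts are Poisson-resampled to give simulated "true"
   t0 frequencies;
3. frequencies are propagated one cycle, f' = f * w / mean(w);
4. t1 counts are Poisson-sampled at the real t1 sequencing depth;
5. singles, pairs and epsilon are re-estimated from the real t0 counts
   plus the simulated t1 counts, exactly as for the real data.

Over many replicates the simulated epsilon-hat distributions describe the
measurement noise; an observed epsilon is assigned a one-sided empirical
confidence against them (fraction of simulated values below it for
positive epsilon, above it for negative). Selection-step drift noise is
deliberately ignored (large population relative to diversity), and
off-target mutations are invisible to allele-IDs, so these confidences
are an upper bound.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counts import CountTable
from .enrichment import (
    DEFAULT_PSEUDOCOUNT,
    MarginalFitness,
    batch_fitness,
    focal_mutations,
    mutation_masks,
)
from .panel import LociPanel

__all__ = [
    "genotype_fitness_from_singles",
    "update_frequencies",
    "poisson_resample",
    "simulate_null",
    "assign_confidence",
    "NullDistribution",
]

DEFAULT_N_SIMS = 1000


@dataclass
class NullDistribution:
    """Simulated no-epistasis epsilon-hat values per mutation pair."""

    pairs: list[tuple[tuple[int, str], tuple[int, str]]]
    #: shape (n_sims, n_pairs); NaN marks replicates with undefined estimates
    epsilon_sims: np.ndarray
    n_sims: int

    def values(self, pair) -> np.ndarray:
        """Defined simulated epsilon-hat values for one pair."""
        j = self.pairs.index(pair)
        col = self.epsilon_sims[:, j]
        return col[np.isfinite(col)]

    @property
    def n_undefined(self) -> pd.Series:
        idx = [f"{pi}{ri}:{pj}{rj}" for (pi, ri), (pj, rj) in self.pairs]
        return pd.Series(np.isnan(self.epsilon_sims).sum(axis=0), index=idx)

    def quantiles(self, q=(0.025, 0.5, 0.975)) -> pd.DataFrame:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            vals = np.nanquantile(self.epsilon_sims, q, axis=0)
        idx = [f"{pi}{ri}:{pj}{rj}" for (pi, ri), (pj, rj) in self.pairs]
        return pd.DataFrame(vals.T, index=idx, columns=[f"q{x}" for x in q])


def genotype_fitness_from_singles(
    singles: list[MarginalFitness],
    panel: LociPanel,
    allele_ids: pd.Index,
) -> pd.Series:
    """Multiplicative (no-epistasis) linear fitness per allele.

    ln w_a is the sum of the single-mutation W over the mutations the
    allele carries; the WT allele gets w = 1. Alleles carrying a mutation
    whose W is undefined get NaN (excluded downstream, with a warning).
    """
    residues = np.array([list(a) for a in allele_ids])
    ln_w = np.zeros(len(allele_ids))
    for s in singles:
        (pos,), (res,) = s.locus, s.residue
        carrier = residues[:, panel.index_of(pos)] == res
        ln_w = ln_w + np.where(carrier, s.W, 0.0)
    w = pd.Series(np.exp(ln_w), index=allele_ids)
    if w.isna().any():
        warnings.warn(
            f"{int(w.isna().sum())} alleles carry a mutation with undefined W; "
            "they are excluded from the null simulation",
            stacklevel=2,
        )
    return w


def update_frequencies(f: pd.Series, w: pd.Series) -> pd.Series:
    """One selection cycle: f'_a = f_a w_a / sum_b f_b w_b."""
    if not np.isclose(f.sum(), 1.0, atol=1e-9):
        raise ValueError("frequencies must sum to 1")
    fw = f * w.loc[f.index]
    mean_w = fw.sum()
    if mean_w <= 0:
        raise ValueError("mean fitness is zero; cannot propagate frequencies")
    return fw / mean_w


def poisson_resample(
    counts: pd.Series | np.ndarray,
    target_total: float | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Poisson draw per allele with mean frequency x target_total.

    With ``target_total`` None (or equal to the observed total) the mean
    is simply the observed count, which is how the simulated t0 is
    initialised from the real t0 counts.
    """
    rng = rng or np.random.default_rng()
    arr = np.asarray(counts, dtype=float)
    total = arr.sum()
    if total <= 0:
        raise ValueError("cannot resample an all-zero count vector")
    mean = arr if target_total is None else arr / total * target_total
    return rng.poisson(mean)


def simulate_null(
    table: CountTable,
    singles: list[MarginalFitness],
    pairs: list[tuple[tuple[int, str], tuple[int, str]]] | None = None,
    t_from: str | None = None,
    t_to: str | None = None,
    n_sims: int = DEFAULT_N_SIMS,
    seed: int = 0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> NullDistribution:
    """Distribution of epsilon-hat under no epistasis, by Poisson resampling.

    ``table`` must already be filtered for the epistasis analysis; the
    pseudocount must match the one used for the real estimates so the
    confidences are comparable. Replicate r draws from an independent
    child stream of ``seed``, so results do not depend on execution order.
    """
    t_from = t_from or table.timepoints[0]
    t_to = t_to or table.timepoints[1]
    panel = table.panel
    if pairs is None:
        pairs = list(itertools.combinations(focal_mutations(panel), 2))

    w = genotype_fitness_from_singles(singles, panel, table.df.index)
    keep = w.notna().to_numpy()
    allele_ids = table.df.index[keep]
    w_vec = w.to_numpy()[keep]
    n0 = table.counts(t_from).to_numpy(dtype=float)[keep]
    t1_total = float(table.counts(t_to).sum())

    single_list = _as_singles(pairs)
    mut_s, wt_s = mutation_masks(allele_ids, panel, single_list)
    mut_p, wt_p = mutation_masks(allele_ids, panel, pairs)

    streams = np.random.SeedSequence(seed).spawn(n_sims)
    sim_t1 = np.empty((n_sims, len(allele_ids)))
    for r, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        sim_t0 = rng.poisson(n0).astype(float)  # totals match, mean = observed count
        total0 = sim_t0.sum()
        if total0 == 0:
            sim_t1[r] = 0.0
            continue
        f0 = sim_t0 / total0
        f1 = f0 * w_vec
        f1 /= f1.sum()
        sim_t1[r] = rng.poisson(f1 * t1_total)

    # estimation uses the real t0 counts with the simulated t1 counts,
    # mirroring the real-data estimator
    W_singles = batch_fitness(n0, sim_t1, mut_s, wt_s, pseudocount)
    W_pairs = batch_fitness(n0, sim_t1, mut_p, wt_p, pseudocount)
    idx = {m: k for k, m in enumerate(single_list)}
    eps = np.empty_like(W_pairs)
    for j, (mi, mj) in enumerate(pairs):
        eps[:, j] = W_pairs[:, j] - (W_singles[:, idx[mi]] + W_singles[:, idx[mj]])

    n_undef = int(np.isnan(eps).any(axis=1).sum())
    if n_undef > 0.05 * n_sims:
        warnings.warn(
            f"{n_undef}/{n_sims} null replicates had undefined epsilon estimates",
            stacklevel=2,
        )
    return NullDistribution(pairs=list(pairs), epsilon_sims=eps, n_sims=n_sims)


def _as_singles(pairs) -> list[tuple[int, str]]:
    seen: dict[tuple[int, str], None] = {}
    for mi, mj in pairs:
        seen.setdefault(mi)
        seen.setdefault(mj)
    return list(seen)


def assign_confidence(
    epistasis: pd.DataFrame,
    null: NullDistribution,
    levels: tuple[float, ...] = (0.95, 0.99),
) -> pd.DataFrame:
    """One-sided empirical confidence of each observed epsilon vs the null.

    For positive epsilon, confidence is the fraction of simulated values
    below it; for negative, the fraction above. Ties count half. A column
    ``sig_<level>`` flags confidence >= level; note the two-tailed
    false-positive rate of such a flag under a symmetric null is
    2 x (1 - level).
    """
    out = epistasis.copy()
    out["confidence"] = np.nan
    out["n_sims"] = 0
    for k, row in out.iterrows():
        pair = ((row.locus_i, row.res_i), (row.locus_j, row.res_j))
        if pair not in null.pairs:
            continue
        sims = null.values(pair)
        eps = row.epsilon
        out.loc[k, "n_sims"] = len(sims)
        if not np.isfinite(eps) or len(sims) == 0:
            continue
        ties = 0.5 * np.sum(sims == eps)
        if eps > 0:
            conf = (np.sum(sims < eps) + ties) / len(sims)
        elif eps < 0:
            conf = (np.sum(sims > eps) + ties) / len(sims)
        else:
            conf = 0.5
        out.loc[k, "confidence"] = conf
    for level in levels:
        out[f"sig_{level:g}"] = out["confidence"] >= level
    return out
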