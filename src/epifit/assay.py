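"""Recombination-assay fold changes and error-propagated epistasis.

The orthogonal, low-throughput view of the same fitness landscape:
recombination frequencies measured as the ratio of recombinant to total
conjugants, fold changes relative to a reference allele, and the
multiplicative (independent-loci) expectation for combined mutations.
Epistasis here is the *expected minus observed* fold increase; its error
is obtained by first-order (delta-method) propagation, and the deviation
is called significant when it exceeds k standard errors (default k = 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AssayMeasurement",
    "AssayEpistasis",
    "recombination_frequency",
    "fold_change",
    "multiplicative_expectation",
    "epistasis_with_error",
    "assay_table",
]


@dataclass(frozen=True)
class AssayMeasurement:
    """Replicate recombination frequencies of one allele in one reaction."""

    allele: str
    reaction: str  # e.g. "attIxattI", "attCxattC", "attIxattC"
    replicates: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(not 0 <= r <= 1 for r in self.replicates):
            raise ValueError("recombination frequencies must lie in [0, 1]")
        if len(self.replicates) < 1:
            raise ValueError("at least one replicate is required")

    @property
    def mean(self) -> float:
        return float(np.mean(self.replicates))

    @property
    def sem(self) -> float:
        """Standard error of the mean (0 for a single replicate)."""
        if len(self.replicates) < 2:
            return 0.0
        return float(np.std(self.replicates, ddof=1) / math.sqrt(len(self.replicates)))


@dataclass(frozen=True)
class AssayEpistasis:
    """Multiplicative expectation vs observation, with propagated error."""

    singles: tuple[float, ...]
    single_errors: tuple[float, ...]
    expected: float  # E = prod of single fold increases
    sigma_expected: float
    observed: float
    sigma_observed: float
    epsilon_fold: float  # E - O
    sigma_epsilon: float
    k: float

    @property
    def significant(self) -> bool:
        return self.epsilon_fold > self.k * self.sigma_epsilon


def recombination_frequency(recombinant_count: int, total_count: int) -> float:
    """Recombinants / total conjugants, a ratio in [0, 1]."""
    if total_count <= 0:
        raise ValueError("total colony count must be positive")
    if recombinant_count < 0 or recombinant_count > total_count:
        raise ValueError("recombinant count must lie in [0, total]")
    return recombinant_count / total_count


def fold_change(
    mutant: AssayMeasurement | float,
    reference: AssayMeasurement | float,
) -> tuple[float, float]:
    """Fold increase of a mutant over the reference allele, with its SE.

    Ratio of the replicate means; the SE follows the quotient delta rule
    fold * sqrt((s_m/m)^2 + (s_r/r)^2). Floats are accepted as exact
    (zero-SE) frequencies.
    """
    m, sm = (mutant.mean, mutant.sem) if isinstance(mutant, AssayMeasurement) else (mutant, 0.0)
    r, sr = (
        (reference.mean, reference.sem)
        if isinstance(reference, AssayMeasurement)
        else (reference, 0.0)
    )
    if r <= 0:
        raise ValueError("reference frequency must be positive")
    fold = m / r
    se = fold * math.sqrt((sm / m) ** 2 + (sr / r) ** 2) if m > 0 else 0.0
    return fold, se


def multiplicative_expectation(folds: Sequence[float]) -> float:
    """Expected combined fold change if loci act independently: prod x_i."""
    if any(x <= 0 for x in folds):
        raise ValueError("fold increases must be positive")
    return float(np.prod(np.asarray(folds, dtype=float)))


def epistasis_with_error(
    singles: Sequence[float],
    single_errors: Sequence[float],
    observed: float,
    observed_error: float,
    k: float = 2.0,
) -> AssayEpistasis:
    """Expected-minus-observed fold epistasis with delta-method error.

    E = prod x_i, sigma_E = E sqrt(sum (s_i/x_i)^2); epsilon = E - O with
    sigma_eps = sqrt(sigma_E^2 + s_O^2). The first-order product formula
    is accurate while relative errors s_i/x_i stay modest (<~20%).
    """
    if len(singles) != len(single_errors):
        raise ValueError("one error per single fold change is required")
    E = multiplicative_expectation(singles)
    rel = [s / x for x, s in zip(singles, single_errors)]
    sigma_E = E * math.sqrt(sum(r * r for r in rel))
    eps = E - observed
    sigma_eps = math.sqrt(sigma_E**2 + observed_error**2)
    return AssayEpistasis(
        singles=tuple(float(x) for x in singles),
        single_errors=tuple(float(s) for s in single_errors),
        expected=E,
        sigma_expected=sigma_E,
        observed=float(observed),
        sigma_observed=float(observed_error),
        epsilon_fold=eps,
        sigma_epsilon=sigma_eps,
        k=k,
    )


def assay_table(path_or_df, reference_allele: str) -> pd.DataFrame:
    """Fold-change table from raw assay rows.

    Input columns: allele, reaction, replicate, and either ``frequency``
    or ``recombinants``+``total``. Returns per (allele, reaction) the mean
    frequency, SE, and fold change vs ``reference_allele`` in the same
    reaction.
    """
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df, sep="\t")
    if "frequency" not in df.columns:
        df = df.assign(
            frequency=[
                recombination_frequency(r, t)
                for r, t in zip(df["recombinants"], df["total"])
            ]
        )
    measurements = {
        key: AssayMeasurement(allele=key[0], reaction=key[1], replicates=tuple(g["frequency"]))
        for key, g in df.groupby(["allele", "reaction"])
    }
    rows = []
    for (allele, reaction), m in measurements.items():
        ref = measurements.get((reference_allele, reaction))
        fold, se = fold_change(m, ref) if ref is not None else (np.nan, np.nan)
        rows.append(
            {
                "allele": allele, "reaction": reaction,
                "n_replicates": len(m.replicates),
                "frequency": m.mean, "sem": m.sem,
                "fold": fold, "fold_se": se,
            }
        )
    return pd.DataFrame(rows).sort_values(["reaction", "allele"]).reset_index(drop=True)
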