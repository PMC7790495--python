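"""Allele-ID count tables across enrichment timepoints."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .panel import LociPanel

__all__ = ["CountTable"]


@dataclass(frozen=True)
class CountTable:
    """Read counts per (allele-ID, timepoint).

    ``df`` is wide: index = allele-ID strings, one column per timepoint in
    chronological order, integer counts. Allele-IDs with unexpected
    residues are retained (callers filter explicitly).
    """

    df: pd.DataFrame
    panel: LociPanel

    def __post_init__(self) -> None:
        if (self.df.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        bad = [a for a in self.df.index if len(a) != len(self.panel)]
        if bad:
            raise ValueError(f"allele-ID length != panel size: {bad[:3]}")

    @classmethod
    def from_counts(
        cls, counts: Mapping[str, Mapping[str, int]], panel: LociPanel
    ) -> "CountTable":
        """Build from {timepoint: {allele_id: count}} (timepoint order kept)."""
        df = pd.DataFrame(counts).fillna(0).astype(np.int64)
        df = df[list(counts)]
        return cls(df=df.sort_index(), panel=panel)

    @property
    def timepoints(self) -> list[str]:
        return list(self.df.columns)

    @property
    def totals(self) -> pd.Series:
        return self.df.sum(axis=0)

    def counts(self, timepoint: str) -> pd.Series:
        return self.df[timepoint]

    def frequencies(self, timepoint: str) -> pd.Series:
        col = self.df[timepoint]
        total = col.sum()
        if total == 0:
            raise ValueError(f"no counts at timepoint {timepoint!r}")
        return col / total

    def subset(self, allele_ids) -> "CountTable":
        return CountTable(df=self.df.loc[list(allele_ids)], panel=self.panel)

    def to_tsv(self, path: str | Path) -> None:
        long = (
            self.df.rename_axis("allele_id")
            .reset_index()
            .melt(id_vars="allele_id", var_name="timepoint", value_name="count")
        )
        long = long[long["count"] > 0][["timepoint", "allele_id", "count"]]
        long.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, panel: LociPanel) -> "CountTable":
        long = pd.read_csv(path, sep="\t", dtype={"allele_id": str})
        order = list(dict.fromkeys(long["timepoint"]))
        wide = (
            long.pivot_table(
                index="allele_id", columns="timepoint", values="count",
                aggfunc="sum", fill_value=0,
            )
            .astype(np.int64)[order]
        )
        wide.columns.name = None
        return cls(df=wide.sort_index(), panel=panel)
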