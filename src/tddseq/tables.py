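"""Count tables with per-sample metadata.

The central in-memory container is a thin wrapper around two pandas
DataFrames: a counts matrix (species or isoform rows x sample columns) and a
sample sheet (genotype, library type, clonal line, depth, efficiency). TSV is
the interchange format throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

SAMPLE_COLUMNS = ("genotype", "library_type", "clone_id")


@dataclass
class CountTable:
    """Species-or-isoform x sample counts plus sample metadata.

    ``counts`` rows are species names, or a (species, category) MultiIndex for
    isoform-resolved tables; columns are sample ids. ``samples`` is indexed by
    sample id and carries at least genotype, library_type and clone_id.
    ``counting_space`` records what the columns sum over: "all_mapped",
    "mirna_space" or "locus_space".
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    counting_space: str = "all_mapped"

    def __post_init__(self) -> None:
        missing = [c for c in self.counts.columns if c not in self.samples.index]
        if missing:
            raise ValueError(f"samples sheet lacks metadata for columns: {missing}")
        for col in SAMPLE_COLUMNS:
            if col not in self.samples.columns:
                raise ValueError(f"sample sheet missing required column {col!r}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("count table contains negative values")

    def sample_ids(self, genotype: str | None = None, library_type: str | None = None,
                   clone_id: str | None = None) -> list[str]:
        """Sample ids matching the given metadata, in column order."""
        meta = self.samples.loc[list(self.counts.columns)]
        keep = pd.Series(True, index=meta.index)
        if genotype is not None:
            keep &= meta["genotype"] == genotype
        if library_type is not None:
            keep &= meta["library_type"] == library_type
        if clone_id is not None:
            keep &= meta["clone_id"] == clone_id
        return list(meta.index[keep])

    def subset(self, genotype: str | None = None,
               library_type: str | None = None) -> "CountTable":
        ids = self.sample_ids(genotype=genotype, library_type=library_type)
        return CountTable(self.counts[ids], self.samples.loc[ids],
                          counting_space=self.counting_space)

    def species_level(self) -> "CountTable":
        """Collapse an isoform-resolved table to species totals."""
        if self.counts.index.nlevels == 1:
            return self
        collapsed = self.counts.groupby(level=0, sort=True).sum()
        return CountTable(collapsed, self.samples, counting_space=self.counting_space)


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t")


def read_counts_tsv(path: str | Path, isoform: bool = False) -> pd.DataFrame:
    index_col = [0, 1] if isoform else 0
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_sample_sheet(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index_label="sample_id")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")
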