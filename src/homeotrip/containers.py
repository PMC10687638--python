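"""Core in-memory containers shared across the pipeline.

Everything is a thin, validated wrapper around :class:`pandas.DataFrame`,
keeping gene/sample orientation and metadata explicit rather than positional.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("control", "cold")


class HomeotripError(ValueError):
    """Base error for invalid inputs."""


@dataclass
class CountMatrix:
    """Gene x sample matrix of non-negative integer read counts.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id, one column per sample.
    samples
        DataFrame indexed by sample id with at least a ``condition`` column
        (values ``control`` / ``cold``) and a ``replicate`` column.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            raise HomeotripError("duplicate gene ids in count matrix")
        if list(self.counts.columns) != list(self.samples.index):
            # allow same set in different order; reorder metadata to match
            if set(self.counts.columns) != set(self.samples.index):
                raise HomeotripError("sample sheet does not match count matrix columns")
            self.samples = self.samples.loc[self.counts.columns]
        if "condition" not in self.samples.columns:
            raise HomeotripError("sample sheet needs a 'condition' column")
        bad = set(self.samples["condition"]) - set(CONDITIONS)
        if bad:
            raise HomeotripError(f"unknown condition(s): {sorted(bad)}")
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise HomeotripError("counts must be non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def library_sizes(self) -> pd.Series:
        """Column sums (total mapped reads per sample)."""
        return self.counts.sum(axis=0)

    def samples_for(self, condition: str) -> list[str]:
        return list(self.samples.index[self.samples["condition"] == condition])


@dataclass
class ExpressionMatrix:
    """Length/depth-normalized expression values (FPKM or TPM)."""

    values: pd.DataFrame
    unit: str  # "FPKM" or "TPM"

    def __post_init__(self) -> None:
        if self.unit not in ("FPKM", "TPM"):
            raise HomeotripError(f"unknown expression unit {self.unit!r}")
        if (self.values.to_numpy() < 0).any():
            raise HomeotripError("expression values must be non-negative")

    def condition_means(self, samples: pd.DataFrame, condition: str) -> pd.Series:
        """Arithmetic mean across the replicates of one condition."""
        cols = samples.index[samples["condition"] == condition]
        return self.values[list(cols)].mean(axis=1)


@dataclass
class TripletMap:
    """Anchor-keyed groups of exactly three homeologous gene ids.

    Emulates a 3:1 syntelog table: each anchor (e.g. a diploid relative's
    gene) maps to the three retained copies in the hexaploid.
    """

    table: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["copy1", "copy2", "copy3"]))

    def __post_init__(self) -> None:
        need = {"copy1", "copy2", "copy3"}
        if not need.issubset(self.table.columns):
            raise HomeotripError("triplet map needs columns copy1, copy2, copy3")
        members = self.table[["copy1", "copy2", "copy3"]].to_numpy().ravel()
        if len(members) != len(set(members)):
            raise HomeotripError("a gene appears in more than one triplet slot")
        for _, row in self.table.iterrows():
            if len({row["copy1"], row["copy2"], row["copy3"]}) != 3:
                raise HomeotripError(f"triplet {_} has repeated members")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def anchors(self) -> pd.Index:
        return self.table.index

    def members(self, anchor: str) -> tuple[str, str, str]:
        row = self.table.loc[anchor]
        return (row["copy1"], row["copy2"], row["copy3"])

    def all_members(self) -> set[str]:
        return set(self.table[["copy1", "copy2", "copy3"]].to_numpy().ravel())

    def check_against(self, counts: CountMatrix) -> None:
        missing = self.all_members() - set(counts.gene_ids)
        if missing:
            raise HomeotripError(
                f"{len(missing)} triplet member(s) absent from count matrix, e.g. {sorted(missing)[:3]}"
            )


def geometric_mean(x: np.ndarray | pd.Series) -> float:
    x = np.asarray(x, dtype=float)
    if (x <= 0).any():
        raise HomeotripError("geometric mean requires positive values")
    return float(np.exp(np.mean(np.log(x))))
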