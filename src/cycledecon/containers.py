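"""Core data containers: time-course matrices, spliced/unspliced pairs, gene sets.

A :class:`TimeCourseMatrix` is a gene x sample matrix whose sample (column)
order is the time order of the experiment.  All downstream analyses assume
equally spaced sampling by index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TimeCourseMatrix",
    "SplicedUnsplicedSet",
    "GeneSet",
    "read_gmt",
    "write_gmt",
]

#: valid layer tags for a TimeCourseMatrix
LAYERS = ("raw", "normalized", "spliced", "unspliced")


class ValidationError(ValueError):
    """Raised when a container violates its structural invariants."""


@dataclass
class TimeCourseMatrix:
    """Gene x time-ordered-sample non-negative matrix.

    Parameters
    ----------
    data : pandas.DataFrame
        Genes as rows (index), samples as columns, columns in time order.
    layer : str
        One of ``raw``, ``normalized``, ``spliced``, ``unspliced``.
    """

    data: pd.DataFrame
    layer: str = "raw"

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValidationError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene IDs: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs: {dups[:5]}")
        vals = self.data.to_numpy(dtype=float)
        if vals.size and not np.all(np.isfinite(vals)):
            raise ValidationError("non-finite values in counts matrix")
        if vals.size and vals.min() < 0:
            raise ValidationError("negative values in counts matrix")

    # -- accessors ---------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def with_layer(self, layer: str) -> "TimeCourseMatrix":
        return TimeCourseMatrix(self.data, layer=layer)

    def subset_genes(self, genes: Sequence[str]) -> "TimeCourseMatrix":
        present = [g for g in genes if g in self.data.index]
        return TimeCourseMatrix(self.data.loc[present], layer=self.layer)

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_tsv(cls, path: str | Path, layer: str = "raw") -> "TimeCourseMatrix":
        """Read a genes-as-rows TSV/CSV with a header row of sample IDs."""
        path = Path(path)
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        return cls(df, layer=layer)

    def to_tsv(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.data.to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class SplicedUnsplicedSet:
    """Aligned spliced and unspliced count layers on identical gene/sample axes."""

    spliced: TimeCourseMatrix
    unspliced: TimeCourseMatrix

    def __post_init__(self) -> None:
        if self.spliced.gene_ids != self.unspliced.gene_ids:
            raise ValidationError("spliced/unspliced gene axes differ")
        if self.spliced.sample_ids != self.unspliced.sample_ids:
            raise ValidationError("spliced/unspliced sample axes differ")

    @property
    def gene_ids(self) -> list[str]:
        return self.spliced.gene_ids

    @property
    def sample_ids(self) -> list[str]:
        return self.spliced.sample_ids


@dataclass
class GeneSet:
    """A named collection of unique gene identifiers."""

    name: str
    genes: list[str] = field(default_factory=list)
    description: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        uniq = []
        for g in self.genes:
            if g not in seen:
                seen.add(g)
                uniq.append(str(g))
        self.genes = uniq

    def __len__(self) -> int:
        return len(self.genes)

    def intersect(self, universe: Iterable[str]) -> list[str]:
        uni = set(universe)
        return [g for g in self.genes if g in uni]


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT gene-set file (name, description, tab-separated genes)."""
    sets = []
    for line in Path(path).read_text().splitlines():
        line = line.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValidationError(f"malformed GMT line (needs >=3 fields): {line[:80]!r}")
        sets.append(GeneSet(name=parts[0], description=parts[1], genes=parts[2:]))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    lines = []
    for s in sets:
        lines.append("\t".join([s.name, s.description or "na", *s.genes]))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("\n".join(lines) + "\n")
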