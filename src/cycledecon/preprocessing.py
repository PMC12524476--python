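"""Count normalization and low-count filtering.

Normalization uses median-of-ratios size factors: a per-gene reference is
the geometric mean across samples (genes containing any zero are excluded),
and each sample's factor is the median over genes of count / reference.
For a paired spliced/unspliced experiment the factors are estimated once on
the two matrices stacked and applied to both layers, so the relative scale
of the layers is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import SplicedUnsplicedSet, TimeCourseMatrix

__all__ = [
    "SizeFactors",
    "estimate_size_factors",
    "normalize_counts",
    "normalize_pair",
    "filter_low_counts",
]


class SizeFactorError(ValueError):
    """Raised when median-of-ratios size factors are undefined."""


class AlignmentError(ValueError):
    """Raised when size factors and matrix sample axes disagree."""


@dataclass
class SizeFactors:
    """Per-sample positive scaling constants, aligned to sample IDs."""

    factors: pd.Series

    def __post_init__(self) -> None:
        vals = self.factors.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise SizeFactorError("size factors must be strictly positive and finite")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.factors.index]

    def to_numpy(self) -> np.ndarray:
        return self.factors.to_numpy(dtype=float)


def estimate_size_factors(raw: TimeCourseMatrix) -> SizeFactors:
    """Median-of-ratios size factors.

    Genes with any zero count are excluded from the reference (their
    geometric mean would vanish and the ratio diverge).  The median of an
    even number of ratios is the mean of the two central values.
    """
    x = raw.values
    if x.shape[1] == 1:
        return SizeFactors(pd.Series([1.0], index=raw.data.columns))
    all_positive = np.all(x > 0, axis=1)
    if not all_positive.any():
        raise SizeFactorError(
            "size factors undefined: no gene has strictly positive counts in every sample"
        )
    pos = x[all_positive]
    log_ref = np.mean(np.log(pos), axis=1)           # log geometric mean per gene
    ratios = np.log(pos) - log_ref[:, None]
    log_factors = np.median(ratios, axis=0)
    # rescale to geometric mean one so normalization is a fixed point
    log_factors -= log_factors.mean()
    return SizeFactors(pd.Series(np.exp(log_factors), index=raw.data.columns))


def _check_alignment(mat: TimeCourseMatrix, sf: SizeFactors) -> None:
    if mat.sample_ids != sf.sample_ids:
        raise AlignmentError(
            f"sample axes differ: matrix {mat.sample_ids[:3]}... vs factors {sf.sample_ids[:3]}..."
        )


def normalize_counts(raw: TimeCourseMatrix, sf: SizeFactors) -> TimeCourseMatrix:
    """Divide each sample's column by its size factor; output layer ``normalized``."""
    _check_alignment(raw, sf)
    norm = raw.data / sf.to_numpy()[None, :]
    return TimeCourseMatrix(norm, layer="normalized")


def normalize_pair(pair: SplicedUnsplicedSet) -> tuple[SplicedUnsplicedSet, SizeFactors]:
    """Normalize a spliced/unspliced pair with shared size factors.

    Factors are estimated on the two matrices stacked gene-wise (so both
    layers contribute to the reference) and applied to both layers.
    """
    stacked = pd.concat(
        [
            pair.spliced.data.rename(index=lambda g: f"{g}::spliced"),
            pair.unspliced.data.rename(index=lambda g: f"{g}::unspliced"),
        ]
    )
    sf = estimate_size_factors(TimeCourseMatrix(stacked, layer="raw"))
    spliced = TimeCourseMatrix(pair.spliced.data / sf.to_numpy()[None, :], layer="spliced")
    unspliced = TimeCourseMatrix(pair.unspliced.data / sf.to_numpy()[None, :], layer="unspliced")
    return SplicedUnsplicedSet(spliced=spliced, unspliced=unspliced), sf


@dataclass
class FilterReport:
    """Record of a low-count filtering step."""

    threshold: float
    removed: list[str] = field(default_factory=list)
    kept: int = 0


def filter_low_counts(
    mat: TimeCourseMatrix, threshold: float = 10.0, report: FilterReport | None = None
) -> TimeCourseMatrix:
    """Remove genes whose total across all samples is strictly below ``threshold``.

    Applied to the normalized matrix; gene order is otherwise preserved and
    an empty result (all genes removed) keeps the sample axis intact.
    Pass a :class:`FilterReport` to capture the removed gene IDs.
    """
    totals = mat.data.sum(axis=1)
    keep = totals >= threshold
    out = TimeCourseMatrix(mat.data.loc[keep], layer=mat.layer)
    if report is not None:
        report.threshold = threshold
        report.removed = [str(g) for g in mat.data.index[~keep]]
        report.kept = int(keep.sum())
    return out
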