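"""Low-dimensional trajectory embedding of the sample time series.

Samples of a synchronized time course selected for oscillatory genes trace
a circular trajectory in principal-component space (one loop per cycle);
adding transiently expressed genes contributes a monotone component.  The
embedding is a plain SVD of the samples x genes matrix after per-gene
z-scoring, with a deterministic sign convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import TimeCourseMatrix

__all__ = ["TrajectoryEmbedding", "pca_embed"]


class TrajectoryError(ValueError):
    pass


@dataclass
class TrajectoryEmbedding:
    """PCA embedding of samples: scores, variance fractions, gene loadings."""

    scores: pd.DataFrame                 # samples x components
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame               # genes x components (orthonormal columns)
    genes_used: list[str]

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca_embed(
    mat: TimeCourseMatrix,
    gene_subset: Sequence[str] | None = None,
    n_components: int = 3,
    scale: bool = True,
) -> TrajectoryEmbedding:
    """Embed samples by SVD of the (z-scored) samples x genes matrix.

    Genes are z-scored across samples by default (``scale=False`` centers
    only); zero-variance genes are dropped with a warning.  Scores are the
    sample projections U*S; the sign of each component is fixed so that its
    largest-magnitude gene loading is positive.
    """
    genes = list(mat.gene_ids) if gene_subset is None else [g for g in gene_subset
                                                            if g in mat.data.index]
    if len(genes) < n_components:
        raise TrajectoryError(
            f"need at least {n_components} usable genes, got {len(genes)}"
        )
    x = mat.data.loc[genes].to_numpy(dtype=float).T      # samples x genes
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    usable = sd > 0
    if not usable.all():
        dropped = [g for g, u in zip(genes, usable) if not u]
        warnings.warn(f"dropping {len(dropped)} zero-variance genes: {dropped[:5]}")
        genes = [g for g, u in zip(genes, usable) if u]
        x, mu, sd = x[:, usable], mu[usable], sd[usable]
    if len(genes) < n_components:
        raise TrajectoryError(f"only {len(genes)} non-constant genes for {n_components} components")
    x = (x - mu) / sd if scale else x - mu

    u, s, vt = np.linalg.svd(x, full_matrices=False)
    m = min(n_components, s.size)
    total_var = float((s**2).sum())
    evr = (s[:m] ** 2) / total_var if total_var > 0 else np.zeros(m)
    scores = u[:, :m] * s[:m]
    load = vt[:m].T
    # deterministic sign: largest-|loading| entry of each component positive
    for c in range(m):
        j = int(np.argmax(np.abs(load[:, c])))
        if load[j, c] < 0:
            load[:, c] *= -1.0
            scores[:, c] *= -1.0
    comp_names = [f"PC{i + 1}" for i in range(m)]
    return TrajectoryEmbedding(
        scores=pd.DataFrame(scores, index=mat.sample_ids, columns=comp_names),
        explained_variance_ratio=evr,
        loadings=pd.DataFrame(load, index=genes, columns=comp_names),
        genes_used=genes,
    )
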