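"""Multinomial topic model (grade of membership) for time-course deconvolution.

Model
-----
Each sample's expression profile is a convex mixture of k latent gene
programs ("topics").  With x_ij the (normalized) count of gene j in sample
i, L the n_samples x k matrix of mixture proportions p(topic|sample) and F
the n_genes x k matrix of gene probabilities p(gene|topic), the model
maximizes the multinomial log-likelihood

    l(L, F) = sum_ij x_ij * log( sum_c L_ic F_jc )

by expectation-maximization:

    E-step:  r_ijc = L_ic F_jc / sum_c' L_ic' F_jc'
    M-step:  L_ic  ∝ sum_j x_ij r_ijc   (rows renormalized)
             F_jc  ∝ sum_i x_ij r_ijc   (columns renormalized)

Non-integer normalized counts enter as weights; EM only needs
non-negativity.  The likelihood target is the same as Poisson
non-negative matrix factorization up to sample-total terms, so the fitted
L and F agree with topic-model fits obtained through that route.

Usage follows the familiar model/results split::

    model = TopicModel(mat, k=3)
    res = model.fit(seed=7, n_restarts=5)
    res.L, res.F, res.summary()
    res.posterior()          # Bayes p(topic|gene) on the simplex
    res.diff_expression()    # per-topic volcano statistics
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GeneSet, TimeCourseMatrix

__all__ = [
    "TopicModel",
    "TopicModelResults",
    "TopicDiffResult",
    "PosteriorSimplex",
    "match_topics",
    "geneset_simplex",
]

_EPS = 1e-300


class TopicModelError(ValueError):
    pass


class TopicModel:
    """Multinomial topic model of a gene x time-ordered-sample matrix.

    Parameters
    ----------
    mat : TimeCourseMatrix or pandas.DataFrame
        Non-negative counts, genes as rows.  Typically the normalized,
        low-count-filtered matrix.
    k : int
        Number of latent topics (temporal components); default 3.
    """

    def __init__(self, mat: TimeCourseMatrix | pd.DataFrame, k: int = 3):
        if isinstance(mat, pd.DataFrame):
            mat = TimeCourseMatrix(mat, layer="normalized")
        if k < 1:
            raise TopicModelError("k must be >= 1")
        if k > mat.n_samples:
            raise TopicModelError(f"k={k} exceeds the number of samples ({mat.n_samples})")
        if mat.values.sum() <= 0:
            raise TopicModelError("all-zero matrix: nothing to fit")
        self.mat = mat
        self.k = k
        # samples x genes orientation internally (documents x words)
        self._x = mat.values.T.copy()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, k: int = 3) -> "TopicModel":
        return cls(TimeCourseMatrix(df, layer="normalized"), k=k)

    # ------------------------------------------------------------------
    def _em(self, seed: int, tol: float, max_iter: int) -> tuple[np.ndarray, np.ndarray, list[float], bool]:
        rng = np.random.default_rng(seed)
        x = self._x
        n, m = x.shape
        k = self.k
        L = rng.dirichlet(np.ones(k), size=n)               # rows on simplex
        F = rng.dirichlet(np.ones(m), size=k).T             # columns on simplex
        trace: list[float] = []
        converged = False
        for _ in range(max_iter):
            D = L @ F.T
            ll = float(np.sum(x * np.log(D + _EPS)))
            trace.append(ll)
            if len(trace) > 1:
                prev = trace[-2]
                if abs(ll - prev) <= tol * (abs(prev) + 1e-12):
                    converged = True
                    break
            R = x / (D + _EPS)
            L_new = L * (R @ F)
            F_new = F * (R.T @ L)
            L = L_new / (L_new.sum(axis=1, keepdims=True) + _EPS)
            F = F_new / (F_new.sum(axis=0, keepdims=True) + _EPS)
        if not converged:
            # record the likelihood of the final parameters
            trace.append(float(np.sum(x * np.log(L @ F.T + _EPS))))
        return L, F, trace, converged

    def fit(self, seed: int = 0, n_restarts: int = 5, tol: float = 1e-8,
            max_iter: int = 1000) -> "TopicModelResults":
        """Fit by EM, keeping the best of ``n_restarts`` random starts.

        Topics are canonically ordered by the time of their peak proportion
        (earliest peak first) so labels are stable across seeds.
        """
        if self.k == 1:
            # closed-form maximum likelihood at k = 1
            x = self._x
            F = (x.sum(axis=0) / x.sum())[:, None]
            L = np.ones((x.shape[0], 1))
            trace = [float(np.sum(x * np.log((L @ F.T) + _EPS)))]
            return self._wrap(L, F, trace, True, seed, 1)
        best = None
        rng = np.random.default_rng(seed)
        restart_seeds = rng.integers(0, 2**31 - 1, size=n_restarts)
        for s in restart_seeds:
            L, F, trace, conv = self._em(int(s), tol, max_iter)
            if best is None or trace[-1] > best[2][-1]:
                best = (L, F, trace, conv)
        L, F, trace, conv = best
        # canonical order: earliest peak of the proportion curve first
        order = np.argsort([int(np.argmax(L[:, c])) for c in range(self.k)], kind="stable")
        return self._wrap(L[:, order], F[:, order], trace, conv, seed, n_restarts)

    def _wrap(self, L, F, trace, converged, seed, n_restarts) -> "TopicModelResults":
        topics = [f"k{i + 1}" for i in range(self.k)]
        return TopicModelResults(
            model=self,
            L=pd.DataFrame(L, index=self.mat.sample_ids, columns=topics),
            F=pd.DataFrame(F, index=self.mat.gene_ids, columns=topics),
            loglik_trace=np.asarray(trace),
            converged=bool(converged),
            seed=seed,
            n_restarts=n_restarts,
        )


@dataclass
class TopicModelResults:
    """Fitted topic model: proportions L, gene probabilities F, diagnostics."""

    model: TopicModel
    L: pd.DataFrame
    F: pd.DataFrame
    loglik_trace: np.ndarray
    converged: bool
    seed: int
    n_restarts: int

    @property
    def k(self) -> int:
        return self.L.shape[1]

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])

    def summary(self) -> str:
        lines = [
            "Multinomial topic model",
            f"  samples: {self.L.shape[0]}   genes: {self.F.shape[0]}   topics: {self.k}",
            f"  restarts: {self.n_restarts}   seed: {self.seed}   converged: {self.converged}",
            f"  log-likelihood: {self.loglik:.4f}   EM iterations: {len(self.loglik_trace)}",
            "",
            "  Topic proportions p(topic|sample):",
        ]
        lines.append("  " + self.L.round(3).to_string().replace("\n", "\n  "))
        peak = {c: self.L[c].idxmax() for c in self.L.columns}
        lines.append("")
        lines.append("  Peak sample per topic: " + ", ".join(f"{c}->{p}" for c, p in peak.items()))
        return "\n".join(lines)

    def structure_frame(self) -> pd.DataFrame:
        """Long-format (sample, topic, proportion) table for structure plots."""
        long = self.L.reset_index(names="sample").melt(
            id_vars="sample", var_name="topic", value_name="proportion"
        )
        return long

    # ------------------------------------------------------------------
    def posterior(self, prior: np.ndarray | None = None) -> "PosteriorSimplex":
        """Bayes posterior p(topic|gene) from F and a prior over topics.

        p(c|g) = F_gc * pi_c / sum_c' F_gc' * pi_c', default prior uniform
        1/k.  Genes with an all-zero F row have no defined posterior and
        are flagged rather than silently set uniform.
        """
        k = self.k
        pi = np.full(k, 1.0 / k) if prior is None else np.asarray(prior, dtype=float)
        if pi.size != k or np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-9:
            raise TopicModelError("prior must be a length-k vector on the simplex")
        w = self.F.to_numpy() * pi[None, :]
        tot = w.sum(axis=1)
        undefined = tot == 0.0
        probs = np.full_like(w, np.nan)
        probs[~undefined] = w[~undefined] / tot[~undefined, None]
        return PosteriorSimplex(
            probs=pd.DataFrame(probs, index=self.F.index, columns=self.F.columns),
            prior=pi,
            undefined_genes=[str(g) for g in self.F.index[undefined]],
        )

    def diff_expression(self, eps: float = 0.5) -> "TopicDiffResult":
        """Per-topic differential expression by responsibility allocation.

        Counts are split across topics by the E-step responsibilities,
        n_gc = sum_i x_ig r_igc.  For each topic the in-topic proportion
        p_gc = n_gc / N_c is compared against the pooled proportion in the
        remaining topics q_gc, giving a log2 fold change (with pseudo-count
        eps) and a two-proportion z-score with pooled variance.
        """
        x = self.model._x                      # samples x genes
        L = self.L.to_numpy()
        F = self.F.to_numpy()
        D = L @ F.T
        R = x / (D + _EPS)
        n_alloc = F * (R.T @ L)                # genes x topics pseudo-counts
        topic_totals = n_alloc.sum(axis=0)
        grand = n_alloc.sum()
        genes = list(self.F.index)
        rows = []
        empty = []
        for c, topic in enumerate(self.F.columns):
            N_c = topic_totals[c]
            N_rest = grand - N_c
            if N_c == 0:
                empty.append(str(topic))
                continue
            n_gc = n_alloc[:, c]
            n_rest = n_alloc.sum(axis=1) - n_gc
            p = n_gc / N_c
            q = n_rest / N_rest
            lfc = np.log2((p + eps / N_c) / (q + eps / N_rest))
            pbar = (n_gc + n_rest) / (N_c + N_rest)
            var = pbar * (1.0 - pbar) * (1.0 / N_c + 1.0 / N_rest)
            with np.errstate(divide="ignore", invalid="ignore"):
                z = np.where(var > 0, (p - q) / np.sqrt(var), 0.0)
            for j, g in enumerate(genes):
                rows.append((g, str(topic), n_gc[j], p[j], q[j], lfc[j], z[j]))
        table = pd.DataFrame(
            rows,
            columns=["gene_id", "topic", "n_gk", "p_in_topic", "p_rest", "log2fc", "z_score"],
        )
        return TopicDiffResult(table=table, topic_totals=topic_totals,
                               grand_total=float(x.sum()), empty_topics=empty)

    def match(self, reference_L: pd.DataFrame | np.ndarray) -> np.ndarray:
        return match_topics(self, reference_L)


@dataclass
class TopicDiffResult:
    """Responsibility-allocated differential expression per (gene, topic)."""

    table: pd.DataFrame
    topic_totals: np.ndarray
    grand_total: float
    empty_topics: list[str] = field(default_factory=list)

    def top_genes(self, topic: str, min_z: float = 3.0) -> list[str]:
        sub = self.table[(self.table.topic == topic) & (self.table.z_score > min_z)]
        return sub.sort_values("z_score", ascending=False).gene_id.tolist()


@dataclass
class PosteriorSimplex:
    """Per-gene posterior p(topic|gene) vectors on the (k-1)-simplex."""

    probs: pd.DataFrame
    prior: np.ndarray
    undefined_genes: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.probs.shape[1]


def match_topics(fit: TopicModelResults, reference_L: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Permutation aligning fitted topics to a reference proportion matrix.

    Exhaustively searches the k! column permutations (k <= 6) for the one
    maximizing the summed Pearson correlation between matched columns.
    Returns ``perm`` such that fitted column ``perm[j]`` corresponds to
    reference column ``j`` (i.e. ``fit.L.iloc[:, perm]`` aligns with the
    reference).
    """
    ref = reference_L.to_numpy() if isinstance(reference_L, pd.DataFrame) else np.asarray(reference_L)
    L = fit.L.to_numpy()
    k = fit.k
    if ref.shape != L.shape:
        raise TopicModelError(f"reference shape {ref.shape} != fitted L shape {L.shape}")
    if k > 6:
        raise TopicModelError(
            "exhaustive matching supports k <= 6; use a greedy assignment for larger k"
        )
    # correlation matrix fit-column x reference-column
    C = np.zeros((k, k))
    for a in range(k):
        for b in range(k):
            la, rb = L[:, a], ref[:, b]
            if la.std() == 0 or rb.std() == 0:
                C[a, b] = 0.0
            else:
                C[a, b] = np.corrcoef(la, rb)[0, 1]
    best_perm, best_val = None, -np.inf
    for perm in itertools.permutations(range(k)):
        val = sum(C[perm[j], j] for j in range(k))
        if val > best_val:
            best_val, best_perm = val, perm
    return np.asarray(best_perm)


def geneset_simplex(posterior: PosteriorSimplex, gene_set: GeneSet) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Barycentric coordinates of a gene set on the topic simplex.

    Returns ``(coords, centroid, missing)``: the per-gene posterior rows
    restricted to the set (directly usable as ternary-plot coordinates for
    k = 3), their mean vector, and the set members absent from the
    posterior (or with undefined posterior).
    """
    usable = [g for g in gene_set.genes
              if g in posterior.probs.index and g not in set(posterior.undefined_genes)]
    missing = [g for g in gene_set.genes if g not in usable]
    if not usable:
        raise TopicModelError(f"gene set {gene_set.name!r} has no genes with a defined posterior")
    coords = posterior.probs.loc[usable]
    centroid = coords.mean(axis=0)
    return coords, centroid, missing
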