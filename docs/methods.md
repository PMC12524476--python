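# Methods

## Study design emulated by the generator

The synthetic module emulates a bulk RNA-seq time course of cells released
from cell-cycle arrest: `n_samples = 14` equally spaced samples spanning
`n_cycles = 2` oscillation cycles. Three latent components drive
expression, with raw per-sample weights

- oscillatory A (G1-S-like): `w_A(t) = (1 + cos(2π·n_cycles·t/n)) / 2`
- oscillatory B (G2-M-like): `w_B(t) = (1 + cos(2π·n_cycles·t/n − 2π·φ)) / 2`,
  phase offset `φ = 0.5` (anti-phase)
- transient (release response): `w_T(t) = exp(−t/τ)`, `τ = 3` sampling
  intervals, chosen so the component has effectively vanished by the end
  of the first cycle; no published quantitative decay shape exists for
  this program, so a single exponential is the simplest adequate form

normalized per sample to the simplex. Each component owns 100 genes whose
within-component probabilities are a flat Dirichlet draw carrying 91.8% of
the topic's mass; 0.2% leaks uniformly onto the other components' genes
("near-zero" membership) and 8% spreads uniformly over 200 background
genes, identical in every topic — background genes are therefore
temporally flat. 50 additional low-count genes get flat expected course
totals uniform in [2, 8), below the filtering threshold of 10.

Sequencing is one multinomial draw per sample with library size
`N_t = 10⁶` (so spliced column totals are conserved exactly);
`noise_mode="expectation"` returns the exact expectations and makes the
whole pipeline deterministic. The unspliced layer evaluates the spliced
expectation at index `t + d` (default delay `d = 1` interval), clamped at
the last sample because the experiment is not circular, and scaled by a
global unspliced fraction of 0.25 — a typical intronic-read share of bulk
libraries. Unspliced counts are drawn independently of spliced counts
(separate count layers, as produced by read-annotation tools). There is no
mechanistic transcription/splicing kinetics and no cell-desynchronization
model: the generator reproduces the *statistical* structure the estimators
consume, not the biochemistry, so passing recovery tests demonstrates
correctness of the estimators under the stated mixture-plus-multinomial
assumptions, not robustness to phase drift, amplitude heterogeneity or
overdispersion found in real data.

`cycling_gene_set` exposes a 67-gene "core cycling" set mixing the two
oscillatory programs about 2:1 (45 + 22). The imbalance is deliberate: the
two synthetic programs are *exact* anti-phase cosines, so a phase-balanced
average cancels the oscillation entirely, leaving a monotone residual from
which the spliced/unspliced lag cannot be identified — a degeneracy real
curated core cell-cycle sets avoid because their phase membership is
unequal (G2-M genes typically outnumber G1-S roughly 2:1) and their phases
are heterogeneous. Analyses of sets suspected to be phase-balanced should
use the correlate-then-average option (below).

## Normalization and filtering

Size factors are median-of-ratios: per-gene reference = geometric mean
across samples (genes with any zero excluded, since their geometric mean
vanishes), per-sample factor = median over genes of count/reference, with
the median of an even count defined as the mean of the two central values.
Factors are rescaled to geometric mean one, which makes normalization a
fixed point (re-estimating factors on normalized output yields all ones);
this differs from the common tool convention only by a global constant.
For spliced/unspliced pairs the factors are estimated once on the two
matrices stacked gene-wise and applied to both layers, preserving their
relative scale. Filtering removes genes whose total *normalized* counts
across all samples are strictly below 10; it is idempotent and an
all-removed result keeps the sample axis intact.

## Periodicity screening

The periodogram uses mean removal only — no linear detrend, taper or
padding (a `log1p` switch is available). Densities are
`I(f_j) = |Σ_t x_t e^{−2πi j t/n}|²/n` at `f_j = j/n`,
`j = 1..⌊n/2⌋`; the score `S1/(S2+S3)` is a within-gene ratio, so
windowing conventions largely cancel, and it is invariant to affine
rescaling of the series. Exact density ties rank toward the lower
frequency; `S2 = S3 = 0` yields an infinite score with an explicit flag.
Samples are treated as equally spaced by index even though real sampling
intervals may vary (1.5–3 h in the emulated design); uneven-spacing
estimators (Lomb–Scargle) are out of scope. The null permutes each gene's
sample order independently, with a fresh permutation per gene per shuffle
from one seeded generator, and bins shuffled scores by their dominant-cycles
index. Gene selection takes dominant cycles in a chosen band set with
score strictly greater than the cutoff (default 3).

## Spliced/unspliced lag

Default estimator: z-score each gene's series per layer (dropping
zero-variance genes), average the z-scored series across the gene set per
layer, then Pearson-correlate the averaged unspliced series at time `t`
with the averaged spliced series at `t + ℓ` for `ℓ = −L..L`, using only
overlapping indices (no padding or wrap-around). Positive peak lag =
unspliced leads. Ties break toward smaller `|ℓ|`, then positive `ℓ`.
Z-scoring before averaging prevents high-expression genes from dominating
the average. The alternative `method="per-gene"` correlates each gene's
own pair of series and averages the correlation curves; it is robust to
anti-phase cancellation in the averaged signal. The ±1.96/√n band is the
usual white-noise reference, descriptive only at these series lengths.

## Topic model

The multinomial topic model (grade of membership) maximizes
`Σ_ij x_ij log(Σ_c L_ic F_jc)` by plain EM: responsibilities
`r_ijc ∝ L_ic F_jc`, then `L_ic ∝ Σ_j x_ij r_ijc` (rows renormalized) and
`F_jc ∝ Σ_i x_ij r_ijc` (columns renormalized), both updated from the same
responsibilities. This is the same likelihood targeted by Poisson NMF
topic-model fits up to sample-total terms. Non-integer normalized counts
enter as weights; EM needs only non-negativity. Initialization draws L
rows and F columns from flat Dirichlets; the best of `n_restarts = 5`
restarts by final log-likelihood is kept; convergence is relative
log-likelihood improvement below `tol = 1e-8` (capped at 1000 iterations),
and the trace is checked non-decreasing within 1e-7. `k = 1` uses the
closed-form MLE. Topics are canonically ordered by the time of their peak
proportion (earliest first), giving stable labels across seeds. Matching
to a reference is exhaustive over the k! column permutations (k ≤ 6),
maximizing summed per-column Pearson correlation.

**Identifiability caveat.** With the default temporal shapes the transient
component's true proportion never exceeds 0.5 — no sample is close to pure
in it. The maximum-likelihood factorization is then not unique: a flat
ridge of solutions differing by up to ~0.05–0.08 in individual entries of
L attains the same likelihood (to numerical precision), and EM lands on an
arbitrary ridge point depending on initialization. Matched *correlations*
are insensitive to this (observed > 0.99 throughout), but absolute
proportion values carry that intrinsic uncertainty. When each topic has
near-pure samples and anchor genes, the ridge vanishes and restarts agree
to < 0.02; the test suite demonstrates both regimes. Practically: trust
the shape of the proportion curves and the gene rankings, not the second
decimal of any single proportion.

Per-topic differential expression allocates counts by responsibilities,
`n_gc = Σ_i x_ig r_igc` (conserving the grand total), and contrasts each
gene's in-topic proportion `p = n_gc/N_c` against the pooled rest
`q`, reporting `log2((p + ε/N_c)/(q + ε/N_rest))` with pseudo-count
`ε = 0.5` and a pooled two-proportion z-score. This statistic is a
declared stand-in for unspecified tool-internal variants; absolute z
thresholds are therefore not portable across implementations and are
exposed as configuration. The Bayes posterior uses a uniform prior 1/k by
default; genes with an all-zero probability row are flagged as undefined
rather than silently set uniform.

## Trajectory embedding

PCA embeds samples via SVD of the samples × genes matrix after per-gene
z-scoring (centering-only is available; the default standardization keeps
mixed-scale gene selections comparable). Scores are `U·S`; explained
variance fractions are normalized squared singular values; each
component's sign is fixed so its largest-magnitude gene loading is
positive. Zero-variance genes are dropped with a warning.

## Problem sizes and determinism

All shipped analyses run at desk scale: 14 samples, 550 simulated genes,
10⁶ counts per sample, 200-shuffle nulls, 10-seed recovery sweeps — the
full test suite and the reproduction script each complete in seconds on
one CPU. All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); expectation-mode pipelines are bit-identical
across runs, and every stage writes plain-text TSV/JSON that can be
reloaded to resume at any stage boundary.

## Known limitations

- Equal-spacing-by-index spectral analysis; no uneven-sampling support.
- No overdispersion (negative-binomial) noise; multinomial only.
- The grade-of-membership L is identifiable only up to the MLE ridge when
  no near-pure samples exist (see above).
- Real-data ingestion expects pre-computed count matrices (TSV/CSV);
  alignment and spliced/unspliced read annotation are out of scope.
- No GO/GSEA computation; per-topic ranked gene lists are exported for
  external enrichment services.
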