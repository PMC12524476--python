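# cycledecon

Temporal deconvolution of synchronized-cell RNA-seq time courses.

When a population of cells is synchronized (for example by a double
thymidine block) and sampled by bulk RNA-seq at consecutive time points,
the resulting expression profiles mix several biological programs evolving
in parallel: oscillatory cell-cycle programs (G1-S and G2-M) and a
transient program triggered by the release itself (immediate-early-like
response). `cycledecon` separates these hidden temporal components and
quantifies them, for computational biologists analyzing designs of roughly
10-20 equally spaced samples spanning a couple of cycles.

## What it computes

Given a gene × sample count matrix (samples in time order), the package

1. **Normalizes** counts with median-of-ratios size factors and removes
   genes whose total normalized counts fall below 10 (for a paired
   spliced/unspliced experiment the factors are estimated on the two
   matrices stacked and applied to both).
2. **Screens for periodicity**: for each gene the raw periodogram
   `I(f_j) = |Σ_t x_t e^{-2πi j t/n}|² / n` at Fourier frequencies
   `f_j = j/n`, the *dominant frequency* `F1` (largest density `S1`), and
   the *dominant-frequency score* `S1/(S2+S3)`. Significance comes from a
   null built by independently shuffling each gene's sample order.
3. **Estimates the spliced/unspliced lag**: each gene's spliced and
   unspliced series are z-scored, averaged over a cycling gene set, and
   cross-correlated; a positive peak lag means the unspliced (precursor)
   signal leads the spliced (mature) one.
4. **Fits a multinomial topic model** (grade of membership) by EM,
   maximizing `Σ_ij x_ij log(Σ_c L_ic F_jc)` over sample-topic proportions
   `L` (rows on the simplex) and gene-topic probabilities `F` (columns on
   the simplex). Per-topic volcano statistics come from
   responsibility-allocated pseudo-counts, and gene-topic association is
   summarized by the Bayes posterior
   `p(k|g) = F_gk π_k / Σ_k' F_gk' π_k'` with uniform prior `π = 1/k`,
   which places every gene on the (k−1)-simplex.
5. **Embeds the trajectory** by PCA of the z-scored samples × genes matrix
   (cycling samples trace a circle; transient programs add a monotone
   component).

A synthetic-data module generates the whole design — two anti-phase
oscillatory components, one transient component, multinomial sequencing
noise, a delayed unspliced layer and a low-count gene tail — together with
its ground truth, so every estimator is tested by parameter recovery.

## Worked example

```python
from cycledecon import *

pair, truth = simulate_timecourse(SimConfig(seed=42))
norm_pair, sf = normalize_pair(pair)
mat = filter_low_counts(norm_pair.spliced.with_layer("normalized"), 10.0)

res = average_cross_correlation(norm_pair, cycling_gene_set(truth), max_lag=5)
print(f"peak lag: {res.peak_lag:+d} intervals ({res.n_genes_used} genes)")

records = scan_genes(mat)
print(len(select_genes(records, {2}, 3.0)), "genes at 2 cycles with score > 3")

fit = TopicModel(mat, k=3).fit(seed=0, n_restarts=5)
print(fit.summary())
```

prints

```
peak lag: +1 intervals (67 genes)
200 genes at 2 cycles with score > 3
Multinomial topic model
  samples: 14   genes: 504   topics: 3
  restarts: 5   seed: 0   converged: True
  log-likelihood: -73093298.4075   EM iterations: 131

  Topic proportions p(topic|sample):
          k1     k2     k3
  D1   0.542  0.458  0.000
  D2   0.453  0.435  0.112
  ...
  Peak sample per topic: k1->D1, k2->D8, k3->D12
```

The `+1` peak lag says the unspliced signal of the cycling genes leads the
spliced signal by one sampling interval — the configured maturation delay.
All 200 simulated oscillatory genes are recovered at two cycles over the
course with a concentrated spectrum. In the fitted model, topic `k1`
(peaking at the first sample and fading) is the transient release program,
while `k2` and `k3` oscillate in anti-phase across both cycles — the two
cell-cycle programs. `fit.posterior()` then assigns each gene a point on
the topic simplex, and `fit.diff_expression()` ranks genes per topic for
enrichment analysis.

The same pipeline runs from the shell on TSV inputs:

```bash
cycledecon simulate --outdir sim --seed 42
cycledecon preprocess --counts sim/spliced.tsv --unspliced sim/unspliced.tsv --out prep
cycledecon spectral --counts prep/normalized_filtered.tsv --shuffles 100 --seed 7 --out spec
cycledecon topics --counts prep/normalized_filtered.tsv --k 3 --out topics
cycledecon run-all --config run.yaml
```

## Layout

- `cycledecon.simulate` — synthetic time courses with ground truth
- `cycledecon.preprocessing` — size factors, normalization, filtering
- `cycledecon.spectral` — periodograms, dominance score, permutation null
- `cycledecon.velocity` — spliced/unspliced cross-correlation lag
- `cycledecon.topics` — `TopicModel` / `TopicModelResults`, posteriors
- `cycledecon.trajectory` — PCA trajectory embedding
- `cycledecon.pipeline` / `cycledecon.cli` — orchestration and CLI

See `docs/methods.md` for the models, assumptions and numerical choices.
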