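# Methods

This document specifies the models, parameters, and numerical conventions
implemented in `scxaa`. It is the authoritative description of what the code
computes; the README gives the scientific motivation and worked examples.

## 1. Data model and preprocessing

Expression is handled as FPKM throughout. A `CellMatrix` is a genes × cells
`DataFrame` with a declared unit (`count` or `FPKM`); an `ExpressionProfile`
is a single genes-indexed vector (bulk sample or one cell). Gene annotation
carries a `chromosome_class` per gene (`X`, `autosome`, or `other`; Y and
mitochondrial genes are `other` and excluded from every analysis), an `is_xe`
flag for X-inactivation escapees, and a gene length in bp.

Count matrices are converted as

    FPKM[g, c] = count[g, c] * 1e9 / (length_bp[g] * total_counts[c]),

which errors on genes missing from the annotation and on cells with zero
total counts rather than producing NaN.

Quality control removes cells with fewer than 1,500 detected genes
(detected = FPKM or count > 0; the comparison is strict, so a cell with
exactly 1,500 detected genes is retained) and flags a tissue when fewer than
50 cells survive. Flagged tissues are reported, not silently dropped; the
caller decides. QC is idempotent.

## 2. Synthetic data generator

One replicate is built in three steps.

**Bulk profile.** Autosomal FPKM values are drawn i.i.d. log-normal:
`log2(FPKM) ~ Normal(2.0, 2.5)`. These two numbers are package choices, not
measurements: they give a realistic heavy-tailed FPKM distribution spanning
roughly 10^-2 to 10^3. X-linked values are then created by one of two dosage
models:

* **compensated** — X values are sampled without replacement from the
  realized autosomal values, so X and autosomes follow the same distribution
  and the true X:AA ratio is 1;
* **noncompensated** — as above, but every sampled X value is divided by 2
  *before* any single-cell transformation, so the true bulk ratio is 0.5.

Default sizes are 18,500 autosomal and 508 X-linked genes (the X count
matches the analyzed X-linked gene set size); the acceptance suite and the
analysis drivers use a 5,000-gene autosomal pool for speed, which changes
Monte-Carlo error but no estimand.

**Compression transform.** A single cell's expected expression is a
deterministic log-linear compression of bulk:

    FPKM_sc = 2^(slope * log2(FPKM_bulk) + intercept),  slope = 0.26, intercept = 3.75.

A two-fold bulk difference therefore shrinks to 2^0.26 ≈ 1.20-fold in the
cell, and a truly halved X chromosome yields a single-cell ratio of
2^-0.26 ≈ 0.835 rather than 0.5.

**Dropout.** Each cell detects a random fraction of genes drawn from a
truncated Normal(0.15, 0.05) on (0, 1]; the number of detected genes is
`round(fraction * n_genes)`. Which genes are detected is a weighted sample
without replacement, with logistic weights in log2 bulk FPKM centered at the
profile median (steepness 1.0), so higher-expressed genes are detected more
often. The weighted sample uses the Efraimidis–Spirakis exponential-key
top-k construction, equivalent to sequential draws with weight
renormalization but vectorizable. Undetected genes are exactly 0.

**Intrinsic noise (optional).** With `expression_noise_log2_sd = (lo, hi)`,
each gene gets a per-dataset σ_g ~ Uniform(lo, hi), and each detected value
is multiplied by `2^Normal(0, σ_g)`. The default is (0, 0) — off — so that
the generator reproduces the deterministic-transform setting in which full
detection equals the exact transform. The noise-simulation base dataset
enables the range (0.1, 1.2) because a mean–CV scatter is the premise of the
DM statistic: with a deterministic transform, genes at equal mean have
near-identical CVs and every noise endpoint degenerates.

`fit_generator_to_real` recovers slope/intercept as the median of per-cell
OLS fits over jointly positive genes, the per-gene detection frequencies,
and the per-cell detected fractions from a real (bulk, cells) pair.

## 3. X:AA ratio estimators

X:AA = median X-linked FPKM / median autosomal FPKM within one profile,
after one of two gene selections at threshold t ∈ {0, 1, 2, 5, 10} FPKM:

* **filter-by-expression** — keep every gene strictly above t. Under true
  halving this removes proportionally more X genes and biases the ratio
  toward (and past) the compensated value.
* **filter-by-fraction** — compute the fraction of genes above t separately
  for X (f_X) and autosomes (f_A), set f = min(f_X, f_A), and keep the top
  f of each group ranked by expression. Gene counts are rounded half away
  from zero with a floor of one gene whenever f > 0. On bulk data with
  exact halving this estimator returns exactly 0.5.

Single-cell matrices are summarized per cell and then by the median across
cells ("per-cell-then-median"); replicate-level summaries take the median
across replicates. Ratios are undefined (NaN, excluded from tests with
`n_defined` reported) when a selection is empty or the autosomal median is 0.

Associated tests are one-sided Wilcoxon signed-rank: per-cell ratios against
0.5 (greater) and against 1 (less), and a paired test that halving the Xe
genes decreases the per-cell ratio.

## 4. Compression and sparsity quantification

Per cell: OLS of log2 cell FPKM on log2 bulk FPKM over genes strictly above
the threshold in both profiles (≥ 2 genes required). Sparsity is the
fraction of all genes above the threshold per cell. Slopes are tested below
1 with a one-sided Wilcoxon per threshold; the summary also reports the
maximum p across thresholds.

## 5. Expression noise: CV and DM

CV = sd/mean of FPKM across cells, zeros included, sample sd (`ddof=1`);
mean-0 genes get NaN. DM corrects CV for its mean dependence:

* genes with defined CV are sorted by mean FPKM (ties broken by gene ID);
* each gene's *expected CV* is the median CV of the 100 rank-nearest genes
  (50 below and 50 above; at the extremes the block is shifted to preserve
  its size; the focal gene is excluded from its own window);
* DM = CV − expected CV. A 50-gene window is supported as a variant.

Genes with DM > 1 (strict) are classified dosage-insensitive. The X/A
"quotient" is the ratio of insensitive fractions. Operational housekeeping
genes are those with mean FPKM > 2 in *every* tissue; their sensitive
fraction is reported per tissue with a bootstrap standard error.

The X−A DM difference is `median(DM_X) − median(DM_A)` after the
filter-by-fraction selection applied to the group means, with a 90%
percentile-bootstrap CI (1,000 resamples, genes resampled with replacement
within groups). The sign convention (X minus A; positive = X noisier)
follows the reported results it models.

## 6. Noise simulation

From a base per-gene (mean, CV) table of autosomal genes — here derived
from one simulated compensated single-cell dataset with intrinsic noise on —
each of 1,000 replicates builds:

* **A′**: the full autosomal pool with each gene's CV replaced by a uniform
  draw from its 100-gene rank window (focal excluded);
* **X′**: a uniform 508-gene subset of the pool, CVs re-drawn the same way;
* **X-halved′**: the X′ means divided by 2, CVs drawn from the window of
  pool genes whose (unhalved) means are closest to the halved value — the
  window start is `clip(insertion_position − 50, 0, n − 100)`, the same
  half-below/half-above convention as the expected-CV window;
* **noisy variants**: X′ (or X-halved′) CVs multiplied by 1.05, 1.10, 1.15
  (inflation) or 0.98, 0.96, 0.94 (deflation, optional), capped at the
  maximum CV observed in the base table.

Each dataset pair is reduced to the filter-by-fraction X−A DM difference at
each threshold, with expected CVs computed on the merged A′+X′ table so both
groups share one mean–CV reference.

Endpoints:

* **location** — the median across replicates per condition/threshold;
* **variance** — median-centered Levene test of halved vs baseline
  replicate differences, *at thresholds > 0 only* (see §7);
* **detectability** — for each inflation factor, a one-sided Wilcoxon of
  the replicate DM-difference distribution against 0 at α = 0.01; the
  smallest significant factor is reported as a percent.
* **calibration** — an observed DM difference can be inverted against the
  simulated factor → median-difference curve by monotone linear
  interpolation (out-of-range observations are clamped and flagged).

## 7. Numerical conventions and known limitations

* **Threshold 0 is structurally pinned.** At threshold 0 every gene is
  selected and each simulated CV is a uniform draw from (almost) the same
  window whose median defines the expected CV, so per-replicate median DM
  differences are identically ~0 for baseline *and* halved conditions. The
  location endpoint is trivially met there and the variance comparison is
  uninformative; variance tests therefore use thresholds > 0.
* **Small positive bias of the halved condition at threshold 10.** CVs for
  X-halved′ are drawn around the halved mean, but DM's expected CV is taken
  at the halved gene's *rank* in the merged table; in the sparse upper tail
  of a log-normal pool the two windows differ slightly, leaving a median DM
  difference of ≈ +0.02 at threshold 10 (measured at 1,000 replicates;
  ≈ 0.000–0.002 at thresholds 1–5). It shrinks with pool density and is
  documented rather than corrected.
* **Detection power.** The across-replicate Wilcoxon on 200+ replicate
  medians is very powerful: a 5% CV inflation shifts the median difference
  by ≈ 0.05 × median CV ≫ its replicate-to-replicate sd, so the smallest
  detectable inflation on this synthetic base is 5%, not 10%. On noisier
  empirical base data the threshold can be higher; the implementation
  reports what it measures.
* **Rounding and ties.** Fraction-to-count uses round-half-away-from-zero;
  sorting ties break by gene ID for bit-reproducibility; medians of even
  windows are midpoints of the two central order statistics.
* **Randomness.** Every draw derives from one top-level seed through named
  `SeedSequence` substreams (`substream(seed, *keys)` hashes the key path),
  so stages can be re-run independently without coupling, and runs are
  byte-reproducible.
* **Statistical caveats.** Wilcoxon p-values on 100+ cells from one
  simulated dataset treat cells as independent; per-gene FPKM draws are
  i.i.d., which understates biological gene–gene correlation. Bootstrap CIs
  resample genes within groups and ignore between-replicate variation.
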