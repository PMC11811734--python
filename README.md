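# scxaa

Simulation and estimation toolkit for two questions about the mammalian X
chromosome in single-cell RNA-seq data:

1. **Dosage compensation (X:AA ratio).** Is X-linked expression upregulated
   to match autosomal expression (X:AA ≈ 1), or uncompensated (≈ 0.5)?
   scRNA-seq has two properties that bias this estimate: *sparsity* (only
   ~15% of genes are detected per cell) and *compression* (expression
   differences shrink — a per-cell regression of single-cell on bulk log2
   FPKM has slope ≈ 0.26, so a true two-fold difference appears as only
   2^0.26 ≈ 1.2-fold). This package simulates both dosage models through a
   parameterized compression + dropout channel and compares two estimators:
   **filter-by-expression** (keep genes above an FPKM threshold; biased
   toward 1 when X is truly halved, because thresholding removes more X
   genes) and **filter-by-fraction** (keep the same top fraction of each
   gene group; unbiased on bulk data).
2. **Expression noise (DM).** Are X-linked genes noisier than autosomal
   genes? Noise is measured as DM: a gene's CV across cells minus the
   median CV of the 100 genes nearest in mean expression. The package
   simulates chromosome-wide CV changes (halved means, inflated or deflated
   CVs) to ask how large a change the X−A DM difference can actually detect
   across 1,000 replicates.

The library lives in `src/scxaa`; numbered driver scripts under `analysis/`
reproduce every result table into `results/`.

## Worked example

Simulate both dosage models through the single-cell channel and sweep both
estimators (5,000 autosomal + 508 X genes, 100 cells, 250 replicates;
`analysis/02_xaa_simulation.py` runs exactly this):

```python
from scxaa.pipeline import run_xaa_simulation
from scxaa.simulate import GeneratorConfig

gen = GeneratorConfig(n_autosomal_genes=5000, n_x_genes=508, n_cells=100, seed=1)
df = run_xaa_simulation(gen, 250)
print(df.groupby(["model", "kind", "strategy"])["xaa"].median().round(3))
```

Output (medians over 250 replicates, pooled thresholds 0/1/2/5/10 FPKM):

```
model           kind  strategy
compensated     bulk  by_expression    1.003
                      by_fraction      0.999
                sc    by_expression    1.001
                      by_fraction      1.002
noncompensated  bulk  by_expression    0.741
                      by_fraction      0.500
                sc    by_expression    0.908
                      by_fraction      0.820
```

Three facts of interest are visible:

* with true halving, filter-by-fraction on **bulk** recovers 0.50 exactly,
  while filter-by-expression is pulled toward 1 as the threshold rises
  (0.50 at threshold 0 up to 0.85 at threshold 10);
* on **single-cell** data even the unbiased estimator cannot reach 0.5:
  compression limits it to ≈ 2^−0.26 ≈ 0.835 (observed 0.820), so a
  noncompensated X measured in scRNA-seq still looks "almost compensated";
* when the models are truly compensated, everything is ≈ 1 — the biases
  only push upward, toward compensation.

The noise side (`analysis/04_noise_simulation.py`): with X CVs inflated
chromosome-wide by 5/10/15%, the median X−A DM difference across 1,000
replicates shifts by ≈ 0.10/0.23/0.36 and is significantly positive
(one-sided Wilcoxon, α = 0.01) already at 5% on this synthetic base;
halving X means alone leaves the median difference within ±0.02 of 0 at
every threshold while inflating its replicate-to-replicate variance.

## Command line

```
scxaa simulate-xaa   --replicates 250 --seed 1 --out runs/xaa_sim
scxaa simulate-noise --replicates 1000 --seed 1 --out runs/noise_sim
scxaa xaa   --matrix m.tsv --annotation ann.tsv [--xe-list xe.txt] --out runs/xaa
scxaa noise --matrix m.tsv --annotation ann.tsv --out runs/noise
scxaa report runs/xaa_sim
```

Exit codes: 0 ok, 1 validation error, 2 compute error. All outputs are tidy
TSV with `# key: value` provenance headers; every random draw derives from
the one `--seed` through named substreams, so runs are byte-reproducible.

## Layout

```
src/scxaa/        library (datamodel, io, preprocess, simulate, compression,
                  ratio, noise, noisesim, pipeline, cli)
analysis/         numbered thin drivers -> results/
scripts/          acceptance.py (endpoint JSON)
tests/            pytest suite (unit, property, acceptance)
docs/methods.md   models, parameters, conventions, limitations
```
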