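# corepress

Analysis pipeline for studying how a transcription factor that recruits
co-repressor complexes (NCoR1/NCoR2 with Tbl1x) rewires chromatin when
stem cells exit self-renewal. The package re-implements, as a tested and
reusable library, the computational chain that links growth-factor/Erk
signalling withdrawal to repressive chromatin outcomes:

1. **Phospho time course** — TMT 10-plex reporter tables over a
   0/1.5/5/15/30-minute Mek-inhibition course: spectrum retention filters,
   peptide grouping by confident site localisation (>95%), a two-fold
   regulation screen, and k-means clustering of the dynamics.
2. **Replicate reproducibility (IDR)** — the irreproducible discovery rate
   copula-mixture model fit by EM over rank-transformed replicate peak
   scores; peaks retained at global IDR ≤ α.
3. **Multi-factor co-occupancy** — merged-overlap classification of peak
   sets across factors (e.g. the regions bound by all of Erf, Tbl1x, Ncor1
   and Ncor2, "ETNN" regions).
4. **Spike-in-normalized differential occupancy** — per-region negative
   binomial GLM with a Wald contrast over a merged consensus peak-set,
   size factors from exogenous (spike-in) chromatin or median-of-ratios,
   BH multiple-testing correction, and the combinatorial loss/gain
   classifier: regions grouped by the strict sign pattern of per-factor
   log2 fold changes, screened at min-FDR < 0.5 ("TNN loss" = concordant
   loss of Ncor1, Ncor2 and Tbl1x).
5. **Super-enhancers** — ROSE-style stitching (12.5 kb, TSS exclusion
   2.5 kb), background-subtracted signal ranking, and the tangent-slope-1
   SE/RE split.
6. **Expression** — the same NB Wald machinery on gene counts
   (significant ⇔ |log2FC| > 1 and padj < 0.05), shifted-log variance
   stabilization, top-variance gene selection, Ward clustering with
   elbow-selected k, and per-cluster Wilcoxon comparison of ETNN-bound vs
   other genes.
7. **Integration** — Spearman correlation of chromatin and expression fold
   changes, a signal-correlation coregulator screen (cutoff 0.4), and
   one-sided hypergeometric over-representation analysis with BH.

Every stage is exercised on synthetic fixtures with planted ground truth
(module `corepress.simulate`), so the full chain runs and is tested
without any external data.

## The model in brief

Counts over regions follow `K_ij ~ NB(s_j · q_g(j), α_i)` with
`Var = μ + α μ²`; spike-in size factors are `s_j ∝ spikein_reads_j`
(equivalently multiplicative factors `∝ 1/spikein_reads_j`) anchored to
geometric mean 1. The Wald statistic is `log2(q_B/q_A) / SE` with the SE
from per-group Fisher information; dispersions are method-of-moments
estimates shrunk toward an `α(μ) = a/μ + b` trend. The IDR model mixes a
correlated bivariate normal (reproducible peaks, parameters π₁, ρ, μ, σ)
with independent standard normals, fit by EM on copula pseudo-values. The
SE cutoff scales rank and signal to [0,1] and places the threshold where a
slope-1 line is tangent to the curve from below.

## Worked example

Run the full pipeline on a self-generated fixture:

```sh
corepress run-all --seed 1 --outdir demo_run
```

or in Python:

```python
from corepress.integrate import run_pipeline
manifest = run_pipeline({"seed": 1}, "demo_run")
```

With the default configuration (80 planted 4-way co-occupied regions, 60
planted concordant-loss regions, 8 planted super-enhancer domains, 3
planted phospho dynamics, 300 clean spectra) the manifest reads:

```
"n_etnn_regions": 79,        # 79/80 planted co-occupied regions recovered
"n_tnn_loss": 72,            # 60 planted losses plus FDR-screen passers
"n_super_enhancers": 8,      # all 8 planted SE domains
"k_expression": 4,           # elbow-selected cluster count
"n_phospho_retained": 300,   # exactly the planted clean spectra
```

`demo_run/etnn_responsiveness.tsv` then holds the per-cluster Wilcoxon
comparison; in the cluster carrying the planted ETNN-biased induction the
ETNN genes shift strongly (`median_lfc_etnn 1.88` vs `0.48`,
`p 7.4e-05`) while a background cluster does not (`p 0.82`). All output
tables carry the config hash in their header line and two runs with the
same seed are byte-identical.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the entire pipeline from scratch under the given seed (writing the
stage tables to `results/acceptance_run/`) and writes the JSON report to
`--out`.
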