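# Methods

This note documents the statistical models, the numerical choices, and what
the synthetic fixtures do and do not establish.

## Differential occupancy / expression model

Per region (or gene) `i` and sample `j`, counts are modelled as negative
binomial, `K_ij ~ NB(mean = s_j q_{g(j),i}, dispersion = α_i)` with the
mean-dispersion parameterization `Var = μ + α μ²`. `s_j` is a per-sample
size factor and `q_g` a per-group concentration; contrasts are two-group.

**Size factors.** Two estimators, both anchored to geometric mean 1 so the
global scale is conserved:

- *Spike-in*: multiplicative normalization factors proportional to
  `1 / spikein_reads_j` (the standard exogenous-chromatin definition —
  constant spiked material sequenced at the sample's depth). Samples with
  zero spike-in reads are an error with a pointer to the fallback.
- *Median-of-ratios*: per-region ratios to the geometric mean across
  samples, median per sample; requires at least one region with nonzero
  counts everywhere. Note the known mild bias of median-of-ratios when a
  large asymmetric fraction of regions truly changes; the spike-in route
  exists precisely for near-global occupancy shifts.

**Dispersions.** Method-of-moments on within-group residuals of normalized
counts (`α̂ = (v − μ̄·E[1/s]) / μ̄²`), clipped to `[1e-8, 10]`; a trend
`α(μ) = a/μ + b` is fit by least squares over informative regions and the
final estimate shrinks the raw value toward the trend on the log scale with
prior weight `prior_df = 10` against the residual degrees of freedom. With
4+4 replicates this yields a null raw-p<0.05 fraction of ~0.05-0.06
(asserted in tests) and near-exact agreement with an established NB Wald
reference implementation on the same matrix (cross-checked in one test;
the reference is never used as the engine).

**Wald test.** Group concentrations are per-region NB maximum likelihood
(vectorized Newton on the score equation); `Var(log q)` comes from the
observed Fisher information `Σ s q/(1+αsq)`. The statistic is
`log2(q_B/q_A) / SE`, two-sided p from the normal reference, BH step-up
across all tested regions. All-zero regions are flagged degenerate with
p = 1. No fold-change shrinkage is applied (raw LFCs are reported).

**Combinatorial classifier.** Two fixed steps: (1) group regions by the
strict sign pattern of their per-factor LFCs — an exactly-zero LFC in any
factor excludes the region from sign grouping (reported separately);
(2) retain a region only if the minimum of the per-factor BH-adjusted
p-values is below the permissive screen (default 0.5). Group labels
enumerate all 2^k sign patterns; the all-negative pattern over
Ncor1/Ncor2/Tbl1x is the concordant-loss ("TNN loss") class. The screen
uses per-factor adjusted p-values from separate tests, not a joint
adjustment.

## IDR (replicate reproducibility)

Scores of paired replicate peaks are rank-transformed to uniforms
(`(rank − 0.5)/n`, average ranks) and mapped through the inverse mixture
marginal CDF to pseudo-values. The mixture has a reproducible component
(bivariate normal, equal means `μ`, sd `σ`, correlation `ρ`, weight `π₁`)
and an irreproducible independent standard-normal component. Fitting has
two phases:

1. *Tracking*: pseudo-values are refreshed from the current parameters
   before every EM iteration until the largest parameter change falls
   below 1e-4 (or 200 iterations). Freezing pseudo-values per stage and
   running EM to convergence inside stages was measured to have a biased
   fixed point (π₁ overestimated by ~0.1 and independent data passing the
   filter); per-iteration refreshing recovers planted mixtures accurately.
2. *Final*: pseudo-values are frozen and plain EM runs to a log-likelihood
   change below 1e-6 (at most 200 iterations, else an error with parameter
   diagnostics). Within this phase the log pseudo-likelihood is monotone
   non-decreasing, which the tests assert.

Initialization `π₁ = 0.5, ρ = 0.8, μ = 2, σ = 1`. A peak's local idr is
its posterior irreproducibility; global idr at a rank is the running mean
of local idr down the ranked list, with tied local values sharing one
global value (so the pass-set is a well-defined prefix and monotone in α).
Peaks are retained at global idr ≤ α (defaults: 0.05 for co-occupancy
analyses, 0.01 for the differential reference set). With more than two
replicates, all pairwise fits are intersected ("across all replicates"
read conservatively). Below 50 pairs the copula fit is unstable and the
filter falls back to plain replicate intersection, flagged in the output.

## Super-enhancer calling

Peaks fully contained in TSS ± 2.5 kb are removed (partial overlaps are
kept), remaining peaks chained while gaps ≤ 12.5 kb. Signal per stitched
domain is the sum over constituents of (sample − control) coverage
integrals, clamped at zero; replicate coverage is averaged before scoring.
Rank and signal are scaled to [0, 1] and the cutoff placed where a slope-1
line is tangent to the curve from below — the index maximising
(scaled rank − scaled signal), ties to the highest rank. This is the
stable discrete form of the "slope exceeds 1" rule: a literal
first-crossing scan of finite differences fires on local jitter and labels
most of a noisy landscape. If the maximum diagonal gap is below the
one-sided Kolmogorov–Smirnov 1% critical deviation `√(ln 100 / 2n)`, the
curve is statistically indistinguishable from a tier-free landscape and no
super-enhancers are called. The split is scale-invariant by construction.

## Phospho time course

Fixed-order pure stages: (1) drop spectra with ≥ 5 of 10 missing reporter
channels or all present reporters strictly below 2000; (2) group spectra
into peptides keyed by sequence plus the set of sites with localisation
probability strictly above 0.95 (median aggregation per channel, missing
ignored); (3) collapse channels to per-timepoint medians and fold changes
against the 0-minute channel median; peptides with an empty timepoint or
zero baseline are excluded and reported; (4) keep peptides with ≥ 2-fold
regulation at any timepoint (boundary inclusive); (5) k-means on log2 fold
changes, k-means++ with best of 20 restarts. `k` has no default — the
cluster count is data-dependent — and the elbow helper from the expression
stage can be used to choose it. The channel-to-timepoint layout is a
configurable mapping (default: consecutive channel pairs over
0/1.5/5/15/30 min).

## Expression clustering

Counts are stabilized as `log2(count/s + 1)` — a deliberate shifted-log
proxy for regularized NB transforms: monotone, desk-scale and
variance-flattening (tested: high/low-mean variance ratio < 3), not an
emulation of any specific tool. Top-n selection is by row variance over
the pooled sample set (ties by gene id). Clustering Z-scores rows, takes
Euclidean distances and Ward linkage; if k is not forced, it is the argmax
over k = 2..10 of the second difference of the within-cluster sum of
squares (the elbow). Agglomeration is deterministic. The per-cluster
ETNN-vs-other comparison uses the two-sided Wilcoxon rank-sum test: exact
enumeration when min(n, m) ≤ 8 without ties, otherwise the normal
approximation with tie correction.

## Integration

Spearman correlations use average ranks; p-values come from the t
approximation, replaced by exhaustive permutation enumeration for n ≤ 9.
The coregulator screen passes a dataset iff its maximum Spearman
correlation with any reference factor column reaches 0.4; constant columns
are excluded with a warning. ORA is the one-sided hypergeometric upper
tail with BH across terms; odds ratios from the 2×2 table (Haldane 0.5
correction only when a margin is zero). Region-to-gene matching for the
correlation analyses uses the nearest TSS to the region midpoint, ties to
the lexicographically smaller gene id; "regulatory" regions are those
annotated non-promoter by the feature prioritizer (Promoter > 5'UTR >
3'UTR > Exon > Intron > Downstream > Intergenic; promoter window
±3000 bp, downstream window 3000 bp — conventional defaults, not sourced
values; gene models without UTR/exon records never yield those labels).

## Synthetic fixtures: what they emulate and what a green test shows

All generators draw from one explicit seed; identical seeds reproduce
byte-identical outputs, and every planted object is recorded in a
`SimulationTruth` so recovery is scored without re-inference.

- **Peak sets** plant an all-factor shared core and per-factor private
  regions on a spaced anchor grid (membership never ambiguous), jitter
  replicate boundaries (N(0, 30 bp) by default), and add noise peaks with
  reproducible positions but independent per-replicate scores — the
  irreproducible IDR component. True-peak scores share a per-region
  strength across replicates (log-normal, sd 0.5) plus replicate noise
  (sd 0.2).
- **Counts** are NB draws at the planted per-sample scale with log-uniform
  base means (50-500 by default) and dispersion 0.1; the spike-in column
  is Poisson at 1e6 × scale.
- **The acetylation landscape** plants SE domains of 4 constituent peaks
  (3 kb apart) at 50× a flat uniform(0.5, 1.5) background. The background
  is deliberately tier-free: the stated design puts the heavy tail in the
  planted domains, so background-only landscapes yield no SE calls.
- **Phospho tables** assign each peptide one of up to six log2 dynamics
  templates (all swinging ≥ 2-fold) with per-channel noise, plus decoy
  spectra violating each retention rule. Clean spectra that would by
  chance trip a filter are deterministically repaired at generation time,
  making retained-count bookkeeping exact.

None of the fixtures model read-level noise, fragment sizes, GC or
mappability structure, overlapping gene architecture, isotope impurity, or
batch effects. A green suite therefore establishes that the algorithms
recover planted structure under the stated stochastic model — it does not
establish performance on real sequencing or MS data.

## Known limitations

- Two-group contrasts only; no covariates or interaction designs.
- No LFC shrinkage, blacklist filtering, or outlier (Cook's) handling.
- Median-of-ratios bias under near-global change is documented, not
  corrected; spike-in normalization is the intended route there.
- IDR with > 2 replicates is the conservative pairwise intersection, not a
  joint multivariate fit.
- The interval routines are plain-Python over DataFrames, sized for
  fixture-scale inputs (thousands of regions), not whole-genome peak sets.
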