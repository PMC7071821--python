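# Methods

`floranet` reimplements, as a tested and reusable pipeline, a comparative
analysis of gene co-expression during flower development across related
plant species with contrasting pollination syndromes (bee, butterfly,
hummingbird). The pipeline builds one signed weighted co-expression network
per developmental stage (an early bud stage and an intermediate pre-anthesis
stage) over orthogroups shared across species, identifies modules and their
hub/periphery structure, quantifies module preservation between stages,
tests module–trait association while controlling for phylogeny, and relates
per-orthogroup evolutionary rates (dN/dS) to network position. Every stage
is exercisable end-to-end on seeded synthetic data.

## Preprocessing

The input is an orthogroup × sample count matrix with sample metadata
(species, stage, replicate). The chain is: variance-stabilizing transform →
quantile normalization → orthogroup filtering → optional confounder-PC
regression, per stage.

* **Variance-stabilizing transform.** A fully specified stand-in for the
  parametric transform of differential-expression tooling: median-of-ratios
  size factors (geometric-mean reference over rows with no zeros or missing
  values), then `log2(count / size_factor + 1)`. It removes library-size
  variation and compresses the count scale; it does not model the
  count-specific mean–variance relationship of the parametric original.
* **Quantile normalization.** Classic mean-of-order-statistics
  normalization; ties receive the average of the reference values they
  span; missing values are excluded from rank computation and columns with
  missing entries are mapped through interpolated quantiles.
* **Filtering.** Orthogroups with more than 50% missing values (judged on
  the raw matrix) or expression variance below 0.3 in either stage are
  removed; the removal rule is strict (`< 0.3` removes, exactly 0.3 is
  kept) and the surviving rows are intersected across stages. The variance
  threshold is applied to *transformed* values: a 0.3 cutoff is only
  meaningful on a log-like scale. Both interpretations (raw vs transformed
  variance; zero-count vs missing-orthogroup missingness) are configurable.
* **Confounder removal.** Each orthogroup is regressed on the top-k
  sample-space principal components of the standardized matrix and replaced
  by its residuals (row mean restored). `k='auto'` keeps components whose
  eigenvalue exceeds the 95th percentile of 100 within-row permutation
  nulls (a Buja–Eyuboglu-style parallel analysis).

## Network construction

* **Correlation.** Tukey biweight midcorrelation with outlier capping:
  weights `(1 − u²)²` for `u = (x − median)/(9·MAD)`, with `u` rescaled per
  side so at most `maxPOutliers = 0.05` of the points receive zero weight.
  Genes with zero MAD fall back to Pearson (logged); pairs with fewer than
  4 shared non-missing samples are recorded missing. Because the biweight
  transform depends only on each gene's own values, the complete-data
  matrix is a single product of transformed rows.
* **Soft threshold.** Signed adjacency `a_ij = ((1 + cor)/2)^β`. β is the
  lowest power in the grid (1–20, then 22–30 by 2) whose signed scale-free
  fit reaches 0.9. The fit index bins connectivity into 10 equal-width bins
  on the raw k scale and regresses `log10 p(k)` on `log10 k̄`; signed fit is
  `−sign(slope)·R²`. Powers that leave the median node effectively
  disconnected (median k < 1) are excluded from selection: their fit
  indices are degenerate. When no power qualifies, the best-fitting
  eligible power is used (or a caller-supplied fallback), with a warning.
* **Topological overlap.** Signed TOM,
  `TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)`;
  clustering uses average linkage on `1 − TOM`.
* **Module detection.** A gap-based dynamic branch decomposition: a branch
  counts as a module when the merge that absorbs it into the rest of the
  dendrogram sits well above its own top merge (its *detachment gap*,
  relative to the dendrogram height range, exceeds a threshold mapped from
  deepSplit 0–4 → 0.20/0.10/0.05/0.025/0.01; default deepSplit 2). The
  deepest qualifying branches of at least `min_module_size` (default 20, a
  conventional lower bound for stable eigengenes)
  become modules; everything else is unassigned (label 0, the ME0 set).
  Qualifying sub-branches of one module are rejoined by the eigengene merge
  step: modules whose eigengenes are closer than `mergeCutHeight = 0.25`
  (dissimilarity `1 − cor`) are merged iteratively. Labels are renumbered
  by decreasing size. The PAM-style refinement of the hybrid tree cut is
  not implemented.

## Module statistics

Eigengenes are the first principal component of the module's standardized
expression, oriented to correlate positively with the module mean profile
and scaled to unit sample variance. kME is the Pearson correlation of a
gene with each module eigengene. Connectivity is the off-diagonal adjacency
row sum, split into kWithin/kOut by module co-membership. Hubs are genes
with own-module kME strictly above 0.9 (unassigned genes are never hubs);
the periphery is the `floor(0.1·N)` least-connected genes over all genes
including ME0, ties broken by gene id. Cross-network overlap uses Fisher's
exact test (hypergeometric two-sided p) with both the sample odds ratio
(0.5 Haldane correction when a cell is zero) and the conditional-MLE odds
ratio reported, since the two conventions differ on real tables.

## Module preservation

Permutation Z statistics against random same-size gene sets from the
common universe (200 permutations by default), with a "gold" calibration
module of `min(1000, universe/2)` randomly selected orthogroups. Component
statistics: two density (mean within-module test correlation; proportion of
test variance explained by the module eigengene) and two connectivity
(Spearman correlation of intramodular connectivity between reference and
test; Pearson correlation of kME). Zdensity/Zconnectivity are the medians
within class; Zsummary their mean; medianRank the median over the four
observed-statistic ranks across modules. Published preservation composites use a
larger battery of component statistics; this subset preserves the
Zdensity/Zconnectivity/Zsummary architecture and the calibration of the
published thresholds (>10 strong evidence, <2 no evidence, strict
inequalities) on planted fixtures.

## Phylogenetic module–trait association

A categorical trait is regressed on a module eigengene at species level
(species-mean eigengene over replicates) with a probit threshold model:

    z_s = b0 + b1·x_s + u_s + e_s,   y_s = 1{z_s > 0},
    u ~ N(0, σ²·C),  e_s ~ N(0, 1 fixed),

where C is the tree's shared-path-length correlation matrix. σ² carries an
inverse-gamma(0.001, 0.001) prior; the residual variance is fixed at 1 for
identification. Multi-level traits are decomposed one-vs-rest. Fits are
repeated over a set of candidate ultrametric trees (default 50, sampled
without replacement; with replacement plus a warning when fewer exist) and
two chains of 250,000 iterations with 50,000 burn-in per tree; posterior
samples are pooled across chains and trees.

Sampler design (all conjugate or one-dimensional; no tuning):

* latent liabilities by single-site truncated-normal Gibbs against the
  *collapsed* covariance `σ²C + I` (the phylogenetic effects are integrated
  out, removing the slow u↔σ² coupling);
* fixed effects by a GLS conjugate normal update;
* σ² by an independent inverse-CDF draw on a 600-point log grid of its
  one-dimensional conditional;
* one Metropolis *scale move* per sweep, proposing `(cz, cb, c²σ²)` with
  log-normal c: threshold models are nearly invariant along this ray, and
  the joint proposal traverses it far faster than coordinate updates.

Two identification choices matter and are deliberate. First, the
inverse-gamma(0.001, 0.001) prior is nearly flat in log σ², and with a
dozen species a threshold likelihood plateaus as σ² → ∞, so the posterior
would otherwise escape to astronomically large latent scales; the prior is
truncated at σ² = 10³ (liability-scale heritability 0.999), which excludes
only that degenerate region. Second, fixed effects are reported on the
unit-variance latent scale, `b/√(1 + σ²)` — the standard scale-invariant
parameterization for threshold models — with raw-scale draws retained.

Significance: the pooled 95% credible interval excludes zero. Species are
flagged when *all* replicates have eigengene values above +1.0 (or below
−1.0); an association is **strong** when at least two flagged species share
the significant trait level, **weak** when at most one does. The ±1.0
threshold is expressed on the unit-variance eigengene scale and is
configurable.
Convergence is monitored by the Gelman–Rubin PSRF
(`sqrt(((n−1)/n·W + B/n)/W)`) and an initial-positive-sequence
autocorrelation ESS, both on the rescaled fixed effects.

## Evolutionary rates

dN/dS (ω) per orthogroup is estimated by Nei–Gojobori (1986) counting:
per-codon synonymous/nonsynonymous site fractions (changes to stop codons
count as nonsynonymous), pathway-averaged difference counts for multi-hit
codons (pathways through stops are excluded; if all pathways cross a stop,
all are used), Jukes–Cantor correction `d = −¾·ln(1 − 4p/3)`, and the
orthogroup estimate `ω = mean(dN) / mean(dS)` over all sequence pairs.
This is a stand-in for a maximum-likelihood one-ratio codon model (as
fitted by codeml); counting is downward-biased under transition/transversion bias
(roughly 15–20% at κ = 2 on the simulator's output — the round-trip tests
document a 25% tolerance), and every report states the estimator. A
user-supplied ω column can replace it downstream.

Rows are removed when ω equals the 999 sentinel (zero synonymous
differences), is invalid (dS = 0 or a saturated correction), or when ω,
connectivity or mean expression is non-positive (all enter log-scale
models). The rate models are: OLS of log ω on log kTotal × log mean
expression with overall F, per-term η², and case-resampling bootstrap
percentile CIs (default 10,000 pseudoreplicates; `n_boot = 0` degrades to
point estimates); one-sided permutation Welch t-tests (hubs lower /
periphery higher, 10,000 permutations, `+1`-corrected p, Cohen's d on
pooled SD) — Welch's unequal-variance statistic is used because hub and
background groups differ in size and spread; and OLS of log ω on the module
syndrome-association factor with "none" as reference level.

## Synthetic data

The generator plays the role of the study system: 12 species on an
ultrametric tree, two stages × 2–3 replicates, planted modules, and codon
alignments.

* **Tree.** Pure-birth (Yule) with exponential waiting times, rescaled to
  unit root depth. Ultrametricization of arbitrary trees uses mean-path-
  length smoothing (each node's depth rescaled by global over subtree mean
  tip depth, clipped monotone).
* **Traits.** Syndromes evolve by a Markov walk along branches (switch
  rate 2.0 per unit depth, resampling from the stationary proportions), so
  syndromes are phylogenetically clustered but a 12-species draw usually
  contains more than one — matching the mixed syndrome composition of the
  study clade. Color, shape and corolla spur are then drawn from the
  syndrome's trait suite; spurs occur only with the butterfly syndrome.
* **Expression.** Per stage and module, a species-level eigengene =
  Brownian motion on the tree (+ configured trait shifts, in units of the
  Brownian SD) + replicate noise, standardized across samples. Gene i is
  `√r_i·eigengene + √(1−r_i)·noise` with per-gene membership r_i jittered
  around the target within-module correlation (uniform ± `cor_jitter`), so
  modules have hub-to-periphery structure; background genes are pure noise.
  Values live on a log2 scale around per-gene baselines (uniform 4–10) and
  are exponentiated to a count-like scale. Library sizes are uniform —
  library-size variation and count-level (Poisson/NB) noise are *not*
  simulated, so passing tests say nothing about robustness to those.
  Because the variance-stabilizing transform estimates size factors by the
  median ratio, fixtures in which planted modules dominate the gene count
  (≥ ~50%) leak module signal into the size factors; recovery fixtures
  therefore keep modules a minority of genes (≈25%), as in real data.
* **Codon alignments.** A Muse–Gaut-style 61-state rate matrix with
  uniform codon frequencies: single-nucleotide changes only, κ (default 2)
  for transitions, ω scaling nonsynonymous changes, normalized to one
  expected substitution per codon per unit branch length and scaled by
  `tree_scale` (default 0.5, keeping pairwise synonymous divergence well
  below Jukes–Cantor saturation at depth-1 trees). Sequences evolve
  site-independently by matrix exponentials along branches; stop codons are
  excluded from the state space.

## Benchmark scenarios and problem sizes

The packaged acceptance script (`scripts/acceptance.py`) recomputes five
methodological bounds on generator output; sizes were chosen so the whole
script runs in minutes on one CPU:

* **MCMC convergence.** The trait is drawn from the probit model itself
  (slope 1.0 on a planted module's species-mean eigengene, unit Brownian
  effect, unit residual) — a moderate, non-separable effect with
  phylogenetic signal; deterministic trait constructions produce complete
  separation, which puts the slope on the prior scale and makes
  convergence statistics meaningless. Reference sampler settings (2 ×
  250,000 iterations) are used unchanged.
* **Scale-free fit.** 500 genes: 10 modules with a decreasing size
  distribution (90…10), graded membership (mean within-module correlation
  ≈ 0.7, spread ±0.26) and a 150-gene unassigned fraction — the
  composition real transcriptome networks have. Ten equal crisp blocks
  produce an *anti*-scale-free degree distribution and no power selection
  procedure would (or should) reach the criterion on them.
* **Preservation.** One 30-gene module (correlation 0.8) + 300 background
  genes, two stages from the same generator, 200 permutations; the
  no-preservation row replaces the test-data module block with independent
  noise.

Tests scale simulation counts to suite-friendly sizes (e.g. 60 null
datasets, shortened chains for power checks); the reference chain settings
are exercised where the claim is specifically about them.

## Known limitations

* The dynamic tree cut is the gap-based tree variant; no PAM refinement,
  so borderline genes near module boundaries tend to stay unassigned.
* The preservation composite uses 4 component statistics, not the full
  published battery; absolute Z values are comparable only in calibration
  (>10 / <2 behaviour), not numerically.
* NG86 counting is biased relative to ML codon models; analyses of real
  data should inject ML estimates via the ω-column adapter.
* The probit one-vs-rest decomposition is not a joint multinomial model;
  per-level significance calls are what it reproduces.
* Desk scale only: dense gene × gene matrices (≲15,000 genes); no
  block-wise approximation.
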