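# Methods

## The problem and the model

Rhizosheath size — the mass of soil that stays bound to the root system
after gentle shaking — is quantified as the ratio RAS/RT of root-adhering
soil dry mass to root tissue dry mass.  The package maps the genetic control
of this trait in an F2 population from two inbred parents by bulked-segregant
analysis (BSA): the phenotypic extremes of the F2 are pooled into a low and a
high bulk, both bulks are sequenced, and loci where the bulks' allele
frequencies diverge mark QTLs.

At a biallelic marker with alternate-allele frequencies `f_aL` and `f_aH` in
the low and high bulks, the per-marker statistic is the Euclidean distance
between the bulk frequency vectors

    ED_m = sqrt((f_aL − f_aH)² + (f_AL − f_AH)²) = √2 · |f_aL − f_aH|,

ranging from 0 (identical bulks) to √2 (opposite fixation).  A literal
"within-bulk" form `sqrt((f_aL − f_AL)² + (f_aH − f_AH)²)` is also exposed
(`variant="within"`); it measures the distance of each bulk from 1:1 rather
than divergence between bulks and cannot distinguish the direction of
selection, so the between-bulk form is the default.  To suppress
read-sampling noise, ED is summed over sliding windows of 100 consecutive
markers and the sum is raised to the fourth power (ED⁴), assigned to the
window-centre marker; windows never cross chromosome boundaries, and markers
without a full window carry no value.  The alternative windowing
`sum of ED⁴ over the window` is available (`stat="pow4sum"`).

Alleles are polarized before scanning so that the reference allele is always
the low-phenotype parent's allele; the alternate allele then measures the
high-parent contribution in both bulks.

## Filter cascade

Raw pooled calls pass an ordered cascade, each removal attributed to the
first applicable rule:

1. multiallelic sites;
2. pooled alternate-allele read fraction (both bulks combined) < 0.25.  The
   published wording "total allele frequency less than 0.25" is ambiguous;
   the one-sided reading on the alternate allele is the default because,
   after polarization, a genuine F2 marker segregates near 0.5 and the rule
   plainly targets artefactual low-frequency calls.  A symmetric option
   (also dropping > 0.75) is available;
3. total per-site depth (summed over both bulks) outside the [25th, 95th]
   percentiles of the post-step-2 depth distribution.  Percentiles use
   linear interpolation between order statistics; boundary values are kept,
   so a constant-depth table loses nothing.  The bounds are recorded in the
   filter report; re-running with bounds frozen from a first pass is
   strictly idempotent;
4. missingness: with two bulk samples, ">50% missing" is operationalized as
   "missing in at least one bulk" (a bulk is missing when it contributed no
   reads at the site);
5. pooled minor-allele frequency < 5%, computed on read counts.

## Significance threshold

The published analysis draws a "95% confidence interval" line without
describing its construction, so the package builds one by simulation.  Under
the no-QTL null, each bulk's composition at a marker is a draw of
`bulk_size` F2 genotypes from the Mendelian 1:2:1 distribution; read counts
are Binomial(observed site depth, pooled bulk frequency).  The windowed
statistic is computed on each simulated genome, and the default threshold is
the (1 − α) quantile of the per-genome *maximum*, which controls the
family-wise false-positive rate over all ~10³–10⁴ windowed markers.  A
pooled per-marker quantile mode is available for exploratory scans.  α = 1
is honoured as a limiting case (threshold 0: every windowed marker flagged).

**Known limitation.**  The null redraws bulk composition independently at
every marker and therefore ignores linkage: in real (and fully simulated)
bulks, allele frequencies of nearby markers are strongly correlated, which
inflates the variance of the window sum relative to this null.  The
threshold is consequently anti-conservative on tightly linked designs — the
worked example in the README shows a small spurious region on the chromosome
that carries no QTL.  Calibration checks in the test suite are therefore
self-consistency checks against the same marker-by-marker null (fresh null
genomes vs. the threshold's quantile), not against linked genomes.  A null
that resamples whole bulks from a simulated F2 would capture linkage at
roughly 100× the cost; it is left as an extension.

## Region calling and GWAS overlap

A significant marker is localized no better than the physical span of the
100-marker window that produced its statistic, so each significant marker
contributes that span; overlapping or abutting spans merge into one region
(closed, 1-based bp internally; BED conversion only at export).  Each region
reports the marker of maximal ED⁴ as its peak, its limits, length
(end − start) and the number of significant markers inside; regions are
named `RAS<chrom>.<k>`.  GWAS hits contribute ±50 kb windows, merged when
they overlap; the overlap report gives, for every same-chromosome
region/window pair, the overlap length, the gap when disjoint, and the
distance from the region peak to the window edge and to the underlying hit.

## Phenotype statistics

* **Block model.**  One-way fixed-effect ANOVA of log(RAS/RT) on phenotyping
  block (natural log; the base only rescales residuals and cannot change
  their ranking).  Rows with nonpositive ratios are excluded and counted.
  Residuals — log ratio minus block mean — rank the F2 for bulk selection:
  k = round(tail × n) smallest and largest residuals (547 × 10% → 55), ties
  broken by id.
* **Heritability.**  One-way random-effects model value = μ + line + ε.
  Default estimator: ANOVA method of moments with the effective replicate
  number n₀ = (N − Σnᵢ²/N)/(k − 1) for unbalanced designs and negative line
  variance truncated to zero; REML via `statsmodels` MixedLM behind
  `method="reml"`.  H² = Var(line)/(Var(line) + Var(res)/n̄) with n̄ the
  average plants per line.  The estimate is invariant to affine transforms
  of the phenotype.
* **Trait correlations.**  Pairwise Spearman by default (Pearson
  selectable), complete cases per pair, ≥3 observations required, constant
  traits reported as missing; r² is the squared coefficient.  Adjusted
  (least-square) line means across experiments come from the additive
  two-way fixed-effect fit value ~ line + experiment, averaging predictions
  over experiments.
* **Mycorrhization.**  From 0–5 fragment scores: frequency
  F = n/N × 100 and intensity I = (95·n5 + 70·n4 + 30·n3 + 5·n2 + n1)/N,
  both in percent.

## Synthetic data generator

The generator emulates the study design and is the test bed for every stage:

* **Meiosis.**  Crossovers follow a Poisson process on the genetic map with
  no interference (Haldane).  Restricted to the marker positions this is a
  Markov chain whose switch probability between adjacent markers is the
  Haldane recombination fraction c = (1 − e^(−2d))/2 — the implementation
  uses that chain directly, which is distributionally identical at the
  markers and vectorizes.  Physical and genetic coordinates are related by a
  uniform per-chromosome rate.  A zero-length map with several markers is
  flagged as degenerate (warning, not error).
* **Phenotypes.**  log(RAS/RT) = grand mean (default 3.1, i.e. ratio ≈ 22)
  + block effect (round-robin blocks, N(0, 0.15)) + QTL effects
  a(g − 1) + d·1{g=1} at the marker nearest each QTL + residual.  The
  residual SD is derived from the realized genetic variance to hit
  `heritability_target`; contradictory settings (target 1 with nonzero
  residual, a nonzero target with no QTL) are rejected.  Root tissue mass is
  lognormal around 0.35 g, and RAS mass is ratio × RT, keeping ratios on the
  observed 1.6–55 scale.
* **Pooled reads.**  True bulk frequency = mean genotype/2; per-site depth
  is gamma-Poisson around `mean_depth` (default 875, the study's mean of
  887X/863X) with dispersion 0.2; alternate reads Binomial(depth, freq);
  2% missingness and 2% multiallelic contamination by default so the filter
  cascade has work to do.  Seeded runs are bit-reproducible.
* **Not modelled:** library preparation, alignment error, genotype-calling
  error, non-uniform recombination, segregation distortion, multi-QTL
  epistasis.  Passing tests therefore demonstrate correctness of the
  statistics under the stated sampling model, not robustness to those
  artefacts.

## Validation scenarios and problem sizes

`rhizoqtl.scenarios` fixes the desk-scale designs the acceptance checks run:

* **QTL recovery** — 547 F2 on two 40 Mbp chromosomes of 2,000 markers each
  at 1 cM/Mbp (about the pearl-millet average recombination rate), one
  additive QTL mid-chromosome 1 explaining 25% of phenotypic variance,
  depth 200X, 10% bulks of 55, per-run simulated-null threshold
  (200 genomes).  The 100-marker window then spans ~2 Mbp, matching the
  2 Mbp localization tolerance; across 100 seeded runs the called region
  covers the true QTL in ≥90% and the global ED⁴ peak lands within 2 Mbp in
  about 90% of runs.
* **Threshold calibration** — two 2,000-marker chromosomes, bulks of 55,
  depth 200; threshold from 1,000 null genomes, family-wise false-positive
  rate measured on 200 fresh null genomes (nominal 5%).
* **Heritability recovery** — 181 lines × 1,408 plants, Var(line) = 1,
  Var(res) = 3, so the generating H² = 1/(1 + 3/7.78) ≈ 0.72; 200 replicate
  trials.

## Numerical conventions

1-based closed intervals internally; BED is 0-based half-open at export
only.  Percentiles: linear interpolation.  Window centre: index
start + (window − 1)/2 rounded down.  Bulk-size rounding: nearest integer.
Ties in bulk selection: id order.  All randomness flows through
`numpy.random.default_rng` seeded from the configuration, so equal
configurations give byte-identical outputs.
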