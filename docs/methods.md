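# Methods

This note documents the statistical models, the numerical choices, and the
synthetic-data conditions under which the package validates itself.

## Study design assumed by the pipeline

The sampling design is ten sites nested pairwise in five landscapes, with
two cohorts (reproductive adults and juveniles) genotyped at codominant
microsatellite loci, and open-pollinated maternal sib families grown in a
randomized nursery design.  Node-level analyses treat sites as units
(n = 10); link-level analyses treat the site pair within each landscape as
the unit (n = 5).  Landscape structure is measured in circular buffers:
0.5 km around each site (node) and 2/4/6 km around each pair midpoint
(link).

## Neutral estimators

* **He** — unbiased expected heterozygosity per locus,
  `(2n/(2n−1))(1 − Σp̂²)`, averaged over loci with ≥ 2 genotyped diploids.
* **AR** — rarefied allelic richness,
  `Σ_a [1 − C(N−N_a, g)/C(N, g)]` per locus; the default rarefaction size g
  is the smallest non-missing gene-copy count across populations at that
  locus, so sites are compared at a common sample size.
* **f, F_IS, F_ST, F_IT** — Weir–Cockerham variance components, summed over
  alleles and loci before taking ratios.  Multilocus estimators are always
  ratios of summed components, never averages of per-locus ratios.  Slightly
  negative F_ST estimates are reported as-is (standard convention).
* **G′_ST and Jost's D** — computed from within-population (H_S) and total
  (H_T) gene diversities on plain allele frequencies (populations weighted
  equally), with H_S and H_T averaged across loci before the final ratio.
  Degenerate cases (H_S = 1) return NaN, not zero.
* **R_ST** — among-population fraction of allele-size variance from the
  one-way ANOVA on gene copies, multilocus by summing components.  The
  R_ST = F_ST test permutes the size labels among allelic states within each
  locus, which destroys stepwise-mutation memory while preserving the
  frequency structure; p = (1 + #{permuted ≥ observed})/(n_perm + 1) with
  10,000 permutations by default (seedable).
* **Hierarchical AMOVA** — three levels (landscape / population / within).
  Distances between gene copies are allele mismatches, so all sums of
  squares reduce to combinatorial counts of allele-count matrices; variance
  components use the standard unbalanced-design coefficients, computed per
  locus and summed.  F_CT significance permutes whole populations among
  landscapes; F_SC permutes individuals among populations within their
  landscape.  When there is no variation below the landscape level at all,
  F_SC is reported as 0 (no sub-structure) rather than NaN.
* **Missing data** — per-locus pairwise deletion everywhere; an individual
  is missing at a locus when either allele is missing; rarefaction sizes are
  computed after deletion.

### Effective size from molecular coancestry — a documented limitation

Ne is estimated as `1/(2 f̄)` from the mean pairwise molecular coancestry,
chance-corrected per locus with `f = (s − m)/(1 − m)`, `m = Σp̂²`, combined
across loci as a ratio of sums.  When the chance term is estimated from the
sample itself, the mean corrected coancestry over distinct pairs is
algebraically `−f̄_self/(n−1)` — the ordered-pair mean including
self-comparisons equals `Σp̂²` exactly — so for samples without strong
internal clone or sib clusters the estimate is non-positive and Ne is
reported as undefined (NaN).  This mirrors the "Infinite" outputs this class
of single-sample estimators is known to produce.  The raw (uncorrected)
variant is available but conflates chance matching with coancestry.  The
pipeline drops Ne as a model-selection predictor when it is undefined and
records that in the manifest.  Fully degenerate data (every individual the
same homozygote) sit at the f̄ = 1 limit and return Ne = 0.5.

## Quantitative genetics under mixed mating

Wright's-equilibrium relations link the juvenile-marker inbreeding f to the
selfing rate and the within-family coancestry:

    s = 2f/(1+f),  θ = (1+3f)²/(8(1+f)),  c = 2θ = (1+s)²/(2(2−s)).

Negative marker-based f estimates are clamped to 0 (with a warning) before
the correction.  The additive variance is `V_a = σ²_fam / c`; we read the
divisor this way because it is the only reading consistent with c = 2θ and
the half-sib limit V_a = 4 σ²_fam.  Heritability is truncated at 1 (with a
warning); CV_a% is undefined for non-positive trait means.

**REML.**  Variance components are estimated by REML implemented directly:

* one-way model (family within one site): the likelihood is profiled down to
  the variance ratio γ = σ²_fam/σ²_e and minimized by bounded 1-D search
  (absolute tolerance 1e-12 on γ).  For balanced data the interior solution
  equals the ANOVA closed form (MS_B − MS_W)/n₀; agreement is tested at
  1e-6.  The degenerate case of zero within-family variance is handled
  explicitly (σ²_e = 0, σ²_fam = variance of family means).
* nested model (site / family-in-site, used for Q_ST): dense REML with the
  residual variance profiled out and the two variance ratios optimized by
  L-BFGS-B from several moment-based starting points, including the
  boundary fits.  The dense formulation is O(N³) per likelihood evaluation
  and is sized for paired-site analyses (N of a few hundred), which is the
  regime the design targets.  statsmodels MixedLM serves as an independent
  cross-check in the test suite, not as the implementation.

**Q_ST / P_ST.**  Q_ST = σ²_site/(σ²_site + 2 V_a(within)) per site pair
within each landscape, truncated into [0,1].  P_ST (for field-measured seed
traits where V_a is not estimable) is c·σ²_B/(c·σ²_B + 2h²·σ²_W) from the
one-way site decomposition, with defaults c = h² = 1 and a mandatory
sensitivity sweep over c/h² ∈ {0.25, 0.5, 1, 2} — the defaults are the
conventional neutral assumption, and the sweep is the honest statement of
how strongly P_ST depends on it.

**Trait pruning.**  Redundant traits (|r| > 0.5) are removed greedily: drop
the trait with the most above-threshold partners, ties broken by column
order.  The greedy set is verified against exhaustive subset search on
designed cases.

## Landscape metrics

A raster cell belongs to a buffer when its center lies within the radius —
reproducible and resolution-convergent.  SHDI is −Σ p ln p over present
classes.  Habitat patches are 8-connected components (4-connectivity by
flag); functional connectivity at the node level sums the focal patch plus
all patches intersecting the 0.5 km buffer, at the link level all patches
intersecting the buffer; areas are cell counts × cell area (1 ha =
10,000 m²), with no polygonization.  A focal point off habitat falls back to
the patches within the buffer and is flagged.

The landscape-quality index follows a split-matrix-quality logic: expert
scores of each land-cover class for the pollinator and seed-disperser
species enter a centered PCA; PC1 class scores are ranked and linearly
rescaled to [1, 10] (a direct min-max rescale of raw PC1 scores is available
as an option, since rank-then-rescale and min-max are both defensible
readings of "ranked and rescaled").  The PC1 sign is oriented so the class
with the highest mean raw score receives the highest weight, removing the
usual sign ambiguity.  The rescaled weights are used directly as quality
(high = good); LQ = Σ (P_i/100)·W_i lies in [1, 10].  The resistance
(inverted) orientation can be obtained by reversing the scores upstream.

## Model selection

Scale of effect: per radius, the raw R² of the simple linear fit of the
response on the predictor; the radius with maximal R² wins, ties to the
smallest radius.  Adjusted R² is not used (documented choice; with a single
predictor the ranking differs only through the tie-break).

Collinearity: VIF_j = 1/(1 − R²_j) from regressing predictor j on the
others; predictors are dropped iteratively while any VIF exceeds 5
(strictly), largest first, ties by declaration order; perfect collinearity
(infinite VIF) is dropped first.

Candidates are Gaussian OLS models ranked by AICc with
k = #coefficients + 1 (the residual variance is counted — implementations
differ, so this is stated).  The null model is intercept-only OLS: a
"β = 0" reference on the same likelihood scale, which is the only form
whose AICc is comparable to the candidates'.  Akaike weights are
exp(−Δ/2) normalized; models with ΔAICc < 2 are flagged as equally
plausible.  At the link level (five landscapes) model choice rests on slope
significance instead, and every result with n < 8 carries a small-sample
flag.  No multiple-testing correction is applied across responses.

## Synthetic data: what it emulates and what it does not

* **Genotypes** — the Balding–Nichols construction: per locus an ancestral
  frequency vector over ~8 integer allele sizes; population frequencies are
  Dirichlet draws with concentration (1−F)/F, so E[F_ST] equals `target_F`
  exactly and recovery has a closed-form target.  Within populations,
  genotypes are autozygous with probability f = s/(2−s), reproducing the
  equilibrium heterozygote deficit of partial selfing.  Cohorts are
  independent draws from the same population frequencies (the null
  configuration — the motivating system showed no cohort differences);
  a cohort-effect option redraws frequencies per cohort.  There is no
  explicit mutation, spatial mating or dispersal kernel: size labels are
  assigned to frequency classes, which is exactly the exchangeability the
  R_ST permutation null assumes.  Consequently the generated data cannot
  show stepwise-mutation signal (R_ST > F_ST) and carry no pedigree
  structure, which is why the molecular-coancestry Ne is typically
  undefined on them.
* **Family phenotypes** — trait = mean + site + family + residual with
  family variance 2θV_a and residual (1−2θ)V_a + V_e, so the total
  phenotypic variance is V_a + V_e and the mixed-mating correction has a
  known truth.  No dominance, maternal effects, or genotype×environment
  interaction.
* **Rasters** — a seeded Gaussian field, smoothed with kernel radius
  `clustering` and sliced at the quantiles of the target class proportions;
  realized composition tracks targets within ~2 points on 200×200 grids and
  smoothing yields aggregated patches.  No landscape pattern realism beyond
  composition and aggregation is claimed.

Passing the recovery tests therefore demonstrates estimator correctness
under the stated generative models, not robustness to mutation processes,
null alleles, genotyping error, or spatially autocorrelated environments.

## Validation conditions and problem sizes

The validation suite and `scripts/acceptance.py` use: F_ST recovery at
targets {0, 0.05, 0.20} with 10 populations × 50 individuals × 20 loci over
20 seeds (tolerances ±0.02/±0.02/±0.04); inbreeding recovery at n = 500
(±0.03); V_a = V_e = 10 with 100 families × 20 offspring over 20 seeds
(±10% at s = 0, ±15% at s = 0.5, and the uncorrected half-sib reading
overestimates by the c-ratio, ×3 at s = 0.5); null Q_ST with 2 × 10
families × 10 offspring; null calibration with 200 permutation replicates
(99 permutations each) and 300 OLS replicates, KS at α = 0.01; and
planted-effect recovery (He linear in SHDI at 500 m, R² = 0.8 by
construction, 10 sites) over 50 seeds with a ≥ 80% selection-rate
criterion.  These sizes were chosen as the smallest designs at which the
estimators' sampling noise is clearly below the stated tolerances.

All generators and permutation tests are deterministic given their seeds;
the pipeline derives per-stage seeds from one root seed via
`numpy.random.SeedSequence`.

## Known limitations

* The nested REML is dense (O(N³)); very large family designs would need a
  sparse or per-block formulation.
* G′_ST and Jost's D use plain frequency estimators without small-sample
  bias correction; on few, small samples they inherit the usual upward bias
  of H_T-based measures.
* The molecular-coancestry Ne is structurally undefined for unstructured
  samples (see above); interpret defined values with care.
* The AMOVA defaults to the allele-mismatch (frequency-based) distance; the
  size-squared (R_ST-analog) variant is available via ``distance="size"``
  but the pipeline tables report only the default form.
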