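# Methods

## Score model

The expression-based polygenic score of individual *i* in brain region
*R* is

    score_i(R) = Σ_{j ∈ S_R} d_ij · β_j · s_g(j)

where `S_R` is the post-clump SNP set of the region's co-expression
network, `d_ij ∈ [0, 2]` the dosage of SNP *j*'s eQTL effect allele,
`β_j` the eQTL slope (per-allele change in the source gene's
expression), and `s_g(j) ∈ {+1, −1}` the sign of the source gene's
correlation with the anchor gene.  The multiplication by `s_g` makes the
score orientation-consistent: an allele that raises the expression of a
gene negatively co-expressed with the anchor moves the score down, so
the score tracks the network's anchor-aligned expression state.  The
combined corticolimbic score is the plain sum of the two regional
scores — no per-region standardization and no division by SNP count
(both are available as options, but summation is the reference
behavior).  A SNP appearing in both regional weight sets contributes to
both regional scores, hence twice to the sum (the regions are
constructed independently; `dedupe_combined` offers the alternative).

Missing dosages are replaced by the SNP's cohort-mean dosage, which
preserves each SNP's expected contribution under missingness completely
at random.  Allele orientation is resolved once, at harmonization:
records whose alleles match the cohort after swapping effect/other get a
`flip` flag and contribute via `2 − d`.  Flipping is inference-neutral —
it shifts every individual's score by the same `2β` constant, leaving
median-split labels, group contrasts and regression slopes unchanged
(property-tested).

## Network construction

Two sequential, boundary-inclusive filters define a regional network:

1. **Co-expression**: Pearson correlation of each gene with the anchor
   over the region's samples; retained iff |r| ≥ 0.5.  Pearson is the
   default estimator (Spearman is a config option).  Genes with zero
   variance have undefined r and are excluded with an explicit reason.
2. **Developmental enrichment**: mean expression in early postnatal
   samples (0–18 months) over mean adult expression (20–40 years);
   retained iff fold ≥ 1.5.  A pseudocount ε = 0.01 expression units is
   added to the adult mean so zero-expression denominators stay finite;
   at realistic expression levels (units of 10) its effect is ~0.1%.

The anchor gene is included in its own network with sign +1 by default
(`include_anchor=False` drops it); published network sizes can be read
either way, and both behaviors are supported.  Filter monotonicity —
raising either threshold never adds a gene — is property-tested against
a brute-force reimplementation.

When one matrix serves both filters, pooling early and adult samples in
the correlation step lets a shared developmental mean shift masquerade
as co-expression (two genes that are both early-enriched correlate
through the stage means alone).  The `corr_stage` option restricts the
correlation to one stage; pipelines built on a single developmental
matrix should set it (the synthetic study runner uses `early`).  With
separate sources for co-expression and development (the real-data
situation: a dedicated co-expression compendium vs a developmental
atlas), the pooled default is appropriate.

## Variant assembly

- **cis pairs**: catalog records are taken at face value for pairing
  (GTEx-style catalogs encode the cis relationship); the GRCh37
  annotation gates network-gene membership.  For synthetic catalogs the
  cis window is ±1 Mb of the gene.
- **Harmonization**: exact allele match → keep; swapped match → keep
  with flip; strand-ambiguous pairs (A/T, C/G) → drop by default
  (overridable); anything else → drop.  All drops are reason-coded.
- **Dedup**: a variant that is cis-eQTL for several network genes keeps
  the record with the smallest nominal p, ties broken by larger |slope|
  then lexicographic gene id — a total order, so the result is
  deterministic.
- **LD clumping**: greedy; index SNPs ranked by ascending eQTL nominal p
  (ties as above, then variant id), each index removes not-yet-retained
  SNPs within 250 kb whose dosage r² ≥ 0.2.  r² is the squared Pearson
  correlation of dosages in the analysis cohort itself, over pairwise
  complete observations.  The boundary is strict in the retained sense:
  removal at r² ≥ threshold, i.e. retained pairs satisfy r² < 0.2.  The
  post-condition (no retained within-window pair at or above the
  threshold) is re-verified exhaustively after every clump and audited
  by `max_retained_r2`.  Priority by eQTL significance mirrors standard
  GWAS-p clumping with the only per-SNP significance available here;
  window and priority are configurable since reference implementations
  differ.  Monomorphic SNPs are dropped before clumping.

## Association battery

- **Median split**: midpoint median; scores strictly above → high, at or
  below → low (ties to low, documented and deterministic).  Distinct
  scores give equal halves at even n; duplicated score values — which
  arise whenever two individuals share a genotype profile over the
  scored SNPs — produce unequal groups.
- **Baseline tests**: two-sample t from group summaries (Student pooled
  or Welch–Satterthwaite; `auto` switches to Welch when an F-ratio
  pretest rejects equal variances at α = 0.05, since the conditional
  rule needs an explicit test) and 2×2 Pearson χ² with Yates continuity
  correction by default.
- **Regression**: OLS of the outcome on the score, adjusting for sex and
  genotype principal components (default 3 — the typical
  population-stratification adjustment; configurable).  Complete cases;
  two-sided p from the t reference with residual df; rank-deficient
  designs raise and name the collinear columns.
- **Bonferroni**: `p_adj = min(1, m·p)` with the family size m an
  explicit configuration per outcome family, not something inferred.

### Power analysis

For a single regression predictor at Cohen's effect size f², the
noncentrality is λ = f²·n.  The default convention is the **one-sided
noncentral-t**: power = P(T(df, ncp=√λ) > t₁₋α(df)) with df = n − 2.
The two-sided noncentral-F convention (numerator df 1) is also
implemented behind a flag.  The two genuinely disagree — at f² = 0.02,
n = 202, α = 0.05 the one-sided t gives 0.64 while the two-sided F gives
≈ 0.52 — and published power figures for this design match the
one-sided-t convention, so that is the default; the package implements
both rather than reconciling them.  The analytic power is cross-checked
against a vectorized Monte-Carlo regression simulation (planted slope
√f², closed-form OLS, 10,000 replicates) to within 0.02.

## Synthetic data

The generators exist so every downstream stage has recoverable ground
truth; their defaults are chosen to emulate the study conditions at desk
scale.

- **Expression**: a shared latent anchor factor z per sample; gene g is
  `baseline·fold(stage) + noise_sd · (r_g z + √(1−r_g²) ε)`.  Additive
  construction on a positive baseline (default 10 units, noise SD 1)
  gives *exact* control of the planted Pearson r — which is all the
  correlation filter reads — while keeping expression positive (negative
  values would require ~9σ noise excursions).  Fold changes are planted
  on the stage means, so empirical mean_early/mean_adult converges to
  the target.  Correlation targets hold exactly within a stage; pooled
  across stages they are attenuated when fold ≠ 1 (see `corr_stage`
  above).
- **Genotypes**: block-LD via thresholded correlated Gaussians per
  haplotype.  Thresholding attenuates the correlation of the resulting
  0/1 alleles below the latent Gaussian r, so the latent correlation is
  solved per block by tetrachoric inversion (Owen's-T orthant
  probability, Brent root-finding); the *allele-level* correlation then
  equals the requested r and dosage r² converges to r².  One MAF per
  block, drawn from `maf_range` (equal within-block MAFs keep every
  target r up to 1 attainable for binary variables).  Missingness is
  completely at random, matching the mean-imputation contract.
- **eQTL catalog**: per network gene, SNPs placed uniformly in the cis
  window, slopes N(0, 0.5) (or pinned constant), nominal p log-uniform
  in [1e-8, 1e-1].  Slopes are the ground truth retained for recovery
  tests.
- **GWAS summary**: null SNPs get U(0,1) p-values and N(0, effect_sd)
  betas; non-null SNPs inflated betas and p = 10^U(−30,−5) — enough
  structure for threshold/top-k selection, not a model of polygenic
  architecture.
- **Phenotypes**: linear model with planted score/sex/PC coefficients
  plus Gaussian noise; seed-reproducible.
- **Study builder** (`simulate_study`): one expression matrix over the
  union of per-region gene panels (a gene planted for one region is null
  in the other, so networks cannot leak); planted pass/fail values sit
  far from the filter boundaries (|r| 0.8 vs 0.1 against a 0.5
  threshold; fold 2.0 vs 1.0 against 1.5) so sampling noise at the
  default sample sizes (120 early + 120 adult samples per region) cannot
  flip membership — planted network recovery is then exact for any seed.
  Each gene's cis-SNPs form LD blocks (size 3, allele r 0.85) so
  clumping has real structure to prune.

All generators are seed-deterministic; substreams are derived from one
global seed via CRC-32 stage labels, so stages are decoupled and
bit-reproducible across processes.

What the generators deliberately do not model: coalescent-realistic
haplotypes (no recombination gradients or allele-frequency spectra),
imputation dosage uncertainty (hard calls only), cross-tissue
correlation of eQTL slopes (regions drawn independently), informative
missingness, and X-chromosome variants (the filters are defined on
autosomal transcripts).  Passing tests therefore demonstrate the
correctness of the pipeline's mechanics and statistics under controlled
conditions — not that a real-data ePRS will associate with any
phenotype.

## Numerical and design choices

- Coordinates are 1-based inclusive (GRCh37/VCF convention) in every
  file and table.
- Dosages are oriented once (to the eQTL effect allele) and scoring
  never consults allele labels again.
- PLINK BED/BIM/FAM reading and writing is implemented directly (the
  2-bit SNP-major format), with the BIM allele1 column as the
  dosage-counted allele; VCF round-trips through GT + DS fields.
- The full-scale verification runs use 5,000 individuals and ~4,900
  SNPs (17 cis-SNPs per gene over 154- and 72-gene planted networks) —
  large enough for tight recovery of a planted −0.04 score coefficient,
  small enough to rerun routinely.
- Acceptance quantities are recomputed from scratch at every run of
  `scripts/acceptance.py`; nothing is cached or hard-coded.

## Known limitations

- Cohort-LD clumping only; no external reference panel.
- Multi-allelic variants and indels are excluded at schema validation.
- The stability analysis (childhood vs adulthood co-expression) uses
  average-linkage hierarchical clustering on 1 − r with a configurable
  cut height; cluster definitions, and hence the preservation statistic,
  depend on that choice as in any heatmap-based analysis.
- `simulate_study` plants co-expression through a single latent factor,
  so planted networks are one-block; it does not emulate multi-module
  co-expression topology.
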