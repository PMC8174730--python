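# Methods

## Problem and model

Quantitative anthropometric traits such as height and body fat
percentage differ on average between human females and males, and the
genetic associations underlying them can differ in strength by sex.
`sexdiffscan` implements a three-part analysis of sex-stratified GWAS
summary statistics:

1. **Sex-difference scan.** For each SNP with female and male effect
   estimates `b_f`, `b_m` (standard errors `se_f`, `se_m`), the
   heterogeneity statistic

   ```
   t = (b_m − b_f) / sqrt(se_m² + se_f² − 2·ρ·se_m·se_f)
   ```

   is computed, where ρ is the genome-wide Spearman rank correlation
   between male and female effect sizes for the trait.  `t` is converted
   to a two-sided P-value under a normal reference by default (`df`
   configurable: with cohort sizes in the 10⁵–10⁶ range the Student-t
   and normal references are numerically indistinguishable, so the
   infinite-df limit is the default and a finite df is accepted for
   exact replication against a t reference).  Within each trait, the
   P-values over the phenotype-associated SNP set (P < 5×10⁻⁸ in either
   sex) are Benjamini–Hochberg adjusted, and SNPs are classified at the
   four FDR thresholds 0.05, 0.01, 0.005, 0.001.  The multiple-testing
   universe is deliberately the per-trait phenotype-associated set, not
   the genome, because that is the set the statistic is applied to.

2. **Biological plausibility.** SNP sets are mapped to genes within an
   inclusive ±10,000 bp window and enrichment of the sexual
   differentiation GO term (GO:0007548) among genes co-localized with
   sex-difference SNPs is quantified as a ratio of proportions and
   tested by drawing unique genes from the pool of all co-localized
   GO-classified genes (a resampling test rather than Fisher's, because
   one gene can be co-localized with SNPs of both groups).  Pleiotropy
   with an external catalog trait is tested on an LD-pruned SNP set by
   a two-sided Fisher exact test (minimum-likelihood convention, as in
   R's `fisher.test`; the tail-doubling convention is available) and by
   a SNP-draw resampling test.

3. **Recent selection.** Raw singleton density scores (positive =
   derived allele rose in frequency over ~3,000 years) are sign-fixed
   into trait-SDS (positive = trait-increasing allele rose): the sign
   flips once if the effect allele is the ancestral allele and once
   more if the effect estimate is negative.  Mean trait-SDS of each
   pruned sex-difference SNP subset is compared with same-size draws
   from the corresponding pruned phenotype-associated pool; the
   empirical P is the one-tail proportion of replicate means at least
   as extreme as the observed mean — the tail taken in the direction of
   the observed deviation from the pool mean — multiplied by two and
   capped at one.  The same engine runs with per-SNP minor-allele-
   frequency matching (±0.05, without replacement within a replicate,
   subset order re-randomized each replicate), on |iHS| (SNPs without a
   score are excluded from that analysis only), and on the count of
   intergenic SNPs.  Each analysis family — the ten (trait × sex)
   tests — is BH-adjusted on its own, mirroring how the per-statistic
   result tables are reported.

## LD pruning

The genome is partitioned into ~1,703 approximately LD-independent
blocks (half-open 1-based intervals).  Pruning keeps, per occupied
block, the SNP minimizing a stated key; three keys are needed because
different analyses rank candidates differently: the sex-difference P
(cross-trait curated set), the sex-specific GWAS P (sex-split subsets),
and the better of the two sex-specific GWAS P-values (phenotype pools).
Key ties break to the smaller position, then the lexicographically
smaller identifier; SNPs outside every block are dropped with a logged
count.

## Synthetic data generator

The generator emulates the statistical structure the analyses consume,
with known ground truth:

* One chromosome of `n_blocks` equal-width blocks (default 1,703 ×
  200 kb); `n_genes` (default 2,570) uniformly tiled 20 kb genes, a
  fraction `frac_go_sexdev` flagged GO:0007548.
* MAF ~ Uniform(0.05, 0.5); SE per sex follows the quantitative-trait
  GWAS form `1/sqrt(2·n_sex·MAF·(1−MAF))` with the cohort sizes
  defaulting to 194,174 females and 167,020 males.
* A fraction `frac_assoc` of SNPs is causal for exactly one trait
  (round-robin over traits — this keeps per-trait associated counts
  balanced and every downstream per-trait analysis exercised without
  modeling cross-trait pleiotropy).  True effects are bivariate normal
  with scale `effect_sd` and correlation `rho_target`; observed betas
  add Normal(0, SE) noise with two-sided Wald P-values.
* `rho_target` is the correlation of *true* female/male effects.  Its
  default is 1.0: the two sexes share one true effect, which is exactly
  the null hypothesis of the sex-difference scan, so non-sex-
  differentiated SNPs are genuine nulls.  Values below 1 inject diffuse
  genome-wide heterogeneity (useful for studying the statistic's
  behavior, but then "non-sexdiff" SNPs are no longer null).
* A fraction `frac_sexdiff` of causal SNPs gets a magnitude boost of
  scale `sexdiff_effect_sd` in one randomly chosen ("stronger") sex, so
  that sex has the larger absolute effect — giving the log₂ effect-size
  ratio diagnostics a known direction.
* Raw SDS is standard normal; `sds_shift` adds a mean shift to the
  female-stronger sex-differentiated SNPs, applied through the
  alignment sign so the *trait-aligned* mean rises by the shift.
  |iHS| is half-normal; both score tables have configurable coverage
  (default 90%, associated SNPs always covered so injected signal
  survives the SDS-availability filter).
* Sex-differentiated causal SNPs are placed inside flagged-gene ±10 kb
  windows with probability `base_rate × sexdiff_placement_enrichment`
  (neutral at 1), and catalog annotations are applied at
  `catalog_rate`, boosted by `catalog_enrichment` on sex-differentiated
  SNPs.

`effect_sd` defaults to 0.05 trait SD per allele, which with the default
cohorts puts the typical true association around |z| ≈ 13 — i.e.
decisively past the 5×10⁻⁸ threshold, the regime of the large-biobank
anthropometric hits this pipeline targets.  This choice matters; see
the selection-bias note below.

What the generator does **not** emulate: within-block LD (block
membership only), realistic gene maps, cross-trait pleiotropy of causal
variants, allele-frequency-dependent effect sizes, population
stratification, or imputation artifacts.  Passing tests therefore show
the machinery is correct and calibrated under its stated model, not
that real-data results are free of those confounders.

## Winner's curse and FDR calibration

The scan is applied only to SNPs selected at P < 5×10⁻⁸ in at least
one sex.  Conditioning on that selection biases the selected sex's
effect estimate away from zero, which inflates the sex-difference
statistic for marginally significant SNPs even when the true effects
are identical.  On synthetic null bundles the realized false-discovery
proportion at q < 0.05 is near its nominal level when true effects are
decisively significant (mean FDP ≈ 0.075 at the default `effect_sd` =
0.05, ≈ 0.05 at 0.1 over 50 null trait families), but degrades sharply
when typical effects sit at the threshold (≈ 0.22 at `effect_sd` =
0.02, where the mean true |z| nearly equals the significance cutoff).
This is an inherent property of any two-stage select-then-test design,
not of the implementation; it is worth keeping in mind when the scan is
applied to traits whose hits cluster near the significance threshold.

## Numerical and convention choices

* **Boundaries.** Primary QC filters are strict (`>` 0.001 MAF, 0.8
  INFO, 10⁻¹⁰ HWE-P); the analysis MAF filter removes `< 0.05`, keeping
  exactly 0.05; the gene window is inclusive at exactly 10,000 bp.
* **Degenerate variance.** The heterogeneity variance
  `se_m² + se_f² − 2ρ·se_m·se_f` can collapse when ρ ≈ 1 with equal
  SEs; this raises by default, with an opt-in logged clamp to a small
  positive floor.
* **Ties.** Stronger-sex ties (equal sex-specific P) go to the larger
  |beta|, then female; pruning ties to smaller position, then smaller
  id.  All tie-breaks are logged.
* **Empirical P.** Plain proportion (no +1 correction, so a zero-
  exceedance floor is reportable as `< tails/reps`; the (r+1)/(n+1)
  correction is available behind a flag).  Resampling uses
  `argpartition` over uniform keys, chunked to bound memory, with one
  child seed per stage derived from the master seed via CRC-32-salted
  `SeedSequence` so stages are independently reproducible.
* **Log₂ effect ratios.** Both betas are oriented to the trait-
  increasing allele of the more significant sex; pairs left with
  opposite signs after alignment (no meaningful log-ratio) are excluded
  and counted.  The one-sample t-test on ratios is one-sided (greater
  for female-stronger sets, less for male-stronger); the
  ratio-vs-pool permutation reports one tail in the observed direction
  by default (`tails` configurable).  An all-zero ratio vector sits
  exactly on the null and returns the boundary P of 0.5.
* **trait-SDS alignment for pools.** The phenotype-associated pools are
  aligned by the more significant sex's beta (configurable); the
  sex-split subsets by that sex's own beta.
* **Per-trait vs intersected SNP universes.** Filtering is per-trait by
  default with an `intersect_traits` flag to force a common universe.

## Problem sizes in the test suite

Hand-checkable oracles (exhaustive enumeration, hypergeometric closed
forms) run at toy sizes; permutation-oracle agreement is asserted
within three Monte Carlo standard errors at 10,000 replicates.
Calibration and recovery suites use bundles of 2×10⁴–10⁵ SNPs: raw-P
uniformity on a 10⁵-SNP null bundle, realized-FDR estimation over ten
2×10⁴-SNP null bundles (50 trait families), and selection-recovery
power at the 9-subset-vs-181-pool geometry with a unit trait-SDS shift
over 100 simulations at 10,000 replicates each.

## Known limitations

* The gene-draw enrichment P is sensitive to the exact composition of
  the co-localized gene pool, which on small synthetic bundles can be
  only a few dozen genes; enrichment results there are directional
  checks, not calibrated estimates.
* Injecting a trait-SDS shift into a subset also shifts the pool that
  contains it, so the uninjected sex's subsets can drift mildly
  negative relative to the pool — visible in the worked selection
  example.
* MAF-matched resampling is a per-replicate sequential assignment; with
  very tight windows and small pools it can exhaust matches, in which
  case the replicate is redrawn a bounded number of times before the
  run aborts with advice to widen the window.
* The scan assumes the two sex cohorts are disjoint (independent
  errors given ρ); overlapping cohorts would need a different error
  model.
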