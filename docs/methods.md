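# Methods

## Statistical models

**Differential expression.** Each probe's log2 intensity is modelled per
cohort. Cohorts with one serum sample per subject use OLS on age, sex (a
single male indicator) and plate (indicator columns with the first plate
as reference); inference on the tested coefficient is a two-sided Wald t
test with residual degrees of freedom. The two-visit cohort uses a
random-intercept linear mixed model with an added week-22 indicator,
fitted by maximum likelihood (not REML), with a two-sided Wald test on the
ML estimator against a standard normal — the usual ML asymptotics. With a
single visit per subject the mixed fit degenerates to OLS (the profile
likelihood is flat in the variance ratio and the fixed effects coincide);
this reduction is asserted in the tests.

**Mixed-model fitting.** All repeated-measures models have exactly one
random intercept per subject, so ML fitting is a one-dimensional profile
likelihood in the variance ratio θ = σ²ᵤ/σ²ₑ. Given θ the marginal
covariance per subject is σ²ₑ(I + θJ), whose inverse and log-determinant
reduce to per-subject sums; β and σ²ₑ then have closed GLS/ML forms. θ is
located on a fixed grid ({0} ∪ 29 log-spaced points in [1e-4, 1e3]) and
refined by bounded Brent search between the bracketing grid points
(xatol 1e-10). The boundary θ = 0 is always a candidate, so the ML
log-likelihood never falls below the OLS value. Fixed-effect covariance is
σ²ₑ(XᵀΣ⁻¹X)⁻¹ at the ML variance estimates. The test suite checks
estimates, standard errors, variance components and log-likelihood against
a general-purpose ML mixed-model fitter (statsmodels MixedLM) to ~1e-5.
A singular design (true collinearity) yields a flagged, p-absent result;
per-pair monomorphic genotype columns are flagged before fitting.

**Inverse-normal transform.** pQTL traits are transformed per probe with
Blom scores Φ⁻¹((r − 3/8)/(n + 1/4)), average ranks on ties. The transform
fixes the trait's sample SD near 1, so a planted effect β on the raw log2
scale is recovered at approximately β/σ_total on the transformed scale;
validation checks use σ_total = √(σ²ᵤ + σ²ₑ + β²·2·maf·(1−maf)) as the
scaled truth. A constant trait is an error (ranks carry no information).

**Empirical permutation FDR.** With observed p-values as thresholds t,
FDR(t) = min(1, avg over iterations of #(permuted p ≤ t) / #(observed
p ≤ t)), counting pooled over all probes (or all cis pairs). The permuted
quantity is the exposure in differential expression — age or sex permuted
across subjects, both visits of a subject receiving the subject's permuted
value, which preserves the outcome correlation structure — and the
genotype subject identifiers in the pQTL scan (whole dosage rows move as
units, conserving allele frequencies and the within-subject sharing of a
genotype). One permutation per run; the default is 1000 runs for
differential expression and 10 for the pQTL scan (each pQTL run refits
every cis pair, and the pooled counting across pairs gives the null
distribution plenty of mass; both counts are configurable). The literal
FDR(t) is not monotone in t, so a monotonized q-value (running minimum
over decreasing t) is reported in a separate column; declaring discoveries
at a cutoff uses the q-value.

**Cis windows and leads.** Candidate pairs are all variants with
|position − gene anchor| ≤ 1 Mb (closed interval) on the same chromosome;
1 Mb is the field convention and is configurable. The gene anchor is a
single representative (TSS-like) position supplied in the probe
annotation. The per-probe lead SNP is the minimum-p pair, ties broken by
smaller |distance| then lexicographic variant id. The conditional scan
tests every variant in an explicit region (ignoring the window), adds the
conditioning variant's dosage as a fixed covariate and excludes that
variant from testing; a tested variant perfectly collinear with the
conditioning dosage is flagged.

**Heterogeneity.** Cochran's Q with inverse-variance weights and a
chi-square (k−1) reference. Note that recomputing Q from published
per-cohort estimates that were printed to two decimals is only
approximate: the rounded MMP7-style inputs (0.09/0.02, −0.01/0.03,
0.15/0.13) give Q ≈ 8.2 rather than the originally reported 7.16, because
Q is quadratic in the rounded SEs. The implementation therefore documents
this sensitivity and asserts only the closed-form example
((1,1,3) with unit SEs → Q = 24/9, p = exp(−Q/2)).

**Overlap enrichment.** For sets A, B on a background of N tested genes
the 2×2 table is a = |A∩B|, b = |B\A|, c = |A\B|, d = N−a−b−c; reported
are the expected overlap |A||B|/N, fold enrichment a/expected, the sample
(cross-product) odds ratio ad/bc — infinite-OR tables are flagged, not
raised — a secondary conditional-MLE odds ratio, and the two-sided exact p
(sum of tables with point probability ≤ that observed, the common
convention; alternatives differ in the third decimal). For
signature-overlap tests the default background is 1126 genes: the assay
measures 1128 proteins and inverting the published sample odds ratios
(6.29, 2.84) consistently implies ≈1126 distinct tested gene symbols. For
pQTL/eQTL overlap tests the background is the explicit shared tested list
(991 genes in the published comparison).

**GWAS rank enrichment.** A GWAS table is reduced to the variants covered
by the pQTL study, p-values are ranked ascending (average ranks on ties)
and each pSNP (scan p ≤ 1e-5 by default, closed threshold) gets relative
rank = rank/M. The rank–rank plot compares observed −log10 relative ranks
with uniform order statistics i/(k+1). Relative ranks are invariant under
monotone transformation of the GWAS p-values.

## Synthetic data

The generator reproduces the study conditions: cohorts of 84 CD (two
visits: baseline and week 22), 88 UC and 15 NC subjects (271 samples),
ages uniform within 18–64, 18–77 and 39–62 years respectively, sexes
Bernoulli(1/2), five plates. Ages are uniform because only ranges are
known for the design being emulated. By default samples are laid out
cohort-by-cohort and cut into contiguous plates, so plate and cohort are
confounded as in a plate-per-batch design — a literal round-robin would
balance cohorts across plates and destroy exactly the confound worth
demonstrating — with a `randomized` option for comparison. Genotypes are
Hardy–Weinberg: dosage ~ Binomial(2, maf) per subject, one variant at a
time (no linkage disequilibrium). Protein values are additive in age, sex,
plate shift, time point and cis dosage, plus a subject random intercept
and residual noise; the within/between-subject variances default to
σᵤ = σₑ = 1 log2 unit (unreported for the emulated assay, exposed in
config), and the time-point effect defaults to 0. Randomness is one seed
per operation with per-probe/per-variant sub-streams derived by hashing
the id, so adding a probe never reshuffles existing draws.

What the generator does **not** emulate: linkage disequilibrium between
variants (cis scans are exercised one causal variant at a time, so
conditional-scan behaviour under partial LD is untested), assay
normalization artifacts and intensity-dependent noise, non-uniform age
distributions, missing values (the intensity matrix is complete by
contract), and population structure. Passing tests therefore demonstrate
the statistical machinery under the assumed data-generating model, not
robustness to real-assay pathologies.

## Problem sizes and numerical choices

Property checks run at sizes chosen to make Monte-Carlo error small while
keeping the suite quick: the acceptance-level FDR calibration uses 50
seeds × 500 probes × 20 permutations (differential expression) and the
module-level pQTL calibration 8–10 seeds × 120–150 pairs × 8–10
permutations; cis-effect recovery uses 200 seeds at the genotyped cohort's
size (51 subjects × 2 visits); signature-recall and signal-absorption
checks use 20–30 seeds. All simulations are seeded, so every reported
fraction is deterministic. Calibration is judged as mean realized
false-discovery proportion ≤ nominal + 3 Monte-Carlo SDs of the mean.
Dosages are analyzed as continuous values in [0,2] (imputed dosages are
never rounded to hard calls); values outside [0,2] by more than 1e-6 are
an input error, within that tolerance they are clipped. No minor-allele-
frequency filter is applied; monomorphic variants are flagged per fit.

## Known limitations

- The permuted quantity in differential expression (the exposure) is a
  design choice; permuting outcomes or residuals would give slightly
  different nulls under strong covariate effects.
- Wald inference on the mixed model ignores uncertainty in the variance
  components (standard ML practice; anti-conservative for very few
  subjects).
- The literal FDR(t) column can be non-monotone and should not be
  thresholded directly; use the q-value column.
- The conditional-MLE odds ratio is reported alongside the sample odds
  ratio because published overlap tables do not always state which was
  used; they differ noticeably for extreme tables.
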