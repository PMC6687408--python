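# Methods

## The analysis in brief

Alleles that lower systolic blood pressure (SBP) through a drug's protein
target are a lifelong, randomized analogue of taking the drug. The pipeline
(i) selects such variants from SBP GWAS summary statistics restricted to
drug-target gene regions, (ii) estimates their effect on binary outcomes by
two-sample Mendelian randomization (MR), rescaled to the SBP reduction the
drug class achieves in trials so estimates read per "one treatment's worth"
of blood-pressure lowering, (iii) scans the phenome for side effects and
repurposing signals with a genetic risk score (GRS), (iv) checks that a
PheWAS hit is target-specific rather than a blood-pressure effect generally
via a matched-SNP permutation null, and (v) pools discovery and replication
cohorts by fixed-effects meta-analysis.

## Instrument selection

Within the target intervals, variants with *P* < 5×10⁻⁸ are greedily
clumped: records are ranked by ascending *P* (ties broken lexicographically
by variant id, so the output is invariant to input order), the best
remaining record is kept and all others with *r*² ≥ 0.1 against it are
discarded. Strength is summarized per variant by *F* = (β/se)² and
*R*² = 2·EAF·(1−EAF)·β²/var(trait); the trait variance is configurable with
default 1 (standardized betas), since different pipelines define *R*²
against raw or standardized traits.

Harmonization aligns outcome records to the exposure's allele orientation:
swapped alleles flip the beta sign and complement the EAF; strand-flipped
non-palindromic alleles are complemented first. Palindromic variants (A/T,
C/G) with outcome EAF in [0.42, 0.58] are dropped as strand-ambiguous —
a conventional window, surfaced as a parameter because no single standard
exists.

## MR estimators

Instruments retained at *r*² < 0.1 are correlated, so the IVW estimate is
generalized least squares through the origin with covariance Σ = D·r·D,
where r is the signed LD matrix and D = diag of outcome SEs:
β̂ = (xᵀΣ⁻¹x)⁻¹xᵀΣ⁻¹y, se = √((xᵀΣ⁻¹x)⁻¹). With identity LD this reduces
exactly to the textbook fixed-effect IVW of per-variant Wald ratios (a unit
test asserts equality to 10⁻¹⁰), and with a single instrument to the Wald
ratio. Exposure betas are treated as fixed (the standard two-sample
assumption); standard errors are fixed-effect, with optional inflation by
max(1, √(Q/df)) left to the caller via the reported Cochran's Q. MR-Egger
is the same regression with a free intercept (the intercept tests
directional pleiotropy, at the cost of much lower precision when exposure
betas span a narrow range). The weighted median uses the step-function
weighted quantile — the smallest ratio whose cumulative inverse-variance
weight reaches one half — rather than interpolation; this makes "one
variant carries the majority of weight" return exactly that variant's
ratio. Its SE comes from a seeded parametric bootstrap (1000 draws).

Before estimation, effects are re-signed so a positive exposure beta means
mmHg of SBP *lowering* (allele flips propagate to outcome betas, EAFs and
the signs of LD correlations); protective effects of an antihypertensive
then appear as OR < 1. Rescaling to a trial reduction multiplies beta and
SE by the constant (ACEI 21.14, BB 9.51, CCB 8.90 mmHg), leaving the z
statistic and *P* unchanged. Odds ratios convert to relative risks at an
assumed baseline incidence p₀ by RR = OR/(1−p₀+p₀·OR), applied to the
point estimate and both CI bounds; CIs are Wald at the fixed 95% level
(z = 1.959964).

## PheWAS

The GRS is Σⱼ wⱼ·dⱼ with wⱼ the per-allele SBP-lowering effect (alleles
aligned, opposite-allele dosages flipped 2−d, missing dosages mean-imputed
per variant) and is standardized to mean 0, SD 1 over the analysis cohort,
so associations read per SD of the score. ICD codes are case-folded,
dot-stripped and matched by most-specific prefix, since real maps mix
dialects. For each phecode: cases carry it; persons carrying only a
phecode inside its exclusion ranges are removed (related conditions would
contaminate controls); the rest of the cohort are controls — the three
sets partition the cohort by construction. Sex-specific phecodes restrict
the cohort to the applicable sex when the catalog marks one; constant
covariate columns (e.g. sex after such a restriction) are dropped from the
design automatically. Logistic regressions adjust for age, sex and
principal components (presets: 4 PCs for the discovery-biobank setting,
3 for the replication setting); phecodes with fewer than 200 cases are
skipped for power; non-converged or separated fits are flagged and removed
before Benjamini–Hochberg ranking at 5% FDR, so they do not distort the
number of tests.

## Permutation null

A hit for the drug-target GRS might reflect SBP lowering generally. The
null is built by resampling: k variants (k = the drug-target set size) are
drawn without replacement from genome-wide-significant SBP variants
clumped to *r*² < 0.001 (stricter than within-locus clumping because the
pool spans the genome), a standardized SBP-lowering-weighted GRS is built,
and the same adjusted logistic model is refit on the same case-control
set. The adjusted *P* is the fraction of permutations with the observed
effect direction and a smaller *P* (so 10 qualifying of 1000 gives 0.01).
Failed fits are excluded from the denominator (logged; configurable), and
a +1 correction is available but off by default to keep the plain-count
arithmetic. The permutation OR summary is the exponentiated mean log-OR
with both an empirical percentile interval and a normal-theory interval,
since either convention is seen in print.

## Fixed-effects meta-analysis

Pooling uses weights 1/se²; heterogeneity is reported as Cochran's Q and
I² = max(0, (Q−df)/Q). Standard errors are recovered from printed summaries:
from a 95% CI as (ln hi − ln lo)/(2·1.959964), or from a two-sided *P* as
|ln OR|/z(P). When both are printed the *P*-derived SE is preferred —
printed CIs are rounded more coarsely and can contradict the reported
significance — and this choice is what reproduces the printed pooled
estimate in the worked example.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
any particular population. Genotypes come from independent LD blocks: per
block, two haplotypes per individual are drawn from an exchangeable latent
Gaussian and thresholded at the allele-frequency quantile. Thresholding
attenuates correlation (tetrachoric vs Pearson), so the latent correlation
is calibrated by bisection on the bivariate-normal orthant probability so
that the *dosage* correlation equals the requested within-block r (the
calibration uses the block-mean MAF; with heterogeneous MAFs it is
approximate). SBP is intercept + Σ effectⱼ·dosageⱼ + N(0, 19²) mmHg, with
the intercept centered so the cohort mean sits at the configured 125 mmHg.
Binary outcomes follow logit(p) = c + θ·(genetic SBP) with c solved by
Newton so the expected prevalence matches. The phenome draws each
phecode's status from logit(p) = c + β·GRS + age/sex terms, with β planted
on one focal phecode (log 1.5 per SD by default, prevalence 0.10 — a
common-outcome setting) and zero elsewhere; cases emit ICD-9/10 codes that
map back to the phecode under a bundled synthetic phecode catalog whose
exclusion ranges contain occasional "sibling" phecodes, so the
related-phecode exclusion logic is exercised. A "shared-SBP" phenome mode
makes the focal phecode depend on genetically determined SBP overall
instead of the drug-target score, which is the contrast the permutation
null is designed to detect.

Defaults are sized for a desk-scale study: 20 000 individuals, 350
variants in 70 blocks, within-block r = 0.6, MAF 0.2–0.5, planted
per-allele effects of 2.5 mmHg. Two constraints drive the effect size:
genome-wide significance at n = 20 000 requires a per-variant *R*² of
roughly 30/n ≈ 0.15%, so biobank-realistic per-SNP variance shares
(< 0.1%, as in large SBP GWAS) are not detectable at this n; the chosen
effects give *R*² ≈ 0.3–0.7% and *F* ≈ 50–200, preserving the *ordering*
noise ≫ per-variant signal and trial-like instrument strength while
keeping every planted variant reliably significant. The demo target sets
mirror the real drug classes' instrument counts (1 ACEI, 6 BB, 24 CCB
variants), with one planted variant per LD block so all survive clumping,
and one short region interval per planted variant (gene, promoter or
enhancer) so region filtering recovers exactly the planted set.

What the generator does *not* emulate: recombination gradients and
long-range LD, imputation uncertainty, relatedness (kinship exclusion is
assumed upstream), ascertainment, and genome-scale variant counts.
The last matters for the permutation pool: with ~39 background SBP loci,
draws of 24 overlap heavily, so permutation estimates share a common
random component and their mean OR can sit a centile or two off 1 in any
one cohort realization — at genome scale this vanishes. Tests that need a
clean target-free pool also exclude pool candidates in LD with the target
set (r² > 0.01), a step that is immaterial at genome scale where the
target locus is a vanishing fraction of the SBP genome. Consequently,
passing tests demonstrate the estimators' correctness and calibration
under the assumed structure, not robustness to the full messiness of real
cohort data.

## Numerical choices

LD matrices are stabilized to positive semi-definite by eigenvalue
clipping at 10⁻⁸ (with diagonal renormalization) before any solve, since
sample LD from finite panels is often indefinite; a covariance that is
singular even after stabilization raises an error advising stricter
clumping. Monomorphic variants are emitted from the summary-statistics
derivation with beta 0, *P* = 1, missing SE and a flag rather than being
dropped silently. Logistic fits use Newton iterations (statsmodels) with
separation and non-convergence converted to flagged results. All
randomness flows from explicit integer seeds; scenario components draw
from independent child seeds so configurations differing only in seed
share no randomness, and identical configurations are bit-identical.

## Problem sizes used in validation

The validation suite runs at sizes chosen for a single-CPU desktop: null
calibration uses 50 phenome replicates of 200+ phecodes at n = 50 000;
CI-coverage checks use 200 replicates of a 24-instrument system generated
at the summary-statistics level (exposure precision in the large-GWAS
regime, *F* ≈ 900, matching the two-sample setting where exposure noise
is negligible); permutation specificity uses 200 permutations per
replicate rather than the full 1000, which changes only the resolution of
the adjusted *P*.

## Known limitations

MR-Egger is nearly uninformative when planted exposure betas span a
narrow range (its regression leverage vanishes); this is a property of
the estimator, visible in the examples. The OR→RR conversion assumes the
outcome incidence is known and homogeneous. The phecode catalog shipped
for synthesis is deliberately minimal; real phecode maps carry
hierarchies and sex restrictions that are exercised in tests only at
small scale. Cox/observational analyses and multivariable or
colocalization extensions of MR are out of scope.
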