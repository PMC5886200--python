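# Methods

## The estimation problem

Maternal genotype and offspring birth weight are associated whenever either
(a) the maternal genotype shapes the intrauterine environment (a true
maternal effect, *m*), or (b) the child inherits a birth-weight-affecting
allele from the mother (a fetal effect, *f*, seen through the mother–child
genotype correlation of ≈ 0.5).  A marginal maternal GWAS estimates
*m + f/2*; a marginal fetal GWAS estimates *f + m/2*.  Separating the two
requires either genotyped mother–child pairs (rare at scale) or a model that
exploits the fact that many biobank participants report both their **own**
birth weight and the birth weight of their **first child**.

## The structural equation model

Observed variables per individual: genotype SNP, own birth weight BW,
offspring birth weight BW_O.  Latent variables: the genotype of the
individual's mother (G_G) and of their first child (G_O), each connected to
SNP by a fixed path of 0.5 (the expectation of Mendelian transmission).
Free parameters: the maternal path *m*, the fetal path *f*, the genotype
variance Φ, residual variances σ², σ_O², residual covariance ρ (absorbing
shared polygenic and environmental sources), and three means.

Path tracing gives the implied moments listed in the package README; these
were re-derived by hand for this implementation and are verified in the test
suite against a brute-force Monte-Carlo oracle (500 000 simulated trios)
before anything downstream relies on them.

### Likelihood and missingness

Records fall into three patterns — own birth weight only, offspring birth
weight only, both — and each contributes the multivariate-normal log-density
of exactly the variables it observed (full-information maximum likelihood).
This is valid when the pattern is independent of the phenotypes (missing
completely at random), which is how the simulator assigns patterns, and is
an *assumption* about any real questionnaire data.

Each pattern's contribution is evaluated from its sufficient statistics
(block size, mean vector, maximum-likelihood scatter matrix):

    ll_block = −n/2 · [k·log 2π + log|Σ_b| + tr(Σ_b⁻¹ S_b) + (x̄−μ_b)ᵀΣ_b⁻¹(x̄−μ_b)]

which is algebraically identical to the per-record density sum (tested to
1e-10 against a literal per-record oracle) and makes each likelihood
evaluation O(1) in sample size, so replicate studies at n = 78 674 are cheap.

The genotype is treated as Gaussian in the likelihood although it is a 0/1/2
count — the standard pseudo-maximum-likelihood simplification of SEM
engines.  Point estimates are driven by moments and remain consistent;
standard-error calibration under the misspecification is checked by
simulation (coverage 91–99% at cohort scale is part of the acceptance
suite).

### Optimization and standard errors

- Working scale: *m*, *f* and the three means are unconstrained; variances
  enter as logs and the residual correlation as atanh, which enforces
  positivity and the Cauchy–Schwarz bound without constrained optimization.
- Objective: the **mean** (per-record) negative log-likelihood.  Totals grow
  with n, which would make any fixed gradient-norm criterion meaningless
  across sample sizes; on the mean scale a gradient max-norm of 1e-6 is the
  convergence criterion at every n.
- Starting values: Φ from the pooled genotype variance, (*m*, *f*) from the
  closed-form moment inversion on pattern-pooled covariances, means from
  sample means, ρ from the BOTH-block covariance net of the genetic part.
  These are near-solution starts in a near-quadratic likelihood.
- Algorithm: L-BFGS-B followed by a damped Newton polish using central-
  difference gradients and Hessians, which drives the gradient to its
  finite-difference noise floor (~1e-7); two jittered restarts on failure
  before a fit is flagged non-converged.  With complete data the model is
  just-identified and the polish lands on the saturated solution to machine
  precision (the acceptance suite bounds the gap at 1e-4; observed ~1e-15).
- Standard errors: inverse of the numerical observed information (central
  differences, relative step 1e-5) of the **total** log-likelihood in the
  natural parameterization at the optimum.  Wald z uses a normal reference.
  A fit is reported converged only if the gradient criterion holds and the
  observed information is positive definite.
- The 2-df test refits the model with *m = f = 0* and refers
  2·(ll_full − ll_null) to χ²₂; a null likelihood exceeding the full one
  beyond tolerance raises an optimizer-failure error rather than reporting a
  negative statistic.
- Φ is a free parameter by default (a `fix_phi` switch pins it, e.g. at
  2p(1−p)), since fixing it buys nothing in a just-identified mean/covariance
  structure and freeness matches a saturated mean model.

## The simulator

Defaults encode the study conditions the package is built around: n = 78 674
individuals with reporting-pattern mix 0.42 / 0.27 / 0.31 (own only /
offspring only / both — matching a 33 238 / 20 963 / 24 473 split), allele
frequency 0.3, effects *m* = 0.05 and *f* = 0.03 SD of birth weight per
allele (the scale of the loci that motivate the method), unit residual
variances and residual covariance ρ = 0.1.

Generative chain: grandmother and all partners are independent HWE draws
(random mating, no assortment — an assumption the SEM itself makes); each
child genotype is one uniformly drawn allele from each parent; phenotypes
follow the two path equations with bivariate-normal residuals; patterns are
assigned multinomially, independent of phenotype.  Genotypes are hard calls
(an optional dosage-noise switch emulates imputed dosages; downstream
association accepts any dosage in [0, 2]).  One SNP per call; multi-locus
cohorts are independent replicate calls, since the model is per-SNP and no
LD model is attempted.

What the simulator does **not** emulate: linkage disequilibrium, polygenic
background (beyond what ρ absorbs), assortative mating, non-Gaussian
residuals, informative missingness, X-chromosome dosage compensation, and
real questionnaire error beyond the three injected artifact classes.
Passing tests therefore demonstrate correctness of the estimators under the
model's own assumptions, not robustness to their violation in real cohorts.

Raw-report generation maps birth-weight z-scores to kilograms with mean
3.5 kg and SD 0.484 kg (≈ the 484 g per SD of the source cohorts) and
compresses tails into [2.55, 4.45] kg so that the plausible-range filter is
exercised only by deliberately injected artifacts; reports are emitted in
pounds (kg / 0.45) to exercise the unit conversion.

## Cleaning and QC conventions

- Offspring birth-weight range filter reads "< 2.5 or > 4.5 kg" literally:
  exactly 2.5 and 4.5 kg are kept.  The repeat-report rule is inclusive:
  a difference of exactly 1 lb (0.45 kg) excludes.
- z-scores use the n−1 SD denominator and are computed after exclusions
  (exclusions change the mean and SD).
- The inverse-normal transform uses Blom offsets (c = 3/8), configurable.
- Blood pressure: readings differing by more than 4.56 trait SDs
  (SD 19.7 mmHg systolic, 13.1 diastolic) are excluded; remaining readings
  averaged (a single reading is used and noted); +15/+10 mmHg added for
  antihypertensive users **before** the 4.56-SD outlier screen, which uses
  the analysis sample's own mean.  Adjustment-first ordering and the sample
  mean as reference are choices this package fixes; alternatives are
  defensible.
- Discovery imputation-quality filters remove strictly-below-threshold
  values (info < 0.8 PLINK, r2hat < 0.3 MACH/Beagle, proper_info < 0.4
  SNPTEST: a value equal to the threshold is kept); the follow-up rule keeps
  only quality > 0.8 (the boundary is excluded).  Quality metrics slightly
  above 1 are clamped at read.
- The exact HWE test conditions on allele counts and sums the probabilities
  of heterozygote counts no more probable than the observed one; it is
  verified against an exact-rational enumeration oracle for all tables with
  n ≤ 50.  It is intended for directly genotyped hard calls.
- Genomic control divides by λ = median(χ²)/0.4549 only when λ > 1; test
  statistics are never inflated.  GC is a per-study stage only.
- Allele harmonization rejects palindromic (A/T, C/G) variants outright
  rather than inferring strand from frequency.
- The meta-analysis `verify` mode recomputes the pooled estimate via an
  independent accumulation code path and requires agreement to 1e-10 —
  a software stand-in for parallel meta-analysts.
- Variance explained is the additive approximation Σ 2p(1−p)β² on the
  z-score scale, assuming independent loci; no standard error is reported
  for it.

## Problem sizes

The test and acceptance runs use: 100 000 trios for genotype-structure
constants; 20 seeds × 20 000 complete records for the saturation check;
200 replicates at n = 78 674 for recovery/coverage; 500–1 000 replicates at
n = 10 000 for null calibration (calibration does not depend on n, and the
sufficient-statistic likelihood makes the per-replicate cost independent of
n anyway); 10 000 replicates for the null distribution of Cochran's Q.

## Known limitations

- Pseudo-ML treatment of a discrete genotype as Gaussian; calibration is
  verified by simulation, not theory.
- MCAR is assumed for the missingness patterns; real reporting behaviour
  may violate it.
- The pair and SEM estimates combined by `combine_sem_pairs` are treated as
  independent; overlapping samples would make the pooled SE anticonservative.
- No relatedness handling: the model is for unrelated individuals.
- No paternal genotypes, no multi-SNP joint model.
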