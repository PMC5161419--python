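# Methods

## The model

`gremlkin` partitions the phenotypic variance of traits measured in
family cohorts with the linear mixed model

    y = Xb + u_G + u_K + u_F + u_S + u_C + e,
    Var(y) = s2_G G + s2_K K + s2_F F + s2_S S + s2_C C + s2_e I,

where each random effect is governed by an n x n relationship matrix:

* **G** — genomic relationship matrix from per-SNP-standardized dosages,
  `G_ik = (1/m) sum_j (x_ij - 2p_j)(x_kj - 2p_j) / (2 p_j (1 - p_j))`,
  with sample allele frequencies, minor-allele-frequency filter
  (default 0.01) and mean imputation of missing calls. Its component is
  the SNP heritability h_g².
* **K** — G with off-diagonal entries below a relatedness threshold
  (default 0.05) set to zero, the diagonal untouched. Retained entries
  equal the corresponding G entries, so K isolates close relatives.
  Fitted jointly with G, its component h_p² captures additive genetic
  variance that co-segregates in pedigrees but is not tagged by common
  SNPs (rare and structural variation). The narrow-sense heritability
  is h_n² = h_g² + h_p².
* **F, S, C** — 0/1 indicator matrices with unit diagonal for shared
  nuclear-family, full-sibling and couple status, giving environmental
  components e_f², e_s², e_c². A couple is a pair who are parents of a
  common child or declared spouses; full sibs share both known parents;
  nuclear-family co-membership is the union of couple, full-sib and
  parent-offspring pairs, and an individual may belong to several
  nuclear units. The exact indicator construction is a design choice of
  this package: the union definition matches the verbal description of
  the design and makes F ≥ max(S, C) elementwise by construction.

Fixed effects default to intercept, age, age², sex, and the top 20
eigenvectors of G (fewer if n is small). Principal-component signs are
fixed by making the largest-magnitude loading positive, and eigenvalue
ties resolve through the deterministic symmetric eigensolver, so runs
are reproducible.

Binary traits are analyzed as 0/1 on the observed scale (no
probit/logit link). An observed-scale proportion converts to the
liability scale by the factor K(1−K)/z², with K the population
prevalence, t = Φ⁻¹(1−K) and z = φ(t); the factor multiplies the
standard error as well. The case-control ascertainment correction
(extra factor K(1−K)/(P(1−P)) for sample case fraction P) is available
but not the default, because the intended sampling design is
population/family-based with sample prevalence close to K.

## REML machinery

The REML log-likelihood (constant dropped) is
`-0.5[log|V| + log|X'V⁻¹X| + y'Py]`. Maximization uses
average-information (AI) updates with:

* an active-set Newton step — parameters clamped at the floor whose
  gradient points further below it are held fixed and the reduced AI
  system is solved for the rest (this prevents boundary zigzag);
* step-halving against the likelihood (up to 15 halvings), then a
  guarded doubling extrapolation while the likelihood keeps improving,
  which speeds up boundary-divergent cases such as correlations tending
  to 1;
* an expectation-maximization fallback step when no AI step is
  admissible (for free-sign covariance parameters, where the EM update
  is invalid, a damped gradient step is used instead);
* variance components constrained to a positive floor of 1e-6 x var(y)
  rather than allowed negative, so boundary estimates report as ~0;
* convergence when |Δ logL| < 1e-6 and the largest free-parameter
  gradient is below 1e-4, with a 200-iteration cap.

Sampling covariance of the variance components is the inverse AI matrix
at the optimum; proportion standard errors follow by the delta method.
Component tests are the one-sided Wald test z = h/SE(h) and the
boundary LRT referred to the 50:50 mixture of χ²₀ and χ²₁
(p = 0.5 P(χ²₁ > stat), statistic clipped at zero). One-sided Wald for
variance components and the 50:50 mixture are design choices for
boundary-null parameters; correlations are tested two-sided.

The bivariate model stacks two traits with a 2x2 (co)variance block per
component, V = Σ_c B_c ⊗ A_c restricted to observed trait-sample
entries: samples missing one trait still inform the other, and the
residual covariance is estimated only from jointly phenotyped samples
(fixed at zero, with a warning, when no overlap exists). Component
correlations r_c = cov_c/√(v_c1 v_c2) carry delta-method SEs from the
AI covariance of (v_c1, v_c2, cov_c); covariances are unconstrained in
sign during fitting and |r| is projected to 1 at reporting with a flag.
Tests against r = 0 refit without the covariance parameter (still a
linear covariance structure, handled by the same AI engine); tests
against r = 1 refit under the rank-1 reparameterization
cov_c = √(v_c1 v_c2) = a·b with a quasi-Newton optimizer (L-BFGS-B with
analytic gradients) on the REML surface, and both LRTs are referred to
χ²₁. When a component variance sits at the floor in either trait the
correlation is reported as undefined and its tests are skipped.

A degenerate but instructive boundary case: fitting the *same* trait
twice makes the likelihood unbounded as every correlation approaches 1
and V approaches singularity; iterates approach the boundary only
asymptotically (roughly as 1/iteration), so finite-iteration estimates
stop slightly short of 1. This affects only exactly-degenerate inputs.

## Stepwise selection

Backward selection starts from GKFSC and removes, at each step, the
component that is non-significant at level α = 0.05 in *both* tests and
has the highest Wald p among such components, until every remaining
component is significant in at least one test. Forward selection starts
from the fixed-effects-only model and adds the candidate that is
significant in both tests, does not render any current component
non-significant in both tests, and has the lowest Wald p among
qualifying candidates. Ties in Wald p resolve by the fixed order
G, K, F, S, C; candidate refits that fail to converge are logged and
treated as failing significance rather than aborting the run. Every
step's p-values are reproducible by refitting the before/after models.
The pipeline's consensus rule picks the majority model across the
per-trait forward/backward selections, resolving ties toward the
larger model.

## The synthetic cohort generator

Because family cohorts with linked genotype, pedigree and diagnosis
data are access-restricted, every analysis path is exercised on
simulated cohorts with known truth:

* **Pedigree** — founder couples, sibship sizes Poisson(3) truncated at
  1 (or fixed), each parent genotyped with probability 0.95. These
  defaults reproduce couple : full-sib : nuclear-family pair-count
  ratios of roughly 1 : 4.9 : 11.5, the structure of a large
  family-based cohort in which most spouses are recruited.
* **Genotypes** — Mendelian gene-dropping: founders draw dosages
  binomial(2, p) with common-SNP MAF ~ U(0.05, 0.5) (default 1,500
  SNPs) and rare-variant MAF ~ U(0.002, 0.01) (default 300); offspring
  inherit one uniformly chosen allele per parent per site. Rare
  variants are withheld from the GRM, so they create pedigree-associated
  genetic variance for the same mechanistic reason the K component
  exists — genetic sharing among close relatives that common SNPs do
  not tag. No linkage disequilibrium is simulated.
* **Liabilities** — liability = g + k + f + s + c + e, each term
  empirically standardized to its configured variance fraction (so
  recorded truths are exact on the realized cohort), with shared draws
  per nuclear family, sibship and couple. Binary traits threshold the
  liability at Φ⁻¹(1 − K). Cross-trait correlations are imposed on the
  effect draws (identical SNP effect vectors when r_g = 1, correlated
  couple draws for r_c, and so on). Covariates (age, age², sex) are
  generated with zero true effect: the analysis adjusts for them, but
  power for fixed effects is not a goal here.
* **Deliberately absent** — assortative mating (couple effects are
  drawn independently of genotype and phenotype), LD structure,
  genotyping error, and ascertainment sampling. Passing recovery tests
  therefore shows the estimator is calibrated under the stated
  generative model, not that real-data confounds (notably phenotypic
  assortment, which inflates couple and genetic components) are
  handled.

## Problem sizes and test design

Default verification runs use cohorts of roughly 600–800 individuals
(100–150 families), 1,500 common SNPs, and 8–20 replicates per
experiment, with 200 replicates of small two-component fits for the
LRT null-calibration check; these sizes were chosen so the full suite
runs comfortably on a single CPU while leaving Monte-Carlo intervals
tight enough to detect calibration errors of a few percentage points.
Recovery checks compare replicate means to truth within three-sigma
Monte-Carlo intervals computed from the replicates themselves.
Selection-behaviour checks use the quantitative liability as the trait
(binary thresholding discards information and the reduced cohorts
would otherwise lack the power the property presumes).

## Known limitations

* Observed-scale linear modelling of binary traits is an approximation,
  and the K(1−K)/z² transform is exact only to first order in the
  between-relative liability correlation ρ: the exact observed-scale
  correlation is (Φ₂(t,t,ρ) − K²)/(K(1−K)), which exceeds the linear
  value ρz²/(K(1−K)) by ~20% at ρ = 0.25 and ~50% at ρ = 0.5 for
  K = 0.09. When the total of the simulated liability components is
  near 1 (so close relatives have large liability correlations), the
  back-transformed estimates of the large components are therefore
  biased upward — visible in the acceptance-script recovery means for
  the low-prevalence, high-heritability setting. At moderate component
  totals the distortion is within Monte-Carlo noise. A generalized
  (probit) model would remove this but is out of scope.
* SEs of transformed proportions apply the liability factor linearly;
  no second-order correction.
* The bivariate LRT against r = 1 uses χ²₁ as reference; the boundary
  nature of the null makes this conservative.
* Couple effects and phenotypic assortment are not separable by this
  design; the generator deliberately draws couple effects independently
  of genotype and phenotype, and does not simulate assortative mating.
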