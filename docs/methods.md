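# Methods

This note documents the models, the simulator, the numerical choices and
the limitations of `sprucegs`. It is the package's own account of its
science; every empirical statement here is something the test suite or
`scripts/acceptance.py` computes.

## The setting

The package targets progeny trials of conifer breeding programs organized
in closed *breeding groups* (sublines): a small set of founder parents per
group (effective population size on the order of 20), a partial diallel of
full-sib crosses made within groups, and offspring planted across two test
sites in randomized complete blocks. Genotypes are biallelic SNP dosages
(0/1/2); phenotypes are growth and wood-quality traits measured once per
tree, each tree on exactly one site.

## Relationship matrices

**A (numerator relationship matrix).** Tabular method over a
topologically sorted pedigree: founders have `a_ii = 1` and are mutually
unrelated, then `a_ii = 1 + a_sd/2` and `a_ij = (a_js + a_jd)/2`. The
sparse inverse follows Henderson's rules with inbreeding taken from the
tabular diagonal (Mendelian-sampling variance `0.5 - (F_s + F_d)/4`,
with a missing parent contributing `F = -1`). The Gibbs samplers only
ever touch this sparse inverse.

**K (realized genomic relationship matrix).** Dosages are oriented so
the counted allele is the minor one (ties keep the input orientation),
centered as `Q = M - P` where column m of P is constant at twice the
allele frequency, and normalized as `K = QQ'/k` with `k` the mean
diagonal of `QQ'`, so `mean(diag K) = 1` and K sits on the same scale as
A. Two textual ambiguities in the source formula were resolved in favor
of internal consistency: centering uses `2 p_m` (plain `p_m` would not
zero the mean breeding value), and the normalizer divides the trace by
the number of individuals (dividing by the number of markers is not "the
mean of the diagonal" and would not give a unit diagonal).

The spectral scan reports eigenvalues and the fraction of variance per
eigenvector (numerically negative eigenvalues floored at zero for the
fractions only). Class-wise summaries (unrelated / half-sib / full-sib /
parent-offspring, read shallowly from the recorded pedigree) give the
quartiles of realized coefficients per expected class.

## Phenotype preparation

Per trait: subtract least-squares block means (blocks nested in sites;
blocks with fewer than two observations fall back to the site mean with a
warning), censor residuals beyond three residual standard deviations to
missing, then standardize by the within-site standard deviation of the
adjusted values. Marker regressions pool the standardized values across
sites, treating the trait as one trait with across-site genetic
correlation one — the bivariate model exists to check that assumption.

## Animal models

The univariate model is `y = Xb + Za + e` with `a ~ N(0, A sigma2_a)`;
the bivariate model stacks the same trait on the two sites with genetic
covariance `C (x) A` (C a 2x2 matrix) and a residual covariance that is
structurally zero across sites because no tree is measured twice.
Estimation is single-site Gibbs throughout: scalar updates for fixed
block effects (Gaussian prior, variance 1e8), scalar (univariate) or
2-vector (bivariate) updates for breeding values driven by the sparse
A-inverse, conjugate scaled-inverse-chi-square / inverse-Wishart draws
for variances. Priors follow the weakly-informative convention of
partitioning the phenotypic variance: scale = phenotypic variance
divided by the number of random terms, degree of belief 1 (univariate)
or 2 (bivariate). Default chain settings are 26,000 iterations, 6,000
burn-in, thinning 20 (1,000 saved samples) — a desk-scale tenth of the
production-scale 260,000/60,000/200 — and a split-R-hat above 1.1 on any
variance chain raises a warning. Posteriors are summarized by the
Gaussian-KDE mode (Silverman bandwidth) and the shortest 95% interval
(HPD). DIC uses the deviance conditional on the latent effects:
`DIC = 2 * mean(D) - D(posterior means)`.

The bivariate sampler was validated against an independent dense
implementation (joint multivariate-normal update of all breeding values,
scipy inverse-Wishart draws): the two agree on the same data. A caveat
worth knowing: with few families the marginal likelihood of the
across-site correlation is nearly flat, so its posterior is noticeably
shrunk toward zero relative to the (boundary-seeking) maximum-likelihood
estimate; at the default trial scale (59 families, ~1,700 offspring)
the posterior mode recovers a generating correlation of 0.8 to within
about 0.1 on average over replicates.

## Marker regressions

`y = mu + Z u (+ a) + e` on adjusted, standardized phenotypes with raw
0/1/2 dosages in Z (columns centered internally; the intercept absorbs
the shift, and GEBV = sum of effects times raw dosages). Ridge
regression gives all markers one common variance (Gaussian prior); the
Bayesian LASSO gives each marker its own variance with exponential
mixing (double-exponential marginal), with the regularization parameter
sampled under a Gamma(shape 0.52, rate 1e-4) hyperprior on lambda
squared — the source describes this hyperprior with Gamma-style
shape/rate constants, and that is what is implemented. Variance priors
are scaled inverse-chi-square with df = 3 and scales set so each prior
mode equals an equal split of the phenotypic variance among the active
random terms (for the common marker variance, divided additionally by
the summed dosage variance of the panel, so the implied genetic variance
gets the equal share). The exact prior constants used in the original
analyses are typographically lost in the source; df = 3 with the
equal-split rule is this package's choice and is configurable.

Marker updates are residual-update single-effect Gibbs, O(n) per marker
per sweep, processed in marker-ID-sorted order so that permuting the
columns of the input panel and refitting with the same seed permutes the
estimates exactly. The inverse-Gaussian draw for the LASSO's local
variances switches to its Levy-limit form when the conditional mean
explodes (tiny effects), which keeps lambda's chain stable. Freezing
both variances turns the ridge sampler into a draw from the exact
closed-form ridge posterior, which the tests exploit as an oracle.

## Association scan and subsets

The EMMAX-style scan estimates the genetic and residual variance once,
in a marker-free null model, by exact 1-D REML on the eigen-rotated
data, then tests every marker by GLS with the covariance frozen (1-df F
test). This is the standard approximation: fast, slightly conservative,
and calibrated — the acceptance suite checks the empirical type-I error
at the 5% level sits in [0.035, 0.065] on a relatedness-structured null.

Five subset rules feed subset cross-validation: scan-significant markers
(p < 0.05, no multiplicity correction — a screen, not an inference)
under A- or K-control; the 600 largest absolute effects from the full
ridge-plus-pedigree fit; 600 at random; 600 with the highest minor
allele frequencies. Ties break by (criterion descending, marker ID
ascending) for platform-independent subsets.

## Cross-validation

Folds hold individuals (CV1) or entire full-sib families (CV2, never
split); ten folds, sizes within one unit. Four scenarios: within
breeding group, between breeding groups (train BG1, test BG2 — all known
relatedness removed), within site (groups pooled), and between sites
(no phenotypes from the testing environment). Cross-subpopulation
rounds pair training folds of the first subpopulation with distinct
testing folds of the second in round order. Accuracy is the Pearson
correlation between predictions for withheld individuals and reference
breeding values. Two references are supported and reported side by
side on simulated data: pedigree EBVs from the bivariate fit on *all*
data (the field's convention, which deliberately reuses the test
phenotypes inside the reference) and the simulator's true genetic
values. Relative efficiency is the marker accuracy as a rounded
percentage of the pedigree accuracy on identical folds; the fold-level
dispersion column is the standard error of the fold accuracies.

## Gains

Within-family truncation selection at 5% keeps the top
`ceil(0.05 * family size)` individuals (at least one; family sizes of
25-33 give two) ranked by EBV or GEBV; the gain is the mean of the
selected values minus the family mean, averaged over families weighted
by size, in the units of the input values. Gain per year divides by the
cycle length: 30 years conventional versus 10 years with marker-based
selection and vegetative propagation; the headline ratio is
`100 * (GEBV gain / 10) / (EBV gain / 30)`.

## The simulator

`simdata` generates the study conditions: 2 groups of 19/20 founders,
27/32 crosses per group with each parent used a bounded number of times
(the bound defaults to 4 — the published counts of 20 parents and 32
crosses are arithmetically incompatible with a cap of 3), 25-33
offspring per cross (~1,748 offspring), families split evenly across 2
sites and round-robin over 8 blocks per site, unlinked markers (a
single-chromosome Haldane map is available) with founder frequencies
drawn to a mean minor-allele frequency of 0.20, 2.7% missing calls, and
traits built from causal loci whose per-site effects are
`sqrt(r12) * shared + sqrt(1 - r12) * site-specific`, rescaled so the
population additive variance per site equals the target heritability on
the unit phenotypic scale.

Two simulator regimes matter for interpretation. With causal loci *on*
the genotyped panel (the default; the many-small-effects architecture),
markers carry real trait LD and cross-group prediction retains signal.
With `causal_on_panel=False` the released panel is in linkage
equilibrium with every causal locus, so marker-based prediction works
through relatedness capture alone — the regime that mirrors the source
trial's empirical findings (near-zero between-group accuracy, random
and high-MAF subsets nearly as good as the full panel). The scenario
acceptance checks use the second regime. Features of real data the
simulator does not emulate: genotyping error, pedigree errors and
cryptic relatedness between groups, short-range LD from historical
population structure, dominance and epistasis, and selection history in
the founders. Passing scenario tests therefore demonstrate the
relatedness arithmetic of the method, not field-trial realism.

## Problem sizes and reproducibility

Acceptance-scale runs use 59 families (~1,700 offspring) with panels of
600-2,000 markers and desk-scale chains (26,000 iterations for variance
estimation; 1,200-1,500 for per-fold CV refits), sizes at which the full
pipeline completes in minutes on one core. One integer seed drives
every stage through a splittable stream (`numpy.random.SeedSequence`);
the numba kernels seed their own generator from the same stream, making
runs bit-reproducible for a fixed seed. All randomized operations
(imputation, fold assignment, subset draws) take explicit seeds.

## Known limitations

* The animal models accept a dense relationship matrix (e.g. K) in
  place of A, but invert it densely; at n in the tens of thousands the
  A-inverse path is the only practical one.
* DIC with likelihood conditional on latent effects (the convention
  used here) rewards flexible random effects; it is comparable across
  the model family it is computed for, not an absolute criterion.
* The EMMAX scan fixes variance components at the null fit; per-marker
  exact REML (EMMA) is out of scope.
* No dominance/epistatic components, no multi-generation selection
  simulation, no factor-analytic multi-site extensions.
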