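# Methods

This note documents the statistical models implemented in `ssrherit`,
the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical decisions that
matter when reproducing results.

## Clone identification and probability of identity

Clonal plants are sampled as *ramets* (patches) of underlying *genets*.
Two patches are candidate clones when their multilocus genotypes are
near-identical. We use the Lynch band-sharing similarity on allele
*sets*: at a locus where the two individuals carry sets A and B
(a heterozygote contributes two distinct alleles, a homozygote one),

    s = 2 |A ∩ B| / (|A| + |B|),   d = 1 − mean(s over usable loci).

Only loci typed in both individuals enter the mean; a pair with no
shared typed locus has undefined distance and is never merged (it is
counted and reported). Pairs with d < 0.05 (strict) are merged by
single linkage — i.e. connected components of the thresholded graph —
and one member per component is drawn uniformly at random with a
recorded seed. The 0.05 default reflects the empirical gap between the
near-zero distances of true clonal replicates and the smallest
distances among distinct genotypes when loci are highly polymorphic;
with 7 loci, d < 0.05 in fact requires identity at every locus, so
error-free replicates are recovered exactly.

The multilocus probability of identity,

    PI = Π_l [ Σ_i p_i⁴ + Σ_{i<j} (2 p_i p_j)² ],

is the chance that two independent Hardy–Weinberg genotypes coincide;
the package reports it per marker-combination size so users can verify
that their panel resolves genotypes (PI is non-increasing in the number
of loci).

Clone filtering precedes every relatedness computation, and allele
frequencies used by the relatedness estimators are taken from the
clone-filtered sample, to avoid clonal pseudo-replication. A
relatedness matrix containing off-diagonal entries of 1 (clones
retained) is rejected by the model-fitting code with an instruction to
filter first, since it is exactly singular.

## Relatedness estimators

Four method-of-moments estimators convert allele sharing plus
population allele frequencies into pairwise relatedness r. Throughout,
x carries alleles (a, b), y carries (c, d), p are frequencies, and
δ denotes allele identity indicators.

**Queller–Goodnight (`qg`).** Reference-x numerator and denominator per
locus are ½(δac+δad+δbc+δbd) − pa − pb and 1 + δab − pa − pb; loci are
combined as a ratio of sums, and the estimate is the average of the two
reference directions. A locus whose reference denominator vanishes
(reference homozygous for a frequency-1 allele) is skipped for that
direction and counted.

**Li (`li`).** The shared-allele similarity S (mean over both
directions of the fraction of an individual's two gene copies present
in the other's allele set) has unrelated-pair expectation
S₀ = 2a₂ − a₃ with a_k = Σ p_i^k; the estimator is
(ΣS − ΣS₀) / (Σ1 − ΣS₀) over loci.

**Lynch–Ritland (`lr`).** Reference-x estimator
[pa(δbc+δbd) + pb(δac+δad) − 4papb] / [(1+δab)(pa+pb) − 4papb], with
the published inverse-variance locus weights w = den/(2 pa pb) (the
weighted mean telescopes into sums of num/(2papb) and den/(2papb));
averaged over reference directions. A flag switches to simple
equal-locus averaging, since published software differs on this point.

**Wang (`wang`).** Each locus sorts a dyad into one of four observable
similarity classes: (1) identical genotypes, (2) a homozygote and a
heterozygote sharing the homozygote's allele, (3) two heterozygotes
sharing exactly one allele, (4) no sharing. Writing φ and Δ for the
probabilities that the dyad shares one and two pairs of genes identical
by descent, the class probabilities are linear:

    P1 = b + cφ + (1−b)Δ,  P2 = d + eφ − dΔ,  P3 = f + gφ − fΔ,

with b = 2a₂² − a₄, c = a₂ − b, d = 4(a₃ − a₄), e = 2(a₂ − a₃) − d,
f = 4(a₂ − a₂² − 2a₃ + 2a₄), g = 1 − 7a₂ + 4a₂² + 10a₃ − 8a₄. These
coefficients were re-derived from the class definitions and are
verified in the test suite by exhaustive enumeration of genotype pairs.
The package estimates (φ, Δ) by ordinary least squares on the stacked
per-locus moment equations and reports r = φ/2 + Δ. This differs from
Wang's original variance-weighted closed form in the weighting only;
by linearity the OLS solution is exactly unbiased, and it degrades
gracefully when some loci carry no information (their rows are zero).
Dyads whose 2×2 normal system is numerically singular are treated as
missing.

Monomorphic loci are skipped by all estimators. Pairs with no usable
value are filled with 0 — the unrelated-pair expectation — before
conditioning, and the filled count is reported.

**Conditioning.** The diagonal is set to exactly 1 (self-relatedness of
a non-inbred genet), then the matrix is replaced by its nearest
positive-(semi)definite neighbour using Higham's alternating
projections with Dykstra's correction, restoring the unit diagonal at
every iteration (the projection onto the unit-diagonal affine set).
Convergence is declared when the relative sup-norm change falls below
1e-10 (cap 600 iterations; non-convergence raises with the iteration
count). A final eigenvalue floor of eps = 1e-8 with diagonal
renormalization guarantees strict feasibility for downstream Cholesky
and spectral factorizations; the operation is idempotent to 1e-10.

## The animal model

For one trait, y = Xβ + Za + e with one record per genet (Z = I),
Var(a) = M σ²ₐ, Var(e) = I σ²ₑ, where M is the conditioned relatedness
matrix. Fixed effects are transect (3 levels), elevation (2),
microhabitat (2), microhabitat×elevation and microhabitat×transect —
treatment-coded with an intercept, 8 columns in the balanced 12-site
layout. Higher-order interactions are excluded (they are poorly
identified in this layout); columns made aliased by the data are
detected by pivoted QR, dropped, and reported.

**Fitting.** One spectral decomposition M = U diag(d) U′ rotates the
model so V = σ²ₑ(λ diag(d) + I) with λ = σ²ₐ/σ²ₑ. The restricted
likelihood is profiled over λ on a 201-point log grid spanning
[1e-6, 1e6] plus the λ = 0 boundary, then refined by bounded Brent
search; the convergence tolerance on the profile is effectively 1e-12
in log λ. Variance components are non-negative by construction
(boundary-closed ratio parameterization). The fitted −2·log-REML
includes all constants, so it is directly comparable with a dense
brute-force evaluation — the test suite exploits this with an
independent `inv`/`slogdet` oracle.

Standard errors of (σ²ₐ, σ²ₑ) come from the inverse expected REML
information ½tr(P Vᵢ P Vⱼ), evaluated in the rotated basis (well
defined also on the λ = 0 boundary). h² = σ²ₐ/(σ²ₐ+σ²ₑ) gets a
delta-method standard error and a normal CI that is deliberately *not*
truncated at 0 or 1; a negative lower bound is meaningful output.
Significance of σ²ₐ uses a one-sided Z-test (variances cannot be
negative), with the convention p = 0.5 at the boundary estimate
σ̂²ₐ = 0; the boundary makes the test conservative, which the type-I
simulation in the tests confirms. Fixed terms get incremental
(sequential) Wald F-tests at the estimated V with residual denominator
degrees of freedom n − rank(X).

If M is numerically proportional to I the additive and residual
components are confounded; the fit is flagged non-identifiable and h²
is reported as undefined rather than a number.

**Genetic covariances.** Rather than one joint 6-trait REML — which is
numerically fragile with a dense marker M — the G matrix is assembled
from univariate fits (diagonal) and pairwise bivariate fits
(off-diagonal). The bivariate model has Var(a) = G₀⊗M, Var(e) = R₀⊗I
with 2×2 G₀ and R₀ kept positive definite through Cholesky
parameterization, optimized by L-BFGS-B from univariate starting
values; the restricted likelihood factorizes into per-eigenvalue 2×2
blocks, so each evaluation is O(n). Covariance standard errors come
from a finite-difference observed-information Hessian on the natural
(g₁₁, g₁₂, g₂₂, r₁₁, r₁₂, r₂₂) scale, and covariances are tested
two-sided. Supplying the same trait twice makes the residual
cross-covariance unidentifiable (R₀ singular in the limit); this
degenerate input is detected and the univariate decomposition returned,
whose analytic limit has σ̂ₐ₁₂ equal to the univariate σ̂²ₐ. Pairwise
assembly does not enforce joint positive-definiteness of G across more
than two traits — a known difference from a joint fit, visible mainly
when several traits are strongly genetically correlated.

Missing phenotypes are handled by listwise deletion per model (each
univariate or bivariate fit uses its own complete cases, with the
design rebuilt on those rows).

## Trait derivation

The snowmelt day of a soil-temperature series (5 cm depth, 2-h
sampling) is the first day whose daily mean exceeds 1.5 °C after a run
of at least 5 consecutive days with daily means inside ±0.5 °C — the
snow-insulation plateau. Intermediate "ramp" days between the plateau
and the threshold do not reset the detector. All three parameters are
exposed; the defaults were chosen so that a noiseless planted
change-point is recovered exactly and sub-threshold noise
(σ = 0.1 °C) leaves the detected day unchanged. Site-level snowmelt is
the median over the site's loggers. Days missing more than 25% of their
twelve 2-h readings are excluded and reported.

Growing-degree days accumulate max(0, daily mean − 5 °C) over an
inclusive day-of-year window (the snowmelt day itself is included);
accumulation is from daily means, with sub-daily accumulation available
behind a flag. GDD is additive over contiguous windows by construction.
Leaf area is the ellipse π·(L/2)·(W/2). The stem-number ratio
(2012/2011) and the proportion of flowering stems (flowering/total
2012) are left missing — never imputed — when their denominators are
zero, and a phenophase preceding snowmelt flags the record instead of
producing a negative interval. Standardization is (x − mean)/sd with
the n−1 denominator over non-missing values.

## Performance regressions

Performance measures (stem-number ratio for clonal reproduction;
proportion of flowering stems for sexual reproduction) are regressed on
the four standardized traits, microhabitat, and the four
trait×microhabitat interactions, with random intercepts for transect
and site-within-transect, fit by REML (statsmodels MixedLM). With
standardized predictors the slopes are comparable across traits, in the
spirit of a selection-gradient analysis — though not formally one,
since the responses are performance proxies rather than demographic
fitness. Both responses are modelled as Gaussian; treating the bounded
proportion as Gaussian is a documented simplification.

Per-term tests are marginal Wald F with 1 numerator df; the
denominator df uses the containment heuristic n − p − (number of
sites) by default, with a residual n − p option, since the reference
software's df method is not uniquely determined. Interactions
significant at α = 0.05 (no multiple-testing correction) trigger
separate per-habitat refits of the trait slopes. Elevation is excluded
from this model. When an estimated random-effect variance falls below
1e-3 of the residual variance it is treated as boundary-collapsed and
the term is dropped with a refit; in the no-group-effect limit the
coefficients therefore coincide exactly with ordinary least squares.

## Synthetic data

The generator emulates the study system's structure, not its exact
values: 7 SSR loci with 23 alleles each drawn from Dirichlet(0.3)
spectra (many rare, few common alleles); founder genotypes in
Hardy–Weinberg proportions; descendants produced in full-sib families
(default size 4) from random parent pairs, as in seed families of an
outcrossing plant — family structure is what gives the marker panel
relatedness signal to detect; a configurable fraction of genets
duplicated as *error-free* clonal patches; patches assigned at random
to the 12-site factorial layout; traits generated by the animal-model
forward equation with declared h², total variance, fixed effects, and
optionally a genetic correlation matrix coupling breeding values
(clonal patches share their genet's breeding value but draw independent
residuals); and 2-h logger series with a planted snowmelt day, a
half-sine summer curve, a diurnal cycle and Gaussian noise.

What it does **not** emulate: genotyping error and null alleles,
isolation by distance and spatial relatedness gradients, inbreeding,
selection, and non-Gaussian trait distributions. Passing tests
therefore demonstrate the correctness of the estimators and the
machinery under the model's own assumptions — not robustness to these
real-data complications. In particular, heritability estimated through
a 7-locus marker relatedness matrix is attenuated relative to the
generating values (regression dilution from noise in M); the tests that
quantify *estimator* bias therefore use the true pedigree relationship
matrix A, while marker-based runs are checked for rank agreement with
truth rather than unbiasedness.

The study-like preset uses 350 founders plus one descendant generation
and a 13% clone rate (≈790 patches, ≈700 genets) with true h² of
(0.06, 0.07, 0.03, 0.18, 0.14, 0.18) for the six traits — magnitudes
in the low-to-moderate range typical of field heritability studies.
Test and acceptance runs use smaller sizes (stated in each test) chosen
to keep Monte-Carlo error comfortably inside the asserted tolerances.

## Numerical choices and limitations

- λ search bounds [1e-6, 1e6] on a log scale; λ = 0 always evaluated.
- Relatedness denominators below 1e-12 are treated as zero (locus
  skipped for that reference direction).
- near_pd: tol 1e-10, max 600 iterations, final eigenvalue floor 1e-8.
- Seeds: every stochastic routine takes an explicit seed and records it
  in its output (clone representative choice, simulation truth).
- The delta-method CI for h² is symmetric and can be anticonservative
  near the boundary; the parametric-bootstrap comparison in the tests
  bounds the disagreement at moderate h².
- The G matrix from pairwise fits is symmetric by construction but not
  guaranteed jointly PSD.
- Wald F denominators (residual / containment) are heuristics, not
  Kenward–Roger; p-values near the significance threshold should be
  read accordingly.
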