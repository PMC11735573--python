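# Methods

## The meiosis model

`tetraseg` models the gamete dosage distribution of a tetraploid parent at
a biallelic locus under two meiotic processes. In the three-parameter
form, a meiosis forms a quadrivalent with probability τ; given a
quadrivalent, double reduction occurs with probability β (capped at
c, default 1/6, the maximum under complete equational segregation); given
bivalents, the two chromosomes carrying like alleles pair with probability
γ. This model reduces exactly to a two-parameter form with double
reduction rate α = βτ and preferential pairing parameter

    ξ = 1 − [(2/3)·τ·(1−β) + (1−τ)·(1−γ)] / (1 − βτ),

a mapping we re-derived by equating the duplex gamete rows of the two
parameterizations and validate in the test suite by a 10×10×10 grid
identity check at 1e-12. ξ = 1/3 is tetrasomic (random pairing); ξ = 0 or
1 is fully disomic. The two parents share α but carry separate ξ₁, ξ₂ —
which chromosomes share alleles differs between parents, so their pairing
parameters are not interchangeable. α and ξ are jointly bounded
(`xi_bounds`); at α = c the interval degenerates to {1/3}.

Offspring genotype frequencies are the discrete convolution of the two
parental gamete distributions. The model is **not identified** when a
parent is duplex — e.g. (α, ξ) = (1/6, 1/3) and (0, 1/9) give identical
gamete frequencies — which is harmless for testing but makes single-locus
estimates of α and ξ unreliable; the package exposes the fitted α̂ only
under a name that flags this (`alpha_hat_unreliable` in result tables).

The model describes one F1 generation only. Offspring may carry different
alleles on different subgenomes than their parents, so the fitted
parameters must not be propagated through multiple simulated generations,
and ploidies other than four are out of scope (only the hypergeometric
baseline generalizes).

## Null maximum likelihood and boundary geometry

The null fit maximizes the multinomial (known genotypes) or
genotype-likelihood mixture (Σᵢ log Σₖ gᵢₖ qₖ, computed with log-sum-exp)
over the box 0 ≤ τ, γ₁, γ₂ ≤ 1, 0 ≤ β ≤ c using L-BFGS-B. Because
non-identifiability creates likelihood ridges, the optimizer restarts from
one canonical point (τ = 1/2, β = c/2, γ = 1/3) and four deterministic
pseudo-random points (fixed seed 0), keeping the best optimum. Parameters
that cannot affect the likelihood for the given parental dosages (τ, β
when both parents are homozygous; γⱼ unless parent j is duplex) are frozen.

Degrees-of-freedom bookkeeping works on the *effective directions* of the
null manifold in offspring-frequency space rather than on the raw box:

* one shared direction (α) whenever a simplex or triplex parent is
  present;
* one direction per duplex parent (its gamete heterozygote frequency
  p₁ = (1−α)(1+ξ)/2, which absorbs both α and ξ for that parent).

The count of these directions is the base null dimension (0, 1 or 2); a
numerical Jacobian-rank oracle in the tests confirms it for every parental
configuration. This is also our resolution of the ambiguity in how to
count parameters with two heterozygous parents: (1, 1) contributes one
dimension (shared α), (1, 2) and (2, 2) contribute two. A direction is "on
the boundary" when its estimate is within 1e-4 of its feasible limit —
α̂ against [0, c]; a duplex p̂₁ against its α̂-conditional interval when
another parent pins α, or against the global [1/2, 1] otherwise. Boundary
directions are subtracted from the null dimension (Susko-style
data-dependent degrees of freedom), because box-boundary status of the raw
(τ, β, γ) coordinates is meaningless along ridges.

The alternative parameter count is the number of theoretically possible
offspring genotypes minus 1 (counts data; observing an impossible genotype
short-circuits to p = 0), or 4 minus the number of genotype classes that
are both impossible under the null and estimated below 1e-8 by EM
(genotype-likelihood data, where nothing is ever strictly impossible).
When df = 0 the test reports p = 1 for λ ≈ 0 and otherwise falls back to
the 1-df tail as a conservative convention; the reference distribution for
df = 0 is not defined by the asymptotic theory, and this choice can only
lose power, never inflate type-I error.

The unconstrained MLE under the alternative uses x/n for counts and the
genotype-frequency EM for likelihoods (uniform start so every component
can move; relative log-likelihood tolerance 1e-10, cap 2000 iterations;
monotonicity is asserted in tests). Unknown parental dosages are estimated
by exhaustive search over the 25 pairs, scoring a_{ℓ₁}·b_{ℓ₂}·max-null-
likelihood, ties broken to the lexicographically smallest pair; the test
then proceeds as if the estimated pair were known (the impossible-genotype
rule applies after estimation).

## Bayes factors

The Bayes factor is oriented **null over alternative**: positive log BF
means no evidence of distortion. Default priors: τ ~ Uniform(0,1),
β ~ Uniform(0, c), γ₁, γ₂ ~ Beta(5/9, 10/9) — mean 1/3 (the tetrasomic
value) with the variance of a uniform — and q ~ Dirichlet(½,…,½) under the
alternative (the Jeffreys-type choice; concentrations below 1 are standard
for proportion testing). All hyperparameters are user-settable.

The alternative marginal for known genotypes is the closed-form
Dirichlet-multinomial. All other marginals are estimated by plain Monte
Carlo over prior draws with log-sum-exp pooling: the active parameter
space is at most 4-dimensional and bounded, so prior sampling is adequate
and dependency-free, and every estimate carries a delta-method standard
error (sd(w)/(mean(w)·√N) on the weight scale). The default draw count is
50 000; the per-marker pipeline and the simulation studies use 10 000 by
default, which keeps the MC standard error of a log BF well below 0.1 in
the regimes exercised here — raise `draws` for sharper factors. The
estimator is validated against adaptive quadrature on ≤2-active-parameter
cases and against the closed form. As a reporting convention, log BF
< −16 is treated as strong evidence of distortion in summaries; no
decision is hard-coded.

## Baselines

The plain chi-squared test compares counts against the
no-double-reduction, no-preferential-pairing (hypergeometric)
expectations, with p = 0 when a zero-expectation category is occupied. The
`polymapr_like` test mimics the published description of polymapR's
`checkF1` screen: for every combination of fully polysomic / fully
disomic segregation per parent, a chi-squared test on the pattern's
"valid" genotypes times a one-sided binomial test of the "invalid" count
against a 3% ceiling, reporting the maximum product over patterns;
posterior-matrix input is first collapsed to pseudo-counts (per-dosage
posterior sums, sums below a configurable threshold — default 0.001·n —
zeroed, renormalized to n). The original software's internal thresholds
are not published, so this baseline is faithful in spirit, not
bit-compatible, and is named accordingly.

## Synthetic data

The generator draws offspring genotypes multinomially from the meiosis
model (null scenarios) or from an explicit frequency vector (alternative
scenarios; a fixed menu of 14 distorted vectors plus a uniform-simplex
sampler). Sequencing is emulated by a beta-binomial read-count model:
allele fraction f = (k/4)(1−ε) + (1−k/4)ε at dosage k with sequencing
error ε = 0.01, no allele bias, overdispersion ρ = 0.01 (shapes
a = f(1−ρ)/ρ, b = (1−f)(1−ρ)/ρ; ρ → 0 degenerates to binomial), at a
fixed depth of 10 reads per individual. Genotype likelihoods are the
exact beta-binomial masses of the simulated count under each candidate
dosage, row-normalized to max 1.

Two fidelity caveats. First, real pipelines obtain genotype likelihoods by
fitting an empirical-Bayes genotyper to the read counts; the simulator
instead evaluates the true generative model, so passing tests show the
tests behave correctly given well-calibrated likelihoods, not robustness
to genotyper misfit. Second, the chi-squared baseline at finite depth
consumes posterior-mode genotypes under a uniform dosage prior, a
simplification of what practitioners run. The generator also fixes depth
exactly (no depth distribution) and does not emulate allele bias ≠ 1,
linkage between markers, or missing individuals.

## Problem sizes and numerics

The packaged studies use n ∈ {20, 200}, 200 replicates per null scenario,
and the test suite exercises the reduced grid {(1,0), (2,2)} × α ∈
{0, 1/6} × depth {∞, 10} at n = 200 — sizes chosen so the full suite runs
in a few minutes on one core while binomial error on an empirical
rejection rate at 200 replicates (±0.03 near 0.05) stays small against
the 0.10 acceptance margin. Larger grids are available through
`run_null_study`/`run_alt_study`.

Numerical conventions: probability vectors with cancellation-level
negative entries (deficit < 1e-10) are clipped and renormalized, larger
deficits raise; λ in [−1e-6, 0] is clipped to 0 and more negative values
raise; genotype-likelihood rows are normalized to max 1 on input
(scale-invariance of the likelihood) to avoid underflow; EM zeros are
declared at 1e-8. All simulators are bit-reproducible under a seed, and
the Bayes tests accept either a seed or a shared `numpy` Generator.
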