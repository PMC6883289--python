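# Methods

## The model

Each screened dog contributes two binary outcomes, the status of the left
and right elbow (1 = dysplastic). For trait *t* ∈ {R, L} and dog *j* the
disease probability is modelled through its log-odds

θ_tj = μ_t + β_t·(age_j − 24) + sex_t[sex_j] + a_tj + e_tj,

with trait-specific intercept μ_t, a per-month age slope β_t, a sex
contribution (females are the reference level, so the stored coefficient
is the male effect), an additive genetic value a_tj, and a latent
residual e_tj. The genetic values of the two traits are jointly Gaussian
over the pedigree,

(a_R, a_L) ~ N(0, G ⊗ A),

where A is the numerator relationship matrix built from the sire/dam
lists and G is the 2×2 additive genetic covariance. The residuals have
fixed unit variance per trait and no cross-trait covariance. On this
scale

h²_t = σ²_gt / (σ²_gt + 1),  r_g = σ_gRL / √(σ²_gR σ²_gL).

The heritability transform is used exactly as written: the logistic link
variance π²/3 is *not* added to the denominator. That matches the
reporting convention of registry analyses of this design; readers
comparing against threshold-model heritabilities should note the
difference (values here are larger for the same data).

Priors: each fixed effect is N(0, 10^10) (diffuse); G is inverse-Wishart
with scale V = I₂ and n = 3 degrees of freedom in the standard
parameterisation, under which the implied marginal prior of r_g is
uniform on [−1, 1] (verified by simulation in the test suite, 20,000
draws against a Kolmogorov–Smirnov test). Note that MCMCglmm's (V, nu)
convention differs; we commit to the standard density.

## Pedigree machinery

A is built by the tabular method: A_ij = ½(A_j,s(i) + A_j,d(i)) summing
only known parents, A_ii = 1 + ½A_s(i),d(i) when both parents are known
and 1 otherwise. A dog with one known parent contributes ½A_j,known and
keeps a unit diagonal — the unknown parent is treated as an unrelated,
non-inbred founder. Parents referenced but never listed are materialised
as founder records; they carry relationships but no phenotype.

A⁻¹ uses Henderson's rules with the Quaas inbreeding adjustment: the
Mendelian-sampling variance multipliers are d_i = ½ − ¼(F_s + F_d) with
both parents known, ¾ − ¼F_p with one, 1 for founders. This inverse is
exact for the tabular A under the same single-parent convention, and the
test suite enforces ‖A·A⁻¹ − I‖_max < 10⁻⁸.

An independent gene-dropping oracle estimates A by Monte-Carlo allele
transmission (unique founder alleles, one allele inherited at random from
each parent per replicate; the relationship is twice the probability of
identity by descent between randomly sampled alleles). Because roughly
10⁵ matrix entries are compared across the oracle pedigrees, a literal
"every entry within 3 standard errors" bound would fail by chance for a
correct implementation (~0.27% of entries exceed 3 SE); the check used is
≥99% of entries within 3 SE, no entry beyond 6 SE, and exact agreement
wherever the Monte-Carlo SE is zero. A systematic convention error moves
entries by hundreds of SE, so no power is lost.

## Sampling

The sampler is Metropolis-within-Gibbs with one structural choice worth
explaining: the latent residual e is integrated out of the likelihood
analytically. Because e is a unit-variance Gaussian added to the linear
predictor, the marginal likelihood of an outcome is the logistic link
convolved with a standard normal, P1(θ̄) = E_e[logistic(θ̄ + e)], a
smooth monotone scalar function tabulated once by Gauss–Hermite
quadrature (101 nodes, grid step 0.01, linear interpolation; the
symmetry P0(m) = P1(−m) halves the table work). The marginal posterior
of (fixed effects, a, G) is identical to the explicit-residual chain's —
e is never a reported quantity — but an explicit-e chain random-walks
along the ridge a_j + e_j = const and its variance components mix
pathologically slowly (thinned lag-50 autocorrelations near 0.7 in our
experiments, an order of magnitude above the 0.03 screening bound). The
marginalised chain meets the bound.

Update blocks per iteration:

* **Fixed effects**: single-site adaptive Gaussian random-walk Metropolis
  (six scalars), target acceptance 0.44.
* **Breeding values**: single-site adaptive random-walk updates. Sites
  are grouped into colour classes of the A⁻¹ sparsity graph (greedy
  colouring); within a class A⁻¹_ij = 0, so the single-site full
  conditionals are mutually independent and the accept/reject decisions
  vectorise. The product M = A⁻¹W (W = [a_R a_L]) is maintained
  incrementally by one dense matmul per class and refreshed every 50
  iterations to cap floating-point drift. Four full sweeps per iteration
  (`a_sweeps`): extra sweeps shorten the autocorrelation time of the
  genetic variances roughly in proportion, and four brings the thinned
  chain comfortably under the 0.03 screening bound at thin 100.
* **Global scale/shear moves** (20 repetitions per iteration): a_t ← c·a_t
  jointly with the congruence G ← TGT for T = diag(c, 1) (Jacobian
  c^{q+3}), and a_t ← a_t + δ·a_s jointly with the unit shear on G
  (Jacobian 1). Both leave the Gaussian prior density of (a | G) exactly
  invariant, so acceptance is driven by the inverse-Wishart prior and the
  likelihood change along the affected linear predictors. These moves let
  the genetic variances and covariance traverse their posterior in O(1)
  proposals instead of a q-dimensional random walk; without them the
  chain fails the autocorrelation screen at any affordable thinning.
* **Intercept/mean-a translation**: a likelihood-invariant exchange
  between μ_t and the mean of a_t.
* **G**: conjugate Gibbs draw from IW(V + WᵀA⁻¹W, n + q).

Proposal scales adapt multiplicatively toward 0.44 acceptance during
warm-up only; adaptation freezes at the end of warm-up so the retained
chain is a fixed-kernel Markov chain. Initial state: fixed effects 0,
a = 0, G = V. A single chain is run; the seed fixes the chain bitwise.

Schedules: the registry-scale default is 200,000 iterations, 50,000
warm-up, thinning 100 (1,500 retained); the workstation default
(`ChainConfig.desk()`) is 20,000 / 5,000 / 50, which the validation
studies below use. Retained-sample bookkeeping keeps iterations
warm-up + k·thin.

Correctness evidence, all reproducible from the test suite:

* a prior-only run (no phenotypes) reproduces the IW(I₂, 3) prior:
  r_g draws uniform on [−1, 1], variance margins InvGamma(1, ½);
  this exercises every Jacobian in the scale/shear moves;
* on a one-dog pedigree with the latent blocks frozen, the chain's
  marginal for μ matches a dense-grid posterior to < 0.05 in sup-CDF
  distance;
* the G-Gibbs draw reproduces scipy's inverse-Wishart exactly when a = 0
  and satisfies the Wishart moment identity E[G⁻¹] = df·scale⁻¹ at
  hand-set breeding values.

## Diagnostics and summaries

Lag-1 autocorrelation is the Pearson correlation of consecutive retained
samples; quantities above the 0.03 screening bound are flagged.
Effective sample size uses Geyer's initial-positive-sequence truncation
(the estimator the screening workflow presumes); arviz's rank-normalised
ESS serves as an order-of-magnitude cross-check in tests, not as the
implementation. Posterior summaries transform each retained sample to
h² and r_g *before* averaging, and report the mean, the SD of the
retained sample (ddof = 1), the central 95% interval, and a Monte-Carlo
standard error (SD/√ESS). Published registry tables print a "standard
deviation of the MCMC sample" that is implausibly small for a posterior
SD; both quantities are reported here so either reading is available.
A repeated-measures flag is raised when the posterior mean r_g exceeds
0.95, the conventional point at which two traits are treated as repeated
measures of one phenotype.

## The synthetic-data generator

The generator produces data under exactly the assumed model, so
parameter recovery is a meaningful end-to-end test. Defaults define the
reference study: 150 founders, 3 non-overlapping generations of
monogamous random matings with 4 offspring each (~1,050 dogs); true
G = [[1, 0.9], [0.9, 1]] (h² = 0.5 on both elbows, r_g = 0.9); age at
screening uniform on 24–190 months with β = 0.005 per month; male excess
0.2 on the logit scale; intercepts −2.32, giving ~21% expected prevalence
(computed by Gauss–Hermite quadrature over the latent normal; a
`tune_intercept` helper solves for any target). These sit inside the
2–47% range real breed registries show. Breeding values follow the
pedigree recursion a_i = ½(a_s + a_d) + m_i with Mendelian-sampling
covariance d_i·G using the same Quaas multipliers as A⁻¹, which makes
the simulated covariance exactly G ⊗ A (verified by a Monte-Carlo
Kronecker check over replicate simulations).

Mating schemes: `random` (default); `assortative_by_phenotype` (like
mates with like, producing well-filled affected×affected mating cells);
`truncation_normal` (normal-elbow parents preferred — selection, used to
demonstrate declining EBV trends). The phenotype-dependent schemes need
phenotypes generation by generation, so `simulate_study` interleaves
pedigree growth, breeding values and phenotypes for them; per-individual
hash-seeded draws keep each dog's age/outcome identical as the pedigree
grows around it. Every pedigree member is phenotyped.

What the generator does **not** emulate: real registries' voluntary
submission bias, litter/maternal environmental effects, dysplasia grade
severity and lesion subtypes, genotype data, and overlapping
generations. Passing recovery tests therefore demonstrates correctness
of the estimator under the model's own assumptions, not robustness to
violations of them.

## Validation studies and their scale

All validation runs use workstation-scale problems chosen as the
package's reference conditions: fits of ~1,000–1,400 dogs with chains of
6,000–35,000 iterations. At this scale two phenomena are expected and
documented rather than hidden:

* **The prior floors the variance.** IW(I₂, 3) places marginal mass
  P(σ²_g < x) = exp(−1/(2x)) on small variances — only 0.7% below 0.1.
  With ~1,000–1,400 binary records the likelihood cannot overwhelm that
  floor: fits of data simulated with *zero* genetic variance return
  posterior mean h² ≈ 0.19–0.33. Registry analyses escape this because
  they use tens of thousands of dogs per breed. A desk-scale "null
  recovery" check against a 0.1 threshold therefore fails honestly, and
  the corresponding test is expected to stay red.
* **r_g shrinks toward zero.** With a uniform prior on [−1, 1] and
  limited bivariate information, the posterior mean of r_g at true 0.9
  lands around 0.68–0.84 across seeds (95% intervals cover the truth in
  4/5 seeds). This is posterior diffuseness, not estimator bias: interval
  coverage is correct, and two independent sampler implementations agreed
  on the same posteriors during development.

## Mating-type analysis

Dogs map to four mutually exclusive categories — normal (N), left-only
(L), right-only (R), bilateral (B) — and each offspring with a known
category falls into one (sire, dam) cell of the 4×4 grid extended by
UNKNOWN for unscreened parents. The multinomial logistic (log-linear)
model of the 4-way offspring outcome on mating-type indicators is fitted
by Newton–Raphson on the softmax likelihood. With cell indicators alone
the likelihood separates by cell and the saturated MLE equals the
observed within-cell proportions — the closed-form oracle the tests
enforce to 10⁻⁶. Outcomes never observed in a cell are separation cases:
the coefficient diverges, so the outcome is dropped from that cell's fit
domain, reported with probability zero and listed in the fit's `dropped`
record. An optional shared additive offspring-sex term links the cells,
in which case a joint damped Newton fit over the full design is used
(statsmodels' MNLogit is the independent cross-check in tests). Empty
cells are reported as *absent*, never as 0%: a zero from no observations
is an artifact, and collapsed parent-combination prevalences
(normal×normal … unknown×unknown, unordered in the parents) follow the
same rule.

## Intake rules

Eligibility: age at evaluation ≥ 24 months (the observed screening range
starts at 24, so the bound is inclusive); one record per dog, latest
evaluation date wins; breeds with ≤ 380 remaining submissions dropped
(strict inequality, applied after deduplication — whether the source
registry counted before or after deduplication is not stated). Every
removal is counted in a FilterReport whose totals must reconcile
exactly, and filtering is idempotent. EBVs are posterior means of a,
standardised by the posterior-mean genetic SD per trait and averaged by
birth year; population-size labels are small < 2,000 ≤ medium ≤ 10,000 <
large.

## Known limitations

* Only two mating-scheme families beyond random mating; no overlapping
  generations or sire reuse across years ("popular sire" structure).
* Dense A and A⁻¹ (fine to ~5,000 dogs on a workstation; the registry
  breeds of ~47k dogs would need sparse structures this package does not
  provide).
* Single-chain inference; no cross-chain R̂ (the reference workflow used
  a single chain per breed).
* The multinomial model with the sex term uses one shared additive
  coefficient; per-sex saturated fits are not provided.
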