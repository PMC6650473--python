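# Methods

## Model

A released table D is assumed to be a uniform i.i.d. sample of n_D
records from a population of known size n; each record has d discrete
attributes with per-attribute sample spaces coded 1..K_j (code 0 is a
reserved sentinel for the lower integration bound, F(0) = 0). The joint
law p(x) is modeled by a latent Gaussian copula: marginals Ψ_1..Ψ_d give
each attribute's CDF F_j, and a correlation matrix Σ couples them through
a zero-mean multivariate normal Z. The probability of a full record is
the normal mass of the latent rectangle

    q(x | Σ, Ψ) = P( Φ⁻¹(F_j(x_j − 1)) < Z_j ≤ Φ⁻¹(F_j(x_j)), j = 1..d ),

with F_j(0) = 0 mapping to −∞ and F_j(K_j) = 1 to +∞. Sampling inverts
the construction: draw z ~ N(0, Σ), set u_j = Φ(z_j) and
x_j = F_j⁻¹(u_j) by the generalized inverse (smallest code whose CDF
reaches u_j; the inverse is plateau-safe because the marginals are
discrete).

From q(x) the risk quantities follow in closed form: uniqueness
ξ = (1 − q)^(n−1); correctness κ = (1/(nq))(1 − (1 − q)^n), the
expectation of 1/(T+1) over T ~ Binomial(n−1, q) false-positive
candidates; population uniqueness Ξ = Σ_x q(x)(1 − q(x))^(n−1), computed
either by exhaustive enumeration of the sample space (refused above a
configurable cell cap, default 10^5) or as the mean unique fraction of
synthetic populations sampled from the model (with a between-trial
standard error).

Assumptions worth keeping in view: rows are exchangeable and uniformly
sampled from the population (no post-stratification weights, no
selection bias); attributes are discrete with a fixed, known sample
space; the population size n is supplied by the user; the dependence
structure is exchangeable-Gaussian (no tail dependence, no negative
latent correlation — see Limitations).

## Fitting

**Marginals.** Each attribute is fitted by maximum likelihood over three
families — categorical (plug-in frequencies), negative binomial (size r,
success θ, shifted to support 1.., moment-matching start, Nelder–Mead on
(log r, logit θ)) and logarithmic/log-series (single parameter p, bounded
scalar minimization) — and the family minimizing
BIC = −2 log L̂ + k log n_D is kept (k = K−1, 2, 1 respectively; ties
prefer fewer parameters). The two count families have infinite support
and are truncated to 1..K and renormalized so F(K) = 1, which the
rectangle bounds require. A family whose optimization degenerates is
skipped, not fatal. Exogenous exact marginals (population count tables)
can replace fitting per attribute (k = 0).

Nominal attributes carry no meaningful category order, so a uniform
random permutation of their categories is drawn (seeded) once at fit
time and baked into the model; ordinal attributes keep the identity
order. Scores of a fixed record are therefore reproducible within a
fitted model.

**Dependence.** Each pairwise correlation Σ_ij ∈ [0, 1] is found by
minimizing |A(D_i; D_j) − A(Y_1; Y_2)| where Y is a synthetic bivariate
sample drawn from the pair copula at the candidate σ and A is mutual
information adjusted for chance with a permutation null,
A = (I − E[I]) / (max{H_i, H_j} − E[I]); the adjustment matters because
plug-in MI overestimates association in small samples over large
supports. Raw MI is available behind a flag. The latent normal draws
behind Y and the permutation index sets are generated once per pair and
reused for every σ the optimizer visits, so the objective is a
deterministic function during the search. The assembled matrix gets its
eigenvalues clipped at a floor (default 1e-6, keeping the copula density
invertible) and is rescaled to unit diagonal.

**Optimizer.** The bounded Nelder–Mead search pays +∞ outside [0, 1] and
stops at 1e-3 on σ. Because the common-random-number objective is
deterministic but jagged, the search starts from the best of an 11-point
grid over [0, 1] with an initial simplex of half-width 0.05; started
instead from a near-zero point with Nelder–Mead's default (proportional,
hence tiny) initial step, the search can stall in a local ripple and
report σ̂ ≈ 0 for a pair whose true correlation is 0.3.

## Numerical choices

- Rectangle probabilities use the separation-of-variables transform of
  the Genz–Bretz randomized quasi-Monte-Carlo method, vectorized over
  batches of cells sharing one Σ: scrambled Sobol' points, 8 independent
  scramblings, error estimated as 3 standard errors across scramblings,
  and sample size doubling (from 2^11 points) until the target absolute
  tolerance or the point budget (default 2^17) is reached. The attained
  error is reported per cell. d = 1 is the exact marginal mass; d = 2 is
  a 1-D adaptive Gauss quadrature of the conditional normal band
  (~1e-10). A fixed integration seed is stored in the model so repeated
  scoring is bit-stable.
- The default integration tolerance is 1e-6 per cell. An error of 1e-6
  in q moves ξ by at most ~(n−1)ξ·1e-6 — about 1e-2 at n = 10^5 in the
  worst case and far less for rare cells — which is negligible against
  the sampling error of any fitted model; tightening the tolerance is a
  model option for users who need it.
- Zero-mass cells under any marginal return q = 0 exactly, without
  integration. Duplicate records in a batch are integrated once.
- Powers are taken in log space: ξ = exp((n−1) log1p(−q)) and
  1 − (1 − q)^n = −expm1(n log1p(−q)), stable for n ~ 10^8 and q down to
  the double-precision floor; the q = 0 and ξ ∈ {0, 1} limits are handled
  exactly. Note the ξ-parameterized correctness κ(ξ) runs through
  log ξ / (n − 1), so ξ values below ~1e-308 (unrepresentable) collapse
  to the exact ξ = 0 limit κ = 1/n.
- Near-singular Σ (e.g. a pair driven to σ = 1) receives a diagonal
  jitter at the Cholesky step rather than failing.

## Defaults that matter

| parameter | default | meaning |
|---|---|---|
| `population_size` | required | population size n behind the sample |
| `mc_sample_size` | max(10000, n_D) | size of the synthetic pair sample Y; smaller values make the AMI objective too jagged to optimize |
| `n_perm` | 25 | permutations estimating E[I] in the chance correction |
| `sigma_bounds` | (0, 1) | latent correlation search domain |
| `eigen_floor` | 1e-6 | eigenvalue clip of the PSD projection |
| `abs_tol` / `max_points` | 1e-6 / 2^17 | per-cell integration tolerance and QMC budget |
| `min_records` | 50 | scoring guard: smaller training samples refuse to score unless overridden |
| `n_trials` (empirical Ξ) | 5 | synthetic populations averaged per estimate |

All randomness — category orders, common random numbers, permutations,
integration, sampling — derives from one root seed through
`numpy.random.SeedSequence.spawn`, so any intermediate result is
reproducible in isolation.

## Synthetic scenario suite

The shipped scenarios are fully specified generative models (known Σ and
Ψ) plus one drawn population, so ground truth per-record uniqueness is
available by exhaustive counting. Two small scenarios (`tiny_binary`:
3 binary attributes, 8 cells, n = 60; `tiny_mixed`: 5×4×3 cells,
n = 300) support exact-versus-simulated cross-checks by enumeration.
Three standard scenarios use n = 100,000 populations with d = 4–5
attributes of cardinality ≤ 12 — the scaled-down study conditions used
throughout the tests — with Zipf-skewed categorical and truncated
log-series marginals and latent correlations 0.2–0.6, realizing
population uniqueness of about 0.02 (`correlated_mixed`), 0.055
(`mid_sparse`) and 0.39 (`high_card`). Under the cardinality cap the
attainable uniqueness tops out well below what large real sample spaces
produce; the suite spans low-to-high within that envelope.

What the suite does and does not show: the generator draws exactly from
the model family being fitted, so passing tests demonstrate correct
inference, integration and calibration under correct specification and
uniform sampling — not robustness to misspecified dependence, biased
sampling, measurement error or attribute semantics found in real
releases. Benchmark attributes are declared ordinal because a
latent-copula ground truth carries ordered dependence by construction;
declaring such an attribute nominal would randomize its category order
against a truth that has one, a misspecification real order-free
attributes do not present.

The benchmark protocol mirrors a realistic attack evaluation: train on a
single 1% sample, score 1,000 population records disjoint from the
training rows, label each by exhaustive counting, and report ROC/AUC,
false-discovery rates at thresholds 0.9/0.95/0.99, and the Brier score
against the best constant predictor (assigning every record the
population's unique fraction — the quadratic-loss-optimal constant).

## Limitations

- Latent correlations are restricted to [0, 1] as a design default;
  negative association is representable only through nominal
  category-order randomization, and the search domain is a config
  override for users who need it.
- Per-record calibration under nominal-order randomization is
  intrinsically limited when an attribute's dependence is strongly
  ordered: matching mutual information reproduces the strength of
  association but not its cell-level pattern under an arbitrary order.
- The pairwise-then-project estimate of Σ is not a joint maximum
  likelihood; it trades statistical efficiency for d(d−1)/2 cheap
  one-dimensional searches.
- Non-uniform sampling, post-stratification weights and missing-data
  mechanisms are out of scope; missing values are rejected unless
  explicitly declared a category.
- Exhaustive Ξ is capped (default 10^5 cells); beyond it only the
  synthetic-population route is offered.
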