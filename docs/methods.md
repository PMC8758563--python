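# Methods

This note documents the models, the numerical choices, and the synthetic
data-generating processes behind `healthprod`, including the points where
the design was genuinely open and what the packaged defaults imply.

## 1. Efficiency measurement (EBM DEA)

### Model

Each calendar year is a separate cross-sectional frontier: provinces are
compared only with peers in the same year, because the covariates are
deflated to a base year and scores are reported yearly. Pooled or window
frontiers are out of scope.

The non-oriented EBM program blends a radial pair (θ for inputs, φ for
outputs) with weighted non-radial slacks. Undesirable outputs (medical
waste, mortality) sit on the output side scaled by φ, with slack credit
for reduction; the desirable output is the perinatal survival rate
(1 − perinatal mortality). We implement the equality-with-slack form
(Σλx + s⁻ = θx_k, etc.), which at the optimum coincides with the printed
mixed-inequality form and is numerically cleaner.

Super-efficiency excludes the evaluated unit from its own reference set
(λ_k = 0), so frontier units score above 1. Under this exclusion the LP
can be genuinely infeasible — typically a unit whose desirable/undesirable
output ratio is unmatched by any convex combination of the others. Such
cells are reported as missing with a diagnostic, never imputed; downstream
spatial statistics drop the affected unit for that year and re-standardise
the weight sub-matrix.

### Linearisation and solver

The fractional objective is linearised exactly with the Charnes–Cooper
transform (all variables scaled by t = 1/denominator; the denominator is
pinned to 1). Under constant returns the program is positively
homogeneous, so the denominator-1 representative of (θ, φ, λ, s) is
reported directly; under variable returns (Σλ = t) and in the pinned
θ = φ = 1 configuration, t is identified and the solution is unscaled by
it. LPs are solved with HiGHS at feasibility tolerance 1e-9; score
comparisons in tests use 1e-6.

### ε and slack weights

No canonical data-driven rule is forced on the user, but the default
follows the diversity/affinity idea of the EBM's originators: for each
pair of rows (input series across units) compute log-ratios
d_j = ln(a_j/b_j), the diversity D = Σ|d − d̄| / (n(d_max − d_min))
(zero for proportional series), and the affinity S = 1 − 2D. Weights are
the Perron eigenvector of the affinity matrix normalised to sum 1, and
ε = (m − ρ(S))/(m − 1) where ρ(S) is its spectral radius: proportional
rows give ε = 0 (pure radial — there is no independent non-radial
information), fully diverse rows push ε toward 1. The output-side weights
treat desirable and undesirable series jointly (they sum to 1 together).
A single input row gets ε⁻ = 0 by convention. ε⁻ and ε⁺ are determined
separately but default to the same procedure.

### Decomposition

TE is the full-reference CRS score, PTE the full-reference VRS score
(convexity constraint Σλ = 1), SE = TE/PTE ≤ 1. The decomposition
deliberately does **not** use super-efficiency, so that the CRS frontier
envelops the VRS frontier by construction and SE is well defined.

### Validation oracles

Three independent solvers guard the implementation: a radial
super-efficiency LP normalised by φ = 1 (no Charnes–Cooper), a weighted
SBM solver using Dinkelbach's parametric iteration, and a refined-grid
search over (θ, φ) with an inner slack LP for tiny instances. The ε = 0
and θ = ε = 1 limits of the EBM solver agree with the first two to 1e-6
on hundreds of random instances; the grid oracle agrees to 1e-4 on 3-unit
instances. The SBM equivalence is exercised on the full-reference model,
where the classic SBM program is defined; super-efficiency SBM variants
use a different program entirely and are out of scope.

## 2. Panel utilities

- **Missing values**: interior gaps are filled by linear interpolation
  between the nearest observed neighbours, edge gaps by the nearest
  observed value. The rule is idempotent and preserves observations
  exactly.
- **Grading**: bands are the half-open intervals (0, 0.8] low,
  (0.8, 1] medium, (1, ∞) high. The 8-grade refinement uses 0.1-wide
  half-open intervals with edges 0.6, 0.7, …, 1.2 and open tails;
  the edges are configurable. Each grade lies inside exactly one band.
- **Presentation rounding** is decimal-exact half-even at 3 decimals and
  applied only at the reporting layer.
- **Known fixture errata**: the packaged published score grid carries
  printed per-row Max/Min/Mean columns. Max and Min reproduce from the
  grid for all 31 rows; the Mean column disagrees by exactly 0.001 for
  two rows (JiangSu, JiLin), and four of the eight printed regional means
  similarly sit 0.001 from the grid recomputation — the original table
  was evidently summarised from unrounded machine scores. The package
  always reports its own recomputed aggregates.

## 3. Spatial weights

The packaged China scheme is queen-style land-border contiguity among the
31 provincial units plus a Hainan–Guangdong sea link (the usual community
convention), so no island rows exist. Row standardisation divides each
nonzero row by its sum and leaves genuinely islanded rows zero with a
warning. Inverse-distance weights (1/d with cutoff) are provided as the
alternative family. All downstream stages default to the row-standardised
contiguity matrix, whose spectral radius is exactly 1.

## 4. Spatial statistics

Moran's I uses the standard cross-product form; its expectation under
spatial randomness is −1/(n−1). Inference offers the analytic
randomisation (Cliff–Ord) z-score and a seeded permutation test with
pseudo p-value (count + 1)/(n_perm + 1); the two-sided variant counts
|I − E[I]| exceedances and one-sided variants are available. Default:
999 permutations.

Local quadrants (HH/LH/LL/HL) pair the sign of a unit's deviation from
the cross-sectional mean with the sign of its row-standardised spatial
lag's deviation; exact zeros go to the low side (configurable).

Gi\* is the self-inclusive neighbourhood share Σⱼ W_ij x_j / Σⱼ x_j with
self-weights added and rows re-standardised; the z-scored variant and the
self-exclusive Gi are options.

## 5. Spatial panel econometrics

### Estimation

SLM/SEM/SDM are estimated by (quasi-)maximum likelihood with the spatial
coefficient concentrated out and the log-determinant computed exactly
from the eigenvalues of W (n = 31 makes this cheap). Fixed effects are
removed by within transformation. Two corrections matter and are applied:

- cross-sectional (time-effect) demeaning annihilates the unit
  eigenvector of a row-standardised W, so one eigenvalue (= 1) is dropped
  from the log-determinant and the effective cross-section is n − 1;
- time demeaning (individual effects) removes one period (T − 1
  effective copies).

Without these the spatial coefficient is visibly biased (≈ −0.09 at
ρ = 0.4, n = 31, T = 11); with them the bias is below 0.01. The
covariance over [β, θ, ρ or λ] comes from the numerical Hessian of the
full log-likelihood (central differences, relative step 1e-5).

R² is the squared correlation between observed and reduced-form fitted
values on the transformed data — the comparator used to pick the
fixed-effect variant, mirroring common spatial-panel software output.

### Diagnostics

- **HT unit-root screen** for short panels (T < N): pooled LSDV AR(1)
  estimate compared with its exact random-walk expectation at fixed T —
  1 − 3/(T+1) with unit intercepts — and the corresponding finite-T
  variance; z is asymptotically standard normal in N, rejection is
  left-tailed. Convention: T counts the lagged regressions, so a panel
  with 12 time points has T = 11 and null expectation 0.75.
- **LM tests** (lag, error, robust variants) are the standard score
  tests on pooled OLS residuals with per-period spatial lags and traces
  scaled by T.
- **Hausman** compares within (FE) and Swamy–Arora GLS (RE) estimates of
  the non-spatial panel regression — the classic individual-effects
  contrast — with a pseudo-inverse fallback when the covariance
  difference is indefinite.
- **LR/Wald degeneracy**: LR = 2(logL_SDM − logL_restricted) with k
  degrees of freedom against SEM and SLM; Wald tests H₀: θ = 0 (vs SLM)
  and the common-factor restriction H₀: θ + ρβ = 0 (vs SEM, delta
  method). A negative LR beyond tolerance signals non-convergence and
  raises.

### Model selection

`select_model` runs the chain in order: HT screen per covariate → LM on
OLS residuals (neither spatial statistic significant ⇒ OLS) → Hausman
(reject ⇒ fixed effects) → SDM under time/individual/two-way FE, keeping
the variant with the highest R² → LR/Wald against SEM and SLM (both
reject ⇒ keep SDM, otherwise degenerate to the better-supported
restricted model). All significance levels default to 5% and are
configurable.

### Effects

Direct/indirect/total effects use the spatial multiplier
S_k = (I − ρW)⁻¹(Iβ_k + Wθ_k): direct = mean diagonal, total = mean row
sum, indirect = total − direct (the identity holds to machine precision).
Inference simulates 1000 seeded draws from the estimated sampling
distribution of (β, θ, ρ), discarding draws with ρ outside the stable
interval.

## 6. Synthetic data

Two generators supply data with the structure each stage assumes; both
are pure functions of their spec including the seed.

**Frontier panel**: inputs are lognormal; the desirable output lies on a
log-linear frontier y = Π xᵢ^aᵢ (default elasticities summing to 0.8,
i.e. mildly decreasing returns) scaled down by exp(−v) with v half-normal
(default scale 0.3); a designated subset of units has v = 0, so the true
frontier is populated. Undesirable outputs are proportional to aggregate
input use, divided by true efficiency (inefficient units pollute more)
with 5% lognormal jitter. The generator returns the true efficiency grid
for recovery tests; EBM scores rank units consistently with that truth
(Spearman ≥ 0.8 at n = 31). What it does **not** emulate: the real
yearbook covariate distributions, serial dependence of inputs, or
measurement error in outputs — so passing recovery tests show the method
works under its own assumptions, not that the published province scores
are correct.

**SDM panel**: y_t = (I − ρW)⁻¹(Xβ + WXθ + effects + ε) per period, with
iid standard-normal covariates by default. Two optional features emulate
real provincial panels for the end-to-end selection test: persistent
unit-specific covariate means (between variation) and unit effects
correlated with the unit's covariate level — the feature that makes
random effects inconsistent and drives the Hausman rejection, at a
strength chosen to produce Hausman statistics of the magnitude seen in
provincial studies (tens, not units). Defaults are ρ = 0.4, σ = 0.5-1,
n = 31, T = 11, matching the reference panel's dimensions.

## 7. Problem sizes and tolerances used in the checks

Property checks run at the reference dimensions (n = 31, T = 11) with
200 replicates for parameter recovery, 500–1000 for test-size
calibration, 50–100 random 8-unit instances for the DEA limiting cases,
and 999 permutations for Moran calibration — sizes at which Monte-Carlo
error is well below the asserted bands. LP agreement tolerances: 1e-6
against the independent radial/SBM solvers, 1e-4 against the grid oracle;
Moran brute-force agreement 1e-12; effects identities 1e-10.

## 8. Known limitations

- The published study's exact ε, slack weights and weight matrix are not
  stated, so its Moran magnitudes (Table-4-style) and regression
  coefficients are not bit-reproducible even from the printed score grid;
  only the aggregates of that grid are.
- Super-efficiency VRS cells can be infeasible; they propagate as missing
  values rather than scores.
- The random-effects arm is the classic individual-effects GLS; spatial
  random-effects estimators (and GMM/IV estimators generally) are out of
  scope.
- The permutation test treats the score field as exchangeable across
  units; scores are themselves estimates, and their sampling error is not
  propagated into the spatial inference.
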