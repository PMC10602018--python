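# Methods

## Model

`sprisk` implements the meta-analytic causal association model for
surrogate evaluation: a bivariate linear mixed model for surrogate S and
true endpoint T across N randomized trials, with subject-level bivariate
normal errors (covariance `sigma`, entries σ_ss, σ_st, σ_tt) and
trial-level multivariate normal random effects (covariance `D`). Covariates
enter the fixed part as main effects (γ) and treatment interactions (δ);
under Scenario 2 (S2) one scalar or binary covariate additionally carries
trial-level random effects (c for the main effect, d for the interaction),
growing D from 4×4 to 8×8. S2 is deliberately restricted to a single
covariate: each further covariate would add four random effects and the
associated rows of D, which is rarely estimable with realistic numbers of
trials; constructing an S2 parameter set with p > 1 raises.

D entries are stored as a full symmetric matrix with a fixed index map from
the field's flat names (documented in `model.py`): random effects are
ordered (a_S, a_T, b_S, b_T, c_S, c_T, d_S, d_T) with labels
(s, t, a, b, cs, ct, ds, dt), so `d_ab` = Cov(b_S, b_T) = D[2,3] and
`d_a_ds` = Cov(b_S, d_S) = D[2,6]. Covariates are used exactly as supplied
(no centering or scaling; binary covariates coded 0/1), and the S2
formulas accept any real x, not only {0, 1}.

The trial-level treatment effects at covariate level x are jointly
bivariate normal: mean (β_S + δ_S x, β_T + δ_T x), covariance the base
(d_aa, d_ab, d_bb) block under S1, and under S2 the x-weighted quadratic
forms

    d*_aa = d_aa + x² d_ds_ds + 2x d_a_ds
    d*_ab = d_ab + x (d_a_dt + d_b_ds) + x² d_ds_dt
    d*_bb = d_bb + x² d_dt_dt + 2x d_b_dt

computed as w' D w with loading vectors w_S = e_bS + x e_dS,
w_T = e_bT + x e_dT (the same vectors serve the conditional measures
below). The x²-coefficient in d*_ab is the covariance Cov(d_S, d_T), not a
product of entries. Parameter sets whose implied effect covariance is not
PSD are rejected at the model layer, never repaired; eigenvalue clipping
(at 1e−10) exists only inside the Gibbs sampler to absorb numerical jitter
in Wishart scale matrices.

## Risk measures

All measures are orthant probabilities of that bivariate normal law.
ψ_SP13 = 1 − Φ₁(0; m_S, v_SS) − Φ₁(0; m_T, v_TT) + 2Φ₂((0,0); m, C) and
ψ_SP123 = 1 − Φ₁(0; m_T, v_TT) + Φ₂((0,0); m, C). The bivariate normal CDF
is evaluated from Owen's T function (`scipy.special.owens_t`), a
deterministic vectorised identity accurate to ~1e−14 — far inside the
1e−7 absolute tolerance needed for three-decimal comparisons; exact zero
arguments are nudged by 1e−13 (error far below any tolerance) and
correlations within 1e−12 of ±1 are handled by their comonotone /
antimonotone limits. A zero-variance margin with exactly zero mean has an
undefined sign and raises; with nonzero mean its indicator factorises out.

The s-value solves P(Δ_T < 0 | O_S = s, X = x) = α where the observed
surrogate effect O_S(x) (arm-mean difference within level x) has variance
inflated by sampling noise: d̃_aa = d*_aa + σ_ss (1/n₁ₓ + 1/n₀ₓ). The
conditional probability is strictly decreasing in s when d*_ab > 0, so the
implementation inverts it by bracketed root-finding (Brent, xtol 1e−12) and
cross-checks the closed form
s = m_S − (d̃_aa/d*_ab)(Φ⁻¹(α)√(d*_bb − d*_ab²/d̃_aa) + m_T); the two agree
to 1e−8 in the tests. d*_ab ≤ 0 (threshold direction reversed) and
nonpositive conditional variance raise. α defaults to 0.05 and is exposed
everywhere; arm counts are user-supplied planning values for prospective
use, or counted from data at the stated x level retrospectively. Marginal
(covariate-averaged) measures use empirical point masses at observed x
values — the sample-average approximation of ∫ψ(x)P(x)dx.

## Ongoing-trial (partial-data) prediction

For a trial with data collected on the surrogate but few or no true-endpoint
values, the conditional law of its random-effect vector is the exact MVN
conditional γ_N | Y_N ~ N(D W'V⁻¹(Y − Mμ), D − D W'V⁻¹W D) with
V = W D W' + R. Missing T values are handled by deleting their rows from
(Y, M, W) and the corresponding rows/columns of R — for a joint normal this
deletion *is* analytic marginalisation, and the equivalence is unit-tested
against the full-matrix computation to 1e−10. The implementation uses the
algebraically identical precision form D̃ = (D⁻¹ + W'R⁻¹W)⁻¹,
γ̃ = D̃ W'R⁻¹(Y − Mμ), which costs O(q³ + n) rather than inverting the
2n×2n V; R carries a 1e−8 diagonal floor and a singular conditional
precision raises rather than being regularised further. With no data the
prior (0, D) is returned, and D̃ ⪯ D holds in the Loewner order on every
call.

The conditional measures plug the conditional mean
β̂_S + δ̂_S x + w_S'γ̃ (and T analogue) and covariance w' D̃ w into the ψ
formulas. Under S2 the published display reuses the 4-dimensional d̃₃₃/d̃₄₄
notation; the implementation reconstructs the intended x-weighted
combination with the same (1, x) loading vectors used for d*, which reduces
exactly to the 4-dimensional form under S1 and to the unconditional
measures when no data are observed. Parameters may be point estimates or,
by default for credible intervals, propagated per posterior draw.

## Bayesian estimation

All four full conditionals of (D⁻¹, σ⁻¹, {γ_i}, μ) are conjugate; the
sampler cycles them in the fixed order D → σ → {γ_i} → μ (any fixed order
is a valid Gibbs kernel — the source lists the conditionals without an
order). Priors: μ ~ N(0, 10⁶ I); Wishart priors on the precisions in the
convention W(ν, S) with E = νS, defaulting to ν = q + 1 and scale
I_q/(q + 2) for a q-dimensional random vector (q = 2 for σ⁻¹, 4 or 8 for
D⁻¹). Because the per-subject designs factor as f ⊗ I₂ (features
1, Z, X, XZ), every conditional reduces to Kronecker algebra on small
per-trial cross-product sums; a sweep is O(n + N q³), and a 30-trial ×
50-subject fit of 4000 iterations runs in a few seconds. Defaults: 4000
iterations, 1000 burn-in, no thinning, one chain; with ≥2 chains the seed
is split through `numpy.random.SeedSequence` and Gelman–Rubin R̂ is
reported. Initialisation: μ from pooled least squares, D and σ at the
identity, γ_i = 0. Runs are bitwise reproducible given the seed. Trials
with a single treatment arm, or with missing true endpoints, are excluded
from the fit with a logged warning (missing-T trials enter through the
partial-data measures instead). Correctness was validated two ways: a
long-run comparison against an independent MCMC implementation of the
identical model in JAGS (all marginal means within 0.05 posterior SDs at
matched run lengths — retained as a test at moderate length with
commensurate tolerances), and parameter recovery on data from the
generating model.

Posterior draws are transformed measure-by-measure; intervals are
equal-tailed empirical quantiles. Draws violating the s-value precondition
(d*_ab ≤ 0) are counted and reported, and an error is raised if they exceed
5% of the chain — s is then simply not identified at that covariate level.
Scenario comparison uses the marginal WAIC: per draw, each trial's
random effects are integrated out analytically (MVN likelihood with
covariance W_i D W_i' + R_i, evaluated in O(q³ + n_i) via the matrix
determinant and Woodbury lemmas, in log space), and
WAIC = −2(lppd − p_WAIC) with the variance-based effective-parameter term;
lower is better.

## Synthetic data and the replication study

The generator emulates the validation design: N ∈ {30, 100} trials of
n ∈ {20, 50, 500} subjects, half of each trial treated, a binary covariate
balanced within trial across the four treatment-by-covariate cells when n
is divisible by 4 (otherwise Bernoulli(0.5)); fixed effects
α_S = α_T = 1, β_S = 2, β_T = 1, γ_S = γ_T = 0, δ_S = −1, δ_T = 1; base
D with unit diagonal, d_ab = 0.5 and remaining off-diagonals 0.3; under S2
unit variances for the four covariate random effects and every off-diagonal
involving them equal to 0.3 (the full 8×8 matrix is verified PD at load).
The residual covariance is not part of the published design; the default is
σ_ss = σ_tt = 1, σ_st = 0.3 — unit-variance errors of the same order as the
random effects, with a modest positive endpoint correlation matching the
base off-diagonals. None of the ψ truths depend on σ.

Error families for sensitivity analyses: multivariate t₁₅ (single mixing
variable, scale matrix σ(ν−2)/ν so the covariance is exactly σ) and a
skew-normal (i.i.d. standardised skew-normal margins mapped through the
Cholesky factor of σ, so mean 0 and covariance exactly σ). The published
description of the skew-normal setting is ambiguous; here the shape is tied
to the scale as a = 0.1ω with ω solved for unit variance and the location
centring the mean — a mild right skew (standardised skewness ≈ 2×10⁻⁴) —
and the interpretation is recorded here so alternatives are one parameter
away.

`run_study` simulates replicates, fits each by Gibbs, and tabulates bias,
empirical SE and coverage of the 95% credible intervals against analytic
truths computed from the generating parameters (invariant to seed). True
s-values are computed from the package's own formula at user-stated
(α, n₁ₓ, n₀ₓ): the published "true value" rows for s are not reproducible
from the printed formulas (they differ between the 30- and 100-trial tables
although the formula involves no trial count, and the arm counts and α
behind them are unstated), so they are not used as references. For the
ongoing-trial measure the final trial has half the subjects of the others;
it is held out of the fit and its random effects are conditioned on its own
partial data per draw. Replicate-level estimation failures are logged,
excluded, and counted in the output.

What the generator does *not* emulate: real meta-analyses have unbalanced
arms, unequal trial sizes, informative missingness in T, and non-normal
endpoints. Passing tests therefore demonstrate correctness of the
estimators and measures under the model and mild tail/skew
misspecification, not robustness to those features.

## Test and study sizes

The suite uses scaled-down problem sizes chosen to exercise every claim
while keeping a full run under a minute of compute for the deterministic
parts: Monte-Carlo oracles at 10⁵–10⁶ draws, Gibbs recovery at 30×50 with
4000 iterations, the JAGS cross-check at 28k/25k iterations on a 6-trial
dataset, and the replication study at 20 replicates of 100 trials × 20
subjects with 1500 iterations (a stochastic reproduction of the published
100-trial cells, compared at ±0.05 bias and ±10 coverage points). The
Monte-Carlo orthant checks use a two-stage rule — a 10⁶-draw band at 3
binomial SEs, confirmed once at 4×10⁶ fresh draws if exceeded — because
~100 simultaneous 3-SE comparisons would falsely reject an exact
implementation about a quarter of the time, while the confirmation stage
halves the SE and so detects genuine discrepancies more sharply.

## Known limitations

- Frequentist (ML/REML) estimation is not provided: with 8-dimensional
  random effects the covariance estimate is frequently non-PD at realistic
  sample sizes, and inference here flows through posterior draws.
- Only one covariate under S2; no copulas or non-normal endpoint
  distributions; no sequential/interim monitoring logic.
- The s-value requires a positive surrogate–outcome effect association
  (d*_ab > 0) and is unstable when trials are few — posterior draws
  violating the precondition are reported rather than hidden.
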