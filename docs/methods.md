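# Methods

This note documents the statistical model behind `mcsagree`, the
choices made where the design was genuinely open, what the synthetic
generator does and does not emulate, and the package's known limits.

## Model family and estimation

The core object is the two-method replicated-measurement mixed-effects
model described in the README. Four switches define the family:
homo- vs heteroscedastic errors, linked vs unlinked replication,
optional mean covariates (no interactions), and the choice of
magnitude anchor. Free-parameter counts are 6 (homoscedastic,
unlinked), 8 (heteroscedastic), +1 for a linked occasion variance and
+1 per covariate.

**Variance-function convention.** The error law is
`Var(ε_ijk) = σ_εj² · u_i^(2δ_j)`: the power function `g(u, δ) = u^δ`
multiplies the error *SD*, so the variance carries the exponent `2δ`.
This convention is load-bearing — the intra-method TDI and LOA values
it produces are the ones the acceptance script reproduces to four
decimals — and it is asserted throughout the index formulas.

**Magnitude anchor.** `u_i` is the plug-in per-subject mean of the two
methods' replicate means (option: the reference method's mean alone;
the two choices differ negligibly on study-like data, which a test
asserts). Anchors are computed once from the data before optimization
and held fixed. A consequence worth knowing: because the observed
anchor carries noise that is weakly correlated with the per-subject
method difference, the GLS-type weighting induces a small finite-sample
bias in the fixed-bias estimator (on the order of 1e-3 pH units at 30
subjects × 10 replicates, roughly one sixth of the estimator SD). The
recovery suite measures it; it vanishes as replicates grow.

**Optimization.** Variances are log-transformed; `δ`, fixed effects and
covariate terms stay on the identity scale, so the parameter space is
unconstrained. L-BFGS-B with numerical gradients maximizes the summed
per-subject multivariate-normal log-densities (evaluated via batched
Cholesky factorizations of the 2K × 2K subject blocks). Moment-based
starting values (method means, pooled within-subject variances, a
log-variance-on-log-magnitude regression for `δ`) put the optimizer
close to the optimum; on failure, three jittered restarts are tried,
and a linked fit that still fails falls back to the unlinked model with
a recorded note — the occasion component is the usual culprit, and the
original analysis workflow proceeds the same way. Likelihood
convergence tolerance: 1e-8. The covariance of the estimates is the
inverse of a central finite-difference Hessian, eigenvalue-clipped to
positive semidefinite.

**Degenerate inputs.** Data with no variation raise immediately;
parameter points whose covariance overflows (large `δ`) raise a
numerical-domain error rather than returning a silent value.

## Indices and bounds

All inter-method indices flow from `D|u ~ N(β₀, τ²(u))` with
`τ² = 2ψ² + Σ_j σ_εj² u^(2δ_j)`. The linked occasion effect cancels
when same-occasion replicates are differenced, so `σ_c²` never enters
`τ²`. TDI(p) uses the noncentral-χ²₁ quantile form; intra-method TDI
reduces to the central folded-normal quantile because replicate
differences are centered at zero. The identity
`τ² = 2ψ² + v₁/2 + v₂/2` (with `v_j` the intra-method difference
variances) is asserted as a property test.

Confidence bounds are one-sided 95% (z = 1.6449), lower for CCC and
upper for TDI, via the delta method on transformed scales — Fisher z
for CCC, log for TDI and the precision ratio — with gradients taken
numerically against the Hessian-based covariance. `log λ(u)` is exactly
linear in the transformed parameters, so its interval needs no
numerical gradient. Model-based LOA use the fixed multiplier 1.96; the
small-sample t-quantile construction lives only in the classic
Bland–Altman statistics of the explore module.

**Recalibration** subtracts the fitted `β₀` from every test-method
value and *refits* rather than plugging `β₀ = 0` into the old fit:
shifting the test method also shifts the magnitude anchors, and the
refit propagates that. Reference values are never modified; a second
application changes the data by at most the refitted bias (≈0).

## Exploratory statistics

Bland–Altman pairs are formed by occasion for linked data and as one
per-subject mean pair for unlinked data (artificial replicate pairings
are presentation-only and never reach a model). CIs use the classic
construction: `SE(mean) = s/√n`, `SE(limit) = s·√(3/n)`, t(n−1)
quantiles. The proportional-trend slope is computed on **per-subject
mean** (average, difference) pairs: replicate-level pairs share the
subject × method effect, and regressing all of them treats n·K
correlated points as independent — the false-trend rate under a true
common scale then explodes (we measured ≈57% at the study design
against a nominal 5%). Aggregation restores the nominal level; the
trend verdict threshold (p < 0.05) is this package's choice. The
heteroscedasticity cue from the plot data is advisory; AIC/BIC model
selection is the formal arbiter, with ties broken by BIC and then by
fewer parameters.

Residual diagnostics report conditional residuals
`E Σ⁻¹ (y − μ̂)` standardized by their own SDs
`(E Σ⁻¹ E)_kk^{1/2}` — standardizing by the raw error SD ignores the
BLUP shrinkage, which varies across observations and masquerades as
heavy tails in the QQ display.

## Measurement-error track

Stage 1 estimates latent true values by empirical Bayes from the
reference replicates (`x_i ~ N(μ_x, σ_x²)`, method-of-moments variance
components); stage 2 regresses test replicates on those estimates. The
EB shrinkage exactly offsets regression attenuation, so `β̂` is
consistent — a property the zero-noise tests verify exactly. Intervals
are percentile bootstrap over subjects (500 resamples by default;
stochastic tests use fewer), which propagates stage-1 uncertainty.
Variance functions for the precision profile are quadratic fits on the
log scale of within-subject variances against latent means — the
simplest smooth family consistent with gently curved precision
profiles. This two-stage scheme is a deliberately transparent estimator
of (α, β); it is validated by parameter recovery and coverage, not by
digit-matching any particular alternative implementation.

## Synthetic generator

The generator emulates a two-device pH comparison: subject means drawn
from a two-cluster normal mixture (two fruit varieties; defaults
(2.97, 3.57) ± (0.07, 0.08) with equal weights, putting the reference
marginal mean at 3.27 and the test mean at 3.05), fixed bias −0.22,
`ψ² = e^{−6.67}`, error scales (2.615606e−8, 7.374885e−8) with
exponents (4.07, 3.28), 30 subjects × 10 linked replicate pairs, and an
occasion variance of 0 by default (the published components do not
include one). The generator's error variance uses the latent
cross-method mean `u_i = b_i + β₀/2` — the population counterpart of
the fitted pairwise-mean anchor; using the reference-level mean instead
would offset every anchor by |β₀|/2 ≈ 0.11 against the model it feeds.

What it does **not** emulate: non-normal errors, time drift or carryover
across occasions, operator effects, covariate-driven means (the
emitted cluster label is a null covariate), or the reference device's
single stray minimum reading visible in the real study's summary
table. Passing tests therefore demonstrate correctness of the
estimators under the model's own assumptions at the study's design and
effect sizes — not robustness to the ways real instruments misbehave.

The mixture means were chosen so the implied reference/test marginal
means match the fitted study model (3.27 / 3.05); the mixture then
implies a between-subject variance of ≈0.092, somewhat above the
study's fitted σ_b² — the two constraints cannot both hold with
two symmetric clusters spanning the study's magnitude range, and the
marginal means won.

## Problem sizes in the shipped tests

Monte-Carlo oracles use 10⁶ draws (3-MC-SE tolerances). Recovery runs
200 synthetic studies for the mixed model and 200 for the
measurement-error bias pair; model-selection correctness uses 50
replicates per generating regime; bootstrap-coverage checks use 200
studies × 200 resamples. Smaller module examples (trend verdicts,
spread orderings, crossing counts) use 100 replicates. These sizes give
MC standard errors comfortably below the effects being asserted.

## Known limitations

- Exactly two methods; REML is not offered (ML only, as the df-based
  model comparisons require).
- Only the power-of-magnitude variance family is implemented.
- Delta-method bounds are asymptotic; at 30 subjects the CCC lower
  bound can be mildly conservative (coverage checks sit at 0.92–0.97
  for the fixed bias).
- The intra-method CCC uses `(σ_b²+ψ²)/(σ_b²+ψ²+σ_εj²u^(2δ_j))`;
  published intra-CCC figures from the motivating study are not exactly
  reproduced by this expression, suggesting the original computation
  included terms beyond those printed, and no attempt is made to
  reverse-engineer them.
- The linked heteroscedastic fit is noticeably harder than the unlinked
  one; the automatic fallback mirrors standard practice but means
  linked occasion variance is only estimated when the optimizer
  cooperates.
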