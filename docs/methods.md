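# Methods

## Model class and approximations

The package performs approximate Bayesian inference for models of the form
y = g(β) + ε with ε ~ N(0, Πy(λ)⁻¹) and Πy(λ) = Σₖ exp(λₖ)Qₖ. Three
approximations define the scheme:

1. **Mean-field factorisation.** The posterior over parameters and noise
   hyperparameters is approximated as Q(β)Q(λ).
2. **Laplace form.** Each factor is Gaussian; the free energy (the evidence
   lower bound) is evaluated with a quadratic expansion of the log joint
   around the posterior means, which reduces it to the closed-form sum of
   likelihood, prior, entropy and constant terms used as the objective.
3. **Local linearity of g.** Gradients and curvatures use the Jacobian of g
   (central finite differences) and omit second derivatives of g; the
   parameter posterior precision is the Gauss–Newton form JᵀΠyJ + Πβ, and
   the hyperparameter posterior is kept diagonal.

Two consequences are worth knowing. First, because the objective is a
*quadratic approximation* of the variational functional, it is not a
guaranteed lower bound on the log evidence for nonlinear g: the exact
functional of any Gaussian Q is (the validation suite verifies this by
Gauss–Hermite quadrature), but the approximated objective can exceed the
evidence by an amount that scales with the nonlinearity over the posterior
width — a few hundredths of a nat on the mildly nonlinear test family. It
is exact, and the bound tight, for linear g with fixed λ. Second, the
mean-field/Laplace posterior over hyperparameters is mildly overconfident:
in repeated-sampling calibration the spread of the noise log-precision
estimator is ~10–15% wider than the posterior sd reports, so 90% intervals
cover the truth at roughly 83–87% for the hyperparameter (parameters are
close to nominal). This is a known property of variational schemes, not of
this implementation.

## The ascent

Both mean updates integrate the gradient flow μ̇ = ∇I(μ) over a finite time
t by local linearization, Δμ = (exp(tH) − I)H⁻¹∇, computed through the
matrix exponential of the augmented system [[H, ∇],[0, 0]] (no explicit
inverse; well defined for near-singular H). Small t behaves like gradient
ascent; by t ≈ 2 the update is within exp(−2) ≈ 13.5% of the Gauss–Newton
step. The time is t = exp(v)/α where α = exp(ln|det H|/n) is the
geometric-mean curvature magnitude — steeper landscapes automatically get
shorter integration times. The printed form of this scaling could be read
as multiplying by α; we divide, which is the direction that actually
increases regularization with curvature and matches the stated behaviour.

Per outer iteration: (1) Jacobian at the current means; (2) up to 8
hyperparameter updates (shared v); (3) covariance refresh; (4) one
parameter update; (5) free-energy evaluation. An improvement is accepted
and v rises by ½ (capped at 4); a worsening or an unevaluable candidate
(integration blow-up, non-positive balloon states) restores the previous
state and drops v by 2. Accepted free energies are therefore monotone, and
the whole procedure is deterministic.

**Convergence** is declared when the predicted improvement stays below 0.1
nats for 4 consecutive iterations. The prediction uses the full quadratic
(Gauss–Newton) step, ∇ᵀ(−H)⁻¹∇, rather than the regularized step actually
taken: the regularized prediction shrinks with v, so heavily regularized
early iterations would masquerade as convergence. On nonlinear models the
predicted improvement plateaus at a small positive floor (the mean update's
gradient omits the entropy term's dependence on β through J), which the 0.1
nat default tolerance absorbs; oracle-equivalence experiments that need
1e-6 posterior accuracy use a tighter tolerance (1e-9, 256 iterations),
exposed as `validation.PRECISE`.

Numerical choices: log-determinants and quadratic forms via Cholesky
factorisations throughout (never determinants or explicit inverses); SPD
solves retried once with jitter 1e-10·tr/n; hyperparameter posterior
precisions floored at 1e-8 before inversion; finite-difference step
1e-4·max(1, |μⱼ|) per coordinate.

### The hyperparameter-uncertainty gradient term

The parameter gradient carries a third term propagating posterior
uncertainty about λ: ½ Σⱼ (Σλ)ⱼⱼ JᵀPⱼε_y with Pⱼ = exp(λⱼ)Qⱼ. The ½ is
required for the expression to be the exact derivative of the variational
energy E_Q(λ)[ln P(y, β, λ)] under the quadratic treatment — the
finite-difference cross-checks in the test suite pin this down. (Printed
accounts of the scheme sometimes omit the factor; the term is higher-order
small either way.)

## Dynamic models

An ODE model ẋ = f(x, β, u) with observation map applied at sampling times
becomes an observation function by integrating each interval with the same
local-linearization update, using the state Jacobian of f (central
differences, shared code path with the optimizer) and a 4th-order
Runge–Kutta fallback if the augmented exponential fails numerically. Inputs
are held piecewise constant over each sampling interval (zero-order hold,
matching how experimental stimulus trains are specified). Flattened
predictions are time-major (all channels at t₁, then t₂, …), the
convention precision components index. Default: one internal sub-step per
interval — the update is exact for linear fields regardless of step size —
configurable where the field is strongly nonlinear.

## Worked models

* **GLM** (`glm_design`, `glm_predict`): intercept plus one covariate of
  100 evenly spaced values in [−50, 50]; one identity precision component,
  or contiguous 0/1 block masks (`hetero_components`, last block takes any
  remainder) for heteroskedastic variants.
* **Exponential decay** (`decay_field`): ẋ = −exp(β)x; β is the log rate,
  so the rate is positive by construction.
* **Balloon model** (`hemo_field`, `bold_observation`): states (s, f_in, v,
  q); constants default to the standard literature values α = 0.32 (Grubb's
  exponent), γ = 0.32 /s, E₀ = 0.32, V₀ = 0.04, θ₀ = 40.3 /s, r₀ = 25 /s,
  TE = 40 ms, ε_h = 0.5, all overridable; k₁ = 4.3·θ₀·E₀·TE,
  k₂ = ε_h·r₀·E₀·TE, k₃ = 1 − ε_h. (0, 1, 1, 1) is an exact fixed point
  and the BOLD output is exactly zero there. Transit time and decay rate
  are fitted as logs; efficacy is unconstrained.
* **Bilinear neural model** (`bilinear_field`): ż = (A + Σⱼ uⱼBⱼ)z + Cu.
  In file-specified models, entries with zero prior variance are excluded
  from the parameter vector, so structural zeros survive fitting exactly.

## Synthetic-data fixtures

Each generator is a pure function of a `FixtureSpec`; the seed fixes the
dataset bit-for-bit. Declared study conditions (chosen once, as realistic
desk-scale settings for each model class):

| fixture | truth | priors | size/noise |
|---|---|---|---|
| glm | β = (4, 0.3), λ = −2 | β ~ N(0, 16I), λ ~ N(0, 16) | 100 obs |
| glm-hetero | λ = (−3, −1) | as glm | two blocks of 50 |
| decay | β = −1, λ = 2, x₀ = 1 | β ~ N(0, 1) | 50 samples over 10 s |
| hemo | τ_h = 2 s, κ = 0.64 /s, z = 0.4 | logs ~ N(canonical, 1/16), z ~ N(0, 1) | TR 1 s, 300 s (120 s in calibration runs), noise sd 0.003 |

The hemodynamic priors are centred on the canonical physiological values,
as is standard for this model family; the noise sd 0.003 is about a tenth
of the ~0.03 peak fractional BOLD response. Hemo data are generated at 16
integration sub-steps per TR (error ~1e-6 against a dense Runge–Kutta
reference) while the fitted model integrates at 2 sub-steps (error ~7e-5,
i.e. ~2% of the noise sd) to keep 100-replicate studies fast; the induced
bias is negligible relative to posterior spread.

What the fixtures emulate — and what they do not: correctly specified
generative models, i.i.d. or block-structured Gaussian noise, exactly known
inputs. Real neuroimaging data add serial correlation, drift, model
misspecification and uncertain stimulus timing; passing calibration here
shows the scheme is correct under its own assumptions, not that those
assumptions hold for any particular dataset.

## Validation experiments

`varlaplace.validation` (run by `tests/test_acceptance.py` and
`scripts/acceptance.py`):

* **Conjugate equivalence** — 20 random linear-Gaussian instances (p ≤ 4,
  D ≤ 30, λ clamped by a near-delta hyperprior): posterior mean/covariance
  vs closed-form Bayesian linear regression (1e-6) and maximised F vs the
  closed-form log evidence (0.01 nats).
* **Bound property** — 50 random 1-parameter models (linear trend plus
  bounded sinusoidal distortion, λ clamped): the exact variational
  functional of the fitted posterior, evaluated by 40-node Gauss–Hermite
  quadrature, never exceeds the log evidence from adaptive quadrature; the
  Laplace objective stays within 0.1 nats of the exact functional.
* **Model recovery** — 100 heteroskedastic replicates, three candidate
  noise models: the 2-component model must win with posterior probability
  > 0.95 in ≥ 90 replicates, and all accepted free-energy traces must be
  monotone.
* **Calibration** — 100 replicates per fixture: every generating value must
  fall in its central 90% credible interval at least 80 times (the slack
  below the nominal 90 absorbs the hyperparameter overconfidence noted
  above).

Problem sizes (100 replicates, 120 s hemodynamic runs at 2 sub-steps) were
chosen so the full set runs in minutes on one core while keeping the
binomial assertions meaningful.

## Known limitations

Single-start ascent from the prior means (multimodal posteriors may trap
it); Gaussian posteriors only; diagonal Q(λ) covariance; no stochastic
dynamics; finite-difference derivatives limit g to ~1e-6 gradient accuracy;
the Laplace objective is an approximation to — not a guaranteed bound on —
the log evidence for nonlinear models, as quantified by the bound
experiment.
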