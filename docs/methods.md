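# Methods

`cwresqa` quantifies *structural* misspecification of a nonlinear
mixed-effects (NLME) model as bias in its conditional weighted residuals
(CWRES), and back-translates that bias into the scale of the model's
conditional predictions. This note documents the model, the numerical
choices, the bundled synthetic scenarios and what the test suite does and
does not demonstrate.

## The FOCE engine

An NLME model for subject *i* with observations `y_i` is

    y_i = h(f(θ, η_i), ε_i),    η_i ~ N(0, Ω),   ε_i ~ N(0, Σ),

with `f` the structural prediction, `h` an additive, proportional or
combined residual-error model per dependent variable (DV), and Σ diagonal.
Writing `η̂_i` for the empirical Bayes estimates (EBEs, the mode of the
individual penalised objective) and `F_i = ∂f/∂η` at `η̂_i`, the
first-order conditional estimation (FOCE) moments are

    E(Y_i)   = f(θ, η̂_i) − F_i η̂_i
    COV(Y_i) = F_i Ω F_iᵀ + diag(H_i Σ H_iᵀ),
    CWRES_i  = COV(Y_i)^(−1/2) (y_i − E(Y_i)),

where `H_i = ∂h/∂ε` at ε = 0. With *interaction* (FOCE-I, the default)
`H_i` is evaluated at the individual prediction `f(θ, η̂_i)`; without it, at
the population prediction `f(θ, 0)`. Both are supported because published
CWRES definitions leave this open; FOCE-I matches the prevailing practice.

Numerical choices:

* **Derivatives** — central finite differences with relative step
  `1e-4 · (1 + |η|)` on η; residual-error derivatives are analytic for the
  supported error families.
* **EBEs** — quasi-Newton (L-BFGS-B) from η = 0 plus one random restart
  drawn from N(0, Ω), best objective wins. Subjects sharing a design are
  solved jointly in one vectorised run (the objective is separable, and a
  batched finite-difference gradient prices the whole batch at the cost of
  one subject). Subjects whose final gradient is large are flagged and
  excluded downstream with a warning.
* **Matrix square root** — the symmetric (eigendecomposition) root is used
  for both the whitening `COV^(−1/2)` and the colouring `COV^(+1/2)` of the
  bias correction, so the two are exact inverses; Cholesky is available as
  an option, again used consistently for both directions.
* **Jitter** — if the smallest eigenvalue of a conditional covariance is
  below `1e-12` of the largest, `1e-10 · mean(diag)` is added to the
  diagonal before factorisation.
* **OFV** — the FOCE objective is `Σ_i [log|COV(Y_i)| + rᵀ COV(Y_i)^(−1) r]`
  with `r = y_i − E(Y_i)`; the `n·log 2π` constant is dropped (the usual
  pharmacometric convention), which leaves all OFV differences unchanged.
  Low-rank Woodbury identities keep each evaluation O(n·k²) per subject.
* **Population fitting** — Nelder–Mead on log-transformed positive
  parameters (θ, diag Ω, error variances), chosen for robustness against
  the small numerical noise of the nested EBE step; EBEs are warm-started
  between objective evaluations, and the inner problem runs without random
  restarts during the search. A fit that fails to improve on its initial
  values reports non-convergence and returns the best point found.

## The CWRES bias model

CWRES for one DV are treated as longitudinal data:

    base:      y_ij = Θ₁ + η_i + ε_ij
    extended:  y_ij = Θ_{bin(IDV_ij)} + η_i + ε_ij

with scalar Ω and Σ. For a correct model CWRES are standard normal, so the
expected estimates are Θ₁ = 0, Ω = 0, Σ = 1. The fit is **exact maximum
likelihood**: the compound-symmetry covariance `Ω·J + Σ·I` is handled in
closed form (Woodbury / matrix-determinant identities on per-subject
sufficient statistics), the means are profiled out by GLS, and only
(Ω, Σ) are optimised, bounded below at `1e-10` with boundary hits reported.
The bias statistic is

    ΔOFV_Bias = OFV_base − OFV_extended ≥ 0,

reported as a positive improvement and compared with the χ²(df) quantile at
α = 0.05. `df` defaults to the number of bins N — the convention used with
the printed cutoffs χ²₀.₀₅(10) for time and χ²₀.₀₅(5) for PRED — although
the extended model adds only N − 1 parameters; `df = N − 1` is available.
Testing at χ²(N) is therefore slightly conservative, which in practice
offsets the mild anti-conservatism that FOCE linearisation error induces in
the null distribution (see *Limitations*).

## Binning

Bins partition the observed IDV range with half-open intervals
`[min, X₁), [X₁, X₂), …, [X_{N−1}, max]`; the last bin is right-closed so
no observation is dropped. Density bins put the N − 1 cutoffs at empirical
quantiles k/N snapped to midpoints between adjacent distinct observed
values (ambiguous ties raise an error advising a smaller N). Defaults:
N = 10 for time, N = 5 for a PRED IDV, minimum M = 25 observations per bin.
Randomized binning draws the cutoffs uniformly over the observed range,
redrawing (cap 10 000) until every bin holds M observations, and repeats
bin-draw → extended fit → correction (500 replicates by default) to trace a
confidence-like envelope of the bias trend free of any fixed bin choice.

## Bias correction

The extended fit's bin means form the bias vector `b`; expanding it to
observation level (`b̀`, constant within each bin) and colouring it with the
conditional covariance inverts the whitening:

    δ_i = −COV(Y_i)^(1/2) · b̀_i .

δ_i estimates how far the misspecified model's conditional predictions sit
above the (unknown) correct-model ones, under the working assumption that
the two models share the conditional covariance and that b̀ captures all of
the structural misfit. Corrected predictions are `E(Y_i) − δ_i`. The
percentage bias `%δ = 100·δ_i / E(Y_i)` uses the fitted model's conditional
prediction as denominator and is suppressed (NaN, with δ retained) where
`|E(Y_i)| < 1e-6` of the dataset-wide mean absolute prediction. Binned δ
and %δ average observations equally by default; subject-equal weighting is
an option. When applied to one DV of a multi-DV model, the covariance and
prediction vectors are restricted to that DV's rows.

For simulated data the reference *known bias* compares conditional
predictions under the generating model (EBEs estimated under the truth at
its simulation parameters, on the analysed dataset) with those of the
fitted model:

    % known bias = 100 · (Y_est − Y_sim) / Y_sim ,

positive where the fitted model overpredicts. This sign convention makes
the reference directly comparable to %δ (also positive for overprediction);
entries with `Y_sim = 0` are undefined and excluded from binned means, with
the exclusion count reported.

## Bundled scenarios (synthetic data)

The generator mimics a standard IVGTT: a 0.33 g/kg glucose bolus (70 kg
body weight by default) with 32 samples from 0 to 240 min. Both bundled PK
models describe a concentration that relaxes back to a basal level — the
physiologically relevant feature of IVGTT glucose, and the reason relative
bias stays well defined at late times:

* **Truth** — two-compartment disposition above basal:
  CL = 0.3 L/min, V1 = 12 L, Q = 0.3 L/min, V2 = 8 L, basal 900 mg/L
  (90 mg/dL), giving a 9-min distribution and a 55-min terminal half-life;
  log-normal inter-individual variability on CL, V1 and basal with
  variances 0.09, 0.04, 0.01 (≈30%, 20%, 10% CV) and 10% proportional
  error — typical magnitudes for this kind of data.
* **Misspecified alternative** — one-compartment above basal, same error
  family. What it cannot describe is the distribution phase sampled
  densely in the first 30 min; the resulting conditional-prediction bias
  peaks near ±10–20%, comparable in size to what the method is meant to
  flag in practice, and is detectable with high power at 50–100 subjects
  (a design target of the scenario, not an estimate of anything).

The glucose minimal sub-model ODE

    Ġ₁ = S_G·G_b − (S_G + X(t) + k₂₁)·G₁ + k₁₂·G₂,   G₁(0) = G_b
    Ġ₂ = k₂₁·G₁ − k₁₂·G₂

is bundled as a simulation demo, with glucose effectiveness S_G = k₁ + k₅
and the insulin action X(t) supplied as a configurable forcing function
(bi-exponential pulse by default, peak 0.01 min⁻¹), since the insulin
sub-model that would generate X(t) endogenously is out of scope. Default
rates (k₁ = 0.005, k₅ = 0.02, k₂₁ = 0.05, k₁₂ = 0.07 min⁻¹) are in the
range reported for minimal-model analyses of IVGTT data.

What the generator does **not** emulate: multiple interacting DVs measured
simultaneously (glucose + insulin), assay limits of quantification,
dropout, covariate effects, and inter-occasion variability. Passing tests
therefore demonstrate the mechanics and calibration of the diagnostic under
clean conditions, not its behaviour under every real-data complication.

## Problem sizes used in the checks

The reference calibration run uses 100 subjects × 32 observations. The
null calibration of the bias test uses 200 replicates of 30 subjects, each
re-fitted by FOCE before CWRES are computed — re-estimation is part of the
null pipeline, since evaluating at the known true parameters leaves
linearisation error uncorrected and visibly inflates the test. The
misspecification pattern is checked once at 100 subjects, and the
companion correct-model replicates (50 of them) run at 50 subjects with
fits initialised at the generating values. The randomized-binning study
runs its full 500 replicates on the 100-subject reference run.

## Limitations

* FOCE-I CWRES are only asymptotically N(0, 1); with ≈30% CV log-normal
  variability and proportional error, small systematic per-time trends
  (|mean| up to ≈0.05 after re-fitting) remain. The χ²(N) convention
  absorbs most of this; the null rejection rate sits near, but slightly
  above, the nominal 5%.
* The correction assumes `COV(Y⁻) = COV(Y*)` and a bias expressible as a
  bin-wise constant CWRES shift. Under gross misspecification (bias far
  beyond the ~20% range) the linear back-transform degrades visibly.
* Only diagonal Σ and a single subject-level random effect in the bias
  model are supported; stochastic-model misspecification (CWRES variance
  modelling) is out of scope.
* Estimation is FOCE only (no Laplace/SAEM), and the bias derivation is
  specific to CWRES — other residual types would need their own
  back-transform.
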