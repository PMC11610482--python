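# Methods

## Model

A complete observation factorizes as

```
Pr(V, Y*, X*, Y, X, Z) =
    Pr(V | Y*, X*, Z) · Pr(Y* | X*, Y, X, Z) · Pr(X* | Y, X, Z)
    · Pr(Y | X, Z) · Pr(X | Z) · Pr(Z).
```

`V` is the validation indicator; because validation is decided from Phase I
variables only, the unvalidated `(Y, X)` are missing at random and
`Pr(V | ·)` drops out of the likelihood.  The four unknown components are
logistic regressions whose term lists are configurable (`ModelSpec`): the
analysis model always contains an intercept and `X`; the error models may
be differential (conditioning on `X*`, `X`, `Z`, interactions) or reduced
to classical single-error settings by declaring one surrogate error free
(`Y* ≡ Y` or `X* ≡ X`), which removes that error model from `θ` entirely.
`Z` is a single categorical stratification variable (users cross multiple
covariates beforehand); `Pr(Z)` is always the empirical Phase I
distribution — it carries no parameters and enters only the design
expectation.  All binary terms use {0, 1} coding.

Everything is computed on the complete-data cell grid (at most `16·n_z`
cells): the observed-data log-likelihood, per-record scores, posterior
weights, and the information matrix are exact finite sums, so cohort size
affects only the one-off tabulation.

## Error-rate parametrization

A surrogate's logistic intercept and true-variable slope are derived from
baseline false/true positive rates: `c0 = logit(FPR)`,
`c1 = logit(TPR) − logit(FPR)`, evaluated at reference levels (0) of all
other conditioning variables.  `derive_error_params` applies to the
exposure pair (γ₀, γ on X) and the outcome pair (α₀, α on Y) alike.

## Fitting

`fit_mle` maximizes the observed-data log-likelihood by EM: the E-step
spreads each unvalidated stratum count over the latent `(y, x)` cells with
posterior weights; the M-step solves four independent weighted logistic
regressions (ascent-guarded Newton with a 1e-8 ridge fallback, so empty
validated cells degrade to flagged separation rather than a crash).  EM's
linear convergence is slow here (the unvalidated fraction is large), so
after short EM stretches the fitter switches to ascent-guarded Newton steps
on the observed-data log-likelihood itself (analytic gradient, batched
central-difference Hessian, step halving, ridge on indefinite steps),
falling back to EM whenever a Newton step cannot ascend.  The likelihood
trace is non-decreasing in both phases; a pure-EM mode (`method="em"`)
exists for verification.  Convergence is declared at `|Δℓ| < 1e-8` with a
small gradient; the default initial value is deterministic — naive logistic
fits that treat `(Y*, X*)` as true, plus neutral error-model coefficients at
baseline rates 0.25/0.75 (mildly informative, breaking the label-switching
symmetry).

Standard errors come from the observed information: the central-difference
Hessian of the log-likelihood at `θ̂` (step `1e-5·(|θ|+1)` per coordinate),
inverted; a non-invertible Hessian flags the fit `singular`.

A fit is *unstable* when an analysis-model coefficient exceeds 12 in
absolute value (logistic saturation; empty validated cells can separate the
target).  A separated *error-model* coefficient with a finite target is
tolerated: multiwave planning proceeds with any converged interim fit, and
a genuinely degenerate interim `θ̂` surfaces as a singular-information
search failure.  The simulation harness counts unusable fits and failed
searches per design and excludes them from summaries, reporting the tally.

## Design criterion

With sampling probabilities `π_s = n_s/N_s` per stratum
`s = (y*, x*, z)`, the per-subject expected information is affine in `π`:

```
I(θ; π) = Σ_s [ π_s · E{S_v S_v' ; s} + (1 − π_s) · S_v̄(s) S_v̄(s)' · Pr(s) ],
```

where `S_v` is the validated score, and the unvalidated score `S_v̄(s)` is
the mass-weighted average of `S_v` over the latent cells of stratum `s`
(the only reading under which the unvalidated term is an expectation of
score outer products; verified against a Monte-Carlo oracle).  The
criterion is `Var(β̂) = N⁻¹ [I⁻¹]_{ββ}`, computed by batched linear solves
over whole candidate grids; the Schur-complement form is kept as an
independent cross-check route.  Singular candidates get a `+inf` sentinel
and simply never win.

## Adaptive grid search (optMLE)

Candidate allocations live on a lattice: each free stratum ranges from
`max(min(m, N_s), floor_s)` to `min(n − Σ other minima, N_s)` in steps of
`s(t)` (first iteration), or over the `s(t−1)`-neighbourhood of the current
best design (later iterations); the last nonempty stratum in key order
absorbs the remainder so every candidate sums to `n` exactly, and a clipped
upper bound (e.g., a full stratum) is kept reachable even off-lattice.
Defaults: steps (15, 5, 1) for direct searches and (25, 5, 1) for
multiwave second waves, `m = 10`, maximum grid 25,000 candidates.  When a
grid would exceed the cap the step is doubled for that iteration (and, at
the one-person scale, the neighbourhood halved), after which the schedule
resumes — necessary for eight-stratum problems, where the first-iteration
lattice is astronomically large at any sane step.  One-person iterations
repeat around each new centre until no improvement remains, so the returned
design is locally optimal at the one-person scale; on every instance small
enough to enumerate it matches the exhaustive minimizer in our tests.  Ties
break toward the first candidate in lexicographic stratum-key order.
Optional early stopping (relative improvement below a threshold) is off by
default.  The per-stratum minimum `m` guards against degenerate designs
with empty validated strata.

## Multiwave designs

`optMLE-2` validates `n/2` by BCC* (wave a), fits `θ̂(a)` on Phases I+II(a),
then grid-searches the *cumulative* `n`-subject design with the wave-a
counts as per-stratum floors and draws the increment; the final MLE pools
all waves.  `optMLE-3` splits the adaptive budget over two waves
(`n/2, n/4, n/4`), re-estimating `θ` each time.  Optimizing the cumulative
design (not the increment in isolation) is deliberate: the final
estimator's variance depends on the total sampling probabilities.  A
supplied historical `θ` may replace the balanced first wave
(`WavePlan(wave1="optmle", theta0=...)`).

## Design-stage model specification

The gold-standard optMLE uses the true `θ` under the *minimal* true model:
an interaction whose generating coefficient is zero is not part of the true
distribution, so the design stage drops it (`true_design_spec`).  Carrying
such a term as a free parameter would add nuisance information the true
model does not contain and (verifiably) shift the optimum slightly.  The
misspecification variants optMLE*/optMLE-2* force main-effects-only error
models at the design stage regardless of the truth; with no true
interaction they coincide with the gold standard exactly, and with shared
draw streams the coincidence is replicate-by-replicate.  The analysis stage
always fits the full (interaction-bearing) specification.

## Synthetic cohorts

The generator draws `Z ~ Bern(p_z)` (optional), `X | Z`, `Y | X, Z`, then
`X* | Y, X, Z` and `Y* | X*, Y, X, Z` from the scenario's θ — the same
object the likelihood and criterion use, so generator fidelity is testable
cell by cell.  Scenario defaults are the base study conditions: `N` =
10,000, `n` = 400, `Pr(X=1)` = 0.1, `Pr(Y=1|X=0)` = 0.3, `β` = 0.3, all
baseline error rates FPR 0.1 / TPR 0.9, differential cross-terms 0.45 (Y in
the X* model) and 0.275 (X* and X in the Y* model); the covariate block
(for robustness studies) uses `Pr(Z=1)` = 0.25, analysis/exposure-model Z
coefficients 0.25 and 0.5, error-model Z coefficients 1.0, and X·Z
interactions δ₁, δ₂.  What the generator does *not* emulate about real
audit data: correlated records, covariate measurement error, audit
nonresponse (validation missing not-at-random), continuous mismeasured
variables, and more than one surrogate per true variable — conclusions from
passing tests are limited accordingly.

## Replicate harness and metrics

All designs of a replicate share one generated cohort (a paired comparison
that sharpens efficiency ratios; per-design subject draws use named
substreams from one master seed, shared between a design and its
misspecified variant so identical allocations validate identical
subjects).  Metrics per design over its usable replicates: percent bias
`100·(mean β̂ − β)/β`; empirical SE; `RE = Var_ref/Var_design` and
`RI = IQR_ref/IQR_design` with the true-θ optMLE as reference and quartiles
by linear interpolation (stated in the summary metadata).  The reference's
own RE and RI are 1 by construction.

## Problem sizes and numerical defaults

The acceptance script runs the base-setting study at 600 replicates, the
null-interaction identity at 40, and the SRS bias sweep at 1200 replicates
per setting (the bias of a ratio-scaled mean is the noisiest quantity here,
and a maximum over settings is upward-biased at small replication); the
test suite uses 150/8/150 for the same checks with ±3
Monte-Carlo-standard-error bands computed from those replication levels.
Empirical-variance ratios at R replicates carry a log-scale standard error
of roughly `sqrt(4/R)`, which is what the bands encode.  Key tolerances:
EM/Newton convergence 1e-8 on the log-likelihood; M-step ridge 1e-8;
information PSD tolerance −1e-8 on eigenvalues; criterion cross-checks at
1e-10 relative.

## Known limitations

- The optimality target is the single log OR `β`; D-/A-optimal designs for
  several parameters at once are out of scope.
- Continuous covariates must be discretized before they can define
  sampling strata (the analysis model may still use them numerically).
- The grid search guarantees local optimality at the one-person scale, not
  global optimality, on problems too large to enumerate.
- Heavily separated fits are flagged, not repaired; designs that produce
  empty validated cells (SRS with rare outcomes) are expected to lose
  replicates, and the harness reports exactly how many.
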