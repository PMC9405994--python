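# Methods

`neurodim` implements a head-to-head comparison of two model families for
predicting dimensional psychopathology from neurocognitive and demographic
measures: multivariate multiple regression (the linear reading of the
neurocognition–psychopathology link) and a small feedforward neural network
(the nonlinear, "multidimensional" reading, in which interactions and
compensatory profiles among cognitive abilities carry information that no
main-effects model can see). Because the motivating study's raw data are
not public, the package ships a synthetic-cohort generator whose ground
truth is switchable between linear and nonlinear regimes, so the whole
pipeline — measurement models, both predictors, and the statistical
comparison — is testable end to end.

## Synthetic cohorts

Each case carries age (years), gender (0 = male, 1 = female), eight
neurocognitive task scores and nine symptom/substance domain scores
(six symptom-inventory domains: depression, agoraphobia, hostility, mental
fog, interpersonal anxiety, somatisation; three substance-involvement
domains: alcohol, cannabis, other substances). Defaults reproduce the
reference sample: n = 400, age ~ N(44.47, 16.35²) clipped to [18, 90],
51.5% female. Task scores are i.i.d. standard normal z-scores; real task
batteries are intercorrelated and non-Gaussian, which this generator does
not emulate (see Limitations).

Two latent factors, internalising **i** and externalising **e**, generate
the domains through a fixed loading pattern:

    y_d = λ_d f(d) + sqrt(1 − λ_d²) u_d,   u_d ~ N(0, 1)

with λ in 0.55–0.75 (typical symptom-inventory CFA magnitudes): the five
mood/anxiety-type domains load internalising, hostility and the three
substance domains load externalising. Domains are therefore unit-variance
and continuous; ordinal item-level response scales are intentionally not
simulated because the downstream analysis consumes domain aggregates.

Each factor is a standardised sum of three components:

    f = (demographic effect + task signal + ε) / sd,
    ε bivariate normal, sd = noise_sd, corr = factor_corr (default 0.6)

* demographic effect (all modes but `null`): standardized age slopes
  −0.35 (internalising) and −0.30 (externalising), gender slopes +0.15 /
  −0.15 — magnitudes chosen so a linear model recovers R² ≈ 0.1–0.2 at the
  domain level, the range reported for community samples;
* task signal, variance `effect_size²` (default 0.35), per `effect_mode`:
  * `linear` — additive in four (negated) task z-scores per factor;
  * `interactive` — pairwise products of task z-scores
    (simple-RT × inspection-time and digit-span × Stroop drive
    internalising; go/no-go × shape-number and visual-WM × inferring-
    relevance drive externalising). Products of independent z-scores are
    uncorrelated with every individual task, so the signal is invisible to
    main-effects regression by construction;
  * `compensatory` — the standardised worst deficit over a task pair,
    `max(−z_a, −z_b)`: burden tracks the weaker of two abilities, so a
    preserved ability caps the benefit of the other;
  * `null` — no task or demographic effect; factors are pure correlated
    noise. Only in this mode is the population domain covariance exactly
    Λ Φ Λᵀ + Ψ with Φ off-diagonal `factor_corr`; in signal-bearing modes
    the realised factor correlation also picks up the shared demographic
    drivers, and the implied value is recorded in the cohort metadata.

The "strong nonlinearity" regime used in the discrimination tests is
`effect_size = 1.0, noise_sd = 0.5` (interactive signal four times the
default variance, residual noise halved); it was fixed before any
acceptance measurement and doubles as the acceptance-script scenario.

## Measurement models and factor scores

Two confirmatory factor models are fitted to the 9×9 sample covariance S by
minimising the normal-theory ML discrepancy

    F_ML(θ) = log|Σ(θ)| + tr(S Σ(θ)⁻¹) − log|S| − 9,
    Σ(θ) = Λ Φ Λᵀ + Ψ

with unit factor variances for identification (Φ is then a correlation
matrix): a correlated two-factor model (internalising/externalising, free
correlation, df = 26) and a single-factor model (the p-factor, df = 27).
χ² = (n−1)·F_ML. Estimation is L-BFGS-B with analytic gradients, starting
values λ = 0.7·sd, ψ = 0.51·var, φ = 0.3, and three jittered restarts; a
stalled optimiser returns `converged=False` rather than raising.

Unique variances are deliberately **unconstrained in sign**. A negative ψ
(Heywood case) is a diagnostic outcome this pipeline must be able to
observe — inadmissible measurement models are excluded on exactly this
evidence — so it is reported through per-indicator flags and never clamped
or hidden by a log-parameterisation. When S itself is not positive
definite, F_ML is undefined (log|S| does not exist); the fit then minimises
the unweighted least-squares discrepancy ½‖Σ(θ)−S‖²_F, which has the same
exact-fit solution for just-identified models (this is how the classic
three-indicator Heywood example is handled), and records `estimator="uls"`.

Factor scores use the regression method,
f̂ = Φ Λᵀ Σ(θ)⁻¹ (x − x̄), centred on the scoring sample (a case at the
sample mean scores exactly zero). Score extraction refuses
Heywood-contaminated fits. Internalising/externalising scores come from
the correlated model, the p-factor score from the single-factor model.

## Linear models

For each outcome block (9 domains; 3 factor scores) an ordinary
least-squares regression on the 10 shared predictors (8 tasks + age +
gender) is computed from the normal equations — with a common design
matrix, multivariate multiple regression coefficients coincide with
per-equation OLS. Reported per outcome: raw B, standardized
β = B·sd(x)/sd(y), R², the overall F = (R²/k)/((1−R²)/(n−k−1)) with
df (10, n−11) and upper-tail p, and two-tailed per-predictor t tests.
Predictions are in-sample (no holdout appears in the protocol being
replicated), so in-sample corr(ŷ, y) = √R² exactly — the identity that
ties the regression diagnostics to the comparison tables. An R² of 1 is
reported as an infinite F with p = 0.

## The neural network

A 3-layer feedforward network: 10 inputs, one hidden layer (default 10
units), 9 or 3 sigmoid outputs, bias units in both layers. Weights are
initialised i.i.d. uniform on ±0.5. Training is online (per-pattern)
stochastic gradient descent on squared error E = ½Σ(t−o)², no momentum or
weight decay, learning rate 0.03, 1000 epochs. Each epoch trains on 100 of
the n cases drawn with replacement and visited in random order; the trace
records summed squared error (SSE) on the full evaluation set after every
epoch, and RMSE = sqrt(SSE/n_cases) — the convention consistent with the
reference results (sqrt(34.76/400) ≈ 0.29, sqrt(14.02/400) ≈ 0.19;
computing either quantity on the 100 training cases would contradict the
printed pairs).

Two protocol points were open to interpretation and were settled by which
reading reproduces the reported training behaviour; both alternatives
remain available as configuration:

* **Input scaling.** Targets must be min-max scaled to [0, 1] (sigmoid
  outputs cannot leave that interval; scaling is fitted on the full case
  set and inverted for reporting). Inputs, however, are z-scored, not
  min-maxed: squashing 10 inputs into [0, 1] shrinks first-layer gradients
  roughly sevenfold and leaves the network visibly undertrained at
  lr = 0.03 / 1000 epochs (evaluation SSE stuck near its starting value),
  incompatible with the rapid early error drop the protocol is known to
  produce. Downstream comparisons are correlation-based and invariant to
  either affine choice.
* **Training-set reading.** "Trained randomly, with replacement, on 100 of
  the 400 cases" is read as a fresh with-replacement sample of 100 each
  epoch (`resample_each_epoch=True`, the default). Under the alternative —
  one multiset drawn once, ~63 unique cases ever seen — the network
  carries a fixed generalisation handicap of ≈0.09 in average correlation
  against an in-sample-fitted linear model and loses even when the ground
  truth is strongly interactive, again contradicting the phenomenon the
  protocol demonstrably produced.

Gradient correctness is established against central finite differences
(property-tested over random architectures); a NaN in the weights aborts
training with the offending epoch. The sensitivity sweep retrains over a
learning-rate × hidden-size grid with the training-sample stream shared
across cells (only weight initialisation varies), captures per-cell
failures without aborting the grid, and emits a tidy long-format table.

## Model comparison

Per outcome, Pearson r between predictions and observed values, with a
one-tailed p (r > 0) from t = r√((n−2)/(1−r²)). The nine lower-level
correlations are averaged on the raw r scale — not Fisher-z averaged —
because raw averaging is what reproduces the reference summary values
exactly. Four contrasts form the test family: the lower-level average and
the three higher-level factors, each tested with the two-independent-
samples Fisher statistic

    Z = (atanh r₁ − atanh r₂) / sqrt(1/(n₁−3) + 1/(n₂−3))

two-tailed, at a Bonferroni-adjusted α = 0.05/4 = 0.0125. The two
correlations in each contrast are computed on the *same* cases, so the
independent-samples test is approximate (generally conservative here,
since the positive dependence between the two correlations shrinks the
true variance of their difference); the choice replicates the protocol
under study and is validated against a label-swap permutation oracle for
decision agreement. A dependent-correlations variant is a known extension
and deliberately out of scope.

## Pipeline and reproducibility

`run_pipeline` chains cohort → CFA + factor scores → linear and network
fits at both outcome levels → comparison, writing every stage's output and
a manifest (config echo, package versions, per-file SHA-256) under one run
directory. The global seed is spawned into independent per-stage seeds;
no timestamps or host state enter any artefact, so a rerun with the same
config is bit-identical, and the manifest's config echo alone suffices to
reproduce a run. Factor scores are estimated on the same cohort used for
prediction, matching the in-sample design being replicated. A stage
failure raises a stage-named error (distinct CLI exit codes) and leaves
completed outputs on disk.

## What the green tests do and do not establish

The synthetic world demonstrates *pipeline discrimination*: under
interactive truth the network's predicted-vs-actual correlations reliably
exceed the linear model's (sign test over 20 seeds); under linear truth
the two families are statistically on par (mean difference within ±0.05);
under null truth fewer than 10% of seeds flag any contrast at α = 0.0125.
This validates the machinery, not the substantive claim: Gaussian,
independent task scores with clean two-way products are far kinder to both
model families than real neurocognitive data (skewed scores, correlated
tasks, measurement error, unknown interaction structure). The in-sample
evaluation also inflates both families' correlations — the network, which
eventually samples every case during training, slightly more than the
regression under null truth — which is a fidelity choice, not a
recommendation; out-of-sample validation would be the methodologically
stronger design and is listed as a limitation of the replicated protocol.

## Known limitations

* No robust (sandwich/scaled) test statistics for the CFA; loadings and
  scores are unaffected, standard errors would be.
* No fit indices (CFI/TLI/RMSEA), modification indices, ordinal
  estimators, or bifactor estimation (Heywood *detection* is in scope,
  bifactor fitting is not).
* Printed-source arithmetic is taken as given where internally consistent;
  two reference table entries are mutually inconsistent (an R²/F pair that
  implies a different F, and an R² that contradicts its own text
  percentage) — both numbers are surfaced by the relevant functions and
  neither is asserted anywhere.
* The Fisher comparison ignores the dependence of the paired correlations
  (see above); single-correlation p-values assume bivariate normality.
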