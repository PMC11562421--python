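# Methods

`panelnet` implements two complementary network analyses for few-wave panel
data on continuous symptom scales, plus the scaffolding needed to exercise
them end to end: a synthetic cohort generator, centrality and stability
measures, and hierarchical regressions linking wave-1 executive-functioning
(EF) covariates to later broadband symptom levels.

## Data model and preprocessing

A `PanelDataset` is a persons × waves × variables array of continuous scale
scores with `NaN` for missing cells; every variable carries a community
label (internalizing / externalizing / attention / other). Scale scores are
item means computed when at least a configurable fraction of items is
observed (`min_coverage`, default 0.75 — the conventional ASEBA-style
tolerance; the source instruments do not pin a value, so it is surfaced in
the API).

`detrend_and_standardize` removes, per variable, one pooled regression of
score on wave time and its square over all person-wave observations, and
scales residuals to pooled unit variance (divisor *n*). Pooled — not
per-person — detrending is used because the transformation prepares data for
a model that itself separates within- from between-person variance;
per-wave z-scoring is available behind a flag but changes the estimand and
is off by default. With three waves the quadratic trend basis spans the
wave means, so detrending is equivalent to removing per-wave means; the
transform is idempotent to numerical precision. Wave time codes default to
the wave index (1, 2, 3): the lag unit of every temporal model here is the
assessment wave, not calendar time; mean ages can be substituted.

Missing data are handled two ways, mirroring the estimators: cross-lagged
networks use complete cases per wave pair (each node regression needs full
predictor/outcome rows), while the panel GVAR and the regressions use
full-information maximum likelihood (FIML): persons are grouped by
missingness pattern and each group contributes the Gaussian marginal over
its observed cells. All FIML code paths evaluate likelihoods from per-pattern
sufficient statistics (count, mean, scatter), so cost is independent of the
number of persons.

## Cross-lagged panel networks (CLPN)

For consecutive waves (s, t), each of the p nodes at wave t is regressed on
all p nodes at wave s with an L1 penalty:

    minimize (1/2n) ||y − b0 − X b||² + λ ||b||₁

Predictors and outcomes are z-scored on the complete-case sample so edges
are comparable in magnitude; the diagonal holds autoregressive effects.
λ is chosen per outcome node by 10-fold cross-validation on a 100-point
log-spaced grid from λ_max (empty model) down to 10⁻³ λ_max. The default
selection rule is minimum mean out-of-fold MSE with ties toward the sparser
model; the 1-SE rule is available (`rule="1se"`). One seeded fold partition
is shared across outcome nodes, which keeps the estimator exactly
equivariant to node relabeling.

A caveat documented deliberately: CV-min is not selection-consistent. On
null data λ_max equals the largest realized spurious correlation, so the CV
curve genuinely dips below the empty model and the selected network retains
roughly one small spurious edge per outcome (measured exact-zero fraction of
off-diagonals ≈ 0.90 under a fully null generator). The 1-SE rule removes
these at the price of heavy shrinkage of real edges (a true standardized
edge of 0.37 shrinks to ≈ 0.15–0.22). Neither rule dominates; the default
follows the prediction-oriented convention, and both are tested.

CLPN edges conflate within- and between-person variance by construction —
they answer "does node j at wave s predict node k at wave t across
persons", not "does a within-person change in j precede a change in k".

## Cross-sectional networks (EBIC glasso)

Per wave, a Gaussian graphical model is estimated from the Pearson
correlation matrix of complete cases (Spearman by flag). The graphical
lasso is solved along a 100-point log-spaced path from λ_max = max |r_ij|
down to 0.01 λ_max; each *distinct support* appearing on the path is then
refitted by constrained maximum likelihood (convex optimization over the
free precision entries) and scored by the extended BIC

    EBIC(K) = −n (log det K − tr(SK)) + E log n + 4 E γ log p

with γ = 0.5 and E the edge count; the lowest-EBIC support wins, ties
toward sparsity. Scoring refits rather than penalized estimates is a
deliberate choice: near the dense end of the path the shrinkage loss of the
penalized fit can exceed the per-edge EBIC penalty, so penalized scoring
systematically favors denser graphs than a direct model comparison does.
The reported network is the ML refit of the selected support, so edge
magnitudes are unshrunk partial correlations
`−K_ij / √(K_ii K_jj)`.

Numerical choices: the glasso dual-gap tolerance is 10⁻⁵ (the solver's
achievable precision at these problem sizes); precision entries below 10⁻⁸
count as absent edges.

## Panel graphical VAR

The panel GVAR decomposes the stacked-wave covariance of the detrended,
standardized panel into three networks:

* **between-person**: precision `K_B` of the random intercepts
  (`Σ_B = K_B⁻¹`) — how stable trait levels covary across persons;
* **temporal**: `B`, with `B[k, j]` the lag-1 effect of node j on node k
  (within-person Granger prediction);
* **contemporaneous**: innovation precision `K_ζ` — within-window partial
  correlations after removing temporal carry-over.

With `Σ_W` the stationary solution of the discrete Lyapunov equation
`Σ_W = B Σ_W Bᵀ + K_ζ⁻¹`, the implied covariance between waves t and t+d is
`Σ_B + B^d Σ_W` — the random-intercept cross-lagged panel structure. Means
are free per (wave, variable) cell; after detrending they are ≈ 0 but
freeing them keeps the χ² comparison conventional.

Estimation maximizes the pattern-wise FIML log-likelihood with L-BFGS over
the direct parameter vector (means, free `B` entries, diagonals plus free
off-diagonals of both precisions). The gradient is analytic: the
per-pattern Gaussian derivatives dL/d(μ, Σ) are chained through the
implied-moment map, with the Σ_W sensitivity handled by one adjoint
Lyapunov solve — this is what makes the p = 10 cohort fit take about a
second instead of minutes. Positive definiteness is maintained by a penalty
guard with a push-back gradient (minimum-eigenvalue direction); stationarity
by spectral rescaling of B at radius 0.97. Starts are moment-informed
(EM-saturated moments split into between/within blocks) plus seeded
perturbations (3 by default); convergence at projected-gradient norm 10⁻⁵.

**Model search.** After the saturated fit, every network parameter (all of
B, off-diagonals of both precisions) with an observed-information Wald
p ≥ α (= .05) is fixed to zero and the model refitted; a step-up phase then
repeatedly frees the fixed parameter with the largest score test
(modification index, `g_j² (I⁻¹)_jj`) while it is significant, refitting
after each addition. Because the step-up takes a maximum over all fixed
candidates, the default threshold is Bonferroni-corrected (α / #candidates);
with a raw-α threshold the search re-adds on the order of 1–2 spurious
parameters per fit, defeating the prune's purpose
(`stepup_correction="none"` restores the raw behavior). An oscillation
guard terminates if a parameter is removed and re-added twice; every
decision is recorded in a trace.

**Fit indices.** χ² = 2(logL_sat − logL_model) against the saturated
Gaussian model (free mean, unstructured covariance; fitted by EM under the
same missingness), with the independence model (free means and variances,
zero covariances — closed form per cell) as baseline.
RMSEA = √(max(0, (χ²−df)/(df·n))), CFI and TLI in their standard forms,
capped at [0, 1] and ≤ 1 respectively. Standard errors come from the
observed information (Hessian of the FIML objective, computed as the
finite-difference Jacobian of the analytic gradient); sandwich errors are
out of scope.

## Centrality and stability

In-/out-strength sum absolute edge weights (self-loops excluded by default);
bridge strength sums a node's absolute edges into other communities. The
absolute-value convention prevents positive and negative edges from
cancelling (a signed variant exists). The case-dropping bootstrap
re-estimates the network on person subsamples of size ⌈(1−q)·n⌉ for each
drop proportion q (default 0.05–0.75 in steps of 0.05) and records the
correlation between the subsample and full-sample centrality vectors; the
CS coefficient is the largest q at which ≥ 95% of bootstraps correlate
≥ 0.7 (identical zero-variance vectors count as correlation 1). Estimator
failures on subsamples are skipped and counted; above 20% failures at any q
the analysis aborts.

## EF scores and hierarchical regressions

The eight EF measures follow the task conventions: fluctuation in tempo is
the sample SD (n−1) of 50 per-series mean reaction times in a sustained-
attention task, with the overall error percentage as its accuracy
counterpart; response inhibition is part 2 − part 1 and cognitive
flexibility part 3 − part 1 of a set-shifting task (RT and % errors);
working-memory maintenance is part 3 − part 1 of a memory-search task.
Higher always means worse. Outliers are removed per measure across persons
in a single pass at |z| ≥ 4 (sample mean/SD, n−1); the rule is not
iterated.

Regressions are fitted as a joint Gaussian over (outcome, predictors) by
EM-FIML; slopes, R² and the intercept derive from the implied covariance
and equal least squares on complete data. Reported standard errors use the
asymptotic formula `s²_res Σ_xx⁻¹ / n` on the FIML moments — they reduce to
(MLE-scaled) OLS standard errors on complete data and ignore the extra
uncertainty of the missing-data correction, a display-level simplification.
Standardized betas are emitted alongside raw ones; sex (0/1, 1 = female)
stays raw. Step 1 regresses a wave-w broadband aggregate (community mean of
its symptom scales) on sex and both previous-wave aggregates; step 2 adds
all eight EF measures in the published predictor order; Δ R² compares them.

## Synthetic cohort generator

The generator draws from exactly the process the panel GVAR assumes:
`y_it = μ_v + b₁_v t + b₂_v t² + s_v (b_i + w_it)` with
`b_i ~ N(0, Σ_B)` and the within-process started from its stationary
distribution. Defaults emulate the study design the package targets: three
waves, N = 2,170, ten symptom scales in two communities (7 internalizing,
3 externalizing), monotone attrition to 96% and 76% participation, and sex
Bernoulli(0.5092, female).

The `trails_like` template sets per-variable means, quadratic trends
(interpolated exactly through the three published wave means) and
observation scales from the published descriptives; positive
within-community contemporaneous partials (0.14 internalizing / 0.20
externalizing), a depressive-problems bridge partial to the externalizing
side and one negative social-phobia–conduct partial; a temporal hub
(depressive problems → other internalizing nodes at 0.15 on an AR 0.22
diagonal) and two reciprocal pairs (panic–somatic, ADHD–oppositional); and
community-structured trait covariance with intraclass correlation ≈ 0.4.
Edge magnitudes are calibration choices — the source analyses print no
numeric edge weights — chosen once to be of realistic size and held fixed.

The `random_sparse` template draws seeded sparse stable systems for
recovery experiments. Its between-person network is denser and stronger
(partials 0.25–0.4, trait share 0.7 of unit within-variance) than its
within-person networks: trait covariance in symptom panels is genuinely
strong, and the between block is the least-informed part of the model (one
trait vector per person versus T time points), so recoverable experiments
need the signal there.

Attrition is wave-level and monotone. Under `MAR_baseline` the per-wave
dropout hazard is logistic in the standardized baseline mean symptom score
(slope 0.3 by default, emulating the reported association of attrition with
baseline psychopathology); the intercept is solved numerically so realized
participation matches the target fractions in expectation. `mar_strength=0`
reduces exactly to MCAR.

EF measures are `β · propensity + √(1−β²) · noise` with the propensity the
standardized mean random intercept and unit variance by construction.
Default βs place .07 on fluctuation in tempo — the measure the source
analyses flag — .05 on response-inhibition RT, and ≤ .03 elsewhere,
emulating the "all βs < .07" regime. Regressing a measure on the stored
propensity recovers its β (the generator-level consistency check); in the
hierarchical regression the step-2 coefficient is substantially smaller
than β because previous-wave symptoms proxy the same trait — which is also
the qualitative finding the regime emulates (no meaningful incremental
variance).

What the generator does *not* emulate: bounded ordinal item scales (a
[0, 2] clipping flag exists for robustness studies but the default is
Gaussian — the estimators assume multivariate normality, and that
assumption is a recognized limitation of the approach, not of the
generator); measurement error in scale scores; item-level missingness;
time-varying network structure. Passing recovery tests therefore show the
estimators work when their assumptions hold, not that real questionnaire
data satisfy them.

## Problem sizes used in tests and the acceptance script

Recovery and calibration experiments run at p = 4, T = 3, n = 2,000 (10–20
replicates); CLPN null/signal checks at p = 4, n = 1,000; EBIC-glasso
oracle comparisons at p = 3, n = 1,000 (20 replicates); the end-to-end
pipeline at the full default cohort (p = 10, N = 2,170). These sizes were
chosen to put each estimator in its intended regime while keeping the whole
suite re-runnable in minutes.

## Known limitations

* Lag-1 linear dynamics and stationarity are assumed; processes on other
  time scales are aliased into the estimated matrices.
* The CLPN cannot separate within- from between-person effects; only the
  panel GVAR's temporal network supports within-person interpretation.
* FIML assumes missing-at-random given the modeled variables.
* Observed-information SEs and the score-based step-up are asymptotic;
  at T = 3 the between/temporal separation is weakly identified, and
  finite-sample Wald rejection of null temporal entries runs slightly above
  nominal (~0.09 at α = .05 in strong-trait regimes).
* The EBIC refit convention reports unshrunk partial correlations; users
  comparing against penalized-output conventions should expect larger
  magnitudes at identical supports.
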