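# Methods

## Data model

A trial dataset is wide-format: one row per patient with an arm label and
outcomes at J scheduled visits, visit 1 = baseline. Missingness must be
monotone (a missed visit is never followed by an observed one) and baseline
must be complete; both are enforced at construction and intermittent
missingness is rejected rather than silently handled — the exact conjugate
imputation posterior below relies on the monotone factorization. Per-arm
outcomes are modelled as multivariate normal with arm-specific means and a
covariance matrix common to both arms.

## Imputation engine

Under monotone missingness the Gaussian likelihood factorizes into sequential
normal linear regressions (visit j on visits 1..j−1 among patients still in
follow-up at j). The engine exploits this twice:

* **MLE** (`fit_mle_monotone`): each regression is maximised separately and
  the coefficients are recomposed into (μ per arm, Σ). On complete data this
  is exactly the sample means and the ML (divisor n) covariance. Residual
  variances use the ML divisor throughout.
* **Proper-imputation draws** (`draw_posterior`): each regression's
  parameters are drawn from their exact normal–inverse-chi-square posterior
  under the Jeffreys prior (σ² ~ SSE/χ²_df, then β | σ² Gaussian) and
  recomposed. No MCMC is needed, draws are exact and fast, and each of the K
  draws uses its own spawned RNG substream so the sequence is reproducible
  and independent of K.

Covariance pooling: `"common"` (default) fits the common-covariance model
exactly — arm-specific intercepts with shared slopes and residual variances
in every sequential regression. `"per_arm"` fits and draws each arm
separately and pools the recomposed arm covariances with sample-size weights,
mirroring reference-based MI implementations that fit arms separately; a
paired simulation comparison showed the two samplers give statistically
indistinguishable pooled inferences in this design, and the exact pooled fit
is kept as the default. `"separate"` keeps per-arm covariances and is only
meaningful for MAR/δ analyses.

## Controlled imputation

Each deviator's joint mean vector is assembled from a parameter draw
according to the method (see the README table); the missing block is then
drawn from the Gaussian conditional given the patient's observed history.
Design points worth noting:

* Deviation time = first missing visit j; "pre-deviation" = visits 1..j−1.
* **LMCF** freezes the randomized arm's mean at the *last observed* visit
  (μ_{a,j−1} carried to visits j..J). The phrase "mean at dropout" is
  ambiguous between j−1 and j; the j−1 reading is the one used by the
  standard implementations and makes LMCF distinct from MAR for every
  deviation time.
* **CR** copies the entire reference joint distribution, so the conditional
  mean given the history is also anchored at reference means — the history
  enters as (y_obs − μ_ref,obs).
* Reference-arm deviators are imputed under within-arm MAR for J2R/CIR/CR
  (their reference is themselves); LMCF, an own-arm rule, applies as stated.
* **δ-adjustment** happens after MAR imputation, on the outcome scale. In the
  default *cumulative* mode a deviator at visit j is shifted by (k−j+1)·δ_k
  at visit k ≥ j — a per-visit drift of δ, so the final visit accumulates
  (J+1−j)δ_k; *per_visit* mode adds δ_k at every imputed visit. δ_k is fixed
  when δ_sd = 0, otherwise drawn once per imputation from Normal(δ, σ_δ²)
  (the elicited-prior workflow). A fixed δ is a deterministic edit, so the
  imputation-coefficient draws are bit-identical to the MAR run under a
  shared seed.
* `subsample_reference` re-estimates the imputation model per imputation from
  a random reference subset matched to the active completer count; it
  sharpens anchoring only under very heavy (>40%) dropout and is off by
  default.

Observed cells are never modified; completed datasets carry an imputed-cell
mask and provenance (method, draw index).

## Analysis and pooling

The primary analysis is the classical ANCOVA: OLS of the final-visit outcome
on intercept, baseline and a treatment indicator (reference = 0), with the
homoskedastic variance and a t test on n−3 df. A difference-in-means analysis
supports the unadjusted theory. Rubin's rules pool K results with
V = W + (1+1/K)B and Barnard–Rubin small-sample degrees of freedom (using the
analysis model's complete-data df), the modern convention for trials; the
fraction of missing information is λ = (1+1/K)B/V and the relative efficiency
of K imputations is 1 + λ/K.

## Anchoring calculus

Information is 1/variance of the scalar treatment-effect estimator
throughout. The theoretical pieces:

* **Expected full-data variances.** E[V_full,primary] = 2σ²_{J,J}/n
  unadjusted, or 2σ²_{J.1}/n with σ²_{J.1} = σ²_{J,J} − (σ²_{1,J})²/σ²_{1,1}
  when baseline-adjusted (formulas use n, not n−1). Under a controlled
  pattern-mixture scenario the full-data variance gains non-negative terms in
  the squared final-visit mean offsets Δ_{d,j} = μ_{a,J} − μ_{d,j,J} and
  Δ_{d,p,q}, each scaled by pattern-count products over n³ — O(n⁻²) whenever
  the offsets are O(n^{-1/2}) as trial-sized effects are. For cumulative δ
  the inflation specialises to the closed-form Q term.
* **Anchored variance** = (V_obs,primary/V_full,primary)·V_full,sensitivity;
  it can never fall below V_full,sensitivity (missing data cannot add primary
  information — an input violating this draws a warning, since per-replicate
  Monte-Carlo noise can produce it legitimately inside simulations).
* **Discrepancy first term.** The leading term of
  E[V_anchored] − E[V_Rubin] sums, over deviation visits j,
  π²_{d,j} P̄_j (V_primary,j − V_sensitivity,j) P̄_jᵀ, with P̄_j the pattern's
  history means prefixed by 1. The coefficient covariances are evaluated with
  the exact normal-theory formula for a regression of the final visit on the
  history; at the history mean the quadratic form collapses to
  σ²_{J|1..j−1}(1/n_o − 1/n) for reference-estimated sensitivity models,
  is exactly 0 for fixed δ, and totals −π_d²σ_δ² for random δ (reported with
  per-pattern entries apportioned by π_{d,j} so they sum to the total). The
  remaining discrepancy term is of smaller order and is reported as a note,
  not evaluated: its printed algebraic rendering does not parse, and the
  simulations below measure its size directly.
* **Classification** compares retained-information ratios with a relative
  tolerance (default 5% — the anchoring result is an approximation, not an
  identity). `info_loss_percent` converts two standard errors into the share
  of information the second analysis discards beyond the first.
* **Variance inflation**: adding one Normal(0, V_anchored − V_ML) draw to a
  reference-based ML point estimate yields an estimator whose long-run
  variance is the anchored variance.
* **Sample size**: n = ⌈2(z_{1−α/2}+z_power)²σ²/Δ²⌉ per arm.

## Synthetic-trial engine

The generator emulates a chronic-asthma trial measuring FEV1 (litres) at
baseline, week 4 and week 12: per-arm trivariate normals with means
(2.0, 1.95, 1.9) and (2.0, 2.21, μ_a3), common covariance
[[0.4, 0.2, 0.2], [0.2, 0.5, 0.2], [0.2, 0.2, 0.6]], and 250 patients per
arm; μ_a3 ∈ {1.9, 2.2, 2.9} spans null, moderate (0.3) and large effects,
with full-data ANCOVA power above 90% in the non-null scenarios. Dropout is
MCAR, monotone and confined to the active arm: of a total proportion π,
⌈πn/2⌉ patients lose visits 2–3 and ⌊πn/2⌋ lose visit 3 only, an exact
deterministic split chosen for reproducibility where real trials would have a
random one. What the generator does **not** emulate: missingness related to
observed or unobserved outcomes (MNAR dropout mechanisms), covariates beyond
baseline, non-normal outcomes, or missing reference-arm data — so passing
tests certify the variance calculus under the stated Gaussian/MCAR
conditions, not robustness to those departures.

Each replicate produces four variance estimates for a method: Rubin's V from
K controlled imputations; the anchored variance assembled from the same
replicate's complete-data fit, MAR-MI variance and scenario-complete fit
(the scenario-complete dataset redraws post-deviation data from the
controlled conditional at the true parameters, paired with the same dropout
pattern to cut Monte-Carlo noise); the classical ANCOVA variance averaged
over the K imputed datasets; and the scenario-complete-data variance itself.
The study summary additionally reports the empirical long-run variance of the
pooled estimate across replicates — the repeated-sampling variance the
conventional primary-analysis estimator targets. Under reference-based
scenarios that quantity falls steadily with dropout (the imputed active arm
is increasingly determined by the reference arm, so conventional variance
estimators become information positive), whereas for δ-methods it stays at
the MAR level; the per-dataset classical variance does not show this fall
(it is flat to slightly increasing, as reference-style imputation widens the
active-arm residual spread), which is why the long-run variance is the
reported diagnostic.

Replicate r at grid point g uses the dedicated seed stream (seed, g, r), so
grids are embarrassingly parallel without changing results.

## Replication sizes and measured approximation quality

Test-suite runs use 200 replicates with K = 25 imputations per analysis (the
full 1000 × 50 design is a config change away; the estimands are identical,
only Monte-Carlo error differs). At these sizes, |E V_Rubin − E V_anchored| /
E V_anchored stays within 5% across J2R, CIR, CR and fixed δ ∈ {0, −0.1,
−0.5} for dropout up to 30–40%, with two systematic exceptions at 40%
dropout: CR (≈5–6%) and LMCF (≈8–9%). Both are structural, not Monte-Carlo
noise (z ≈ 8–12): CR's conditioning reuses the reference means, and LMCF's
carried-forward mean — the baseline mean for visit-2 deviators — is estimated
far more precisely (variance ≈ σ²_{1,1}/n) than the MAR imputation
coefficients it replaces (≈ Σ_j/n_o), so the between-imputation variance
falls short of the anchored target by more than the generic leading-term
bound suggests. J2R's measured gap (≈1.7% at 40%) matches the evaluated first
term (≈1.9%) almost exactly. Random-δ imputation (σ_δ = 0.46) is measurably
information negative, with Rubin's variance exceeding the anchored variance
by close to π_d²σ_δ², as the first-term theory predicts.

## Numerical notes

* Conditional covariances are symmetrised and given a 1e-12 jitter before
  Cholesky factorisation; singular observed blocks or sequential-regression
  designs raise errors naming the visit.
* Sequential regressions require more observations than parameters per visit
  (df > 0) for both the MLE and the posterior draws.
* Imputation is vectorised per (arm, deviation-visit) pattern — all patients
  in a pattern share one set of conditional coefficients.
* The simple-mean information crossover is solved by Brent root-finding on
  the information function (bracket doubling upward from σ²), tolerance
  1e-12.
* Ties/degenerate inputs: empty arms, constant baselines, K < 2, non-positive
  variances and out-of-range probabilities all raise explicit ValueErrors
  rather than propagating NaNs.

## Known limitations

* The theory module evaluates only the leading discrepancy term; the
  second-order term is visible in simulations at 40% dropout (≈2–3% even for
  fixed δ where the first term vanishes).
* Reference-based methods use a single common covariance matrix; per-arm
  covariance blending for the patient-specific joint distribution is not
  implemented.
* Scenario-complete data under random δ are generated at the mean δ — a
  deterministic scenario — which suffices for the directional
  information-negative comparison.
* One continuous outcome, baseline as the only covariate, two analysis arms.
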