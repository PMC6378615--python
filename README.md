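# anchormi

Information-anchored sensitivity analysis for longitudinal randomized trials,
via controlled (reference-based and δ-adjusted) multiple imputation.

## The problem

When patients in a trial deviate from protocol (withdraw, switch treatment,
get rescued) their later outcomes are usually set missing, and the primary
analysis imputes them under missing-at-random (MAR). Sensitivity analyses
must then ask: *what if the missing data behaved differently?* Reference-based
multiple imputation answers qualitatively — e.g. "after deviating, an
active-arm patient's mean profile jumps to the reference arm's" — while the
δ-method shifts MAR imputations by a fixed or elicited amount.

These are *class 1* analyses: the primary analysis model (an ANCOVA of the
final-visit outcome on baseline and treatment) is refitted to each imputed
dataset and results are pooled with Rubin's rules, even though the imputation
and analysis models are deliberately uncongenial. The question this package
makes precise is **how much statistical information a sensitivity analysis
should carry**. Writing I(θ̂) for the information (1/variance) about the
treatment effect θ, a sensitivity analysis is *information anchored* when the
proportion of information lost to missing data matches the primary analysis:

    I(θ̂_obs,sens) / I(θ̂_full,sens)  =  I(θ̂_obs,primary) / I(θ̂_full,primary),

equivalently, its variance equals the anchored variance

    V_anchored = (V_obs,primary / V_full,primary) · V_full,sensitivity.

The package implements the whole calculus — anchored variance, expected
full-data variances of the treatment-effect estimator under controlled
pattern-mixture models, the leading term of the discrepancy between the
anchored variance and Rubin's-rules variance, the δ-adjustment inflation term
Q, the information-loss percentage, and the variance-inflation device that
gives a point estimator whose long-run variance is the anchored variance —
together with a simulation engine that demonstrates empirically that Rubin's
rules variance is information anchored for the reference-based and fixed-δ
methods, while random-δ (prior-elicited) adjustment is information negative.

## Imputation methods

For a patient deviating at visit j (visits 1..J, visit 1 = baseline), the
missing block is drawn from the Gaussian conditional of a *controlled* joint
normal whose mean vector is:

| method | post-deviation means |
|---|---|
| `MAR`   | randomized-arm means (primary analysis) |
| `J2R`   | jump to reference: reference-arm means from visit j on |
| `CIR`   | copy increments in reference: own mean at j−1 plus reference increments |
| `CR`    | copy reference: the whole profile (and conditioning) is the reference arm's |
| `LMCF`  | last mean carried forward: own-arm mean at visit j−1, frozen |
| `DELTA` | MAR, then imputed visit k ≥ j shifted by (k−j+1)·δ_k (cumulative) or δ_k |

δ_k is fixed, or drawn once per imputation from Normal(δ, σ_δ²) to propagate
an elicited prior. Parameters come from exact conjugate posterior draws of
the monotone-factorized multivariate normal (sequential normal linear
regressions under Jeffreys priors — no MCMC), with the covariance matrix
pooled across arms.

## Worked example

Simulate an asthma-like trial — FEV1 (litres) at baseline and two follow-up
visits, 250 patients per arm, true final-visit treatment effect 0.3, with 30%
MCAR monotone dropout in the active arm — and compare the primary analysis
with two sensitivity analyses:

```python
import numpy as np
from anchormi import (SimConfig, generate_complete_trial,
                      impose_mcar_monotone_dropout, ImputationSpec,
                      impute_all, fit_ancova, pool)

cfg = SimConfig(seed=2026)
rng = np.random.default_rng(2026)
trial = impose_mcar_monotone_dropout(generate_complete_trial(cfg, rng), 0.30, rng)

for method, kw in [("MAR", {}), ("J2R", {}), ("DELTA", dict(delta=-0.5))]:
    spec = ImputationSpec(method, K=50, **kw)
    completed = impute_all(trial, spec, np.random.default_rng(7))
    pooled = pool([fit_ancova(c) for c in completed])
    print(f"{method:6s} estimate={pooled.estimate:.3f} se={pooled.se:.3f} "
          f"p={pooled.p_value:.4f} lambda={pooled.lam:.2f}")
```

```
MAR    estimate=0.269 se=0.073 p=0.0003 lambda=0.19
J2R    estimate=0.179 se=0.075 p=0.0173 lambda=0.21
DELTA  estimate=0.042 se=0.077 p=0.5864 lambda=0.17
```

The MAR analysis recovers the true effect (0.3 up to sampling noise). Jumping
deviators to the reference profile attenuates the estimate to 0.179 but the
standard error barely moves (0.073 → 0.075): the proportion of information
lost to missing data is held at the primary-analysis level, so the analyst
can read the δ or reference assumption off the point estimate without hidden
precision games. λ is Rubin's fraction of missing information.

The same classification is available empirically:

```python
from anchormi import empirical_anchoring_report
report, _ = empirical_anchoring_report(
    SimConfig(K=25, n_reps=100, dropout_total=0.3, seed=1), "J2R")
print(report.classification)   # "anchored"
```

which pairs full and observed-data analyses over simulated replicates and
compares the retained-information ratios (0.816 primary vs 0.810 sensitivity
in this run).

The same workflows are scriptable from the shell:

```bash
anchormi analyze --input trial.csv --method J2R --imputations 50 --seed 7
anchormi simulate --methods J2R,CR,CIR,LMCF --dropout 0.3 --reps 200 \
    --imputations 25 --seed 0 --out rows.csv --summary-out summary.csv
anchormi samplesize --delta 0.23 --sd 0.5        # -> {"n_per_arm": 75, ...}
```

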