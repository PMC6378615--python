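"""The information-anchoring calculus for controlled sensitivity analyses.

Information about the scalar treatment effect is measured as 1/variance of
its estimator throughout. A sensitivity analysis is *information anchored*
when the proportion of information lost to missing data matches the primary
analysis:

    I(obs, sensitivity) / I(full, sensitivity)
        = I(obs, primary) / I(full, primary),

equivalently, the anchored variance is

    V_anchored = (V_obs_primary / V_full_primary) * V_full_sensitivity.

This module provides: the simple-mean information calculus that motivates
the definitions; the expected full-data variances of the unadjusted and
baseline-adjusted treatment-effect estimators under the controlled
(pattern-mixture) model; the delta-adjustment inflation term Q; the leading
term of the discrepancy between the anchored variance and Rubin's-rules
variance; classification of an analysis as information negative / anchored /
positive; the information-loss percentage between two standard errors; the
variance-inflation device that gives a point estimator whose long-run
variance is the anchored variance; and the two-arm sample-size formula.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .trial_data import PatternSummary

__all__ = [
    "InformationReport",
    "TheoreticalVariances",
    "DiscrepancyReport",
    "info_simple_mean",
    "crossover_variance",
    "classify_information",
    "expected_full_variance_primary",
    "expected_full_variance_sensitivity",
    "delta_Q_term",
    "anchored_variance",
    "theorem1_first_term",
    "info_loss_percent",
    "inflate_to_anchored",
    "sample_size_per_arm",
]


@dataclass
class InformationReport:
    """Observed/full information in primary and sensitivity analyses."""

    I_full_primary: float
    I_obs_primary: float
    I_full_sensitivity: float
    I_obs_sensitivity: float
    rel_tol: float
    classification: str = field(init=False)

    def __post_init__(self) -> None:
        for name in ("I_full_primary", "I_obs_primary", "I_full_sensitivity", "I_obs_sensitivity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        ratio_p = self.ratio_primary
        ratio_s = self.ratio_sensitivity
        if abs(ratio_s / ratio_p - 1.0) <= self.rel_tol:
            self.classification = "anchored"
        elif ratio_s < ratio_p:
            self.classification = "negative"
        else:
            self.classification = "positive"

    @property
    def ratio_primary(self) -> float:
        return self.I_obs_primary / self.I_full_primary

    @property
    def ratio_sensitivity(self) -> float:
        return self.I_obs_sensitivity / self.I_full_sensitivity

    def to_dict(self) -> dict:
        return {
            "I_full_primary": self.I_full_primary,
            "I_obs_primary": self.I_obs_primary,
            "I_full_sensitivity": self.I_full_sensitivity,
            "I_obs_sensitivity": self.I_obs_sensitivity,
            "ratio_primary": self.ratio_primary,
            "ratio_sensitivity": self.ratio_sensitivity,
            "rel_tol": self.rel_tol,
            "classification": self.classification,
        }


@dataclass
class TheoreticalVariances:
    """Expected full-data variances under primary and controlled models."""

    v_full_primary: float
    v_full_sensitivity: float
    q_term: float
    baseline_adjusted: bool


@dataclass
class DiscrepancyReport:
    """Leading term of E[V_anchored] - E[V_Rubin] and its per-pattern parts."""

    first_term: float
    per_pattern_contributions: dict[int, float]
    notes: str = ""


def info_simple_mean(
    n: int, n_m: int, sigma2: float, sigma_m2: float
) -> tuple[float, float, float]:
    """Information about a simple sample mean in the motivating calculus.

    With n intended observations of variance sigma2, of which n_m are missing
    and are imputed as coming from a population with the same mean but
    variance sigma_m2, the estimator (still the mean of all n) carries

        I_full = n / sigma2,
        I_obs  = (n - n_m) / sigma2,
        I_sens = n^2 / ((n - n_m) sigma2 + n_m sigma_m2).
    """
    if not 0 <= n_m < n:
        raise ValueError("need 0 <= n_m < n")
    if sigma2 <= 0 or sigma_m2 <= 0:
        raise ValueError("variances must be positive")
    i_full = n / sigma2
    i_obs = (n - n_m) / sigma2
    i_sens = n**2 / ((n - n_m) * sigma2 + n_m * sigma_m2)
    return i_full, i_obs, i_sens


def crossover_variance(n: int, n_m: int, sigma2: float) -> float:
    """The sigma_m2 at which the sensitivity information equals I_obs.

    Solved by root-finding on the information calculus: below this value the
    sensitivity analysis carries more information than the observed data
    alone; above it, less.
    """
    _, i_obs, _ = info_simple_mean(n, n_m, sigma2, sigma2)

    def gap(sm2: float) -> float:
        return info_simple_mean(n, n_m, sigma2, sm2)[2] - i_obs

    hi = sigma2
    while gap(hi) > 0:
        hi *= 2.0
    return float(optimize.brentq(gap, sigma2 * 1e-9, hi, xtol=1e-12, rtol=1e-14))


def classify_information(
    I_full_primary: float,
    I_obs_primary: float,
    I_full_sensitivity: float,
    I_obs_sensitivity: float,
    rel_tol: float = 0.05,
) -> InformationReport:
    """Classify a sensitivity analysis as information negative/anchored/positive.

    The analysis is anchored when the proportional information retained,
    I_obs/I_full, agrees between primary and sensitivity analyses within
    ``rel_tol`` (the anchoring theory is approximate, not exact); negative
    when the sensitivity analysis loses more information, positive when it
    loses less.
    """
    return InformationReport(
        I_full_primary, I_obs_primary, I_full_sensitivity, I_obs_sensitivity, rel_tol
    )


def _conditional_final_variance(sigma: np.ndarray, baseline_adjusted: bool) -> float:
    sigma = np.asarray(sigma, float)
    j = sigma.shape[0] - 1
    if baseline_adjusted:
        return float(sigma[j, j] - sigma[0, j] ** 2 / sigma[0, 0])
    return float(sigma[j, j])


def expected_full_variance_primary(
    sigma: np.ndarray, n: int, baseline_adjusted: bool = True
) -> float:
    """E[V_full] of the treatment-effect estimator with complete data.

    Unadjusted difference in means: 2 sigma_JJ / n. Baseline-adjusted ANCOVA:
    2 sigma_{J.1} / n with sigma_{J.1} = sigma_JJ - sigma_1J^2 / sigma_11.
    (The n-1 -> n convention of the theory is used.)
    """
    if n <= 0:
        raise ValueError("n must be positive")
    return 2.0 * _conditional_final_variance(sigma, baseline_adjusted) / n


def expected_full_variance_sensitivity(
    sigma: np.ndarray,
    n: int,
    pattern: PatternSummary,
    mu_dev_final: dict[int, float],
    mu_a_final: float,
    baseline_adjusted: bool = True,
) -> TheoreticalVariances:
    """E[V_full] when deviators are actually observed under the controlled model.

    Deviation at visit j shifts the final-visit mean of that pattern from
    mu_a_final to mu_dev_final[j]; the pattern mixture inflates the usual
    sample variance by between- and within-pattern mean-difference terms:

        E[V_full,sens] = E[V_full,primary]
            + sum_j n_o n_dj Delta_dj^2 / n^3
            + sum_{p != q} n_dp n_dq Delta_dpq^2 / n^3,

    with Delta_dj = mu_a_final - mu_dev_final[j] and
    Delta_dpq = mu_dev_final[p] - mu_dev_final[q].
    """
    if pattern.n != n:
        raise ValueError("pattern counts inconsistent with n")
    v_primary = expected_full_variance_primary(sigma, n, baseline_adjusted)
    n_o = pattern.n_complete
    extra = 0.0
    visits = sorted(pattern.n_dev)
    for j in visits:
        n_dj = pattern.n_dev[j]
        if n_dj == 0:
            continue
        delta_dj = mu_a_final - mu_dev_final[j]
        extra += n_o * n_dj * delta_dj**2 / n**3
    for p in visits:
        for q in visits:
            if p == q or pattern.n_dev[p] == 0 or pattern.n_dev[q] == 0:
                continue
            delta_pq = mu_dev_final[p] - mu_dev_final[q]
            extra += pattern.n_dev[p] * pattern.n_dev[q] * delta_pq**2 / n**3
    return TheoreticalVariances(
        v_full_primary=v_primary,
        v_full_sensitivity=v_primary + extra,
        q_term=extra,
        baseline_adjusted=baseline_adjusted,
    )


def delta_Q_term(pattern: PatternSummary, delta: float, J: int, n: int) -> float:
    """Variance inflation Q of the cumulative delta adjustment.

    A deviator at visit j ends (J + 1 - j) * delta below their MAR mean, so

        Q = sum_j n_o n_dj (J+1-j)^2 delta^2 / n^3
          + sum_{p != q} n_dp n_dq ((J+1-p) - (J+1-q))^2 delta^2 / n^3.
    """
    if not np.isfinite(delta):
        raise ValueError("delta must be finite")
    n_o = pattern.n_complete
    visits = sorted(pattern.n_dev)
    q = 0.0
    for j in visits:
        q += n_o * pattern.n_dev[j] * (J + 1 - j) ** 2 * delta**2 / n**3
    for p in visits:
        for qq in visits:
            if p == qq:
                continue
            q += (
                pattern.n_dev[p]
                * pattern.n_dev[qq]
                * ((J + 1 - p) * delta - (J + 1 - qq) * delta) ** 2
                / n**3
            )
    return q


def anchored_variance(
    v_obs_primary: float, v_full_primary: float, v_full_sensitivity: float
) -> float:
    """The information-anchored variance.

    By definition (V_obs,primary / V_full,primary) * V_full,sensitivity: the
    sensitivity-scenario full-data variance, inflated by the primary
    analysis's proportional information loss. Always at least
    V_full,sensitivity since missing data cannot gain primary information.
    """
    if min(v_obs_primary, v_full_primary, v_full_sensitivity) <= 0:
        raise ValueError("variances must be positive")
    ratio = v_obs_primary / v_full_primary
    if ratio < 1.0:
        warnings.warn(
            "v_obs_primary < v_full_primary: missing data cannot increase the "
            "primary information; check the inputs",
            stacklevel=2,
        )
    return ratio * v_full_sensitivity


def _coef_covariance(sigma_hist: np.ndarray, resid_var: float, mean_hist: np.ndarray, n_obs: float) -> np.ndarray:
    """Normal-theory covariance of (intercept, slopes) for a regression of the
    final visit on the (j-1)-visit history, fitted to n_obs patients."""
    s_inv = np.linalg.inv(sigma_hist)
    m = np.asarray(mean_hist, float)
    top = 1.0 + m @ s_inv @ m
    cov = np.empty((m.size + 1, m.size + 1))
    cov[0, 0] = top
    cov[0, 1:] = -(s_inv @ m)
    cov[1:, 0] = cov[0, 1:]
    cov[1:, 1:] = s_inv
    return resid_var / n_obs * cov


def theorem1_first_term(
    sigma: np.ndarray,
    pattern: PatternSummary,
    pattern_history_means: dict[int, np.ndarray],
    n: int,
    n_o: int,
    v_sensitivity_scale: str = "reference_full",
    sigma_delta: float = 0.0,
) -> DiscrepancyReport:
    """Leading term of E[V_anchored] - E[V_Rubin's MI].

    For each deviation visit j the primary (MAR) imputation-model parameters
    are estimated from the n_o on-treatment completers, with coefficient
    covariance V_primary,j; the sensitivity imputation model's covariance
    V_sensitivity,j depends on the assumption. The leading discrepancy is

        sum_j pi_dj^2  Pbar_j (V_primary,j - V_sensitivity,j) Pbar_j^T,

    with Pbar_j the pattern's history-mean vector prefixed by a 1 for the
    intercept. Scales:

    * ``reference_full``: the sensitivity model is estimated from the n fully
      observed reference patients, so the bracket scales with (1/n_o - 1/n);
    * ``delta``: a fixed delta shift leaves the imputation coefficients
      untouched, so the term is exactly zero;
    * ``delta_random``: drawing delta_k ~ N(delta, sigma_delta^2) per
      imputation adds pi_d^2 sigma_delta^2 of between-imputation variance,
      so the term is -pi_d^2 sigma_delta^2 (information negative). The
      per-pattern entries are apportioned by pi_dj so they sum to the total.

    The remaining discrepancy term is O(n^-2) (Q-sized for delta methods) and
    is not evaluated; see ``notes``.
    """
    sigma = np.asarray(sigma, float)
    pis = pattern.pi_dev
    pi_d = pattern.pi_total
    contributions: dict[int, float] = {}
    if v_sensitivity_scale == "delta":
        contributions = {j: 0.0 for j in pis if pattern.n_dev[j] > 0}
        total = 0.0
    elif v_sensitivity_scale == "delta_random":
        total = -(pi_d**2) * sigma_delta**2
        for j, pi_dj in pis.items():
            if pattern.n_dev[j] > 0:
                contributions[j] = -pi_dj * pi_d * sigma_delta**2
    elif v_sensitivity_scale == "reference_full":
        j_total = sigma.shape[0]
        total = 0.0
        for j, pi_dj in pis.items():
            if pattern.n_dev[j] == 0:
                continue
            pbar = np.asarray(pattern_history_means[j], float)
            if pbar.size != j:
                raise ValueError(
                    f"history-mean vector for deviation visit {j} must have length {j} "
                    "(leading 1 plus the j-1 history means)"
                )
            hist = np.arange(j - 1)
            sigma_hist = sigma[np.ix_(hist, hist)]
            last = j_total - 1
            resid_var = float(
                sigma[last, last]
                - sigma[last, hist] @ np.linalg.solve(sigma_hist, sigma[hist, last])
            )
            mean_hist = pbar[1:]
            v_primary = _coef_covariance(sigma_hist, resid_var, mean_hist, n_o)
            v_sens = _coef_covariance(sigma_hist, resid_var, mean_hist, n)
            contrib = float(pi_dj**2 * pbar @ (v_primary - v_sens) @ pbar)
            contributions[j] = contrib
            total += contrib
    else:
        raise ValueError(f"unknown v_sensitivity_scale {v_sensitivity_scale!r}")
    return DiscrepancyReport(
        first_term=float(total),
        per_pattern_contributions=contributions,
        notes=(
            "Leading term only; the residual discrepancy is O(n^-2) "
            "(replaced by the Q term for delta adjustments) and not evaluated."
        ),
    )


def info_loss_percent(se_a: float, se_b: float) -> float:
    """Extra information (%) lost by analysis b relative to analysis a.

    (1/se_a^2 - 1/se_b^2) / (1/se_a^2) * 100 -- the share of analysis a's
    information that analysis b discards beyond the loss already in a.
    """
    if se_a <= 0:
        raise ValueError("standard errors must be positive")
    if se_b < se_a:
        raise ValueError("se_b < se_a would imply a negative information loss")
    return (1.0 / se_a**2 - 1.0 / se_b**2) / (1.0 / se_a**2) * 100.0


def inflate_to_anchored(
    estimate: float, v_ml: float, v_anchored: float, rng: np.random.Generator
) -> float:
    """Add Normal(0, v_anchored - v_ml) noise so the long-run variance of the
    returned estimator equals the anchored variance."""
    if v_anchored < v_ml:
        raise ValueError("anchored variance must be >= the maximum-likelihood variance")
    if v_anchored == v_ml:
        return float(estimate)
    return float(estimate + np.sqrt(v_anchored - v_ml) * rng.standard_normal())


def sample_size_per_arm(delta: float, sigma: float, alpha: float, power: float) -> int:
    """Patients per arm to detect a mean difference delta with a two-sided test.

    n = ceil( 2 (z_{1-alpha/2} + z_power)^2 sigma^2 / delta^2 ).
    """
    if delta == 0:
        raise ValueError("delta must be non-zero")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    z = stats.norm.ppf(1.0 - alpha / 2.0) + stats.norm.ppf(power)
    return int(np.ceil(2.0 * z**2 * sigma**2 / delta**2))
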