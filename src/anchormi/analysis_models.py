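"""Design-based analysis models fitted to each completed dataset.

The primary analysis is the trialist's ANCOVA: OLS of the final-visit
outcome on an intercept, the baseline outcome and the treatment indicator
(reference = 0, active = 1), with the classical homoskedastic variance and a
two-sided t test on n - 3 degrees of freedom. A difference-in-means analysis
(no baseline adjustment) is provided for the unadjusted theory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["AnalysisResult", "fit_ancova", "fit_diff_means"]


@dataclass
class AnalysisResult:
    estimate: float
    variance: float
    se: float
    df: float
    p_value: float
    model: str

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "variance": self.variance,
            "se": self.se,
            "df": self.df,
            "p_value": self.p_value,
            "model": self.model,
        }


def _arm_indicator(data, active_arm: str, reference_arm: str) -> np.ndarray:
    arm = np.asarray(data.arm)
    is_active = arm == active_arm
    is_reference = arm == reference_arm
    if not is_active.any():
        raise ValueError(f"no patients in active arm {active_arm!r}")
    if not is_reference.any():
        raise ValueError(f"no patients in reference arm {reference_arm!r}")
    keep = is_active | is_reference
    return keep, is_active


def fit_ancova(
    data,
    active_arm: str = "active",
    reference_arm: str = "reference",
    outcome_visit: int | None = None,
    baseline_visit: int = 1,
) -> AnalysisResult:
    """ANCOVA treatment effect at ``outcome_visit`` (default: last visit).

    ``data`` is any object exposing complete ``outcomes`` and ``arm``
    (a :class:`TrialDataset` without missing cells or a completed dataset).
    Visit indices are 1-based.
    """
    outcomes = np.asarray(data.outcomes, float)
    j_total = outcomes.shape[1]
    if outcome_visit is None:
        outcome_visit = j_total
    keep, is_active = _arm_indicator(data, active_arm, reference_arm)
    y = outcomes[keep, outcome_visit - 1]
    base = outcomes[keep, baseline_visit - 1]
    treat = is_active[keep].astype(float)
    if np.isnan(y).any() or np.isnan(base).any():
        raise ValueError("ANCOVA requires complete data at the baseline and outcome visits")
    if np.ptp(base) == 0:
        raise ValueError("baseline is constant: ANCOVA design is collinear")
    n = y.size
    x = np.column_stack([np.ones(n), base, treat])
    xtx = x.T @ x
    xty = x.T @ y
    try:
        coef = np.linalg.solve(xtx, xty)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular ANCOVA design") from exc
    resid = y - x @ coef
    df = n - 3
    if df <= 0:
        raise ValueError("too few patients for ANCOVA")
    s2 = float(resid @ resid) / df
    var = s2 * np.linalg.inv(xtx)[2, 2]
    est = float(coef[2])
    se = float(np.sqrt(var))
    tval = est / se
    p = 2.0 * stats.t.sf(abs(tval), df)
    return AnalysisResult(est, float(var), se, float(df), float(p), "ancova")


def fit_diff_means(
    data,
    active_arm: str = "active",
    reference_arm: str = "reference",
    outcome_visit: int | None = None,
) -> AnalysisResult:
    """Difference in arm means at ``outcome_visit`` with the pooled-variance t test."""
    outcomes = np.asarray(data.outcomes, float)
    if outcome_visit is None:
        outcome_visit = outcomes.shape[1]
    keep, is_active = _arm_indicator(data, active_arm, reference_arm)
    y = outcomes[keep, outcome_visit - 1]
    if np.isnan(y).any():
        raise ValueError("difference in means requires complete data at the outcome visit")
    treat = is_active[keep]
    y_a, y_r = y[treat], y[~treat]
    if y_a.size < 2 or y_r.size < 2:
        raise ValueError("each arm needs at least 2 patients")
    n_a, n_r = y_a.size, y_r.size
    est = float(y_a.mean() - y_r.mean())
    pooled = ((n_a - 1) * y_a.var(ddof=1) + (n_r - 1) * y_r.var(ddof=1)) / (n_a + n_r - 2)
    var = pooled * (1.0 / n_a + 1.0 / n_r)
    df = n_a + n_r - 2
    se = float(np.sqrt(var))
    p = 2.0 * stats.t.sf(abs(est / se), df)
    return AnalysisResult(est, float(var), se, float(df), float(p), "diff_means")
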