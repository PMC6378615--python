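"""Rubin's rules for pooling K per-imputation analysis results.

The pooled estimate is the mean of the K estimates; the total variance is
``V = W + (1 + 1/K) B`` with W the mean within-imputation variance and B the
between-imputation sample variance (divisor K - 1). Degrees of freedom use
the Barnard-Rubin small-sample adjustment with the analysis model's
complete-data df, the standard for trial analyses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .analysis_models import AnalysisResult

__all__ = ["PooledResult", "pool", "relative_efficiency"]


@dataclass
class PooledResult:
    estimate: float
    W: float
    B: float
    V: float
    se: float
    df: float
    p_value: float
    lam: float  # fraction of missing information, (1 + 1/K) B / V
    K: int
    model: str

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "within_variance": self.W,
            "between_variance": self.B,
            "total_variance": self.V,
            "se": self.se,
            "df": self.df,
            "p_value": self.p_value,
            "fraction_missing_information": self.lam,
            "K": self.K,
            "model": self.model,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def pool(results: list[AnalysisResult]) -> PooledResult:
    """Combine K analysis results with Rubin's rules (Barnard-Rubin df)."""
    k = len(results)
    if k < 2:
        raise ValueError("Rubin's rules need K >= 2 results")
    models = {r.model for r in results}
    if len(models) != 1:
        raise ValueError(f"cannot pool heterogeneous analysis models: {sorted(models)}")
    estimates = np.array([r.estimate for r in results])
    variances = np.array([r.variance for r in results])
    est = float(estimates.mean())
    w = float(variances.mean())
    b = float(estimates.var(ddof=1))
    v = w + (1.0 + 1.0 / k) * b
    lam = (1.0 + 1.0 / k) * b / v if v > 0 else 0.0
    df_com = results[0].df
    # Barnard & Rubin (1999) small-sample degrees of freedom
    df_obs = (df_com + 1.0) / (df_com + 3.0) * df_com * (1.0 - lam)
    if lam > 0:
        df_old = (k - 1.0) / lam**2
        df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
    else:
        df = df_obs
    se = float(np.sqrt(v))
    p = 2.0 * stats.t.sf(abs(est / se), df) if se > 0 else float(est == 0.0)
    return PooledResult(est, w, b, float(v), se, float(df), float(p), float(lam), k, results[0].model)


def relative_efficiency(lam: float, K: int) -> float:
    """Efficiency of K imputations relative to infinitely many: 1 + lambda/K."""
    if not 0.0 <= lam < 1.0:
        raise ValueError("fraction of missing information must be in [0, 1)")
    if K < 1:
        raise ValueError("K must be >= 1")
    return 1.0 + lam / K
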