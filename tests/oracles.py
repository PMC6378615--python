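"""Independent test oracles.

These deliberately avoid the package's sequential-regression code path: the
MLE oracle is an EM algorithm iterated to convergence, and the conditional-
distribution oracle is plain Monte-Carlo regression on simulated draws.
"""

from __future__ import annotations

import numpy as np


def em_mvn_monotone(y, arms=None, tol=1e-10, max_iter=5000):
    """MLE of per-group MVN means and a common covariance with missing data.

    Plain EM, vectorised over missingness patterns. ``arms=None`` fits a
    single group. Returns (mu_by_label, sigma); for a single group the key
    is ``None``.
    """
    y = np.asarray(y, float)
    n, j = y.shape
    if arms is None:
        labels = [None]
        codes = np.zeros(n, int)
    else:
        labels, codes = np.unique(np.asarray(arms), return_inverse=True)
        labels = list(labels)
    n_g = np.bincount(codes, minlength=len(labels)).astype(float)
    mu = np.vstack([
        np.nanmean(y[codes == g], axis=0) for g in range(len(labels))
    ])
    resid = y - mu[codes]
    sigma = np.diag(np.nanvar(resid, axis=0)) + 1e-6 * np.eye(j)

    masks = {}
    for i in range(n):
        masks.setdefault(tuple(np.isnan(y[i])), []).append(i)
    pattern_rows = [
        (np.array(mask), np.array(rows)) for mask, rows in masks.items()
    ]

    for _ in range(max_iter):
        sum_ey = np.zeros((len(labels), j))
        scatter = np.zeros((j, j))
        for mask, rows in pattern_rows:
            mis = np.flatnonzero(mask)
            obs = np.flatnonzero(~mask)
            ey = y[rows].copy()
            c_full = np.zeros((j, j))
            if mis.size:
                s_oo = sigma[np.ix_(obs, obs)]
                s_om = sigma[np.ix_(obs, mis)]
                a = np.linalg.solve(s_oo, s_om)
                cond_cov = sigma[np.ix_(mis, mis)] - s_om.T @ a
                mu_rows = mu[codes[rows]]
                ey[:, mis] = mu_rows[:, mis] + (y[rows][:, obs] - mu_rows[:, obs]) @ a
                c_full[np.ix_(mis, mis)] = cond_cov
            for g in range(len(labels)):
                sel = codes[rows] == g
                if sel.any():
                    sum_ey[g] += ey[sel].sum(axis=0)
            scatter += ey.T @ ey + len(rows) * c_full
        mu_new = sum_ey / n_g[:, None]
        sigma_new = (scatter - (n_g[:, None] * mu_new).T @ mu_new) / n
        change = max(np.abs(mu_new - mu).max(), np.abs(sigma_new - sigma).max())
        mu, sigma = mu_new, sigma_new
        if change < tol:
            break
    return {lab: mu[g] for g, lab in enumerate(labels)}, sigma


def ancova_estimand_from_params(mu_active, mu_reference, sigma):
    """Baseline-adjusted final-visit treatment effect implied by MVN parameters."""
    j = len(mu_active) - 1
    beta = sigma[0, j] / sigma[0, 0]
    return (mu_active[j] - mu_reference[j]) - beta * (mu_active[0] - mu_reference[0])


def simulate_conditional_oracle(mu, sigma, observed_idx, n_draws, rng):
    """Monte-Carlo conditional distribution: regress the missing block of
    simulated MVN draws on the observed block, returning the affine map
    (intercepts, coefficient matrix) and the residual covariance."""
    mu = np.asarray(mu, float)
    j = mu.size
    observed_idx = np.asarray(observed_idx, int)
    missing_idx = np.setdiff1d(np.arange(j), observed_idx)
    draws = rng.multivariate_normal(mu, sigma, size=n_draws)
    x = np.column_stack([np.ones(n_draws), draws[:, observed_idx]])
    ymat = draws[:, missing_idx]
    coef, *_ = np.linalg.lstsq(x, ymat, rcond=None)
    resid = ymat - x @ coef
    resid_cov = resid.T @ resid / (n_draws - x.shape[1])
    return missing_idx, coef[0], coef[1:], resid_cov
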