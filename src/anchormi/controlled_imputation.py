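"""Controlled multiple imputation: reference-based and delta-adjusted.

Each deviating patient's unobserved post-deviation block is imputed from a
multivariate normal whose *joint mean* is dictated by the chosen sensitivity
assumption (built per patient from the deviation visit and the imputation-
model parameter draw) and whose covariance is the draw's matrix:

* MAR    - randomized-arm means throughout (the primary assumption);
* J2R    - jump to reference: post-deviation means switch to the reference
           arm's means;
* CIR    - copy increments in reference: post-deviation means continue from
           the patient's last on-treatment mean with the reference arm's
           mean increments;
* CR     - copy reference: the whole joint profile (including the part
           conditioned on) is the reference arm's;
* LMCF   - last mean carried forward: post-deviation means frozen at the
           randomized arm's mean at the last observed visit;
* DELTA  - impute under MAR, then shift imputed values by delta (fixed, or
           drawn once per imputation from Normal(delta, delta_sd^2)).

Missing values are then drawn from the Gaussian conditional of the missing
block given the patient's observed history. Observed cells are never
touched. Reference-arm patients with missing data are imputed under
within-arm MAR for J2R/CIR/CR (their own arm is the reference).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .mvn_engine import MVNParams, PosteriorDraw, conditional_coefficients, draw_posterior
from .trial_data import TrialDataset

__all__ = [
    "METHODS",
    "ImputationSpec",
    "CompletedDataset",
    "build_joint_mean",
    "impute_once",
    "apply_delta",
    "impute_all",
    "write_stacked_csv",
]

METHODS = ("MAR", "J2R", "CIR", "CR", "LMCF", "DELTA")
REFERENCE_BASED = ("J2R", "CIR", "CR", "LMCF")


@dataclass
class ImputationSpec:
    """How to impute: method, reference arm, delta specification, K."""

    method: str
    reference_arm: str = "reference"
    delta: float = 0.0
    delta_sd: float = 0.0
    delta_mode: str = "cumulative"  # or "per_visit"
    delta_arms: tuple[str, ...] | None = None  # None = every arm
    subsample_reference: bool = False
    K: int = 50
    pooling: str = "common"

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if self.delta_mode not in ("cumulative", "per_visit"):
            raise ValueError(f"unknown delta_mode {self.delta_mode!r}")
        if self.delta_sd < 0:
            raise ValueError("delta_sd must be >= 0")
        if self.method == "DELTA" and not np.isfinite(self.delta):
            raise ValueError("DELTA requires a finite delta")
        if self.method in REFERENCE_BASED and self.pooling not in ("per_arm", "common"):
            raise ValueError(
                f"{self.method} requires pooling='per_arm' or 'common': reference-based "
                "joint means are only coherent with a covariance shared across arms"
            )


@dataclass
class CompletedDataset:
    """A fully observed dataset: input data with imputed cells filled in."""

    patient_id: np.ndarray
    arm: np.ndarray
    outcomes: np.ndarray
    visit_labels: list[str]
    imputed_mask: np.ndarray
    draw_index: int = 0
    method: str = "MAR"

    def __post_init__(self) -> None:
        if np.isnan(self.outcomes).any():
            raise ValueError("completed dataset still contains missing cells")

    def to_dataset(self) -> TrialDataset:
        return TrialDataset(
            self.patient_id.copy(), self.arm.copy(), self.outcomes.copy(), list(self.visit_labels)
        )

    def to_frame(self, id_col: str = "id", arm_col: str = "arm") -> pd.DataFrame:
        frame = pd.DataFrame({id_col: self.patient_id, arm_col: self.arm})
        for k, label in enumerate(self.visit_labels):
            frame[label] = self.outcomes[:, k]
        for k, label in enumerate(self.visit_labels):
            frame[f"imputed_{label}"] = self.imputed_mask[:, k].astype(int)
        return frame


def build_joint_mean(
    spec: ImputationSpec,
    draw: PosteriorDraw | MVNParams,
    arm: str,
    dev_visit: int,
) -> np.ndarray:
    """Joint J-vector mean for a patient in ``arm`` deviating at visit ``dev_visit``.

    ``dev_visit`` is the 1-based first missing visit (2..J); pass 0 for a
    completer, whose means are the randomized arm's under every method.
    """
    params = draw.params if isinstance(draw, PosteriorDraw) else draw
    mu_a = params.mu_by_arm[arm]
    j_total = mu_a.shape[0]
    if dev_visit == 0:
        return mu_a.copy()
    if not 2 <= dev_visit <= j_total:
        raise ValueError(f"deviation visit must be in 2..{j_total}, got {dev_visit}")
    method = spec.method
    if method in ("MAR", "DELTA"):
        return mu_a.copy()
    if spec.reference_arm not in params.mu_by_arm:
        raise ValueError(f"reference arm {spec.reference_arm!r} not in the fitted parameters")
    # reference-arm deviators keep within-arm MAR means (their reference is themselves)
    if arm == spec.reference_arm and method in ("J2R", "CIR", "CR"):
        return mu_a.copy()
    mu_r = params.mu_by_arm[spec.reference_arm]
    jd = dev_visit - 1  # 0-based index of first missing visit
    out = mu_a.copy()
    if method == "J2R":
        out[jd:] = mu_r[jd:]
    elif method == "CIR":
        out[jd:] = mu_a[jd - 1] + (mu_r[jd:] - mu_r[jd - 1])
    elif method == "LMCF":
        out[jd:] = mu_a[jd - 1]
    elif method == "CR":
        out = mu_r.copy()
    return out


def impute_once(
    data: TrialDataset,
    draw: PosteriorDraw,
    spec: ImputationSpec,
    rng: np.random.Generator,
) -> CompletedDataset:
    """One completed dataset under the spec's assumption.

    Deviators sharing an (arm, deviation-visit) pattern share the same
    conditional coefficients, so imputation is vectorised per pattern.
    """
    params = draw.params
    outcomes = data.outcomes.copy()
    miss = np.isnan(outcomes)
    dev = data.deviation_visits()
    if miss.any():
        keys = sorted(
            {(a, j) for a, j in zip(data.arm, dev) if j > 0},
            key=lambda t: (str(t[0]), t[1]),
        )
        for arm, j in keys:
            idx = np.flatnonzero((data.arm == arm) & (dev == j))
            joint_mu = build_joint_mean(spec, params, arm, int(j))
            sigma = params.sigma_by_arm[arm]
            obs_idx = np.arange(j - 1)
            mis_idx, a_mat, cond_cov = conditional_coefficients(sigma, obs_idx)
            chol = np.linalg.cholesky(
                cond_cov + 1e-12 * np.eye(cond_cov.shape[0])
            )
            y_obs = outcomes[np.ix_(idx, obs_idx)]
            means = joint_mu[mis_idx] + (y_obs - joint_mu[obs_idx]) @ a_mat
            z = rng.standard_normal((idx.size, mis_idx.size))
            outcomes[np.ix_(idx, mis_idx)] = means + z @ chol.T
    return CompletedDataset(
        patient_id=data.patient_id.copy(),
        arm=data.arm.copy(),
        outcomes=outcomes,
        visit_labels=list(data.visit_labels),
        imputed_mask=miss,
        draw_index=draw.draw_index,
        method=spec.method,
    )


def apply_delta(
    completed: CompletedDataset,
    spec: ImputationSpec,
    rng: np.random.Generator | None = None,
) -> CompletedDataset:
    """Shift the imputed cells of a MAR-completed dataset by delta.

    With ``delta_mode="cumulative"`` a patient deviating at visit j has the
    imputed value at visit k >= j shifted by (k - j + 1) * delta_k, so the
    response drifts by delta per post-deviation visit; ``"per_visit"`` adds
    delta_k to every imputed visit. ``delta_k = delta`` when ``delta_sd`` is
    zero, otherwise one Normal(delta, delta_sd^2) draw for this imputation.
    """
    if spec.method != "DELTA":
        raise ValueError("apply_delta is only defined for method='DELTA'")
    if spec.delta_sd > 0:
        if rng is None:
            raise ValueError("delta_sd > 0 requires an rng to draw delta_k")
        delta_k = spec.delta + spec.delta_sd * rng.standard_normal()
    else:
        delta_k = spec.delta
    outcomes = completed.outcomes.copy()
    mask = completed.imputed_mask
    rows = np.flatnonzero(mask.any(axis=1))
    if spec.delta_arms is not None:
        in_arms = np.isin(completed.arm, spec.delta_arms)
        rows = rows[in_arms[rows]]
    for i in rows:
        cols = np.flatnonzero(mask[i])
        if spec.delta_mode == "cumulative":
            outcomes[i, cols] += (np.arange(1, cols.size + 1)) * delta_k
        else:
            outcomes[i, cols] += delta_k
    return replace(completed, outcomes=outcomes)


def impute_all(
    data: TrialDataset,
    spec: ImputationSpec,
    rng: np.random.Generator,
) -> list[CompletedDataset]:
    """K completed datasets: posterior draws, imputation, delta adjustment.

    All randomness flows from ``rng``: substreams are spawned in a fixed
    order (K for the posterior draws, then K for the imputation noise, then
    K for delta draws), so results are reproducible and independent of K
    re-ordering.
    """
    k_imp = spec.K
    if spec.subsample_reference and spec.method in REFERENCE_BASED:
        return _impute_all_subsampled(data, spec, rng)
    draws = draw_posterior(data, k_imp, pooling=spec.pooling, rng=rng)
    imp_streams = rng.spawn(k_imp)
    delta_streams = rng.spawn(k_imp) if spec.method == "DELTA" else [None] * k_imp
    out = []
    for k in range(k_imp):
        completed = impute_once(data, draws[k], spec, imp_streams[k])
        if spec.method == "DELTA":
            completed = apply_delta(completed, spec, delta_streams[k])
        out.append(completed)
    return out


def _impute_all_subsampled(
    data: TrialDataset, spec: ImputationSpec, rng: np.random.Generator
) -> list[CompletedDataset]:
    """Reference-subsampled variant: per imputation, the imputation model is
    estimated using a random subset of the reference arm of the same size as
    the active-arm completer group, sharpening information anchoring when
    dropout is very heavy."""
    ref_mask = data.arm == spec.reference_arm
    act_idx = np.flatnonzero(~ref_mask)
    ref_idx = np.flatnonzero(ref_mask)
    n_complete = int((data.deviation_visits()[act_idx] == 0).sum())
    n_sub = min(n_complete, ref_idx.size)
    sub_streams = rng.spawn(spec.K)
    draw_streams = rng.spawn(spec.K)
    imp_streams = rng.spawn(spec.K)
    out = []
    for k in range(spec.K):
        chosen = np.sort(sub_streams[k].choice(ref_idx, size=n_sub, replace=False))
        keep = np.sort(np.concatenate([act_idx, chosen]))
        sub = TrialDataset(
            data.patient_id[keep], data.arm[keep], data.outcomes[keep].copy(),
            list(data.visit_labels),
        )
        draw = draw_posterior(sub, 2, pooling=spec.pooling, rng=draw_streams[k])[0]
        draw = PosteriorDraw(params=draw.params, draw_index=k, rng_tag=f"subsample[{k}]")
        out.append(impute_once(data, draw, spec, imp_streams[k]))
    return out


def write_stacked_csv(
    completed: list[CompletedDataset], path, id_col: str = "id", arm_col: str = "arm"
) -> None:
    """Export K completed datasets as one stacked CSV with an imputation index."""
    frames = []
    for k, comp in enumerate(completed, start=1):
        frame = comp.to_frame(id_col, arm_col)
        frame.insert(0, "imputation", k)
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
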