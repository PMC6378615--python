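"""Data model and I/O for wide-format longitudinal trial outcomes.

A trial dataset holds one row per patient: an identifier, an arm label and
outcomes at J scheduled visits (visit 1 = baseline). Post-baseline outcomes
may be missing, but only in a *monotone* fashion: once a patient misses a
visit, all later visits are missing too. This is the dropout structure the
controlled-imputation machinery assumes, so it is enforced at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TrialDataset",
    "PatternSummary",
    "read_trial_csv",
    "write_trial_csv",
    "summarize_patterns",
]


@dataclass
class TrialDataset:
    """Wide-format longitudinal outcomes with monotone missingness.

    Parameters
    ----------
    patient_id : array of str
        One identifier per patient; need not be unique across arms but
        duplicates within the file are preserved as given.
    arm : array of str
        Arm label per patient (e.g. ``"active"``, ``"reference"``).
    outcomes : ndarray, shape (n_patients, J)
        Outcome matrix; missing cells are ``nan``. Baseline (column 0)
        must be fully observed.
    visit_labels : list of str
        Ordered visit labels; ``visit_labels[0]`` is baseline.
    """

    patient_id: np.ndarray
    arm: np.ndarray
    outcomes: np.ndarray
    visit_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.patient_id = np.asarray(self.patient_id, dtype=object)
        self.arm = np.asarray(self.arm, dtype=object)
        self.outcomes = np.asarray(self.outcomes, dtype=float)
        if self.outcomes.ndim != 2:
            raise ValueError("outcomes must be a 2-d (patients x visits) array")
        n, j = self.outcomes.shape
        if j < 2:
            raise ValueError(f"need at least 2 visits (baseline + follow-up), got J={j}")
        if len(self.patient_id) != n or len(self.arm) != n:
            raise ValueError("patient_id, arm and outcomes row counts disagree")
        if not self.visit_labels:
            self.visit_labels = [f"y{k}" for k in range(1, j + 1)]
        if len(self.visit_labels) != j:
            raise ValueError("visit_labels length must equal the number of outcome columns")
        self._validate_missingness()

    def _validate_missingness(self) -> None:
        miss = np.isnan(self.outcomes)
        baseline_missing = np.flatnonzero(miss[:, 0])
        if baseline_missing.size:
            pid = self.patient_id[baseline_missing[0]]
            raise ValueError(f"patient {pid!r}: baseline (visit 1) value is missing")
        # monotone: a missing visit may never be followed by an observed one
        bad = (miss[:, :-1] & ~miss[:, 1:]).any(axis=1)
        if bad.any():
            pid = self.patient_id[np.flatnonzero(bad)[0]]
            raise ValueError(
                f"patient {pid!r}: non-monotone missingness "
                "(an observed visit follows a missing one)"
            )

    @property
    def n_patients(self) -> int:
        return self.outcomes.shape[0]

    @property
    def n_visits(self) -> int:
        return self.outcomes.shape[1]

    @property
    def arms(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.arm:
            seen.setdefault(a, None)
        return list(seen)

    def arm_mask(self, arm: str) -> np.ndarray:
        mask = self.arm == arm
        if not mask.any():
            raise ValueError(f"no patients in arm {arm!r}")
        return mask

    def deviation_visits(self) -> np.ndarray:
        """First missing visit per patient, 1-based; 0 for completers."""
        miss = np.isnan(self.outcomes)
        first = np.argmax(miss, axis=1) + 1
        first[~miss.any(axis=1)] = 0
        return first

    def to_frame(self, id_col: str = "id", arm_col: str = "arm") -> pd.DataFrame:
        frame = pd.DataFrame({id_col: self.patient_id, arm_col: self.arm})
        for k, label in enumerate(self.visit_labels):
            frame[label] = self.outcomes[:, k]
        return frame

    def copy(self) -> "TrialDataset":
        return TrialDataset(
            self.patient_id.copy(),
            self.arm.copy(),
            self.outcomes.copy(),
            list(self.visit_labels),
        )


@dataclass
class PatternSummary:
    """Dropout-pattern counts for one arm.

    ``n_dev[j]`` counts patients whose first missing visit is ``j``
    (1-based, j = 2..J); completers are ``n_complete``.
    """

    arm: str
    n: int
    n_complete: int
    n_dev: dict[int, int]

    def __post_init__(self) -> None:
        if self.n_complete + sum(self.n_dev.values()) != self.n:
            raise ValueError("pattern counts do not partition the arm")

    @property
    def pi_dev(self) -> dict[int, float]:
        return {j: c / self.n for j, c in self.n_dev.items()}

    @property
    def pi_total(self) -> float:
        return sum(self.n_dev.values()) / self.n

    @property
    def n_deviators(self) -> int:
        return sum(self.n_dev.values())


def summarize_patterns(data: TrialDataset, arm: str) -> PatternSummary:
    """Count completers and first-missing-visit patterns in one arm."""
    mask = data.arm_mask(arm)
    dev = data.deviation_visits()[mask]
    counts = {j: int((dev == j).sum()) for j in range(2, data.n_visits + 1)}
    return PatternSummary(
        arm=arm,
        n=int(mask.sum()),
        n_complete=int((dev == 0).sum()),
        n_dev=counts,
    )


def read_trial_csv(
    path,
    id_col: str = "id",
    arm_col: str = "arm",
    outcome_cols: list[str] | None = None,
    na_tokens: tuple[str, ...] = ("", "NA"),
) -> TrialDataset:
    """Read a wide-format trial CSV into a validated :class:`TrialDataset`.

    The default dialect is columns ``id, arm, y1..yJ`` with missing cells
    empty or ``NA``. Row order is preserved. Non-numeric outcome cells,
    missing baselines and non-monotone patterns raise ``ValueError`` naming
    the offending patient or column.
    """
    frame = pd.read_csv(
        path, dtype={id_col: str, arm_col: str},
        na_values=list(na_tokens), keep_default_na=False,
    )
    for col in (id_col, arm_col):
        if col not in frame.columns:
            raise ValueError(f"required column {col!r} not found in {path}")
    if outcome_cols is None:
        outcome_cols = [c for c in frame.columns if c not in (id_col, arm_col)]
    if len(outcome_cols) < 2:
        raise ValueError("need at least two outcome columns (baseline + follow-up)")
    missing_cols = [c for c in outcome_cols if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"outcome columns not found: {missing_cols}")
    if frame[arm_col].isna().any():
        pid = frame.loc[frame[arm_col].isna(), id_col].iloc[0]
        raise ValueError(f"patient {pid!r}: missing arm label")
    try:
        outcomes = frame[outcome_cols].apply(pd.to_numeric, errors="raise").to_numpy(float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric outcome value in {path}: {exc}") from exc
    return TrialDataset(
        patient_id=frame[id_col].to_numpy(object),
        arm=frame[arm_col].to_numpy(object),
        outcomes=outcomes,
        visit_labels=list(outcome_cols),
    )


def write_trial_csv(
    data: TrialDataset,
    path,
    id_col: str = "id",
    arm_col: str = "arm",
    na_token: str = "",
) -> None:
    """Write a dataset in the wide CSV dialect read by :func:`read_trial_csv`."""
    data.to_frame(id_col, arm_col).to_csv(path, index=False, na_rep=na_token)
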