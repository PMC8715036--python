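"""Clinical-history container and delimited-text round trip.

A :class:`ClinicalHistory` is one patient's logged trajectory: an ordered
sequence of (state vector, action vector) steps — vitals/labs and drug doses
at each charting time — plus the terminal outcome, death or discharge.  The
on-disk format is CSV with columns ``patient_id, step_index, s_0..s_{d-1},
a_0..a_{k-1}, outcome`` where ``outcome`` is non-empty only on each
patient's last row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .core import InputError

__all__ = ["OUTCOMES", "ClinicalHistory", "write_histories", "read_histories", "histories_equal"]

OUTCOMES = ("death", "discharge")


@dataclass
class ClinicalHistory:
    """One patient's (state, action) sequence and terminal outcome."""

    patient_id: str
    states: np.ndarray  # (T, d)
    actions: np.ndarray  # (T, k)
    outcome: str
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.states = np.atleast_2d(np.asarray(self.states, dtype=float))
        self.actions = np.atleast_2d(np.asarray(self.actions, dtype=float))
        if self.states.shape[0] == 0:
            raise InputError(f"patient {self.patient_id}: history has no steps")
        if self.states.shape[0] != self.actions.shape[0]:
            raise InputError(
                f"patient {self.patient_id}: {self.states.shape[0]} states "
                f"vs {self.actions.shape[0]} actions"
            )
        if self.outcome not in OUTCOMES:
            raise InputError(f"patient {self.patient_id}: unknown outcome {self.outcome!r}")

    @property
    def n_steps(self) -> int:
        return self.states.shape[0]

    @property
    def state_dim(self) -> int:
        return self.states.shape[1]

    @property
    def action_dim(self) -> int:
        return self.actions.shape[1]


def _check_consistent(histories: Sequence[ClinicalHistory]) -> tuple[int, int]:
    if not histories:
        raise InputError("no histories given")
    d, k = histories[0].state_dim, histories[0].action_dim
    for h in histories:
        if h.state_dim != d or h.action_dim != k:
            raise InputError(
                f"patient {h.patient_id}: dimensions ({h.state_dim}, {h.action_dim}) "
                f"differ from ({d}, {k})"
            )
    return d, k


def write_histories(histories: Sequence[ClinicalHistory], path: str) -> None:
    """Write histories to CSV; floats carry 12 significant digits."""

    d, k = _check_consistent(histories)
    rows = []
    for h in histories:
        for t in range(h.n_steps):
            row: dict[str, Any] = {"patient_id": h.patient_id, "step_index": t}
            for j in range(d):
                row[f"s_{j}"] = h.states[t, j]
            for j in range(k):
                row[f"a_{j}"] = h.actions[t, j]
            row["outcome"] = h.outcome if t == h.n_steps - 1 else ""
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def read_histories(path: str) -> list[ClinicalHistory]:
    """Parse a history CSV, validating dimensions and outcome placement."""

    try:
        df = pd.read_csv(path, dtype={"patient_id": str, "outcome": str})
    except pd.errors.EmptyDataError:
        raise InputError(f"{path}: empty history file") from None
    if df.empty:
        raise InputError(f"{path}: history file has no rows")
    required = {"patient_id", "step_index", "outcome"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    s_cols = sorted((c for c in df.columns if c.startswith("s_")), key=lambda c: int(c[2:]))
    a_cols = sorted((c for c in df.columns if c.startswith("a_")), key=lambda c: int(c[2:]))
    if not s_cols or not a_cols:
        raise InputError(f"{path}: need at least one s_* and one a_* column")
    histories: list[ClinicalHistory] = []
    for pid, group in df.groupby("patient_id", sort=False):
        group = group.sort_values("step_index")
        expected = np.arange(len(group))
        if not np.array_equal(group["step_index"].to_numpy(), expected):
            raise InputError(f"patient {pid}: step_index not contiguous from 0")
        states = group[s_cols].to_numpy(dtype=float)
        actions = group[a_cols].to_numpy(dtype=float)
        if np.isnan(states).any() or np.isnan(actions).any():
            bad = int(group.index[np.isnan(group[s_cols + a_cols].to_numpy()).any(axis=1)][0])
            raise InputError(f"patient {pid}: non-numeric state/action near file row {bad + 2}")
        outcomes = group["outcome"].fillna("").to_numpy()
        if any(o != "" for o in outcomes[:-1]):
            raise InputError(f"patient {pid}: outcome set before the last row")
        if outcomes[-1] == "":
            raise InputError(f"patient {pid}: outcome missing on last row")
        histories.append(ClinicalHistory(str(pid), states, actions, outcomes[-1]))
    return histories


def histories_equal(
    a: Sequence[ClinicalHistory], b: Sequence[ClinicalHistory], rtol: float = 1e-9
) -> bool:
    """Equality up to floating-point formatting (12 significant digits)."""

    if len(a) != len(b):
        return False
    for ha, hb in zip(a, b):
        if ha.patient_id != hb.patient_id or ha.outcome != hb.outcome:
            return False
        if ha.states.shape != hb.states.shape or ha.actions.shape != hb.actions.shape:
            return False
        if not np.allclose(ha.states, hb.states, rtol=rtol, atol=1e-12):
            return False
        if not np.allclose(ha.actions, hb.actions, rtol=rtol, atol=1e-12):
            return False
    return True
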