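"""Absolute neutrophil count (ANC) dynamics and schedule feasibility.

Neutropenia (ANC below 1000/mm^3) is the dose-limiting toxicity shared by
the three TKIs.  The ANC is tracked by a truncated linear monthly recursion:
each drug month depletes the count at a drug-specific rate, each holiday
month recovers it, capped at the normal ceiling:

    y^{m+1} = min(y^m + b_anc * z^{m,0} - sum_j d_anc_j * z^{m,j}, U_anc)

Two feasibility readings of the neutropenia threshold L_anc are supported:

* ``hard_bound`` — the ANC must never fall below L_anc (the natural MILP
  constraint, default);
* ``trigger`` — a drug may only be taken in a month whose starting ANC is
  at or above L_anc (a holiday is mandatory once the count has dipped).

hard_bound is strictly stronger than trigger.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import TreatmentSchedule

__all__ = ["ANCParams", "ANCSeries", "anc_step", "anc_trajectory", "check_feasible"]

SEMANTICS = ("hard_bound", "trigger")


@dataclass(frozen=True)
class ANCParams:
    """Rate constants of the monthly ANC recursion (all per mm^3 per month).

    Defaults are the published clinical estimates: nilotinib depletes fastest
    (350), then dasatinib (300), then imatinib (250); one holiday month
    recovers 2000 but never above the normal ceiling of 3000; neutropenia is
    an ANC below 1000.
    """

    d_anc: tuple[float, float, float] = (350.0, 300.0, 250.0)  # nilotinib, dasatinib, imatinib
    b_anc: float = 2000.0
    L_anc: float = 1000.0
    U_anc: float = 3000.0
    y0: float = 3000.0

    def __post_init__(self) -> None:
        if not 0 < self.L_anc < self.U_anc:
            raise ValueError("need 0 < L_anc < U_anc")
        if self.y0 > self.U_anc:
            raise ValueError("initial ANC cannot exceed the normal ceiling")
        if self.b_anc <= 0 or any(d <= 0 for d in self.d_anc):
            raise ValueError("ANC rates must be positive")

    def depletion(self, drug_j: int) -> float:
        return self.d_anc[drug_j - 1]


@dataclass
class ANCSeries:
    """ANC values y^0..y^M along a schedule."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __getitem__(self, m):
        return self.values[m]

    def __len__(self):
        return len(self.values)

    def min(self) -> float:
        return float(self.values.min())


def anc_step(y: float, decision: int, p: ANCParams) -> float:
    """One month of the ANC recursion under the given decision."""
    if decision not in (0, 1, 2, 3):
        raise ValueError(f"decision must be in 0..3, got {decision}")
    if decision == 0:
        return min(y + p.b_anc, p.U_anc)
    return y - p.depletion(decision)


def anc_trajectory(schedule: TreatmentSchedule, p: ANCParams) -> ANCSeries:
    """Fold the recursion over a schedule from the initial count y0."""
    values = np.empty(len(schedule) + 1)
    values[0] = p.y0
    for m, decision in enumerate(schedule):
        values[m + 1] = anc_step(values[m], decision, p)
    return ANCSeries(values)


def check_feasible(
    schedule: TreatmentSchedule,
    p: ANCParams,
    semantics: str = "hard_bound",
) -> tuple[bool, int | None]:
    """Toxicity feasibility of a schedule; returns (verdict, first violating month).

    hard_bound: every y^m (m = 0..M) must be >= L_anc.
    trigger: any month starting below L_anc must be a holiday.
    """
    if semantics not in SEMANTICS:
        raise ValueError(f"semantics must be one of {SEMANTICS}, got {semantics!r}")
    series = anc_trajectory(schedule, p)
    if semantics == "hard_bound":
        below = np.nonzero(series.values < p.L_anc)[0]
        if below.size:
            return False, int(below[0])
        return True, None
    for m, decision in enumerate(schedule):
        if series.values[m] < p.L_anc and decision != 0:
            return False, m
    return True, None
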