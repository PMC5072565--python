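"""The Optimal Treatment Plan (OTP) solver.

Chooses one mode per month — holiday, nilotinib, dasatinib or imatinib — to
minimize the leukemic burden at (or averaged over) a fixed horizon, subject
to optional neutrophil-toxicity constraints.

Because the monthly update of the non-stem compartments is affine in the
state for each drug, the switched dynamics are linearized exactly: binary
mode indicators ``z^{m,j}``, continuous states ``x^m`` and auxiliary
products ``w^{m,j} = z^{m,j} x^m`` (big-M bounded-product constraints with
per-month reachable-state bounds) give a mixed-integer *linear* program,
solved here through HiGHS (:func:`scipy.optimize.milp`).  An exhaustive
enumeration oracle over all 4^M schedules is provided for verification at
small horizons.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .model import DRUG_NAMES, N_DRUGS, DensityDependence, DrugRateTable, StemEffectConfig, SystemState
from .simulate import (
    MonthlyAffineMaps,
    Trajectory,
    TreatmentSchedule,
    average_burden,
    leukemic_burden,
    leukemic_fraction,
    propagate_affine,
    simulate_schedule_ode,
)
from .toxicity import ANCParams, anc_trajectory, check_feasible

__all__ = [
    "OTPInstance",
    "OTPSolution",
    "state_upper_bounds",
    "build_milp",
    "solve_otp",
    "brute_force_otp",
    "compare_schedules",
    "evaluate_schedule",
]

OBJECTIVES = ("terminal_burden", "average_burden")
TOXICITY_MODES = ("off", "hard_bound", "trigger")

# Cell counts reach ~1e12; scaling the state variables keeps the MILP
# coefficient range manageable for the solver.  Values are unscaled on report.
STATE_SCALE = 1e9
# Tiny relative slack on the reachable-state bounds so that solver-side
# floating-point round-off cannot render a truly reachable state infeasible.
BOUND_MARGIN = 1e-7

BRUTE_FORCE_CAP = 10  # 4^10 ~ 1e6 schedules


@dataclass
class OTPInstance:
    """One optimization problem: initial state, dynamics, horizon, objective, toxicity."""

    x0: SystemState
    maps: MonthlyAffineMaps
    horizon_M: int
    objective: str = "terminal_burden"
    toxicity: str = "off"
    anc: ANCParams | None = None
    time_limit: float | None = None  # seconds
    mip_gap: float = 0.0

    def __post_init__(self) -> None:
        if self.objective not in OBJECTIVES:
            raise ValueError(f"objective must be one of {OBJECTIVES}")
        if self.toxicity not in TOXICITY_MODES:
            raise ValueError(f"toxicity must be one of {TOXICITY_MODES}")
        if self.horizon_M > self.maps.horizon_M:
            raise ValueError(
                f"horizon {self.horizon_M} exceeds precomputed map horizon {self.maps.horizon_M}"
            )
        if self.toxicity != "off" and self.anc is None:
            self.anc = ANCParams()


@dataclass
class OTPSolution:
    """A treatment plan with its objective value and solver status."""

    schedule: TreatmentSchedule | None
    objective_value: float
    status: str  # optimal | feasible | infeasible | time_limit
    bound_gap: float = 0.0
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "schedule": str(self.schedule) if self.schedule is not None else None,
            "objective_value": self.objective_value,
            "status": self.status,
            "gap": self.bound_gap,
            "message": self.message,
        }


# ---------------------------------------------------------------------------
# Schedule evaluation (shared by the MILP report and the enumeration oracle)
# ---------------------------------------------------------------------------

def _stem_leukemic_burden(maps: MonthlyAffineMaps, m: int) -> float:
    """Schedule-independent leukemic stem-cell count at month boundary m."""
    return float(maps.stem_traj(m * maps.delta_t)[1:].sum())


def evaluate_schedule(
    x0: SystemState,
    schedule: TreatmentSchedule,
    maps: MonthlyAffineMaps,
    objective: str = "terminal_burden",
) -> float:
    """Objective value of a schedule under the affine dynamics (cells)."""
    monthly = propagate_affine(x0, schedule, maps)
    if objective == "terminal_burden":
        return leukemic_burden(monthly[-1])
    return average_burden(monthly)


# ---------------------------------------------------------------------------
# Reachable-state bounds (big-M prerequisites)
# ---------------------------------------------------------------------------

def state_upper_bounds(
    maps: MonthlyAffineMaps,
    x0: SystemState,
    horizon_M: int,
    safety_factor: float = 2.0,
) -> np.ndarray:
    """Componentwise upper bounds U^m on every reachable non-stem state.

    Shape (M+1, n_types, 3).  Valid interval propagation
    ``U^{m+1} = max_j (E_j U^m + f_{m,j})`` holds because E (a matrix
    exponential of a Metzler matrix) and f (integral of a nonnegative
    forcing) are componentwise nonnegative; if that structure is ever
    violated the bound falls back to propagating componentwise magnitudes
    with a safety factor.
    """
    n = x0.n_types
    U = np.empty((horizon_M + 1, n, 3))
    U[0] = x0.abundance[1:].T
    E, f = maps.E, maps.f
    nonneg = bool(np.all(E >= 0) and np.all(f >= -1e-12))
    for m in range(horizon_M):
        if nonneg:
            cand = np.einsum("jicd,id->jic", E, U[m]) + np.clip(f[m], 0.0, None)
            U[m + 1] = cand.max(axis=0)
        else:  # pragma: no cover - positive-rate models never reach this
            cand = np.einsum("jicd,id->jic", np.abs(E), U[m]) + np.abs(f[m])
            U[m + 1] = safety_factor * cand.max(axis=0)
    return U


# ---------------------------------------------------------------------------
# Solver-agnostic MILP description
# ---------------------------------------------------------------------------

class MILPModel:
    """A minimal linear-program builder (variables, linear constraints, objective).

    Kept solver-agnostic: :meth:`to_scipy` emits the matrices consumed by
    ``scipy.optimize.milp`` (HiGHS) and :meth:`write_lp` exports the model
    in LP file format for external solvers.
    """

    def __init__(self) -> None:
        self.names: list[str] = []
        self.lb: list[float] = []
        self.ub: list[float] = []
        self.integer: list[bool] = []
        self.obj: dict[int, float] = {}
        self.obj_const: float = 0.0
        # constraints as (coeffs {var: val}, lower, upper)
        self.constraints: list[tuple[dict[int, float], float, float]] = []

    def add_var(self, name: str, lb: float = 0.0, ub: float = np.inf, integer: bool = False) -> int:
        self.names.append(name)
        self.lb.append(lb)
        self.ub.append(ub)
        self.integer.append(integer)
        return len(self.names) - 1

    def add_constraint(self, coeffs: dict[int, float], lower: float, upper: float) -> None:
        self.constraints.append((coeffs, lower, upper))

    def set_objective_coeff(self, var: int, coeff: float) -> None:
        self.obj[var] = self.obj.get(var, 0.0) + coeff

    @property
    def n_vars(self) -> int:
        return len(self.names)

    def to_scipy(self):
        c = np.zeros(self.n_vars)
        for v, coef in self.obj.items():
            c[v] = coef
        rows, cols, vals, lo, hi = [], [], [], [], []
        for r, (coeffs, lower, upper) in enumerate(self.constraints):
            for v, coef in coeffs.items():
                rows.append(r)
                cols.append(v)
                vals.append(coef)
            lo.append(lower)
            hi.append(upper)
        A = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(self.constraints), self.n_vars)
        )
        constraints = LinearConstraint(A, np.asarray(lo), np.asarray(hi))
        bounds = Bounds(np.asarray(self.lb), np.asarray(self.ub))
        integrality = np.asarray(self.integer, dtype=int)
        return c, constraints, bounds, integrality

    def write_lp(self, path) -> None:
        """Export in CPLEX LP file format."""
        def term(coef: float, name: str) -> str:
            sign = "+" if coef >= 0 else "-"
            return f"{sign} {abs(coef):.17g} {name}"

        lines = ["Minimize", " obj: " + " ".join(term(c, self.names[v]) for v, c in sorted(self.obj.items()))]
        lines.append("Subject To")
        for r, (coeffs, lower, upper) in enumerate(self.constraints):
            expr = " ".join(term(c, self.names[v]) for v, c in sorted(coeffs.items()))
            if lower == upper:
                lines.append(f" c{r}: {expr} = {lower:.17g}")
            else:
                if np.isfinite(upper):
                    lines.append(f" c{r}u: {expr} <= {upper:.17g}")
                if np.isfinite(lower):
                    lines.append(f" c{r}l: {expr} >= {lower:.17g}")
        lines.append("Bounds")
        for v, name in enumerate(self.names):
            lines.append(f" {self.lb[v]:.17g} <= {name} <= {self.ub[v]:.17g}")
        lines.append("Binaries")
        lines.append(" " + " ".join(n for v, n in enumerate(self.names) if self.integer[v]))
        lines.append("End")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def build_milp(instance: OTPInstance) -> tuple[MILPModel, dict]:
    """Assemble the MILP for an OTP instance.

    Returns the model and an index dictionary mapping (kind, month, ...) to
    variable columns, used to decode solutions.  States and products are in
    units of ``STATE_SCALE`` cells; ANC variables in cells/mm^3.
    """
    M = instance.horizon_M
    maps = instance.maps
    n = instance.x0.n_types
    ncoord = 3 * n  # flattened (type, layer-2..4) coordinates

    U = state_upper_bounds(maps, instance.x0, M) / STATE_SCALE
    U_flat = U.reshape(M + 1, ncoord) * (1.0 + BOUND_MARGIN)
    x0_flat = instance.x0.abundance[1:].T.reshape(ncoord) / STATE_SCALE
    # E as (drug, ncoord, ncoord) block-diagonal over types; f as (M, drug, ncoord)
    E_big = np.zeros((N_DRUGS, ncoord, ncoord))
    for j in range(N_DRUGS):
        for i in range(n):
            E_big[j, 3 * i : 3 * i + 3, 3 * i : 3 * i + 3] = maps.E[j, i]
    f_flat = maps.f.reshape(maps.horizon_M, N_DRUGS, ncoord) / STATE_SCALE

    model = MILPModel()
    z = np.empty((M, N_DRUGS), dtype=int)
    for m in range(M):
        for j in range(N_DRUGS):
            z[m, j] = model.add_var(f"z_{m}_{j}", 0.0, 1.0, integer=True)
    x = np.empty((M + 1, ncoord), dtype=object)  # x[0] is the fixed initial state
    x[0] = None
    for m in range(1, M + 1):
        for c in range(ncoord):
            x[m, c] = model.add_var(f"x_{m}_{c}", 0.0, float(U_flat[m, c]))
    w = np.empty((M, N_DRUGS, ncoord), dtype=int)
    for m in range(M):
        for j in range(N_DRUGS):
            for c in range(ncoord):
                w[m, j, c] = model.add_var(f"w_{m}_{j}_{c}", 0.0, float(U_flat[m, c]))

    # one decision per month
    for m in range(M):
        model.add_constraint({int(z[m, j]): 1.0 for j in range(N_DRUGS)}, 1.0, 1.0)

    # bounded-product linearization of w^{m,j} = z^{m,j} * x^m
    for m in range(M):
        for j in range(N_DRUGS):
            for c in range(ncoord):
                wv, zv = int(w[m, j, c]), int(z[m, j])
                Umc = float(U_flat[m, c])
                # w <= U z
                model.add_constraint({wv: 1.0, zv: -Umc}, -np.inf, 0.0)
                if m == 0:
                    # x^0 constant: w <= x0 and w >= x0 - U (1 - z)
                    model.add_constraint({wv: 1.0}, -np.inf, float(x0_flat[c]))
                    model.add_constraint({wv: -1.0, zv: Umc}, -np.inf, Umc - float(x0_flat[c]))
                else:
                    xv = int(x[m, c])
                    model.add_constraint({wv: 1.0, xv: -1.0}, -np.inf, 0.0)
                    model.add_constraint({xv: 1.0, wv: -1.0, zv: Umc}, -np.inf, Umc)

    # dynamics: x^{m+1} = sum_j (E_j w^{m,j} + f_{m,j} z^{m,j})
    for m in range(M):
        for c in range(ncoord):
            coeffs: dict[int, float] = {int(x[m + 1, c]): -1.0}
            for j in range(N_DRUGS):
                for c2 in range(ncoord):
                    val = float(E_big[j, c, c2])
                    if val != 0.0:
                        coeffs[int(w[m, j, c2])] = coeffs.get(int(w[m, j, c2]), 0.0) + val
                fval = float(f_flat[m, j, c])
                if fval != 0.0:
                    coeffs[int(z[m, j])] = coeffs.get(int(z[m, j]), 0.0) + fval
            model.add_constraint(coeffs, 0.0, 0.0)

    index: dict = {"z": z, "x": x, "w": w}

    # toxicity: ANC recursion upper bounds (larger y only relaxes feasibility)
    if instance.toxicity != "off":
        p = instance.anc
        y_min = p.y0 - M * max(p.d_anc)
        y = np.empty(M + 1, dtype=object)
        y[0] = None  # fixed at p.y0
        lb_y = p.L_anc if instance.toxicity == "hard_bound" else y_min
        for m in range(1, M + 1):
            y[m] = model.add_var(f"y_{m}", lb_y, p.U_anc)
        for m in range(M):
            # y^{m+1} <= y^m + b z^{m,0} - sum_j d_j z^{m,j}
            coeffs = {int(y[m + 1]): 1.0, int(z[m, 0]): -p.b_anc}
            for j in (1, 2, 3):
                coeffs[int(z[m, j])] = p.depletion(j)
            rhs = p.y0 if m == 0 else 0.0
            if m > 0:
                coeffs[int(y[m])] = -1.0
            model.add_constraint(coeffs, -np.inf, rhs)
        if instance.toxicity == "trigger":
            # a drug month must start at or above the neutropenia threshold:
            # y^m >= L (1 - z^{m,0}) - (big-M via y_min)
            for m in range(1, M):
                model.add_constraint(
                    {int(y[m]): 1.0, int(z[m, 0]): p.L_anc - y_min},
                    p.L_anc,
                    np.inf,
                )
        index["y"] = y

    # objective (scaled cells); schedule-independent stem-cell burden enters
    # as a constant
    if instance.objective == "terminal_burden":
        for i in range(1, n):
            for c in range(3 * i, 3 * i + 3):
                model.set_objective_coeff(int(x[M, c]), 1.0)
        model.obj_const = _stem_leukemic_burden(maps, M) / STATE_SCALE
    else:
        for m in range(1, M + 1):
            for i in range(1, n):
                for c in range(3 * i, 3 * i + 3):
                    model.set_objective_coeff(int(x[m, c]), 1.0 / M)
        model.obj_const = (
            sum(_stem_leukemic_burden(maps, m) for m in range(1, M + 1)) / M / STATE_SCALE
        )
    return model, index


def solve_otp(instance: OTPInstance) -> OTPSolution:
    """Solve an OTP instance to (certified) optimality with HiGHS.

    The reported objective is recomputed from the returned schedule by affine
    propagation, so it is consistent with the simulator to round-off.
    """
    if (
        instance.toxicity == "hard_bound"
        and instance.anc is not None
        and instance.anc.y0 < instance.anc.L_anc
    ):
        return OTPSolution(
            None, np.inf, "infeasible", np.inf,
            "initial ANC already below the neutropenia threshold (month 0)",
        )
    model, index = build_milp(instance)
    c, constraints, bounds, integrality = model.to_scipy()
    options: dict = {
        "mip_rel_gap": instance.mip_gap,
        # tight feasibility tolerances: big-M products at 1e3 scale must not
        # leak schedule-inconsistent state into the dynamics
        "presolve": True,
    }
    if instance.time_limit is not None:
        options["time_limit"] = instance.time_limit
    res = milp(
        c,
        constraints=constraints,
        bounds=bounds,
        integrality=integrality,
        options=options,
    )

    if res.status == 2 or (res.status != 0 and res.x is None and res.status != 1):
        # distinguish genuinely toxic instances from solver failure: under
        # hard_bound the most ANC-friendly plan is the all-holiday schedule
        msg = res.message
        if instance.toxicity == "hard_bound" and instance.anc is not None:
            all_holiday = TreatmentSchedule((0,) * instance.horizon_M)
            ok, month = check_feasible(all_holiday, instance.anc, "hard_bound")
            if not ok:
                msg = f"no schedule can keep ANC above threshold (first forced violation by month {month})"
        return OTPSolution(None, np.inf, "infeasible", np.inf, msg)
    if res.x is None:
        return OTPSolution(None, np.inf, "time_limit", np.inf, res.message)

    zvals = res.x[index["z"].reshape(-1)].reshape(instance.horizon_M, N_DRUGS)
    schedule = TreatmentSchedule(tuple(int(j) for j in zvals.argmax(axis=1)))
    objective = evaluate_schedule(instance.x0, schedule, instance.maps, instance.objective)
    gap = float(res.mip_gap) if res.mip_gap is not None else 0.0
    status = "optimal" if res.status == 0 else "time_limit"
    if status == "time_limit" and gap == 0.0:
        status = "optimal"
    return OTPSolution(schedule, objective, status, gap, res.message)


# ---------------------------------------------------------------------------
# Exhaustive enumeration oracle
# ---------------------------------------------------------------------------

def _all_schedules(M: int) -> np.ndarray:
    """All 4^M schedules as an array (4^M, M), in lexicographic order."""
    grids = np.meshgrid(*([np.arange(N_DRUGS)] * M), indexing="ij")
    return np.stack([g.reshape(-1) for g in grids], axis=1)


def _toxicity_mask(schedules: np.ndarray, p: ANCParams, semantics: str) -> np.ndarray:
    """Vectorized feasibility of every schedule row under the ANC recursion."""
    S, M = schedules.shape
    y = np.full(S, p.y0)
    ok = np.ones(S, dtype=bool)
    if semantics == "hard_bound" and p.y0 < p.L_anc:
        return np.zeros(S, dtype=bool)
    depl = np.array([0.0, *p.d_anc])
    for m in range(M):
        dec = schedules[:, m]
        if semantics == "trigger":
            ok &= (y >= p.L_anc) | (dec == 0)
        holiday = dec == 0
        y = np.where(holiday, np.minimum(y + p.b_anc, p.U_anc), y - depl[dec])
        if semantics == "hard_bound":
            ok &= y >= p.L_anc
    return ok


def brute_force_otp(instance: OTPInstance, cap: int = BRUTE_FORCE_CAP) -> OTPSolution:
    """Evaluate every schedule by affine propagation and return the minimum.

    Ties are broken lexicographically (lower drug index earlier wins).  Only
    intended for small horizons (4^M schedules, default cap M <= 10).
    """
    M = instance.horizon_M
    if M > cap:
        raise ValueError(f"brute force limited to horizon <= {cap} (got {M})")
    maps = instance.maps
    n = instance.x0.n_types
    schedules = _all_schedules(M)
    S = schedules.shape[0]

    if instance.toxicity != "off":
        feasible = _toxicity_mask(schedules, instance.anc, instance.toxicity)
        if not feasible.any():
            return OTPSolution(None, np.inf, "infeasible", np.inf, "no schedule passes the toxicity rule")
        schedules = schedules[feasible]
        S = schedules.shape[0]

    states = np.broadcast_to(instance.x0.abundance[1:].T, (S, n, 3)).copy()
    burden_sum = np.zeros(S)
    for m in range(M):
        for j in range(N_DRUGS):
            sel = schedules[:, m] == j
            if not sel.any():
                continue
            states[sel] = np.einsum("icd,sid->sic", maps.E[j], states[sel]) + maps.f[m, j]
        if instance.objective == "average_burden":
            burden_sum += states[:, 1:, :].sum(axis=(1, 2)) + _stem_leukemic_burden(maps, m + 1)

    if instance.objective == "terminal_burden":
        objectives = states[:, 1:, :].sum(axis=(1, 2)) + _stem_leukemic_burden(maps, M)
    else:
        objectives = burden_sum / M
    best = int(np.argmin(objectives))  # first minimum = lexicographically smallest
    schedule = TreatmentSchedule(tuple(int(d) for d in schedules[best]))
    objective = evaluate_schedule(instance.x0, schedule, maps, instance.objective)
    return OTPSolution(schedule, objective, "optimal", 0.0)


# ---------------------------------------------------------------------------
# Schedule comparison (ODE-based reporting)
# ---------------------------------------------------------------------------

def compare_schedules(
    schedules: Sequence[TreatmentSchedule],
    x0: SystemState,
    rates: DrugRateTable,
    dd: DensityDependence,
    se: StemEffectConfig | None = None,
    report_months: Sequence[int] = (24, 36),
    labels: Sequence[str] | None = None,
    delta_t: float = 30.0,
) -> pd.DataFrame:
    """Tabulate terminal/average burdens and leukemic percentages per schedule.

    Uses the full ODE path (not the affine shortcut), so it is also valid
    when the stem effect is enabled.
    """
    if labels is None:
        labels = [str(s) for s in schedules]
    rows = []
    for label, sched in zip(labels, schedules):
        traj = simulate_schedule_ode(x0, sched, rates, dd, se, delta_t=delta_t)
        row = {
            "label": label,
            "schedule": str(sched),
            "terminal_burden": leukemic_burden(traj.monthly_states[-1]),
            "average_burden": average_burden(traj),
        }
        for month in report_months:
            if month <= len(sched):
                state = traj.monthly_states[month]
                row[f"burden_m{month}"] = leukemic_burden(state)
                row[f"leukemic_pct_m{month}"] = 100.0 * leukemic_fraction(state)
        rows.append(row)
    return pd.DataFrame(rows)
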