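"""Propagation of the cell hierarchy under monthly treatment schedules.

Two propagation paths are provided:

* :func:`simulate_schedule_ode` — reference path: piecewise stiff ODE
  integration, switching the vector field at month boundaries.
* :func:`propagate_affine` — fast path used by the optimizer: because layers
  2-4 are linear and (in the baseline model) the stem layer evolves
  independently of the schedule, the exact month-m update of the non-stem
  compartments under drug j is an affine map ``y -> E_j y + f_{m,j}``, with
  ``E_j`` a matrix exponential and ``f_{m,j}`` the stem forcing accumulated
  over the month.  The maps are exact up to quadrature, so the two paths
  agree to integrator tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .model import (
    N_DRUGS,
    N_LAYERS,
    ODE_ATOL,
    ODE_METHOD,
    ODE_RTOL,
    DensityDependence,
    DrugRateTable,
    ModelConfig,
    StemEffectConfig,
    StemTrajectory,
    SystemState,
    ode_rhs,
    stem_cell_trajectory,
)

__all__ = [
    "TreatmentSchedule",
    "Trajectory",
    "MonthlyAffineMaps",
    "simulate_schedule_ode",
    "precompute_affine_maps",
    "propagate_affine",
    "leukemic_burden",
    "average_burden",
    "derive_initial_conditions",
]


@dataclass(frozen=True)
class TreatmentSchedule:
    """A length-M sequence of monthly decisions in {0, 1, 2, 3}.

    0 = drug holiday, 1 = nilotinib, 2 = dasatinib, 3 = imatinib.  Exactly
    one decision per month, so the sequence encoding itself enforces the
    one-drug-at-a-time constraint of the optimization model.
    """

    decisions: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "decisions", tuple(int(d) for d in self.decisions))
        if any(d not in range(N_DRUGS) for d in self.decisions):
            raise ValueError("schedule entries must be in {0 (holiday), 1, 2, 3}")

    @classmethod
    def from_string(cls, text: str) -> "TreatmentSchedule":
        """Parse the notation used in printed schedules, e.g. ``"2 2 2 1 1"`` or ``"2,2,2,1,1"``."""
        tokens = text.replace(",", " ").split()
        if not tokens:
            raise ValueError("empty schedule string")
        try:
            decisions = tuple(int(t) for t in tokens)
        except ValueError as exc:
            raise ValueError(f"malformed schedule token in {text!r}") from exc
        return cls(decisions)

    @classmethod
    def monotherapy(cls, drug: int, months: int) -> "TreatmentSchedule":
        return cls((drug,) * months)

    def __str__(self) -> str:
        return " ".join(str(d) for d in self.decisions)

    def __len__(self) -> int:
        return len(self.decisions)

    def __iter__(self):
        return iter(self.decisions)


@dataclass
class Trajectory:
    """Simulated cell dynamics: a fine time grid plus month-boundary snapshots."""

    times: np.ndarray  # days, strictly increasing
    states: np.ndarray  # shape (len(times), 4, n_types)
    monthly_states: np.ndarray  # shape (M + 1, 4, n_types)
    schedule: TreatmentSchedule
    delta_t: float = 30.0

    def state_at_month(self, m: int) -> SystemState:
        return SystemState(self.monthly_states[m].copy(), m * self.delta_t)


def leukemic_burden(state: SystemState | np.ndarray) -> float:
    """Total leukemic cells: all layers, every type except normal (type 1)."""
    x = state.abundance if isinstance(state, SystemState) else np.asarray(state)
    return float(x[:, 1:].sum())


def leukemic_fraction(state: SystemState | np.ndarray) -> float:
    """Leukemic share of the total cell population (0..1)."""
    x = state.abundance if isinstance(state, SystemState) else np.asarray(state)
    return float(x[:, 1:].sum() / x.sum())


def average_burden(traj: Trajectory | np.ndarray) -> float:
    """Mean leukemic burden over the month-boundary states x^1..x^M.

    x^0 is excluded: no treatment decision affects it.  This is the discrete
    version of minimizing the average burden over the horizon.
    """
    monthly = traj.monthly_states if isinstance(traj, Trajectory) else np.asarray(traj)
    if monthly.shape[0] < 2:
        raise ValueError("need at least one treated month to average over")
    return float(monthly[1:, :, 1:].sum(axis=(1, 2)).mean())


def continuous_average_burden(traj: Trajectory) -> float:
    """Time-integral average of the leukemic burden over the simulated grid."""
    burdens = traj.states[:, :, 1:].sum(axis=(1, 2))
    return float(np.trapezoid(burdens, traj.times) / (traj.times[-1] - traj.times[0]))


def simulate_schedule_ode(
    x0: SystemState,
    schedule: TreatmentSchedule,
    rates: DrugRateTable,
    dd: DensityDependence,
    se: StemEffectConfig | None = None,
    delta_t: float = 30.0,
    points_per_month: int = 10,
    rtol: float = ODE_RTOL,
    atol: float = ODE_ATOL,
) -> Trajectory:
    """Reference propagation: integrate the full stiff ODE month by month.

    The vector field switches at month boundaries according to the schedule;
    the end state of month m is the initial state of month m+1.
    """
    n = x0.n_types
    shape = (N_LAYERS, n)

    def rhs_for(drug_j):
        def rhs(t, y):
            return ode_rhs(SystemState(y.reshape(shape), t), drug_j, rates, dd, se).ravel()

        return rhs

    times = [0.0]
    states = [x0.abundance.copy()]
    monthly = [x0.abundance.copy()]
    y = x0.abundance.ravel().copy()
    for m, drug_j in enumerate(schedule):
        t0, t1 = m * delta_t, (m + 1) * delta_t
        t_eval = np.linspace(t0, t1, points_per_month + 1)[1:]
        sol = solve_ivp(
            rhs_for(drug_j), (t0, t1), y, method=ODE_METHOD,
            rtol=rtol, atol=atol, t_eval=t_eval,
        )
        if not sol.success or not np.all(np.isfinite(sol.y)):
            raise RuntimeError(f"integration failed in month {m} (drug {drug_j}): {sol.message}")
        times.extend(sol.t.tolist())
        states.extend(sol.y.T.reshape(-1, *shape))
        y = sol.y[:, -1].copy()
        monthly.append(y.reshape(shape).copy())
    return Trajectory(
        times=np.asarray(times),
        states=np.asarray(states),
        monthly_states=np.asarray(monthly),
        schedule=schedule,
        delta_t=delta_t,
    )


@dataclass
class MonthlyAffineMaps:
    """Exact monthly affine updates for the linear layers (PC, DC, TC).

    For type i under drug j, the layer 2-4 subvector y satisfies
    ``dy/dt = A_{j,i} y + g_i(t)`` with lower-bidiagonal ``A`` and stem
    forcing ``g_i(t) = (b2_i^j x1_i(t), 0, 0)``.  Over one month,

        ``y(t_{m+1}) = E_{j,i} y(t_m) + f_{m,j,i}``

    where ``E = expm(A * delta_t)`` (drug-dependent only) and ``f`` is the
    forcing integral, evaluated by Gauss-Legendre quadrature on the dense
    stem trajectory.
    """

    E: np.ndarray  # shape (n_drugs, n_types, 3, 3)
    f: np.ndarray  # shape (M, n_drugs, n_types, 3)
    delta_t: float
    stem_traj: StemTrajectory

    @property
    def horizon_M(self) -> int:
        return self.f.shape[0]

    @property
    def n_types(self) -> int:
        return self.E.shape[1]


def _lower_bidiagonal(rates: DrugRateTable, i: int, j: int) -> np.ndarray:
    """Rate matrix of the layer 2-4 subsystem for type i under drug j."""
    b, d = rates.birth[:, i, j], rates.death[:, i, j]
    return np.array(
        [
            [-d[1], 0.0, 0.0],
            [b[2], -d[2], 0.0],
            [0.0, b[3], -d[3]],
        ]
    )


def precompute_affine_maps(
    rates: DrugRateTable,
    dd: DensityDependence,
    stem_traj: StemTrajectory,
    horizon_M: int,
    delta_t: float = 30.0,
    quad_nodes: int = 48,
) -> MonthlyAffineMaps:
    """Build the exact affine month maps for every (month, drug, type).

    Requires the baseline (schedule-independent) stem trajectory covering
    ``[0, M * delta_t]``.  The forcing integral
    ``f = int_0^dt expm(A (dt - s)) g(t_m + s) ds`` is computed with fixed
    Gauss-Legendre nodes; the matrix-exponential kernels at the nodes are
    shared across months, so only the stem abundances vary per month.
    """
    n = rates.n_types
    if stem_traj.t_end < horizon_M * delta_t - 1e-9:
        raise ValueError(
            f"stem trajectory covers [0, {stem_traj.t_end}] but "
            f"{horizon_M} months require {horizon_M * delta_t} days"
        )
    nodes, weights = np.polynomial.legendre.leggauss(quad_nodes)
    s = 0.5 * delta_t * (nodes + 1.0)  # quadrature abscissae in [0, delta_t]
    w = 0.5 * delta_t * weights

    E = np.empty((N_DRUGS, n, 3, 3))
    # kernel[j, i, k, :] = w_k * b2_i^j * expm(A (delta_t - s_k))[:, 0]
    kernel = np.empty((N_DRUGS, n, quad_nodes, 3))
    for j in range(N_DRUGS):
        for i in range(n):
            A = _lower_bidiagonal(rates, i, j)
            E[j, i] = expm(A * delta_t)
            b2 = rates.birth[1, i, j]
            for k in range(quad_nodes):
                kernel[j, i, k] = w[k] * b2 * expm(A * (delta_t - s[k]))[:, 0]

    f = np.empty((horizon_M, N_DRUGS, n, 3))
    for m in range(horizon_M):
        x1 = stem_traj(m * delta_t + s)  # shape (n, quad_nodes)
        # f[m, j, i] = sum_k kernel[j, i, k] * x1[i, k]
        f[m] = np.einsum("jikc,ik->jic", kernel, x1)
    return MonthlyAffineMaps(E=E, f=f, delta_t=delta_t, stem_traj=stem_traj)


def propagate_affine(
    x0: SystemState,
    schedule: TreatmentSchedule,
    maps: MonthlyAffineMaps,
) -> np.ndarray:
    """Month-boundary states x^0..x^M via the precomputed affine maps.

    Layers 2-4 follow ``y^{m+1} = E_j y^m + f_{m,j}``; layer 1 is read from
    the schedule-independent stem trajectory at month boundaries.
    """
    M = len(schedule)
    if M > maps.horizon_M:
        raise ValueError(f"schedule has {M} months but maps cover only {maps.horizon_M}")
    n = x0.n_types
    monthly = np.empty((M + 1, N_LAYERS, n))
    monthly[0] = x0.abundance
    y = x0.abundance[1:].T.copy()  # shape (n, 3): per-type PC/DC/TC
    for m, j in enumerate(schedule):
        y = np.einsum("icd,id->ic", maps.E[j], y) + maps.f[m, j]
        monthly[m + 1, 0] = maps.stem_traj((m + 1) * maps.delta_t)
        monthly[m + 1, 1:] = y.T
    return monthly


def derive_initial_conditions(
    rates: DrugRateTable,
    dd: DensityDependence,
    detection_threshold: float = 1e12,
    mutant_fractions: Sequence[float] = (),
    seed_cells: float = 1.0,
    t_max: float = 40.0 * 365.0,
) -> SystemState:
    """Initial abundances at CML diagnosis.

    A single leukemic WT stem cell is added to the healthy hematopoietic
    equilibrium and the untreated system is integrated until the total
    leukemic burden reaches the detection threshold (~1e12 cells).  Each
    leukemic layer is then split between WT and the preexisting mutants at
    the given fractions (the mutants are assumed to have arisen before
    detection with dynamics identical to WT off treatment).
    """
    n = rates.n_types
    if len(mutant_fractions) != max(n - 2, 0):
        raise ValueError(f"need one fraction per mutant type ({n - 2}), got {len(mutant_fractions)}")
    fr = np.asarray(mutant_fractions, dtype=float)
    if np.any(fr < 0) or fr.sum() >= 1.0:
        raise ValueError("mutant fractions must be nonnegative and sum to < 1")

    # Healthy equilibrium: normal stem cells at K1, downstream layers at
    # their forced equilibria x_l = (b_l / d_l) x_{l-1} (holiday rates).
    eq = np.zeros(N_LAYERS)
    eq[0] = dd.K1
    for layer in range(1, N_LAYERS):
        eq[layer] = rates.birth[layer, 0, 0] * eq[layer - 1] / rates.death[layer, 0, 0]

    x2 = np.zeros((N_LAYERS, 2))
    x2[:, 0] = eq
    x2[0, 1] = seed_cells
    if detection_threshold <= leukemic_burden(x2.reshape(N_LAYERS, 2)):
        x = np.zeros((N_LAYERS, n))
        x[:, :2] = x2
        return _split_mutants(x, fr)

    # Growth to detection uses only (normal, WT): integrate the 2-type
    # untreated system with a terminal event on the leukemic burden.
    b = rates.birth[:, :2, 0]
    d = rates.death[:, :2, 0]
    p2 = dd.p[:2]

    def rhs(t, y):
        x = y.reshape(N_LAYERS, 2)
        phi = 1.0 / (1.0 + p2 * x[0].sum())
        out = np.empty_like(x)
        out[0] = (b[0] * phi - d[0]) * x[0]
        out[1:] = b[1:] * x[:-1] - d[1:] * x[1:]
        return out.ravel()

    def detected(t, y):
        return y.reshape(N_LAYERS, 2)[:, 1].sum() - detection_threshold

    detected.terminal = True
    detected.direction = 1.0

    net0 = b[0, 1] / (1.0 + p2[1] * eq[0]) - d[0, 1]
    if net0 <= 0:
        raise ValueError("leukemic clone cannot expand at the healthy equilibrium (net growth <= 0)")

    sol = solve_ivp(
        rhs, (0.0, t_max), x2.ravel(), method=ODE_METHOD,
        rtol=ODE_RTOL, atol=ODE_ATOL, events=detected,
    )
    if not sol.success:
        raise RuntimeError(f"expansion-to-detection integration failed: {sol.message}")
    if not sol.t_events[0].size:
        raise ValueError(f"leukemic burden did not reach {detection_threshold:g} cells within {t_max:g} days")
    x_det = sol.y_events[0][0].reshape(N_LAYERS, 2)

    x = np.zeros((N_LAYERS, n))
    x[:, :2] = x_det
    return _split_mutants(x, fr)


def _split_mutants(x: np.ndarray, fractions: np.ndarray) -> SystemState:
    """Split each leukemic layer between WT and mutants at fixed proportions."""
    if fractions.size:
        leuk = x[:, 1].copy()
        x[:, 1] = leuk * (1.0 - fractions.sum())
        for k, frac in enumerate(fractions):
            x[:, 2 + k] = leuk * frac
    return SystemState(x, 0.0)


def make_stem_trajectory(
    x0: SystemState,
    rates: DrugRateTable,
    dd: DensityDependence,
    horizon_M: int,
    delta_t: float = 30.0,
) -> StemTrajectory:
    """Convenience: baseline stem trajectory covering an M-month horizon."""
    return stem_cell_trajectory(x0.abundance[0], rates, dd, horizon_M * delta_t)
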