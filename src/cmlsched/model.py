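"""Hierarchical ODE model of hematopoiesis under TKI therapy.

Four differentiation layers — stem cells (SC), progenitor cells (PC),
differentiated cells (DC) and terminally differentiated cells (TC) — for a
set of cell types: type 1 is normal, type 2 is leukemic wild-type (BCR-ABL
positive, no kinase-domain mutation) and types 3..n are leukemic mutants
(e.g. M351T, F317L, E255K) with drug-specific resistance profiles.

Stem cells compete through a density-dependence factor
``phi_i = 1 / (1 + p_i * S)`` where ``S`` is the total stem-cell abundance;
all downstream layers are linear: each is fed by the layer above and dies at
a first-order rate.  Rates are per day; treatment decisions are monthly
(``delta_t`` = 30 days) among a drug holiday (0), nilotinib (1),
dasatinib (2) and imatinib (3).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "HOLIDAY",
    "NILOTINIB",
    "DASATINIB",
    "IMATINIB",
    "DRUG_NAMES",
    "LAYER_NAMES",
    "N_LAYERS",
    "N_DRUGS",
    "ModelConfig",
    "SystemState",
    "DrugRateTable",
    "DensityDependence",
    "StemEffectConfig",
    "StemTrajectory",
    "density_factors",
    "derive_density_param",
    "ode_rhs",
    "stem_cell_trajectory",
]

HOLIDAY, NILOTINIB, DASATINIB, IMATINIB = 0, 1, 2, 3
DRUG_NAMES = ("holiday", "nilotinib", "dasatinib", "imatinib")
LAYER_NAMES = ("SC", "PC", "DC", "TC")
N_LAYERS = 4
N_DRUGS = 4  # three TKIs plus the holiday mode (index 0)

# Integrator defaults: abundances span ~1e4..1e12 cells, so a tight relative
# tolerance with a sub-cell absolute floor resolves small resistant clones.
ODE_RTOL = 1e-9
ODE_ATOL = 1e-3
ODE_METHOD = "LSODA"


@dataclass(frozen=True)
class ModelConfig:
    """Dimensions and time discretization of the model."""

    n_types: int
    delta_t: float = 30.0  # days per treatment-decision period
    horizon_M: int = 36  # months in the planning horizon

    n_layers: int = field(default=N_LAYERS, init=False)
    n_drugs: int = field(default=N_DRUGS, init=False)

    def __post_init__(self) -> None:
        if self.n_types < 2:
            raise ValueError("need at least normal and leukemic WT types (n_types >= 2)")
        if self.delta_t <= 0:
            raise ValueError("delta_t must be positive")
        if self.horizon_M < 1:
            raise ValueError("horizon_M must be >= 1")


@dataclass
class SystemState:
    """Cell abundances ``x[layer, type]`` (cells) at a time point (days)."""

    abundance: np.ndarray  # shape (4, n_types)
    time: float = 0.0

    def __post_init__(self) -> None:
        self.abundance = np.asarray(self.abundance, dtype=float)
        if self.abundance.ndim != 2 or self.abundance.shape[0] != N_LAYERS:
            raise ValueError(f"abundance must have shape (4, n_types), got {self.abundance.shape}")
        if not np.all(np.isfinite(self.abundance)):
            raise ValueError("abundances must be finite")
        if np.any(self.abundance < 0):
            raise ValueError("abundances must be nonnegative")

    @property
    def n_types(self) -> int:
        return self.abundance.shape[1]

    def total(self) -> float:
        return float(self.abundance.sum())

    def copy(self) -> "SystemState":
        return SystemState(self.abundance.copy(), self.time)


@dataclass
class DrugRateTable:
    """Per-day birth/death rates ``b[layer, type, drug]`` and ``d[layer, type, drug]``.

    Drug index 0 is the untreated (drug-holiday) mode.  Under the baseline
    assumption that TKIs spare the stem-cell compartment, layer-1 rates are
    identical across drugs; :meth:`check_stem_invariant` verifies this.
    """

    birth: np.ndarray  # shape (4, n_types, 4)
    death: np.ndarray  # same shape

    def __post_init__(self) -> None:
        self.birth = np.asarray(self.birth, dtype=float)
        self.death = np.asarray(self.death, dtype=float)
        for name, arr in (("birth", self.birth), ("death", self.death)):
            if arr.ndim != 3 or arr.shape[0] != N_LAYERS or arr.shape[2] != N_DRUGS:
                raise ValueError(f"{name} rates must have shape (4, n_types, 4), got {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} rates must be finite")
        # birth may be driven to zero by complete production suppression;
        # death rates must stay strictly positive
        if np.any(self.birth < 0):
            raise ValueError("birth rates must be nonnegative")
        if np.any(self.death <= 0):
            raise ValueError("death rates must be positive")
        if self.birth.shape != self.death.shape:
            raise ValueError("birth and death rate arrays must have identical shapes")

    @property
    def n_types(self) -> int:
        return self.birth.shape[1]

    def stem_rates_drug_independent(self, rtol: float = 0.0) -> bool:
        """True if layer-1 rates do not depend on the drug taken."""
        b0 = self.birth[0, :, :1]
        d0 = self.death[0, :, :1]
        return bool(
            np.allclose(self.birth[0], b0, rtol=rtol, atol=0.0)
            and np.allclose(self.death[0], d0, rtol=rtol, atol=0.0)
        )

    def check_stem_invariant(self) -> None:
        if not self.stem_rates_drug_independent():
            raise ValueError(
                "stem-cell (layer 1) rates differ across drugs; the baseline model "
                "assumes TKIs do not affect the stem-cell compartment"
            )

    def copy(self) -> "DrugRateTable":
        return DrugRateTable(self.birth.copy(), self.death.copy())


@dataclass
class DensityDependence:
    """Stem-cell crowding coefficients.

    ``p[i]`` (per cell) sets the strength of competition felt by type ``i``
    stem cells; ``K1`` and ``K2`` are the single-type equilibrium abundances
    of normal and leukemic-WT stem cells from which ``p1``/``p2`` are derived.
    All mutant types share ``p2``.
    """

    p: np.ndarray  # shape (n_types,)
    K1: float
    K2: float

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.ndim != 1:
            raise ValueError("p must be a per-type vector")
        if np.any(self.p < 0):
            raise ValueError("density coefficients must be nonnegative")
        if self.p.size >= 3 and not np.all(self.p[2:] == self.p[1]):
            raise ValueError("mutant types must share the leukemic-WT density coefficient p2")
        if self.K1 <= 0 or self.K2 <= 0:
            raise ValueError("carrying capacities must be positive")

    @classmethod
    def from_rates(cls, rates: DrugRateTable, K1: float, K2: float) -> "DensityDependence":
        """Derive p1, p2 from the untreated stem-cell rates and equilibria."""
        p1 = derive_density_param(rates.birth[0, 0, 0], rates.death[0, 0, 0], K1)
        p2 = derive_density_param(rates.birth[0, 1, 0], rates.death[0, 1, 0], K2)
        p = np.full(rates.n_types, p2)
        p[0] = p1
        return cls(p, K1, K2)


@dataclass(frozen=True)
class StemEffectConfig:
    """Optional hypothesis that TKIs reduce leukemic stem-cell production.

    When enabled, the birth rate of every leukemic stem cell (type >= 2,
    layer 1) is multiplied by ``1 - a_percent/100`` during drug months.
    Disabled by default: the baseline assumption is that TKIs spare stem
    cells, which makes stem dynamics schedule-independent.
    """

    a_percent: float = 0.0
    enabled: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.a_percent <= 100.0:
            raise ValueError("a_percent must lie in [0, 100]")


def derive_density_param(b_sc: float, d_sc: float, K: float) -> float:
    """Density coefficient ``p = (b/d - 1)/K`` giving equilibrium exactly K.

    At abundance K (single type), ``phi = 1/(1 + pK) = d/b`` so the net
    stem-cell growth rate ``b*phi - d`` vanishes.
    """
    if d_sc <= 0 or K <= 0:
        raise ValueError("d_sc and K must be positive")
    if b_sc <= d_sc:
        raise ValueError("no positive equilibrium: stem birth rate must exceed death rate")
    return (b_sc / d_sc - 1.0) / K


def density_factors(state: SystemState, dd: DensityDependence) -> np.ndarray:
    """Crowding factors ``phi_i = 1/(1 + p_i * S)``, S = total stem cells."""
    S = float(state.abundance[0].sum())
    if S < 0:
        raise ValueError("negative stem-cell abundance")
    return 1.0 / (1.0 + dd.p * S)


def _effective_stem_birth(
    rates: DrugRateTable, drug_j: int, se: StemEffectConfig | None
) -> np.ndarray:
    """Layer-1 birth rates under drug ``drug_j``, with the optional stem effect."""
    b1 = rates.birth[0, :, drug_j].copy()
    if se is not None and se.enabled and drug_j >= 1:
        b1[1:] *= 1.0 - se.a_percent / 100.0
    return b1


def ode_rhs(
    state: SystemState,
    drug_j: int,
    rates: DrugRateTable,
    dd: DensityDependence,
    se: StemEffectConfig | None = None,
) -> np.ndarray:
    """Time derivative (cells/day) of every compartment under drug ``drug_j``.

    Layer 1:     dx1_i/dt = (b1_i^j * phi_i - d1_i^j) x1_i
    Layers 2-4:  dxl_i/dt = bl_i^j x_{l-1,i} - dl_i^j xl_i
    """
    if drug_j not in range(N_DRUGS):
        raise ValueError(f"drug index must be in 0..3, got {drug_j}")
    x = state.abundance
    phi = density_factors(state, dd)
    out = np.empty_like(x)
    b1 = _effective_stem_birth(rates, drug_j, se)
    out[0] = (b1 * phi - rates.death[0, :, drug_j]) * x[0]
    for layer in range(1, N_LAYERS):
        out[layer] = rates.birth[layer, :, drug_j] * x[layer - 1] - rates.death[layer, :, drug_j] * x[layer]
    return out


class StemTrajectory:
    """Dense-in-time layer-1 (stem) abundances on ``[0, t_end]``.

    Because the baseline model keeps stem-cell rates drug-independent, this
    trajectory is the same under every treatment schedule and can be treated
    as a known external forcing for the linear layers 2-4.
    """

    def __init__(self, sol, n_types: int, t_end: float):
        self._sol = sol
        self.n_types = n_types
        self.t_end = t_end

    def __call__(self, t) -> np.ndarray:
        """Stem abundances at time(s) t (days); shape (n_types,) or (n_types, len(t))."""
        t = np.asarray(t, dtype=float)
        if np.any(t < -1e-9) or np.any(t > self.t_end * (1 + 1e-12) + 1e-9):
            raise ValueError(f"time outside covered range [0, {self.t_end}]")
        return np.clip(self._sol(np.clip(t, 0.0, self.t_end)), 0.0, None)


def stem_cell_trajectory(
    x1_init: np.ndarray,
    rates: DrugRateTable,
    dd: DensityDependence,
    t_end: float,
    se: StemEffectConfig | None = None,
    rtol: float = 1e-10,
    atol: float = 1e-6,
) -> StemTrajectory:
    """Integrate the self-contained stem-cell subsystem over ``[0, t_end]``.

    Valid only under the baseline assumption (stem effect disabled and
    layer-1 rates identical across drugs); otherwise stem dynamics depend on
    the schedule and the full ODE path must be used.
    """
    if se is not None and se.enabled:
        raise ValueError(
            "stem effect enabled: stem dynamics are schedule-dependent; "
            "use simulate_schedule_ode instead"
        )
    rates.check_stem_invariant()
    x1_init = np.asarray(x1_init, dtype=float)
    if np.any(x1_init < 0):
        raise ValueError("initial stem abundances must be nonnegative")
    b1 = rates.birth[0, :, 0]
    d1 = rates.death[0, :, 0]
    p = dd.p

    def rhs(t, x1):
        phi = 1.0 / (1.0 + p * max(x1.sum(), 0.0))
        return (b1 * phi - d1) * x1

    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        x1_init,
        method=ODE_METHOD,
        rtol=rtol,
        atol=atol,
        dense_output=True,
    )
    if not sol.success:
        raise RuntimeError(f"stem-cell integration failed: {sol.message}")
    return StemTrajectory(sol.sol, x1_init.size, t_end)
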