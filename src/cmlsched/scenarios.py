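"""Scenario fixtures, parameter-file I/O, and a synthetic parameter generator.

The published study's exact per-drug birth/death rates live in supplementary
material that is not redistributed here; the package therefore runs on
user-supplied JSON parameter files, and ships a seeded synthetic generator
whose rate tables satisfy the qualitative structure the study describes
(drug holiday lets the leukemic clone grow; dasatinib is the strongest
progenitor killer; nilotinib the strongest killer of differentiated cells;
imatinib intermediate to weakest; TKIs spare the stem-cell compartment).
The printed diagnosis-time cell abundances, by contrast, are reproduced
verbatim as fixtures.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .model import (
    N_DRUGS,
    N_LAYERS,
    DensityDependence,
    DrugRateTable,
    ModelConfig,
    SystemState,
)
from .toxicity import ANCParams

__all__ = [
    "Scenario",
    "load_fixture",
    "FIXTURE_NAMES",
    "load_params",
    "save_params",
    "synthetic_params",
    "apply_stem_effect",
]

SCHEMA_VERSION = 1

# Diagnosis-time cell abundances (cells) exactly as printed, columns are
# cell types, rows are layers SC, PC, DC, TC.
_NORMAL_COL = [7.34e4, 1.61e7, 3.24e9, 3.24e11]
_WT_COL = [2.80e5, 3.87e7, 1.03e10, 1.03e12]
_MUTANT_COL = [1.48e4, 2.04e6, 5.40e8, 5.40e10]
# two-mutant case: WT is printed slightly lower so each mutant keeps 5%
_WT_COL_TWO_MUTANTS = [2.66e5, 3.66e7, 9.72e9, 9.72e11]

_FIXTURES = {
    "table1_F317L": {
        "type_labels": ("normal", "WT", "F317L"),
        "columns": (_NORMAL_COL, _WT_COL, _MUTANT_COL),
        "mutant_fractions": (0.05,),
        "source": "printed initial-abundance table, F317L scenario",
    },
    "table2_M351T": {
        "type_labels": ("normal", "WT", "M351T"),
        "columns": (_NORMAL_COL, _WT_COL, _MUTANT_COL),
        "mutant_fractions": (0.05,),
        "source": "printed initial-abundance table, M351T scenario",
    },
    "table5_two_mutants": {
        "type_labels": ("normal", "WT", "M351T", "F317L"),
        "columns": (_NORMAL_COL, _WT_COL_TWO_MUTANTS, _MUTANT_COL, _MUTANT_COL),
        "mutant_fractions": (0.05, 0.05),
        "source": "printed initial-abundance table, M351T + F317L scenario",
    },
}
FIXTURE_NAMES = tuple(_FIXTURES)


@dataclass(frozen=True)
class Scenario:
    """A named initial condition: diagnosis-time abundances and type labels."""

    label: str
    x0: SystemState
    type_labels: tuple[str, ...]
    mutant_fractions: tuple[float, ...]
    source: str

    @property
    def n_types(self) -> int:
        return len(self.type_labels)


def load_fixture(name: str) -> Scenario:
    """Load one of the printed diagnosis scenarios by name."""
    if name not in _FIXTURES:
        raise KeyError(f"unknown scenario {name!r}; known: {FIXTURE_NAMES}")
    spec = _FIXTURES[name]
    x = np.array(spec["columns"], dtype=float).T  # (layers, types)
    return Scenario(
        label=name,
        x0=SystemState(x, 0.0),
        type_labels=spec["type_labels"],
        mutant_fractions=spec["mutant_fractions"],
        source=spec["source"],
    )


# ---------------------------------------------------------------------------
# JSON parameter files
# ---------------------------------------------------------------------------

def _require(payload: dict, key: str, path: str):
    if key not in payload:
        raise ValueError(f"parameter file {path}: missing required key {key!r}")
    return payload[key]


def load_params(path) -> tuple[DrugRateTable, DensityDependence, ANCParams | None, ModelConfig]:
    """Read a model parameter file.

    Schema (JSON): ``schema_version``, ``n_types``, ``delta_t_days``,
    ``type_labels``, ``rates`` with ``birth``/``death`` arrays laid out as
    ``rates[layer][type][drug]`` (0-indexed, drug 0 = holiday), ``K1``,
    ``K2`` and an optional ``anc`` block.  Missing ``anc`` disables toxicity
    features with a warning.
    """
    path = Path(path)
    with open(path) as fh:
        payload = json.load(fh)
    name = str(path)
    version = _require(payload, "schema_version", name)
    if version != SCHEMA_VERSION:
        raise ValueError(f"parameter file {name}: unsupported schema_version {version}")
    n_types = int(_require(payload, "n_types", name))
    delta_t = float(payload.get("delta_t_days", 30.0))
    rates_block = _require(payload, "rates", name)
    arrays = {}
    for key in ("birth", "death"):
        arr = np.asarray(_require(rates_block, key, name), dtype=float)
        if arr.shape != (N_LAYERS, n_types, N_DRUGS):
            raise ValueError(
                f"parameter file {name}: rates[{key!r}] must have shape "
                f"(layers={N_LAYERS}, types={n_types}, drugs={N_DRUGS}), got {arr.shape}"
            )
        arrays[key] = arr
    rates = DrugRateTable(arrays["birth"], arrays["death"])
    K1 = float(_require(payload, "K1", name))
    K2 = float(_require(payload, "K2", name))
    dd = DensityDependence.from_rates(rates, K1, K2)
    anc = None
    if "anc" in payload:
        block = payload["anc"]
        anc = ANCParams(
            d_anc=tuple(block.get("d_anc", ANCParams.d_anc)),
            b_anc=float(block.get("b_anc", ANCParams.b_anc)),
            L_anc=float(block.get("L_anc", ANCParams.L_anc)),
            U_anc=float(block.get("U_anc", ANCParams.U_anc)),
            y0=float(block.get("y0", ANCParams.y0)),
        )
    else:
        warnings.warn(
            f"parameter file {name} has no 'anc' block; toxicity features disabled",
            stacklevel=2,
        )
    config = ModelConfig(n_types=n_types, delta_t=delta_t, horizon_M=int(payload.get("horizon_M", 36)))
    return rates, dd, anc, config


def save_params(
    path,
    rates: DrugRateTable,
    dd: DensityDependence,
    anc: ANCParams | None = None,
    config: ModelConfig | None = None,
    type_labels: tuple[str, ...] | None = None,
) -> None:
    """Write a parameter file in the schema read by :func:`load_params`."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "n_types": rates.n_types,
        "delta_t_days": config.delta_t if config is not None else 30.0,
        "horizon_M": config.horizon_M if config is not None else 36,
        "type_labels": list(type_labels) if type_labels is not None else None,
        "rates": {"birth": rates.birth.tolist(), "death": rates.death.tolist()},
        "K1": dd.K1,
        "K2": dd.K2,
    }
    if anc is not None:
        payload["anc"] = {
            "d_anc": list(anc.d_anc),
            "b_anc": anc.b_anc,
            "L_anc": anc.L_anc,
            "U_anc": anc.U_anc,
            "y0": anc.y0,
        }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# Synthetic parameter generator
# ---------------------------------------------------------------------------

def synthetic_params(
    seed: int,
    n_types: int = 3,
) -> tuple[DrugRateTable, DensityDependence]:
    """Seeded random rate tables with the study's qualitative drug structure.

    All rates are per day.  For every leukemic type the construction
    guarantees, by sorted assignment of per-drug inhibition factors:

    * layer-1 (stem) rates identical across drugs — TKIs spare stem cells;
    * progenitor production most strongly suppressed by dasatinib, then
      nilotinib, then imatinib;
    * differentiated-cell production most strongly suppressed by nilotinib,
      then dasatinib, then imatinib;
    * net leukemic growth off drug, with magnitudes such that clonal
      expansion from one cell to ~1e12 cells takes a few years;
    * normal cells only mildly affected, nilotinib the most, imatinib not
      at all.

    The magnitudes themselves are this package's own synthetic defaults;
    they are not estimates from any clinical data set.
    """
    if n_types < 2:
        raise ValueError("need at least 2 types")
    rng = np.random.default_rng(seed)

    def jit(sigma=0.08):
        return rng.lognormal(0.0, sigma)

    birth = np.empty((N_LAYERS, n_types, N_DRUGS))
    death = np.empty((N_LAYERS, n_types, N_DRUGS))

    # --- holiday (untreated) rates ---------------------------------------
    # normal lineage: slow stem turnover (division every ~1000 days, b/d ~ 2,
    # so the normal stem pool is only mildly depleted during the years of
    # preclinical leukemic expansion), total amplification SC -> TC ~ 4e6
    # (layer ratios ~200 / 200 / 100)
    b1n = 0.001 * jit()
    d1n = b1n / (2.0 * jit(0.05))
    d_norm = np.array([d1n, 0.004 * jit(), 0.02 * jit(), 1.0 * jit()])
    amp_norm = np.array([np.nan, 200 * jit(), 200 * jit(), 100 * jit()])
    b_norm = np.concatenate([[b1n], d_norm[1:] * amp_norm[1:]])

    # leukemic lineage (shared off-drug by WT and mutants): faster stem
    # turnover with a strong proliferative advantage (b/d ~ 6); downstream
    # amplification close to the normal lineage, so the leukemic excess at
    # detection comes mostly from the expanded stem pool
    b1l = 0.012 * jit()
    d1l = b1l / (6.0 * jit(0.05))
    d_leuk = np.array([d1l, 0.004 * jit(), 0.02 * jit(), 1.0 * jit()])
    amp_leuk = np.array([np.nan, 220 * jit(), 220 * jit(), 100 * jit()])
    b_leuk = np.concatenate([[b1l], d_leuk[1:] * amp_leuk[1:]])

    for i in range(n_types):
        col_b, col_d = (b_norm, d_norm) if i == 0 else (b_leuk, d_leuk)
        birth[:, i, :] = col_b[:, None]
        death[:, i, :] = col_d[:, None]

    # --- drug-month rates --------------------------------------------------
    # Inhibition factors multiply birth rates of layers 2-4.  Stem rates
    # (layer 1) stay untouched for every drug.
    # normal cells: nilotinib strongest mild effect, imatinib none
    norm_mult = np.array([1.0, rng.uniform(0.80, 0.90), rng.uniform(0.90, 0.97), 1.0])
    for j in (1, 2, 3):
        birth[1:, 0, j] = birth[1:, 0, 0] * norm_mult[j]

    # leukemic WT: strong suppression; per-layer orderings fixed by sorted
    # assignment (index order: nilotinib, dasatinib, imatinib)
    def sorted_factors(order: tuple[int, int, int]) -> np.ndarray:
        vals = np.sort(np.exp(rng.uniform(np.log(0.02), np.log(0.35), size=3)))
        out = np.empty(3)
        out[list(order)] = vals  # order[k] gets the k-th smallest factor
        return out

    # PC: dasatinib strongest (smallest factor), then nilotinib, imatinib weakest
    pc_wt = sorted_factors((1, 0, 2))
    # DC and TC: nilotinib strongest, then dasatinib, imatinib weakest
    dc_wt = sorted_factors((0, 1, 2))
    tc_wt = sorted_factors((0, 1, 2))
    wt_mult = np.stack([pc_wt, dc_wt, tc_wt])  # (layer 2-4, drug 1-3)

    # mutants: the same factors pulled toward 1 by a per-mutant resistance
    # exponent; a single exponent per mutant preserves every per-layer ordering
    mult_by_type = {1: wt_mult}
    for i in range(2, n_types):
        rho = rng.uniform(0.35, 0.8)
        mult_by_type[i] = wt_mult ** (1.0 - rho)

    for i in range(1, n_types):
        for j in (1, 2, 3):
            birth[1:, i, j] = birth[1:, i, 0] * mult_by_type[i][:, j - 1]

    rates = DrugRateTable(birth, death)
    K1 = 7.0e4 * jit(0.1)
    K2 = 2.8e5 * jit(0.1)
    dd = DensityDependence.from_rates(rates, K1, K2)
    return rates, dd


def apply_stem_effect(rates: DrugRateTable, a_percent: float) -> DrugRateTable:
    """Rate table with leukemic stem-cell production reduced by ``a``% under drug.

    Scales ``b[layer 1, type >= 2, drug >= 1]`` by ``1 - a/100``; holiday
    months and normal stem cells are untouched.  The result no longer
    satisfies the stem-rate drug-independence invariant (for a > 0), so it
    can only be used with the full ODE simulation path.
    """
    if not 0.0 <= a_percent <= 100.0:
        raise ValueError("a_percent must lie in [0, 100]")
    birth = rates.birth.copy()
    birth[0, 1:, 1:] *= 1.0 - a_percent / 100.0
    return DrugRateTable(birth, rates.death.copy())
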