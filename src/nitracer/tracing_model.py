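"""Five-pool, ten-flux kinetic model of soil nitrogen transformations.

The model tracks NH4+, NO3-, a labile (N_lab) and a recalcitrant (N_rec)
organic N pool, and exchangeably adsorbed NH4+ (NH4+_ads).  Ten gross
transformations connect the pools:

====================  ==========================  ====================
name                  process                     direction
====================  ==========================  ====================
M_Nrec                mineralization              N_rec    -> NH4+
I_NH4_Nrec            NH4+ immobilization         NH4+     -> N_rec
M_Nlab                mineralization              N_lab    -> NH4+
I_NH4_Nlab            NH4+ immobilization         NH4+     -> N_lab
O_Nrec                heterotrophic nitrification N_rec    -> NO3-
I_NO3                 NO3- immobilization         NO3-     -> N_rec
O_NH4                 autotrophic nitrification   NH4+     -> NO3-
D_NO3                 DNRA                        NO3-     -> NH4+
A_NH4                 NH4+ adsorption             NH4+     -> NH4+_ads
R_NH4a                NH4+ release                NH4+_ads -> NH4+
====================  ==========================  ====================

Each flux follows zero-order, first-order or Michaelis-Menten kinetics
and carries 15N at the source pool's current atom fraction (no isotopic
fractionation), so total N and total 15N over the five pools are exactly
conserved: the model has no gaseous sink; denitrification losses are
handled separately by :mod:`nitracer.gasflux`.

Enrichments are atom fractions (0-1) internally; atom% appears only at
I/O boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import _kernels
from ._kernels import (
    FIRST_ORDER,
    MICHAELIS_MENTEN,
    TRANSFORM_NAMES,
    ZERO_ORDER,
    ZERO_ORDER_RAMP,
)

__all__ = [
    "POOL_NAMES",
    "TRANSFORM_NAMES",
    "DEFAULT_KINETIC_KINDS",
    "PoolState",
    "KineticLaw",
    "TransformationSet",
    "Trajectory",
    "RateTable",
    "kinetic_rate",
    "simulate",
    "average_gross_rates",
    "derived_rate_sums",
    "round_half_up",
]

POOL_NAMES = ("nh4", "no3", "nlab", "nrec", "nh4ads")

#: Natural-abundance guard: atom fractions below this are treated as
#: physically implausible for soil N (atmospheric 15N is ~0.003663).
NATURAL_ABUNDANCE_FLOOR = 0.003
NATURAL_ABUNDANCE = 0.003663

#: Default kinetic-law assignment.  The choice is configurable and is
#: recorded in run metadata; see docs/methods.md for the rationale.
DEFAULT_KINETIC_KINDS: Dict[str, str] = {
    "M_Nrec": "zero_order",
    "I_NH4_Nrec": "first_order",
    "M_Nlab": "first_order",
    "I_NH4_Nlab": "first_order",
    "O_Nrec": "zero_order",
    "I_NO3": "zero_order",
    "O_NH4": "michaelis_menten",
    "D_NO3": "zero_order",
    "A_NH4": "first_order",
    "R_NH4a": "zero_order",
}

_KIND_CODES = {
    "zero_order": ZERO_ORDER,
    "first_order": FIRST_ORDER,
    "michaelis_menten": MICHAELIS_MENTEN,
}


def round_half_up(x: float) -> int:
    """Round to the nearest integer with ties away from zero.

    Report tables print integer percentages and factors; banker's
    rounding (Python's built-in) would round 0.5 down, which does not
    match conventional table presentation.
    """
    if x >= 0:
        return int(math.floor(x + 0.5))
    return -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class KineticLaw:
    """A kinetic rate law for one gross transformation.

    Parameters
    ----------
    kind:
        ``"zero_order"`` (k in ug N/g/day), ``"first_order"`` (k in
        1/day) or ``"michaelis_menten"`` (k is V_max in ug N/g/day,
        km the half-saturation constant in ug N/g).
    """

    kind: str
    k: float
    km: Optional[float] = None

    def __post_init__(self):
        if self.kind not in _KIND_CODES:
            raise ValueError(f"unknown kinetic law kind: {self.kind!r}")
        if self.k < 0:
            raise ValueError("rate constant must be non-negative")
        if self.kind == "michaelis_menten":
            if self.km is None or self.km <= 0:
                raise ValueError("michaelis_menten requires km > 0")
        elif self.km is not None:
            raise ValueError(f"km is only meaningful for michaelis_menten, not {self.kind}")


@dataclass(frozen=True)
class PoolState:
    """Amounts (ug N/g soil) and 15N atom fractions of the five pools."""

    nh4: float
    no3: float
    nlab: float
    nrec: float
    nh4ads: float
    f_nh4: float = NATURAL_ABUNDANCE
    f_no3: float = NATURAL_ABUNDANCE
    f_nlab: float = NATURAL_ABUNDANCE
    f_nrec: float = NATURAL_ABUNDANCE
    f_nh4ads: float = NATURAL_ABUNDANCE
    time: float = 0.0

    def __post_init__(self):
        for name in POOL_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"pool amount {name} must be >= 0")
            f = getattr(self, "f_" + name)
            if not (NATURAL_ABUNDANCE_FLOOR <= f <= 1.0):
                raise ValueError(
                    f"atom fraction f_{name}={f} outside "
                    f"[{NATURAL_ABUNDANCE_FLOOR}, 1]"
                )
        if self.time < 0:
            raise ValueError("time must be >= 0")

    def to_vector(self) -> np.ndarray:
        """State vector: five amounts followed by five 15N amounts."""
        amounts = np.array([getattr(self, n) for n in POOL_NAMES])
        fractions = np.array([getattr(self, "f_" + n) for n in POOL_NAMES])
        return np.concatenate([amounts, amounts * fractions])

    @staticmethod
    def from_vector(y: np.ndarray, time: float) -> "PoolState":
        amounts = np.maximum(y[:5], 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            fractions = np.where(amounts > 1e-12, y[5:] / np.maximum(amounts, 1e-12),
                                 NATURAL_ABUNDANCE)
        fractions = np.clip(fractions, NATURAL_ABUNDANCE_FLOOR, 1.0)
        kwargs = {n: float(a) for n, a in zip(POOL_NAMES, amounts)}
        kwargs.update({"f_" + n: float(f) for n, f in zip(POOL_NAMES, fractions)})
        return PoolState(time=float(time), **kwargs)

    @property
    def total_n(self) -> float:
        return sum(getattr(self, n) for n in POOL_NAMES)

    @property
    def total_n15(self) -> float:
        return sum(getattr(self, n) * getattr(self, "f_" + n) for n in POOL_NAMES)


class TransformationSet:
    """The ten gross transformations with their kinetic laws.

    The source/sink wiring is fixed by the model topology; only the
    kinetic laws vary.  Construct from a mapping of name -> KineticLaw
    covering exactly the ten transformation names.
    """

    def __init__(self, laws: Mapping[str, KineticLaw]):
        missing = set(TRANSFORM_NAMES) - set(laws)
        extra = set(laws) - set(TRANSFORM_NAMES)
        if missing or extra:
            raise ValueError(
                f"TransformationSet requires exactly {TRANSFORM_NAMES}; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )
        self.laws: Dict[str, KineticLaw] = {n: laws[n] for n in TRANSFORM_NAMES}

    @classmethod
    def from_constants(cls, k: Mapping[str, float],
                       kinds: Optional[Mapping[str, str]] = None,
                       km: Optional[Mapping[str, float]] = None) -> "TransformationSet":
        """Build from rate constants; unlisted transformations get k = 0.

        Michaelis-Menten laws take their half-saturation constant from
        ``km`` and default to 10 ug N/g when unspecified.
        """
        kinds = dict(DEFAULT_KINETIC_KINDS, **(kinds or {}))
        km = km or {}
        laws = {}
        for name in TRANSFORM_NAMES:
            kind = kinds[name]
            laws[name] = KineticLaw(
                kind, float(k.get(name, 0.0)),
                km=float(km.get(name, 10.0)) if kind == "michaelis_menten"
                else None,
            )
        return cls(laws)

    def __getitem__(self, name: str) -> KineticLaw:
        return self.laws[name]

    def __iter__(self):
        return iter(TRANSFORM_NAMES)

    def source_pool(self, name: str) -> str:
        return POOL_NAMES[_kernels.SRC[TRANSFORM_NAMES.index(name)]]

    def sink_pool(self, name: str) -> str:
        return POOL_NAMES[_kernels.SNK[TRANSFORM_NAMES.index(name)]]

    def to_arrays(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(kinds, k, km) arrays in canonical transformation order."""
        kinds = np.array([_KIND_CODES[self.laws[n].kind] for n in TRANSFORM_NAMES],
                         dtype=np.int64)
        k = np.array([self.laws[n].k for n in TRANSFORM_NAMES])
        km = np.array([self.laws[n].km if self.laws[n].km is not None else 1.0
                       for n in TRANSFORM_NAMES])
        return kinds, k, km

    def metadata(self) -> Dict[str, Dict[str, object]]:
        """Kinetic-law assignment for the run manifest."""
        out: Dict[str, Dict[str, object]] = {}
        for n in TRANSFORM_NAMES:
            law = self.laws[n]
            entry: Dict[str, object] = {"kind": law.kind, "k": law.k}
            if law.km is not None:
                entry["km"] = law.km
            out[n] = entry
        return out


@dataclass
class Trajectory:
    """Pool states and per-transformation instantaneous rates on a grid."""

    times: np.ndarray                      # days, strictly increasing
    states: Sequence[PoolState]
    rates: pd.DataFrame                    # one column per transformation

    def __post_init__(self):
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory time grid must be strictly increasing")
        if (self.rates.values < -1e-12).any():
            raise ValueError("instantaneous rates must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t, s in zip(self.times, self.states):
            row = {"time_days": t}
            for n in POOL_NAMES:
                row[n + "_ug_n_g"] = getattr(s, n)
                row["f_" + n] = getattr(s, "f_" + n)
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class RateTable:
    """Time-averaged gross rates with optional uncertainty and derived sums."""

    rates: Dict[str, float]
    se: Dict[str, float] = field(default_factory=dict)
    m_tot: Optional[float] = None
    nit_tot: Optional[float] = None
    i_nh4tot: Optional[float] = None
    contrib_m_nlab_pct: Optional[float] = None
    contrib_o_nh4_pct: Optional[float] = None

    def to_frame(self) -> pd.DataFrame:
        rows = [{"transformation": n, "rate_ug_n_g_day": self.rates[n],
                 "se": self.se.get(n, np.nan)} for n in TRANSFORM_NAMES]
        for name, val in (("M_tot", self.m_tot), ("Nit_tot", self.nit_tot),
                          ("I_NH4tot", self.i_nh4tot)):
            if val is not None:
                rows.append({"transformation": name, "rate_ug_n_g_day": val,
                             "se": self.se.get(name, np.nan)})
        return pd.DataFrame(rows)


def kinetic_rate(law: KineticLaw, substrate: float) -> float:
    """Instantaneous gross rate (ug N/g/day) for a substrate amount.

    Zero-order laws taper linearly to zero below 0.01 ug N/g so an
    empty pool cannot go negative.
    """
    if substrate < 0:
        raise ValueError("substrate amount must be >= 0")
    if substrate == 0.0:
        return 0.0
    if law.kind == "zero_order":
        if substrate < ZERO_ORDER_RAMP:
            return law.k * substrate / ZERO_ORDER_RAMP
        return law.k
    if law.kind == "first_order":
        return law.k * substrate
    return law.k * substrate / (law.km + substrate)


def _rates_at(transformations: TransformationSet, y: np.ndarray) -> np.ndarray:
    kinds, k, km = transformations.to_arrays()
    out = np.empty(10)
    _kernels.transformation_rates(y, kinds, k, km, out)
    return out


def simulate(transformations: TransformationSet, init: PoolState,
             grid: Iterable[float], rtol: float = 1e-8,
             atol: float = 1e-10) -> Trajectory:
    """Integrate the model forward over ``grid`` (days).

    Uses a stiff-capable solver (LSODA).  Raises a RuntimeError with
    solver diagnostics on failure or if a pool goes negative beyond
    tolerance.
    """
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("empty time grid")
    if abs(grid[0] - init.time) > 1e-12:
        raise ValueError("grid must start at the initial state's time")
    kinds, k, km = transformations.to_arrays()
    y0 = init.to_vector()

    dydt = np.empty(10)

    def f(t, y):
        _kernels.rhs(y, kinds, k, km, dydt)
        return dydt.copy()

    sol = solve_ivp(f, (grid[0], grid[-1]), y0, method="LSODA",
                    t_eval=grid, rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"ODE solver failed: {sol.message}")
    ys = sol.y.T
    if (ys[:, :5] < -1e-6).any():
        raise RuntimeError(
            "negative pool amount beyond tolerance; "
            f"min={ys[:, :5].min():.3e} ug N/g"
        )
    states = [PoolState.from_vector(ys[i], grid[i]) for i in range(len(grid))]
    rate_rows = np.array([_rates_at(transformations, ys[i]) for i in range(len(grid))])
    rates = pd.DataFrame(np.maximum(rate_rows, 0.0), columns=list(TRANSFORM_NAMES))
    return Trajectory(times=grid, states=states, rates=rates)


def default_grid(t0: float = 0.0, t1: float = 2.0, n: int = 97) -> np.ndarray:
    """Fixed output grid: 97 points over the two-day incubation."""
    return np.linspace(t0, t1, n)


def average_gross_rates(transformations: TransformationSet,
                        trajectory: Trajectory,
                        interval: Tuple[float, float]) -> RateTable:
    """Time-averaged gross rates over [t0, t1] by trapezoidal integration.

    This is the quantity reported per transformation: the mean of the
    instantaneous rate over the incubation period, in ug N/g soil/day.
    """
    t0, t1 = interval
    if t1 <= t0:
        raise ValueError("interval end must exceed start")
    times = trajectory.times
    if t0 < times[0] - 1e-9 or t1 > times[-1] + 1e-9:
        raise ValueError("interval outside trajectory span")
    mask = (times >= t0 - 1e-12) & (times <= t1 + 1e-12)
    t_sel = times[mask]
    rates = {}
    for name in TRANSFORM_NAMES:
        r = trajectory.rates[name].values[mask]
        rates[name] = float(np.trapezoid(r, t_sel) / (t_sel[-1] - t_sel[0]))
    return derived_rate_sums(RateTable(rates=rates))


def derived_rate_sums(table: RateTable) -> RateTable:
    """Fill in derived sums and percentage contributions.

    M_tot = M_Nrec + M_Nlab, Nit_tot = O_Nrec + O_NH4,
    I_NH4tot = I_NH4_Nrec + I_NH4_Nlab; the contribution percentages
    (M_Nlab/M_tot, O_NH4/Nit_tot) are left None when the denominator
    is zero.
    """
    r = table.rates
    table.m_tot = r["M_Nrec"] + r["M_Nlab"]
    table.nit_tot = r["O_Nrec"] + r["O_NH4"]
    table.i_nh4tot = r["I_NH4_Nrec"] + r["I_NH4_Nlab"]
    table.contrib_m_nlab_pct = (
        100.0 * r["M_Nlab"] / table.m_tot if table.m_tot > 0 else None
    )
    table.contrib_o_nh4_pct = (
        100.0 * r["O_NH4"] / table.nit_tot if table.nit_tot > 0 else None
    )
    return table
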