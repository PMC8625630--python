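"""Parameter sweeps over the tunneling and GHK quantities.

Generates the deterministic data series behind the figures: a quantity
(tunneling probability, conductances, classical or quantum resting
potential, isotope ratio) evaluated on an evenly spaced grid of one
variable (G, L, Vm, D or Li_out) with the remaining parameters fixed at
the reference setting G=5, L=1, Vm=0.087 V, D=1e11 channels/cm^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import PhysicalConstants, get_constants
from .ghk import MembraneBath, classical_ghk_solve, quantum_ghk_solve
from .isotopes import isotope_ratio_at
from .tunneling import (
    ChannelPopulation,
    GateBarrier,
    extracellular_kinetic_energy,
    get_ion,
    intracellular_kinetic_energy,
    membrane_conductance,
    single_channel_conductance,
    tunneling_probability,
)

__all__ = ["SweepSpec", "run_sweep", "REFERENCE_SETTING"]

QUANTITIES = (
    "tunneling_probability",
    "single_channel_conductance",
    "membrane_conductance",
    "quantum_Vm",
    "classical_Vm",
    "isotope_ratio",
)
VARIABLES = ("G", "L", "Vm", "D", "Li_out")

#: Values the sweeps hold fixed unless overridden.
REFERENCE_SETTING = {"G": 5.0, "L": 1.0, "Vm": 0.087, "D": 1e11, "Li_out": 1.0}

#: Ranges the model was exercised over; outside emits a warning, never an error.
_RANGES = {
    "G": (3.0, 7.0),
    "L": (0.0, 2.0),
    "Vm": (0.0, 0.087),
    "D": (1e9, 1e11),
    "Li_out": (1.0, 100.0),
}

#: Quantities whose figures are drawn on a log10 axis.
_LOG_QUANTITIES = {
    "tunneling_probability",
    "single_channel_conductance",
    "membrane_conductance",
}


@dataclass(frozen=True)
class SweepSpec:
    """One sweep: which quantity, over which variable, for which ions."""

    quantity: str
    variable: str
    lo: float
    hi: float
    points: int = 101
    ions: tuple[str, ...] = ("Li-7", "Li-6")
    side: str = "extra"
    fixed: dict = field(default_factory=dict)
    li_ratio: float = 2.0
    mc_li: float = 0.005
    mc_na: float = 0.005

    def __post_init__(self) -> None:
        if self.quantity not in QUANTITIES:
            raise ValueError(f"unknown quantity {self.quantity!r}; one of {QUANTITIES}")
        if self.variable not in VARIABLES:
            raise ValueError(f"unknown variable {self.variable!r}; one of {VARIABLES}")
        if self.points < 1:
            raise ValueError("a sweep needs at least one point")
        lo, hi = _RANGES[self.variable]
        if self.lo < lo or self.hi > hi:
            warnings.warn(
                f"sweep range [{self.lo}, {self.hi}] for {self.variable} is outside "
                f"the modelled box [{lo}, {hi}]",
                UserWarning,
                stacklevel=2,
            )

    def grid(self) -> np.ndarray:
        if self.points == 1:
            return np.array([self.lo])
        return np.linspace(self.lo, self.hi, self.points)


def _evaluate(
    spec: SweepSpec, ion_label: str, value: float, constants: PhysicalConstants
) -> float:
    setting = dict(REFERENCE_SETTING)
    setting.update(spec.fixed)
    setting[spec.variable] = value
    ion = get_ion(ion_label)
    gate = GateBarrier.from_scaled(setting["G"], setting["L"])

    if spec.quantity in _LOG_QUANTITIES or spec.quantity == "isotope_ratio":
        if spec.side == "extra":
            ke = extracellular_kinetic_energy(setting["Vm"], ion, constants)
        else:
            ke = intracellular_kinetic_energy(constants)

    if spec.quantity == "tunneling_probability":
        return tunneling_probability(ion, gate, ke, constants).probability
    if spec.quantity == "single_channel_conductance":
        tq = tunneling_probability(ion, gate, ke, constants)
        return single_channel_conductance(ion, tq, constants)
    if spec.quantity == "membrane_conductance":
        tq = tunneling_probability(ion, gate, ke, constants)
        pop = ChannelPopulation(setting["D"], gate)
        return membrane_conductance(ion, tq, pop, constants)
    if spec.quantity == "isotope_ratio":
        Vm = setting["Vm"] if spec.side == "extra" else None
        return isotope_ratio_at(spec.side, setting["G"], setting["L"], Vm, constants).ratio
    if spec.quantity == "classical_Vm":
        bath = MembraneBath(
            Li_out=setting["Li_out"],
            li_ratio=spec.li_ratio,
            MC_Na=spec.mc_na,
            MC_Li=spec.mc_li,
        )
        return classical_ghk_solve(bath, constants).Vm
    if spec.quantity == "quantum_Vm":
        bath = MembraneBath(Li_out=setting["Li_out"], li_ratio=spec.li_ratio)
        pop = ChannelPopulation(setting["D"], gate)
        return quantum_ghk_solve(bath, ion, pop, constants).Vm
    raise AssertionError("unreachable")


def run_sweep(spec: SweepSpec, constants: PhysicalConstants | None = None) -> pd.DataFrame:
    """Evaluate the sweep; returns a tidy frame (variable, ion, value[, log10])."""
    constants = constants or get_constants()
    rows = []
    for ion_label in spec.ions:
        for value in spec.grid():
            y = _evaluate(spec, ion_label, float(value), constants)
            rows.append({spec.variable: float(value), "ion": ion_label, spec.quantity: y})
    frame = pd.DataFrame(rows)
    if spec.quantity in _LOG_QUANTITIES:
        frame[f"log10_{spec.quantity}"] = np.log10(frame[spec.quantity])
    return frame
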