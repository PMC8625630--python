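"""Li-6/Li-7 discrimination: ratio closed forms and secant rates of change.

Because the tunneling exponent scales with sqrt(mass), the two lithium
isotopes tunnel at measurably different rates; the ratio of their
transmission probabilities (equal to the ratio of their quantum
conductances) is

    Li-6/Li-7 = exp(dc * (L/G) * (G - KE)^(3/2)),

with dc the difference of the isotope exponent coefficients (1.4 with
the rounded coefficients 19.2 and 17.8).  This greatly exceeds the
classical bounds 1.006 (diffusion) to 1.17 (field acceleration), which is
the model's experimentally testable discriminator.  The rate-of-change
statistics are plain secant slopes between the endpoints of the modelled
parameter intervals (G in [3, 7], L in [0, 2], Vm in [0, 87] mV).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from .constants import ENERGY_SCALE, PhysicalConstants, exponent_coefficient, get_constants
from .tunneling import (
    GateBarrier,
    KineticEnergy,
    extracellular_kinetic_energy,
    get_ion,
    intracellular_kinetic_energy,
)

__all__ = ["IsotopeRatioResult", "isotope_ratio", "isotope_ratio_at", "ratio_rate_of_change"]

Side = Literal["extra", "intra"]

#: Classical upper bound on the isotope conductance ratio (field acceleration).
CLASSICAL_RATIO_MAX = 1.17
#: Classical diffusion-limited isotope ratio.
CLASSICAL_RATIO_DIFFUSION = 1.006

#: Endpoints of the modelled intervals for the secant rates, keyed by variable.
RATE_ENDPOINTS = {"G": (3.0, 7.0), "L": (0.0, 2.0), "Vm": (0.0, 0.087)}


@dataclass(frozen=True)
class IsotopeRatioResult:
    """Li-6/Li-7 tunneling-probability ratio at an evaluation point."""

    ratio: float
    side: Side
    G: float
    L: float
    Vm: float | None  # None on the intracellular side


def isotope_ratio(
    gate: GateBarrier,
    ke: KineticEnergy,
    constants: PhysicalConstants | None = None,
) -> float:
    """Closed-form Li-6/Li-7 ratio for a given gate and kinetic energy.

    Equals tunneling_probability(Li-6)/tunneling_probability(Li-7) to
    machine precision; the clamp at KE >= g (both probabilities 1) gives
    ratio 1, as does a zero-length gate.
    """
    constants = constants or get_constants()
    dc = exponent_coefficient(get_ion("Li-7"), constants) - exponent_coefficient(
        get_ion("Li-6"), constants
    )
    G, L = gate.G, gate.L
    ke_scaled = ke.value / ENERGY_SCALE
    if ke_scaled >= G or L == 0.0:
        return 1.0
    return math.exp(dc * (L / G) * (G - ke_scaled) ** 1.5)


def isotope_ratio_at(
    side: Side,
    G: float,
    L: float,
    Vm: float | None = None,
    constants: PhysicalConstants | None = None,
) -> IsotopeRatioResult:
    """Ratio at a scaled-unit evaluation point (Vm required on the 'extra' side)."""
    constants = constants or get_constants()
    gate = GateBarrier.from_scaled(G, L)
    if side == "extra":
        if Vm is None:
            raise ValueError("extracellular ratio needs a membrane potential Vm")
        ke = extracellular_kinetic_energy(Vm, get_ion("Li-7"), constants)
    elif side == "intra":
        ke = intracellular_kinetic_energy(constants)
        Vm = None
    else:
        raise ValueError(f"side must be 'extra' or 'intra', got {side!r}")
    return IsotopeRatioResult(isotope_ratio(gate, ke, constants), side, G, L, Vm)


def ratio_rate_of_change(
    variable: Literal["G", "L", "Vm"],
    side: Side,
    constants: PhysicalConstants | None = None,
    endpoints: tuple[float, float] | None = None,
    fixed: dict[str, float] | None = None,
) -> dict[str, float]:
    """Secant slope of the isotope ratio over the modelled interval.

    Units: per scaled J for G, per scaled m for L, per mV for Vm (the Vm
    endpoints are in volts but the denominator is taken in millivolts).
    Returns the two endpoint ratios and the slope.
    """
    constants = constants or get_constants()
    if variable not in RATE_ENDPOINTS:
        raise ValueError(f"variable must be one of 'G', 'L', 'Vm', got {variable!r}")
    if variable == "Vm" and side != "extra":
        raise ValueError("the membrane potential only enters the extracellular ratio")
    lo, hi = endpoints if endpoints is not None else RATE_ENDPOINTS[variable]
    if lo == hi:
        raise ValueError("rate endpoints must be distinct")
    defaults = {"G": 5.0, "L": 1.0, "Vm": 0.087}
    defaults.update(fixed or {})

    def at(value: float) -> float:
        point = dict(defaults)
        point[variable] = value
        Vm = point["Vm"] if side == "extra" else None
        return isotope_ratio_at(side, point["G"], point["L"], Vm, constants).ratio

    r_lo, r_hi = at(lo), at(hi)
    denom = (hi - lo) * (1e3 if variable == "Vm" else 1.0)
    return {"lower": r_lo, "upper": r_hi, "rate": (r_hi - r_lo) / denom}
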