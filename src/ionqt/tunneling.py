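"""Tunneling of monovalent cations through the closed channel gate.

The closed intracellular gate of a voltage-gated sodium channel is modelled
as a linear energy ramp U(x) = g*x/w on x in [0, w]: the work needed to
force the gate open, spread evenly over the gate length.  An ion with
kinetic energy KE < g faces a classically forbidden region [x1, w] with
x1 = w*KE/g, and crosses it with probability

    T_Q = exp(-sqrt(8 m)/hbar * (2w/3g) * (g - KE)^(3/2))

Extracellular ions arrive at the gate having fallen through the membrane
potential, so KE = q*Vm + (3/2) kB T; intracellular ions carry the thermal
term alone.  The single-channel conductance is the conductance quantum
q^2/h scaled by T_Q, and a membrane patch with D such channels per cm^2
has conductance density D * C_Q (reported in mS/cm^2).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal

from scipy.integrate import quad

from .constants import (
    ENERGY_SCALE,
    LENGTH_SCALE,
    PhysicalConstants,
    conductance_quantum,
    exponent_coefficient,
    get_constants,
    resting_thermal_energy,
)

__all__ = [
    "IonSpecies",
    "GateBarrier",
    "BarrierProfile",
    "KineticEnergy",
    "TunnelingResult",
    "ChannelPopulation",
    "get_ion",
    "ION_REGISTRY",
    "extracellular_kinetic_energy",
    "intracellular_kinetic_energy",
    "tunneling_exponent",
    "tunneling_probability",
    "exponent_integral_oracle",
    "single_channel_conductance",
    "membrane_conductance",
]


class PlausibilityWarning(UserWarning):
    """Parameter outside the range the model was exercised over."""


@dataclass(frozen=True)
class IonSpecies:
    """A tunneling ion: label, mass (kg) and charge (C)."""

    label: str
    mass: float
    charge: float = 1.6e-19

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError("ion mass must be strictly positive")
        if self.charge <= 0:
            raise ValueError("ion charge must be strictly positive (monovalent cation model)")


#: Built-in species. Masses: Li-7 and Li-6 differ by one neutron; K for the
#: worked single-channel comparison.
ION_REGISTRY: dict[str, IonSpecies] = {
    "Li-7": IonSpecies("Li-7", 1.15e-26),
    "Li-6": IonSpecies("Li-6", 9.83e-27),
    "K": IonSpecies("K", 6.5e-26),
}


def get_ion(label: str) -> IonSpecies:
    try:
        return ION_REGISTRY[label]
    except KeyError:
        raise KeyError(
            f"unknown ion {label!r}; registered ions: {sorted(ION_REGISTRY)}"
        ) from None


@dataclass(frozen=True)
class GateBarrier:
    """Closed-gate barrier: energy ``g`` (J) and length ``w`` (m)."""

    g: float
    w: float

    def __post_init__(self) -> None:
        if self.g <= 0:
            raise ValueError("gate energy g must be strictly positive")
        if self.w < 0:
            raise ValueError("gate length w must be non-negative")
        # ulp-tolerant bounds: 3 * 1e-20 lands one ulp below the literal 3e-20
        if not (3e-20 * (1 - 1e-9) <= self.g <= 7e-20 * (1 + 1e-9)):
            warnings.warn(
                f"gate energy {self.g:.3g} J outside the modelled range 3-7e-20 J",
                PlausibilityWarning,
                stacklevel=2,
            )
        if self.w > 2e-10 * (1 + 1e-9):
            warnings.warn(
                f"gate length {self.w:.3g} m outside the modelled range 0-2e-10 m",
                PlausibilityWarning,
                stacklevel=2,
            )

    @classmethod
    def from_scaled(cls, G: float, L: float) -> "GateBarrier":
        """Build from the dimensionless presentation units (G in 1e-20 J, L in 1e-10 m)."""
        return cls(g=G * ENERGY_SCALE, w=L * LENGTH_SCALE)

    @property
    def G(self) -> float:
        return self.g / ENERGY_SCALE

    @property
    def L(self) -> float:
        return self.w / LENGTH_SCALE


@dataclass(frozen=True)
class BarrierProfile:
    """Linear ramp U(x) = g*x/w on [0, w] with its forbidden region."""

    gate: GateBarrier

    def energy(self, x: float) -> float:
        if self.gate.w == 0:
            return 0.0
        return self.gate.g * x / self.gate.w

    def forbidden_region(self, ke: float) -> tuple[float, float]:
        """[x1, x2] where U(x) > KE; collapses to an empty interval at KE >= g."""
        if ke >= self.gate.g:
            return (self.gate.w, self.gate.w)
        return (self.gate.w * ke / self.gate.g, self.gate.w)


@dataclass(frozen=True)
class KineticEnergy:
    """Kinetic energy (J) of an ion hitting the gate, tagged by origin."""

    value: float
    origin: Literal["extracellular", "intracellular"]

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("kinetic energy must be non-negative")


@dataclass(frozen=True)
class TunnelingResult:
    """Tunneling probability with its exponent and echoed inputs."""

    probability: float
    exponent: float
    ion: IonSpecies
    gate: GateBarrier
    ke: KineticEnergy


@dataclass(frozen=True)
class ChannelPopulation:
    """Areal density of closed channels whose gates support tunneling."""

    density: float  # channels per cm^2
    gate: GateBarrier

    def __post_init__(self) -> None:
        if self.density < 0:
            raise ValueError("channel density must be non-negative")


def extracellular_kinetic_energy(
    Vm: float, ion: IonSpecies, constants: PhysicalConstants | None = None
) -> KineticEnergy:
    """KE of an extracellular ion at the gate: q*Vm plus the thermal term.

    ``Vm`` is the magnitude of the inside-negative resting potential in
    volts; signed values are rejected rather than silently folded.
    """
    if Vm < 0:
        raise ValueError(
            "Vm must be the magnitude of the inside-negative resting potential; "
            "pass abs(Vm)"
        )
    constants = constants or get_constants()
    return KineticEnergy(
        value=ion.charge * Vm + resting_thermal_energy(constants),
        origin="extracellular",
    )


def intracellular_kinetic_energy(constants: PhysicalConstants | None = None) -> KineticEnergy:
    """KE of an intracellular ion at the gate: the thermal term alone."""
    constants = constants or get_constants()
    return KineticEnergy(value=resting_thermal_energy(constants), origin="intracellular")


def tunneling_exponent(
    ion: IonSpecies,
    gate: GateBarrier,
    ke: KineticEnergy,
    constants: PhysicalConstants | None = None,
) -> float:
    """Barrier-penetration exponent; zero once the barrier is surmounted.

    Evaluated in the scaled unit system (exactly equivalent to the SI
    closed form): coefficient * (L/G) * (G - KE/1e-20)^(3/2).  For
    KE >= g the forbidden region is empty and the exponent is defined as
    0, consistent with the w = 0 limit.
    """
    constants = constants or get_constants()
    G = gate.G
    L = gate.L
    ke_scaled = ke.value / ENERGY_SCALE
    if ke_scaled >= G or L == 0.0:
        return 0.0
    coef = exponent_coefficient(ion, constants)
    return coef * (L / G) * (G - ke_scaled) ** 1.5


def tunneling_probability(
    ion: IonSpecies,
    gate: GateBarrier,
    ke: KineticEnergy,
    constants: PhysicalConstants | None = None,
) -> TunnelingResult:
    """Transmission probability exp(-exponent) through the closed gate."""
    constants = constants or get_constants()
    exponent = tunneling_exponent(ion, gate, ke, constants)
    return TunnelingResult(
        probability=math.exp(-exponent), exponent=exponent, ion=ion, gate=gate, ke=ke
    )


def exponent_integral_oracle(
    ion: IonSpecies,
    profile: BarrierProfile,
    ke: KineticEnergy,
    constants: PhysicalConstants | None = None,
) -> float:
    """Exponent by adaptive quadrature of sqrt(U(x) - KE) over [x1, x2].

    Independent numerical check of the closed form in
    :func:`tunneling_exponent`; always computed with full-precision
    prefactors (the quadrature has no notion of printed rounding).
    """
    constants = constants or get_constants()
    x1, x2 = profile.forbidden_region(ke.value)
    if x2 <= x1:
        return 0.0
    prefactor = math.sqrt(8.0 * ion.mass) / constants.hbar

    def integrand(x: float) -> float:
        return math.sqrt(max(profile.energy(x) - ke.value, 0.0))

    # the integral is ~1e-20 in SI magnitude, far below quad's default
    # absolute tolerance; drive the adaptive scheme on relative error only
    integral, abserr = quad(integrand, x1, x2, epsabs=0.0, epsrel=1e-11, limit=500)
    if integral > 0 and abserr / integral > 1e-8:
        raise ArithmeticError(
            f"quadrature did not converge: integral={integral!r}, abserr={abserr!r}"
        )
    return prefactor * integral


def single_channel_conductance(
    ion: IonSpecies,
    tq: TunnelingResult,
    constants: PhysicalConstants | None = None,
) -> float:
    """Single-channel conductance C_Q = (q^2/h) * T_Q in siemens."""
    constants = constants or get_constants()
    if not (0.0 < tq.probability <= 1.0):
        raise ValueError("tunneling probability must lie in (0, 1]")
    return conductance_quantum(constants) * tq.probability


def membrane_conductance(
    ion: IonSpecies,
    tq: TunnelingResult,
    pop: ChannelPopulation,
    constants: PhysicalConstants | None = None,
) -> float:
    """Membrane conductance density MC_Q = D * C_Q, in mS/cm^2."""
    constants = constants or get_constants()
    return pop.density * single_channel_conductance(ion, tq, constants) * 1e3
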