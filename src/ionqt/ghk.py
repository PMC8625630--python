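"""Classical and quantum Goldman-Hodgkin-Katz resting-potential solvers.

Both solvers balance the conductance-weighted concentrations on the two
membrane sides,

    [K]e*MC_K + [Na]e*MC_Na + [Li]e*MC_Li
        = exp(-F*Vm/(R*T)) * ([K]i*MC_K + [Na]i*MC_Na + [Li]i*MC_Li),

with Vm the magnitude of the inside-negative resting potential.  In the
classical branch the lithium term uses a fixed leak conductance and the
equation has a closed-form solution.  In the quantum branch the lithium
conductances are the tunneling membrane conductances: the extracellular
one depends on Vm through the kinetic energy q*Vm + (3/2)kB*T, which
makes the balance transcendental; it is solved by bracketed root-finding
after verifying the residual changes sign exactly once on the bracket.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.optimize import brentq

from .constants import PhysicalConstants, get_constants, ghk_voltage_coefficient
from .tunneling import (
    ChannelPopulation,
    IonSpecies,
    extracellular_kinetic_energy,
    intracellular_kinetic_energy,
    membrane_conductance,
    tunneling_probability,
)

__all__ = [
    "MembraneBath",
    "SolverSettings",
    "PotentialSolution",
    "classical_ghk_solve",
    "quantum_ghk_solve",
    "li6_scaled_leak",
    "depolarization_degree",
]


@dataclass(frozen=True)
class MembraneBath:
    """Ionic concentrations (mmol/L) and leak conductances (mS/cm^2).

    ``li_ratio`` is the intracellular-to-extracellular lithium
    concentration ratio R; the intracellular lithium concentration is
    always derived as ``li_ratio * Li_out``, never stored.
    """

    K_out: float = 4.0
    K_in: float = 140.0
    Na_out: float = 142.0
    Na_in: float = 14.0
    Li_out: float = 0.0
    li_ratio: float = 2.0
    MC_K: float = 0.5
    MC_Na: float = 0.005
    MC_Li: float = 0.0

    def __post_init__(self) -> None:
        for name in ("K_out", "K_in", "Na_out", "Na_in", "Li_out"):
            if getattr(self, name) < 0:
                raise ValueError(f"concentration {name} must be non-negative")
        for name in ("MC_K", "MC_Na", "MC_Li"):
            if getattr(self, name) < 0:
                raise ValueError(f"conductance {name} must be non-negative")
        if not (1.0 <= self.li_ratio <= 4.0):
            warnings.warn(
                f"lithium concentration ratio {self.li_ratio} outside the modelled range 1-4",
                UserWarning,
                stacklevel=2,
            )

    @property
    def Li_in(self) -> float:
        return self.li_ratio * self.Li_out


@dataclass(frozen=True)
class SolverSettings:
    """Bracket and tolerances for the root-finder."""

    bracket: tuple[float, float] = (0.0, 0.2)
    tolerance: float = 1e-7  # V
    max_iterations: int = 200

    def __post_init__(self) -> None:
        lo, hi = self.bracket
        if not (0.0 <= lo < hi):
            raise ValueError("bracket must satisfy 0 <= lo < hi")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass(frozen=True)
class PotentialSolution:
    """Resting-potential magnitude (V) with solver diagnostics."""

    Vm: float
    residual: float
    iterations: int
    branch: Literal["classical", "quantum"]
    flags: tuple[str, ...] = field(default=())

    @property
    def non_polarized(self) -> bool:
        return "non-polarized" in self.flags


def _classical_sums(bath: MembraneBath) -> tuple[float, float]:
    outer = bath.K_out * bath.MC_K + bath.Na_out * bath.MC_Na + bath.Li_out * bath.MC_Li
    inner = bath.K_in * bath.MC_K + bath.Na_in * bath.MC_Na + bath.Li_in * bath.MC_Li
    return outer, inner


def classical_ghk_solve(
    bath: MembraneBath,
    constants: PhysicalConstants | None = None,
    settings: SolverSettings | None = None,
) -> PotentialSolution:
    """Resting potential under classical (leak) lithium transport.

    The balance equation has a single exponential, so the solution is the
    closed form Vm = ln(inner/outer) * RT/F.  An inner sum not exceeding
    the outer one means the membrane would not polarize inside-negative;
    Vm = 0 is returned with a 'non-polarized' flag.
    """
    constants = constants or get_constants()
    settings = settings or SolverSettings()
    outer, inner = _classical_sums(bath)
    if outer <= 0 or inner <= 0:
        raise ValueError("each side needs at least one positive concentration*conductance term")
    coef = ghk_voltage_coefficient(constants)
    if inner <= outer:
        return PotentialSolution(0.0, inner - outer, 0, "classical", ("non-polarized",))
    Vm = math.log(inner / outer) / coef
    return PotentialSolution(Vm, 0.0, 0, "classical")


def li6_scaled_leak(bath: MembraneBath, factor: float) -> MembraneBath:
    """Copy of ``bath`` with the lithium leak conductance scaled by ``factor``.

    The light isotope accelerates more in the same electric field
    (a = qE/m), so its leak conductance can be taken up to 1.17x that of
    Li-7; 1.006 is the diffusion-limited ratio.
    """
    if factor <= 0:
        raise ValueError("conductance scale factor must be positive")
    return replace(bath, MC_Li=bath.MC_Li * factor)


def quantum_ghk_solve(
    bath: MembraneBath,
    ion: IonSpecies,
    pop: ChannelPopulation,
    constants: PhysicalConstants | None = None,
    settings: SolverSettings | None = None,
) -> PotentialSolution:
    """Resting potential with lithium carried by tunneling through closed gates.

    The extracellular lithium conductance depends on the potential being
    solved for, so the balance is transcendental.  The residual
    LHS(Vm) - RHS(Vm) is required to change sign exactly once on a 1 mV
    grid over the bracket before Brent's method refines the root.
    """
    constants = constants or get_constants()
    settings = settings or SolverSettings()
    coef = ghk_voltage_coefficient(constants)
    gate = pop.gate

    mcq_in = membrane_conductance(
        ion,
        tunneling_probability(ion, gate, intracellular_kinetic_energy(constants), constants),
        pop,
        constants,
    )
    fixed_out = bath.K_out * bath.MC_K + bath.Na_out * bath.MC_Na
    fixed_in = bath.K_in * bath.MC_K + bath.Na_in * bath.MC_Na

    def mcq_out(Vm: float) -> float:
        ke = extracellular_kinetic_energy(Vm, ion, constants)
        return membrane_conductance(
            ion, tunneling_probability(ion, gate, ke, constants), pop, constants
        )

    def residual(Vm: float) -> float:
        lhs = fixed_out + bath.Li_out * mcq_out(Vm)
        rhs = math.exp(-coef * Vm) * (fixed_in + bath.li_ratio * bath.Li_out * mcq_in)
        return lhs - rhs

    lo, hi = settings.bracket
    grid = np.arange(lo, hi + 5e-4, 1e-3)
    values = np.array([residual(v) for v in grid])
    signs = np.sign(values)
    changes = int(np.count_nonzero(np.diff(signs[signs != 0])))
    if changes == 0:
        raise ValueError(
            f"no sign change of the GHK residual on [{lo}, {hi}] V "
            f"(residuals {values[0]:.4g} .. {values[-1]:.4g}); widen the bracket"
        )
    if changes > 1:
        raise ValueError(
            f"multiple sign changes of the GHK residual on [{lo}, {hi}] V; "
            "root is not unique for these parameters"
        )

    # refine well past the reported tolerance so the residual guarantee
    # (|residual| < 1e-6 of the left side) holds with margin
    Vm, result = brentq(
        residual,
        lo,
        hi,
        xtol=min(settings.tolerance, 1e-10),
        maxiter=settings.max_iterations,
        full_output=True,
    )
    res = residual(Vm)
    lhs_mag = fixed_out + bath.Li_out * mcq_out(Vm)
    if abs(res) > 1e-6 * lhs_mag:
        raise ArithmeticError(f"root-finder converged poorly: residual {res:.3g}")
    return PotentialSolution(Vm, res, result.iterations, "quantum")


def depolarization_degree(initial: PotentialSolution, with_li: PotentialSolution) -> float:
    """DD = Vm(initial) - Vm(with lithium), in volts; positive = depolarized."""
    if initial.Vm < 0 or with_li.Vm < 0:
        raise ValueError("potential magnitudes must be non-negative")
    return initial.Vm - with_li.Vm
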