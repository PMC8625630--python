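"""Reproduction harness for the 36 printed tables.

Every printed cell is recomputed from the model with the table's stated
settings and compared against the packaged fixture
(``_fixtures/tables.yaml``) at a per-cell tolerance.  Cells the source
itself prints inconsistently are flagged — reported with their computed
value and a reason, but never counted as a pass or a failure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd
import yaml

from .constants import PhysicalConstants, get_constants, round_half_up
from .ghk import MembraneBath, classical_ghk_solve, quantum_ghk_solve
from .isotopes import isotope_ratio_at, ratio_rate_of_change
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

__all__ = [
    "CellResult",
    "ComparisonReport",
    "load_fixtures",
    "reproduce_table",
    "reproduce_all",
    "potassium_worked_example",
]

_REFERENCE = {"G": 5.0, "L": 1.0, "Vm": 0.087, "D": 1e11}


@dataclass(frozen=True)
class CellResult:
    table_id: int | str
    label: str
    computed: float
    expected: float
    deviation: float  # relative where tol_rel applies, absolute otherwise
    tolerance: float
    tolerance_kind: str  # 'rel' or 'abs'
    status: str  # 'pass', 'fail' or 'flagged'
    flag: str | None = None


@dataclass(frozen=True)
class ComparisonReport:
    cells: tuple[CellResult, ...]

    @property
    def n_pass(self) -> int:
        return sum(c.status == "pass" for c in self.cells)

    @property
    def n_fail(self) -> int:
        return sum(c.status == "fail" for c in self.cells)

    @property
    def flagged(self) -> tuple[CellResult, ...]:
        return tuple(c for c in self.cells if c.status == "flagged")

    @property
    def ok(self) -> bool:
        """True when no non-flagged cell failed."""
        return self.n_fail == 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.__dict__ for c in self.cells])


def load_fixtures() -> dict:
    """Parse the packaged fixture file."""
    text = resources.files("ionqt").joinpath("_fixtures/tables.yaml").read_text()
    return yaml.safe_load(text)


def _quantum_quantity(entry: dict, cell: dict, constants: PhysicalConstants) -> float:
    setting = dict(_REFERENCE)
    setting.update({k: float(v) for k, v in entry.get("fixed", {}).items()})
    setting[entry["vary"]] = float(cell["at"])
    ion = get_ion(cell["ion"])
    gate = GateBarrier.from_scaled(setting["G"], setting["L"])
    if entry["side"] == "extra":
        ke = extracellular_kinetic_energy(setting["Vm"], ion, constants)
    else:
        ke = intracellular_kinetic_energy(constants)
    tq = tunneling_probability(ion, gate, ke, constants)
    quantity = entry["quantity"]
    if quantity == "tunneling_probability":
        return tq.probability
    if quantity == "single_channel_conductance":
        return single_channel_conductance(ion, tq, constants)
    if quantity == "membrane_conductance":
        pop = ChannelPopulation(setting["D"], gate)
        return membrane_conductance(ion, tq, pop, constants)
    raise ValueError(f"unknown quantity {quantity!r}")


def _classical_vm(entry: dict, R: float, li_out: float, constants: PhysicalConstants) -> float:
    bath = MembraneBath(
        Li_out=li_out,
        li_ratio=R,
        MC_Na=float(entry["mc_na"]),
        MC_Li=float(entry["mc_li"]),
    )
    return classical_ghk_solve(bath, constants).Vm


def _classical_baseline(entry: dict, constants: PhysicalConstants) -> float:
    bath = MembraneBath(Li_out=0.0, li_ratio=1.0, MC_Na=float(entry["mc_na"]), MC_Li=0.0)
    return classical_ghk_solve(bath, constants).Vm


def _quantum_vm(entry: dict, ion_label: str, li_out: float, constants: PhysicalConstants) -> float:
    fixed = {k: float(v) for k, v in entry.get("fixed", {}).items()}
    gate = GateBarrier.from_scaled(fixed.get("G", 5.0), fixed.get("L", 1.0))
    pop = ChannelPopulation(float(entry["D"]), gate)
    bath = MembraneBath(Li_out=li_out, li_ratio=2.0)
    return quantum_ghk_solve(bath, get_ion(ion_label), pop, constants).Vm


def _isotope_cell(entry: dict, cell: dict, constants: PhysicalConstants) -> float:
    side = entry["side"]
    fixed = {k: float(v) for k, v in entry.get("fixed", {}).items()}
    if cell.get("rate"):
        return ratio_rate_of_change(entry["vary"], side, constants, fixed=fixed)["rate"]
    point = {"G": 5.0, "L": 1.0, "Vm": 0.087}
    point.update(fixed)
    point[entry["vary"]] = float(cell["at"])
    Vm = point["Vm"] if side == "extra" else None
    return isotope_ratio_at(side, point["G"], point["L"], Vm, constants).ratio


def _compare(
    table_id, label, computed, expected, tol, kind, flag=None
) -> CellResult:
    if kind == "rel":
        deviation = abs(computed - expected) / abs(expected) if expected != 0 else abs(computed)
    else:
        deviation = abs(computed - expected)
    if flag is not None:
        status = "flagged"
    else:
        status = "pass" if deviation <= tol + 1e-12 else "fail"
    return CellResult(table_id, label, computed, expected, deviation, tol, kind, status, flag)


def _cell_tolerance(entry: dict, cell: dict) -> tuple[float, str]:
    if "tol_abs" in cell:
        return float(cell["tol_abs"]), "abs"
    if "tol_rel" in cell:
        return float(cell["tol_rel"]), "rel"
    if "tol_abs" in entry:
        return float(entry["tol_abs"]), "abs"
    return float(entry["tol_rel"]), "rel"


def reproduce_table(
    table_id: int,
    constants: PhysicalConstants | None = None,
    tol_override: float | None = None,
) -> ComparisonReport:
    """Recompute every cell of one table and compare to the printed values."""
    constants = constants or get_constants()
    fixtures = load_fixtures()
    entry = next((t for t in fixtures["tables"] if t["id"] == table_id), None)
    if entry is None:
        raise KeyError(f"no fixture for table {table_id!r}")

    kind = entry["kind"]
    results = []
    for cell in entry["cells"]:
        expected = float(cell["expected"])
        tol, tol_kind = _cell_tolerance(entry, cell)
        if tol_override is not None:
            tol = tol_override
        flag = cell.get("flag")

        if kind == "quantum_quantity":
            label = f"{cell['ion']} @ {entry['vary']}={cell['at']}"
            computed = _quantum_quantity(entry, cell, constants)
        elif kind == "classical_vm":
            label = f"R={cell['R']} @ Li_out={cell['li_out']}"
            computed = _classical_vm(entry, float(cell["R"]), float(cell["li_out"]), constants)
        elif kind == "classical_dd":
            label = f"R={cell['R']} @ Li_out={cell['li_out']}"
            baseline = round_half_up(_classical_baseline(entry, constants), 3)
            vm = round_half_up(
                _classical_vm(entry, float(cell["R"]), float(cell["li_out"]), constants), 3
            )
            computed = baseline - vm
        elif kind == "quantum_vm":
            label = f"{cell['ion']} @ Li_out={cell['li_out']}"
            computed = _quantum_vm(entry, cell["ion"], float(cell["li_out"]), constants)
        elif kind == "quantum_dd":
            label = f"{cell['ion']} @ Li_out={cell['li_out']}"
            baseline = round_half_up(classical_ghk_solve(MembraneBath(), constants).Vm, 3)
            vm = round_half_up(_quantum_vm(entry, cell["ion"], float(cell["li_out"]), constants), 3)
            computed = baseline - vm
        elif kind == "isotope":
            label = "rate" if cell.get("rate") else f"{entry['vary']}={cell['at']}"
            computed = _isotope_cell(entry, cell, constants)
        else:
            raise ValueError(f"unknown table kind {kind!r}")

        results.append(_compare(table_id, label, computed, expected, tol, tol_kind, flag))
    return ComparisonReport(tuple(results))


def potassium_worked_example(constants: PhysicalConstants | None = None) -> CellResult:
    """Recompute the quoted potassium single-channel conductance (flagged)."""
    constants = constants or get_constants()
    fixtures = load_fixtures()
    entry = fixtures["worked_examples"][0]
    fixed = {k: float(v) for k, v in entry["fixed"].items()}
    ion = get_ion(entry["ion"])
    gate = GateBarrier.from_scaled(fixed["G"], fixed["L"])
    ke = extracellular_kinetic_energy(fixed["Vm"], ion, constants)
    computed = single_channel_conductance(
        ion, tunneling_probability(ion, gate, ke, constants), constants
    )
    expected = float(entry["expected"])
    return _compare(entry["id"], "K single-channel", computed, expected, math.inf, "rel", entry["flag"])


def reproduce_all(
    constants: PhysicalConstants | None = None,
    tol_override: float | None = None,
) -> ComparisonReport:
    """Recompute all 36 tables plus the flagged worked example."""
    constants = constants or get_constants()
    fixtures = load_fixtures()
    cells: list[CellResult] = []
    for entry in fixtures["tables"]:
        cells.extend(reproduce_table(entry["id"], constants, tol_override).cells)
    cells.append(potassium_worked_example(constants))
    return ComparisonReport(tuple(cells))
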