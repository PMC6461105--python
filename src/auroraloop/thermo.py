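"""Equilibrium constants, free energies and thermodynamic-cycle bookkeeping.

Populations of the two activation-loop conformations define a conformational
equilibrium constant ``K_eq = [inactive]/[active]`` and a free energy
``dG = -RT ln K_eq`` (kcal/mol, 25 C by default).  Ligand binding and
phosphorylation each shift the equilibrium by a characteristic free energy:

    ddG_ligand          = dG_apo - dG_ligand      (same phosphorylation state)
    ddG_phosphorylation = dG_unphos - dG_phos     (same ligand)

and any condition's dG composes additively from the unphosphorylated apo
reference::

    dG = dG_apo_unphos - ddG_phosphorylation - ddG_ligand

The independence check quantifies how well ddG_ligand agrees between the two
phosphorylation states across a table of conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .histogram import ConformationalPopulations

__all__ = [
    "R_KCAL",
    "DEFAULT_TEMPERATURE",
    "Condition",
    "EquilibriumResult",
    "IndependenceReport",
    "equilibrium_constant",
    "free_energy",
    "equilibrium_result",
    "ddG",
    "compose_free_energy",
    "independence_check",
    "display_keq",
    "display_value",
]

#: gas constant, kcal mol^-1 K^-1
R_KCAL = 1.9872e-3
#: 25 C
DEFAULT_TEMPERATURE = 298.15

#: displayed K_eq errors are floored here to match common reporting practice
KEQ_ERROR_DISPLAY_FLOOR = 0.1


@dataclass(frozen=True)
class Condition:
    """One experimental condition: construct, phosphorylation state, ligand."""

    construct: str
    phosphorylated: bool
    ligand: str  # "apo" for unliganded

    def __post_init__(self) -> None:
        if not self.construct or not self.ligand:
            raise ValueError("construct and ligand must be set")

    @property
    def label(self) -> str:
        p = "phos" if self.phosphorylated else "unphos"
        return f"{self.construct}/{p}/{self.ligand}"


@dataclass
class EquilibriumResult:
    """K_eq and dG (with propagated errors) for one condition."""

    condition: Condition
    keq: float
    keq_err: float
    dg: float          # kcal/mol
    dg_err: float
    temperature: float

    def __post_init__(self) -> None:
        if self.keq <= 0:
            raise ValueError("K_eq must be positive")
        expected = -R_KCAL * self.temperature * math.log(self.keq)
        if abs(expected - self.dg) > 1e-9:
            raise ValueError("dG inconsistent with -RT ln(K_eq)")


def equilibrium_constant(pop: ConformationalPopulations) -> tuple[float, float]:
    """K_eq = pct_inactive / pct_active with quadrature error propagation.

    The ratio uses the populations exactly as supplied (no renormalization to
    100%): fitted peak areas need not sum to one, and downstream numbers only
    reproduce reported values when the raw ratio is kept.
    """
    if pop.pct_active <= 0:
        raise ValueError("active population must be positive (K_eq would be infinite)")
    if pop.pct_inactive <= 0:
        raise ValueError("inactive population must be positive")
    keq = pop.pct_inactive / pop.pct_active
    err = keq * math.sqrt(
        (pop.err_inactive / pop.pct_inactive) ** 2 + (pop.err_active / pop.pct_active) ** 2
    )
    return keq, err


def free_energy(
    keq: float, keq_err: float = 0.0, temperature: float = DEFAULT_TEMPERATURE
) -> tuple[float, float]:
    """dG = -RT ln(K_eq) in kcal/mol; error = RT * (err_K / K_eq)."""
    if keq <= 0:
        raise ValueError("K_eq must be positive")
    rt = R_KCAL * temperature
    return -rt * math.log(keq), rt * keq_err / keq


def equilibrium_result(
    condition: Condition,
    pop: ConformationalPopulations,
    temperature: float = DEFAULT_TEMPERATURE,
) -> EquilibriumResult:
    keq, keq_err = equilibrium_constant(pop)
    dg, dg_err = free_energy(keq, keq_err, temperature)
    return EquilibriumResult(
        condition=condition, keq=keq, keq_err=keq_err, dg=dg, dg_err=dg_err,
        temperature=temperature,
    )


def ddG(
    dg_ref: float, dg_other: float, err_ref: float = 0.0, err_other: float = 0.0
) -> tuple[float, float]:
    """ddG = dG_ref - dG_other; errors in quadrature."""
    for v in (dg_ref, dg_other):
        if not math.isfinite(v):
            raise ValueError("free energies must be finite")
    return dg_ref - dg_other, math.hypot(err_ref, err_other)


def compose_free_energy(dg_apo_unphos: float, ddg_phosphorylation: float, ddg_ligand: float) -> float:
    """dG for any condition from the unphosphorylated apo reference.

    Either delta may be zero (unphosphorylated and/or unliganded).
    """
    return dg_apo_unphos - ddg_phosphorylation - ddg_ligand


@dataclass
class IndependenceReport:
    """Cross-phosphorylation-state consistency of the per-ligand ddG."""

    per_ligand: dict[str, float]   # ligand -> |ddG_ligand(phos) - ddG_ligand(unphos)|
    max_deviation: float
    worst_ligand: str


def independence_check(results: list[EquilibriumResult]) -> IndependenceReport:
    """Test whether the ligand-induced equilibrium shift is phosphorylation-independent.

    For every non-apo ligand present, computes ddG_ligand in each
    phosphorylation state (requiring the matching apo condition) and reports
    the absolute difference between the two states.  Conditions are matched on
    phosphorylation state and ligand regardless of reporter construct.
    """
    dg: dict[tuple[bool, str], float] = {}
    for r in results:
        dg[(r.condition.phosphorylated, r.condition.ligand)] = r.dg

    ligands = sorted({lig for (_, lig) in dg if lig != "apo"})
    if not ligands:
        raise ValueError("no liganded conditions supplied")

    per_ligand: dict[str, float] = {}
    for lig in ligands:
        needed = [(True, "apo"), (False, "apo"), (True, lig), (False, lig)]
        missing = [key for key in needed if key not in dg]
        if missing:
            raise ValueError(f"missing conditions for ligand {lig!r}: {missing}")
        ddg_phos = dg[(True, "apo")] - dg[(True, lig)]
        ddg_unphos = dg[(False, "apo")] - dg[(False, lig)]
        per_ligand[lig] = abs(ddg_phos - ddg_unphos)

    worst = max(per_ligand, key=per_ligand.get)
    return IndependenceReport(
        per_ligand=per_ligand, max_deviation=per_ligand[worst], worst_ligand=worst
    )


# ---------------------------------------------------------------------------
# display rounding

def display_value(x: float, decimals: int = 1) -> float:
    """Round for display (banker's rounding, as produced by ``round``)."""
    return round(x, decimals)


def display_keq(keq: float, keq_err: float) -> tuple[float, float]:
    """K_eq and its error at 1 d.p. with the 0.1 error display floor."""
    return round(keq, 1), max(round(keq_err, 1), KEQ_ERROR_DISPLAY_FLOOR)


def results_table(results: list[EquilibriumResult]) -> pd.DataFrame:
    """Tidy per-condition table with full-precision and display columns."""
    rows = []
    for r in results:
        keq_disp, keq_err_disp = display_keq(r.keq, r.keq_err)
        rows.append(
            {
                "construct": r.condition.construct,
                "phosphorylated": r.condition.phosphorylated,
                "ligand": r.condition.ligand,
                "keq": r.keq,
                "keq_err": r.keq_err,
                "dg_kcal_mol": r.dg,
                "dg_err": r.dg_err,
                "keq_display": keq_disp,
                "keq_err_display": keq_err_disp,
                "dg_display": round(r.dg, 1),
            }
        )
    return pd.DataFrame(rows)
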