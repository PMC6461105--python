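"""End-to-end orchestration: simulate/ingest -> fit -> thermodynamics -> reports.

A run is described by a :class:`RunConfig` listing conditions; each condition
carries either stated populations (e.g. from a published occupancy table) or
simulation parameters for the synthetic-trace generator.  The pipeline turns
every condition into populations, K_eq and dG, derives kinetics where traces
exist, runs the phosphorylation-independence check when both phosphorylation
states are available, and can emit a required-discrimination table.

Runs are deterministic given the config seed; a failure in one condition is
recorded per-condition and does not abort the others.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import dwell as dw
from .binding import required_discrimination
from .histogram import (
    ConformationalPopulations,
    fit_two_lognormals_mle,
    pool_intensities,
    populations_from_fit,
)
from .simulate import (
    EmissionModel,
    POLARITY_INACTIVE_LOW,
    SimulationConfig,
    TwoStateRates,
    simulate_ensemble,
)
from .thermo import (
    Condition,
    DEFAULT_TEMPERATURE,
    EquilibriumResult,
    IndependenceReport,
    display_keq,
    equilibrium_result,
    independence_check,
)

__all__ = [
    "ConditionSpec",
    "RunConfig",
    "ConditionOutcome",
    "ResultsBundle",
    "run_pipeline",
    "reproduce_table2",
]


@dataclass
class ConditionSpec:
    """One condition: either stated populations or a simulation recipe."""

    name: str
    construct: str
    phosphorylated: bool
    ligand: str
    populations: ConformationalPopulations | None = None
    simulation: SimulationConfig | None = None

    def __post_init__(self) -> None:
        if (self.populations is None) == (self.simulation is None):
            raise ValueError(
                f"condition {self.name!r} must carry exactly one of populations or simulation"
            )

    @property
    def condition(self) -> Condition:
        return Condition(self.construct, self.phosphorylated, self.ligand)


@dataclass
class RunConfig:
    conditions: list[ConditionSpec]
    temperature: float = DEFAULT_TEMPERATURE
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        seed = int(d.get("seed", 0))
        conditions = []
        for i, c in enumerate(d.get("conditions", [])):
            pops = sim = None
            if "populations" in c:
                p = c["populations"]
                pops = ConformationalPopulations(
                    pct_inactive=p["pct_inactive"],
                    err_inactive=p.get("err_inactive", 0.0),
                    pct_active=p["pct_active"],
                    err_active=p.get("err_active", 0.0),
                    polarity=p.get("polarity", c.get("polarity", POLARITY_INACTIVE_LOW)),
                )
            if "simulate" in c:
                s = c["simulate"]
                # derive a per-condition child seed from the run seed
                child = int(np.random.SeedSequence([seed, i]).generate_state(1)[0]) % 2**31
                sim = SimulationConfig(
                    rates=TwoStateRates(s["k_active"], s["k_inactive"]),
                    emission=EmissionModel(**s.get("emission", {})),
                    frame_interval=s.get("frame_interval", 0.08),
                    n_frames=s.get("n_frames", 500),
                    n_molecules=s.get("n_molecules", 500),
                    polarity=c.get("polarity", POLARITY_INACTIVE_LOW),
                    seed=s.get("seed", child),
                )
            conditions.append(
                ConditionSpec(
                    name=c.get("name", f"condition_{i}"),
                    construct=c.get("construct", "K224C/S283C"),
                    phosphorylated=bool(c["phosphorylated"]),
                    ligand=c.get("ligand", "apo"),
                    populations=pops,
                    simulation=sim,
                )
            )
        return cls(
            conditions=conditions,
            temperature=float(d.get("temperature", DEFAULT_TEMPERATURE)),
            seed=seed,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class ConditionOutcome:
    spec: ConditionSpec
    status: str                         # "ok" | "error"
    error: str | None = None
    populations: ConformationalPopulations | None = None
    equilibrium: EquilibriumResult | None = None
    kinetics: dict[str, float] | None = None
    provenance: dict[str, Any] = field(default_factory=dict)


@dataclass
class ResultsBundle:
    outcomes: list[ConditionOutcome]
    independence: IndependenceReport | None
    temperature: float
    seed: int

    def table(self) -> pd.DataFrame:
        rows = []
        for oc in self.outcomes:
            row: dict[str, Any] = {
                "name": oc.spec.name,
                "construct": oc.spec.construct,
                "phosphorylated": oc.spec.phosphorylated,
                "ligand": oc.spec.ligand,
                "status": oc.status,
            }
            if oc.status == "ok":
                r = oc.equilibrium
                keq_disp, keq_err_disp = display_keq(r.keq, r.keq_err)
                row.update(
                    pct_inactive=oc.populations.pct_inactive,
                    pct_active=oc.populations.pct_active,
                    keq=r.keq,
                    keq_err=r.keq_err,
                    dg_kcal_mol=r.dg,
                    dg_err=r.dg_err,
                    keq_display=keq_disp,
                    keq_err_display=keq_err_disp,
                    dg_display=round(r.dg, 1),
                )
                if oc.kinetics:
                    row.update({f"kin_{k}": v for k, v in oc.kinetics.items()})
            else:
                row["error"] = oc.error
            rows.append(row)
        return pd.DataFrame(rows)


def _process_condition(spec: ConditionSpec, temperature: float) -> ConditionOutcome:
    provenance: dict[str, Any] = {"source": "populations" if spec.populations else "simulation"}
    kinetics = None
    if spec.populations is not None:
        pops = spec.populations
    else:
        ens = simulate_ensemble(spec.simulation)
        provenance.update(seed=ens.seed, n_molecules=len(ens.traces))
        fit = fit_two_lognormals_mle(pool_intensities(ens.traces))
        pops = populations_from_fit(fit, spec.simulation.polarity)
        keq_fit = pops.pct_inactive / pops.pct_active
        # dwell kinetics on the inactive-reporting state
        threshold = dw.threshold_from_fit(fit)
        state = dw.LOW if spec.simulation.polarity == POLARITY_INACTIVE_LOW else dw.HIGH
        pooled: dw.DwellTimeSet | None = None
        for tr in ens.traces:
            ds = dw.extract_dwells(dw.assign_states(tr, threshold), state)
            pooled = ds if pooled is None else pooled.extend(ds)
        k_active = dw.fit_single_exponential(pooled, method="mle")
        k_inactive = dw.derived_k_inactive(k_active, keq_fit)
        kinetics = {
            "k_active": k_active.k,
            "k_active_err": k_active.stderr,
            "k_inactive": k_inactive.k,
            "k_inactive_err": k_inactive.stderr,
            "tau_inactive": 1.0 / k_active.k,
            "tau_active": 1.0 / k_inactive.k,
            "n_dwells": k_active.n_dwells,
            "threshold": threshold,
            "true_fraction_inactive": ens.true_fraction_inactive,
            "fraction_molecules_transitioning": ens.fraction_molecules_transitioning,
        }
    eq = equilibrium_result(spec.condition, pops, temperature)
    return ConditionOutcome(
        spec=spec, status="ok", populations=pops, equilibrium=eq,
        kinetics=kinetics, provenance=provenance,
    )


def run_pipeline(config: RunConfig) -> ResultsBundle:
    """Run every condition, then the cross-condition thermodynamic analyses."""
    if not config.conditions:
        warnings.warn("empty condition list: returning an empty bundle", stacklevel=2)
    outcomes = []
    for spec in config.conditions:
        try:
            outcomes.append(_process_condition(spec, config.temperature))
        except Exception as exc:  # per-condition isolation
            outcomes.append(ConditionOutcome(spec=spec, status="error", error=str(exc)))

    independence = None
    ok_results = [oc.equilibrium for oc in outcomes if oc.status == "ok"]
    try:
        independence = independence_check(ok_results)
    except ValueError:
        pass  # not all ligand/phosphorylation combinations present
    return ResultsBundle(
        outcomes=outcomes, independence=independence,
        temperature=config.temperature, seed=config.seed,
    )


def reproduce_table2(
    keq_map: dict[str, float],
    targets: tuple[float, ...] = (0.99, 0.95, 0.90),
    flagged_inverted: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Required-discrimination table over starting conditions x target inactive fractions.

    ``keq_map`` maps a condition label to its apo/ligand-free K_eq.  Labels in
    ``flagged_inverted`` additionally get a row computed from 1/K_eq, flagged
    in the ``convention`` column — used for a published row that is consistent
    only with the inverted equilibrium constant.
    """
    rows = []
    for label, keq in keq_map.items():
        conventions = [("as_given", keq)]
        if label in flagged_inverted:
            conventions.append(("inverted_keq", 1.0 / keq))
        for convention, k in conventions:
            row: dict[str, Any] = {"condition": label, "keq_start": k, "convention": convention}
            for f in targets:
                res = required_discrimination(k, f)
                pct = int(round(100 * f))
                row[f"discrimination_{pct}"] = res.discrimination
                row[f"fold_{pct}"] = res.fold_preference
                row[f"discrimination_{pct}_display"] = res.display_discrimination
                row[f"fold_{pct}_display"] = res.display_fold
            rows.append(row)
    return pd.DataFrame(rows)
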