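"""Reference measurements used as inputs by the thermodynamics and binding layers.

Single-molecule quench-reporter measurements of Aurora-A kinase-domain
activation-loop occupancies under combinations of reporter construct,
activation-loop phosphorylation state and saturating ligand, together with the
measured inactive-state exit rates.  Populations are percentages from
two-log-normal histogram fits (peak areas, not renormalized to 100%);
``reported_keq``/``reported_dg`` are the values published alongside them,
which were computed from the unrounded fitted areas.

Constructs: ``K224C/S283C`` reports the inactive loop as the quenched (low)
peak; ``M373C/S283C`` is the inverted-polarity reporter.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .histogram import ConformationalPopulations
from .simulate import POLARITY_INACTIVE_HIGH, POLARITY_INACTIVE_LOW
from .thermo import Condition

__all__ = [
    "OccupancyRecord",
    "REFERENCE_OCCUPANCIES",
    "REFERENCE_K_ACTIVE",
    "reference_occupancies",
    "record_condition",
    "record_populations",
]


@dataclass(frozen=True)
class OccupancyRecord:
    construct: str
    phosphorylated: bool
    ligand: str
    pct_inactive: float
    err_inactive: float
    pct_active: float
    err_active: float
    reported_keq: float
    reported_keq_err: float
    reported_dg: float


REFERENCE_OCCUPANCIES: tuple[OccupancyRecord, ...] = (
    OccupancyRecord("K224C/S283C", True, "apo", 23, 1, 77, 1, 0.3, 0.1, 0.7),
    OccupancyRecord("K224C/S283C", True, "TPX2", 14, 2, 86, 2, 0.2, 0.1, 1.1),
    OccupancyRecord("K224C/S283C", True, "MLN8054", 43, 2, 57, 2, 0.7, 0.1, 0.2),
    OccupancyRecord("K224C/S283C", True, "CD532", 64, 1, 36, 2, 1.8, 0.1, -0.4),
    OccupancyRecord("K224C/S283C", False, "apo", 52, 1, 46, 2, 1.1, 0.1, -0.1),
    OccupancyRecord("K224C/S283C", False, "TPX2", 46, 2, 56, 4, 0.8, 0.1, 0.1),
    OccupancyRecord("K224C/S283C", False, "MLN8054", 77, 1, 21, 1, 3.7, 0.2, -0.8),
    OccupancyRecord("K224C/S283C", False, "CD532", 83, 1, 13, 1, 6.3, 0.6, -1.1),
    OccupancyRecord("M373C/S283C", True, "apo", 25, 2, 72, 1, 0.3, 0.1, 0.6),
    OccupancyRecord("M373C/S283C", False, "apo", 51, 2, 47, 1, 1.1, 0.1, -0.0),
)

#: measured inactive-state exit rates k_active (s^-1): (value, standard error)
REFERENCE_K_ACTIVE = {
    "unphosphorylated": (2.1, 0.1),
    "phosphorylated": (2.3, 0.1),
}

#: reporter polarity of each construct
CONSTRUCT_POLARITY = {
    "K224C/S283C": POLARITY_INACTIVE_LOW,
    "M373C/S283C": POLARITY_INACTIVE_HIGH,
}


def reference_occupancies() -> pd.DataFrame:
    """The reference occupancy table as a DataFrame."""
    return pd.DataFrame([vars(r) for r in REFERENCE_OCCUPANCIES])


def record_condition(rec: OccupancyRecord) -> Condition:
    return Condition(rec.construct, rec.phosphorylated, rec.ligand)


def record_populations(rec: OccupancyRecord) -> ConformationalPopulations:
    return ConformationalPopulations(
        pct_inactive=rec.pct_inactive,
        err_inactive=rec.err_inactive,
        pct_active=rec.pct_active,
        err_active=rec.err_active,
        polarity=CONSTRUCT_POLARITY[rec.construct],
    )
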