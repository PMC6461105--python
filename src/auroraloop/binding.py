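"""Conformational-selection ligand binding: discrimination and the K_d,overall surface.

A ligand binds the two pre-existing loop conformations with distinct
dissociation constants ``K_d,active`` and ``K_d,inactive``; their ratio is the
*ligand discrimination* ``D = K_d,inactive / K_d,active`` (values < 1 favour
the inactive conformation; *fold preference* = 1/D).  Under saturating ligand
the conformational equilibrium shifts from ``K_eq,apo`` to
``K_eq,ligand = K_eq,apo / D``, so the discrimination required to drive the
loop to a target inactive fraction follows directly from the apo equilibrium.

The apparent dissociation constant measured over both conformations is the
population-weighted harmonic combination

    K_d,overall = (1 + K_eq,free) / (1/K_d,active + K_eq,free/K_d,inactive)

(trace-ligand conformational-selection mass balance, where ``K_eq,free`` is
the ligand-free equilibrium constant).  The surface of K_d,overall over the
(K_d,active, K_d,inactive) plane carries the lead-optimization geometry:
axis-parallel distances to a target affinity contour, the locus equidistant
from a contour along both axes, and plateau regions where the overall
affinity is insensitive to one conformation-specific constant.

Concentrations are in nM throughout unless noted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "DiscriminationResult",
    "BindingSurfaceGrid",
    "EquidistantCurve",
    "GapDistances",
    "PlateauMask",
    "ligand_discrimination",
    "required_discrimination",
    "kd_overall",
    "kd_overall_mass_balance",
    "kd_surface",
    "log_sensitivities",
    "contour_gap_distances",
    "equidistant_line",
    "plateau_mask",
    "log_axis",
]


@dataclass(frozen=True)
class DiscriminationResult:
    """Ligand discrimination D = K_d,inactive / K_d,active and its reciprocal."""

    discrimination: float
    fold_preference: float

    def __post_init__(self) -> None:
        if self.discrimination <= 0:
            raise ValueError("discrimination must be positive")

    @property
    def display_fold(self) -> int:
        """Fold preference rounded to the nearest integer."""
        return round(self.fold_preference)

    @property
    def display_discrimination(self) -> float:
        """Discrimination displayed as the reciprocal of the rounded fold, 3 d.p.

        This is the convention used in reported required-discrimination tables
        (it reproduces entries such as 0.125 = 1/8 that direct 3-d.p. rounding
        of the raw ratio does not).
        """
        return round(1.0 / self.display_fold, 3)


def ligand_discrimination(keq_apo: float, keq_ligand: float) -> DiscriminationResult:
    """Discrimination of a saturating ligand from the equilibrium shift it causes.

    ``D = K_eq,apo / K_eq,ligand``: a ligand that leaves the equilibrium
    untouched has D = 1; one that enriches the inactive conformation
    (K_eq,ligand > K_eq,apo) has D < 1.
    """
    if keq_apo <= 0 or keq_ligand <= 0:
        raise ValueError("equilibrium constants must be positive")
    d = keq_apo / keq_ligand
    return DiscriminationResult(discrimination=d, fold_preference=1.0 / d)


def required_discrimination(keq_start: float, target_fraction_inactive: float) -> DiscriminationResult:
    """Discrimination needed to drive the loop to a target inactive fraction.

    The target fraction f maps to ``K_eq,target = f / (1 - f)``; the required
    discrimination is then ``K_eq,start / K_eq,target``.
    """
    if keq_start <= 0:
        raise ValueError("K_eq must be positive")
    f = target_fraction_inactive
    if not 0.0 < f < 1.0:
        raise ValueError(
            f"target inactive fraction must lie strictly in (0, 1), got {f} "
            "(an endpoint would require infinite discrimination)"
        )
    keq_target = f / (1.0 - f)
    return ligand_discrimination(keq_start, keq_target)


# ---------------------------------------------------------------------------
# K_d,overall

def kd_overall(kd_active: float, kd_inactive: float, keq_free: float):
    """Apparent K_d over both conformations (closed form).

    Exact limits: ``keq_free -> 0`` gives K_d,active, ``keq_free -> inf`` gives
    K_d,inactive; the result always lies between the two conformation-specific
    constants.  Accepts array inputs.
    """
    kd_active = np.asarray(kd_active, dtype=float)
    kd_inactive = np.asarray(kd_inactive, dtype=float)
    if np.any(kd_active <= 0) or np.any(kd_inactive <= 0) or keq_free < 0:
        raise ValueError("dissociation constants must be positive and K_eq >= 0")
    out = (1.0 + keq_free) / (1.0 / kd_active + keq_free / kd_inactive)
    return float(out) if out.ndim == 0 else out


def kd_overall_mass_balance(
    kd_active: float,
    kd_inactive: float,
    keq_free: float,
    protein_total: float = 1e-6,
) -> float:
    """Numerical K_d,overall from the four-species equilibrium (independent oracle).

    Solves the species balance over {active, inactive, active*ligand,
    inactive*ligand} at trace protein (free ligand ~ total ligand) for a grid
    of free-ligand concentrations, and locates by root finding the ligand
    concentration at which half the protein is bound.  Shares no algebra with
    :func:`kd_overall` beyond the equilibrium definitions themselves.
    """
    if min(kd_active, kd_inactive) <= 0 or keq_free <= 0:
        raise ValueError("inputs must be positive")

    def bound_fraction(ligand_free: float) -> float:
        # solve for free active-conformer concentration a from protein conservation
        def conservation(a: float) -> float:
            i = keq_free * a
            al = a * ligand_free / kd_active
            il = i * ligand_free / kd_inactive
            return a + i + al + il - protein_total

        a = brentq(conservation, 0.0, protein_total, xtol=1e-300, rtol=1e-14)
        i = keq_free * a
        al = a * ligand_free / kd_active
        il = i * ligand_free / kd_inactive
        return (al + il) / protein_total

    lo = min(kd_active, kd_inactive) * 1e-4
    hi = max(kd_active, kd_inactive) * 1e4
    return brentq(lambda l: bound_fraction(l) - 0.5, lo, hi, rtol=1e-12)


def log_axis(low: float, high: float, n: int = 50) -> np.ndarray:
    """Log-spaced axis for the binding surface (defaults cover 1 nM - 10 uM)."""
    if low <= 0 or high <= low or n < 2:
        raise ValueError("need 0 < low < high and n >= 2")
    return np.geomspace(low, high, n)


@dataclass
class BindingSurfaceGrid:
    """K_d,overall evaluated on a (K_d,active, K_d,inactive) log grid.

    ``values[i, j] = kd_overall(kd_active[j], kd_inactive[i], keq_free)``.
    """

    kd_active: np.ndarray    # columns
    kd_inactive: np.ndarray  # rows
    keq_free: float
    values: np.ndarray

    def __post_init__(self) -> None:
        lo = np.minimum.outer(self.kd_inactive, self.kd_active)
        hi = np.maximum.outer(self.kd_inactive, self.kd_active)
        if np.any(self.values < lo - 1e-9) or np.any(self.values > hi + 1e-9):
            raise ValueError("K_d,overall must lie between the conformation-specific constants")


def kd_surface(
    kd_active_axis: np.ndarray,
    kd_inactive_axis: np.ndarray,
    keq_free: float,
) -> BindingSurfaceGrid:
    """Elementwise K_d,overall over the axis product."""
    ka = np.asarray(kd_active_axis, dtype=float)
    ki = np.asarray(kd_inactive_axis, dtype=float)
    if len(ka) < 2 or len(ki) < 2:
        raise ValueError("axes need at least 2 points")
    values = kd_overall(ka[np.newaxis, :], ki[:, np.newaxis], keq_free)
    return BindingSurfaceGrid(kd_active=ka, kd_inactive=ki, keq_free=keq_free, values=values)


def log_sensitivities(kd_active, kd_inactive, keq_free: float):
    """Logarithmic sensitivities of K_d,overall to each axis (analytic).

    Returns ``(s_active, s_inactive)`` with
    ``s_active = d ln K_d,overall / d ln K_d,active``; the two always sum to 1.
    """
    ka = np.asarray(kd_active, dtype=float)
    ki = np.asarray(kd_inactive, dtype=float)
    denom = 1.0 / ka + keq_free / ki
    s_active = (1.0 / ka) / denom
    return s_active, 1.0 - s_active


# ---------------------------------------------------------------------------
# contour geometry

@dataclass(frozen=True)
class GapDistances:
    """Axis-parallel distances (in K_d units) from a point to a contour."""

    delta_active: float    # reduction in K_d,active needed, K_d,inactive fixed
    delta_inactive: float  # reduction in K_d,inactive needed, K_d,active fixed


def _kd_active_on_contour(c: float, kd_inactive: float, keq_free: float) -> float:
    """Closed-form K_d,active with kd_overall = c at fixed K_d,inactive (inf if unreachable)."""
    inv = (1.0 + keq_free) / c - keq_free / kd_inactive
    return 1.0 / inv if inv > 0 else math.inf


def _kd_inactive_on_contour(c: float, kd_active: float, keq_free: float) -> float:
    inv = ((1.0 + keq_free) / c - 1.0 / kd_active) / keq_free
    return 1.0 / inv if inv > 0 else math.inf


def contour_gap_distances(
    kd_active: float,
    kd_inactive: float,
    contour: float,
    keq_free: float,
) -> GapDistances:
    """Distances to the ``contour`` level along each axis, by inverting the closed form.

    The point must lie uphill of the contour (kd_overall >= contour).  If the
    contour cannot be reached by moving along one axis alone (the other
    conformation's affinity already caps the achievable K_d,overall above the
    contour), that distance is infinite.
    """
    here = kd_overall(kd_active, kd_inactive, keq_free)
    if here < contour * (1 - 1e-12):
        raise ValueError(
            f"point has K_d,overall = {here:.6g} below the requested contour {contour:.6g}"
        )
    ka_target = _kd_active_on_contour(contour, kd_inactive, keq_free)
    ki_target = _kd_inactive_on_contour(contour, kd_active, keq_free)
    da = kd_active - ka_target if math.isfinite(ka_target) else math.inf
    di = kd_inactive - ki_target if math.isfinite(ki_target) else math.inf
    # a point exactly on the contour is at zero distance along both axes
    return GapDistances(delta_active=max(da, 0.0), delta_inactive=max(di, 0.0))


@dataclass
class EquidistantCurve:
    """Locus where the two axis-parallel contour distances are equal.

    ``points`` is an (n, 2) array of (K_d,active, K_d,inactive); ``metric``
    records the distance convention (linear in concentration by default; a
    log-space metric is available in :func:`equidistant_line`).
    """

    contour: float
    points: np.ndarray
    metric: str

    def max_log_deviation_from_diagonal(self) -> float:
        if len(self.points) == 0:
            return float("nan")
        return float(np.max(np.abs(np.log(self.points[:, 1] / self.points[:, 0]))))

    def log_deviation_at(self, kd_active: float) -> float:
        """|log(K_d,inactive / K_d,active)| of the locus at a fixed K_d,active.

        The surface is homogeneous of degree one in (K_d,active, K_d,inactive,
        contour), so the locus is scale-invariant and a whole-domain maximum
        deviation does not shrink with the contour value; the "approaches the
        diagonal as affinity increases" behaviour is pointwise — at a fixed
        position on the surface the locus moves onto the diagonal as the
        contour decreases — which is what this evaluates (log-log
        interpolation between traced points).
        """
        if len(self.points) == 0:
            return float("nan")
        ka, ki = self.points[:, 0], self.points[:, 1]
        if not ka.min() <= kd_active <= ka.max():
            raise ValueError(f"K_d,active {kd_active:.4g} outside the traced range")
        lki = np.interp(np.log(kd_active), np.log(ka), np.log(ki))
        return float(abs(lki - np.log(kd_active)))


def equidistant_line(
    contour: float,
    keq_free: float,
    kd_active_axis: np.ndarray | None = None,
    domain: tuple[float, float] = (1.0, 1e4),
    n_points: int = 60,
    metric: str = "linear",
) -> EquidistantCurve:
    """Trace the curve where a point is equidistant from the contour along both axes.

    For each K_d,active in a log grid, solves for the K_d,inactive at which
    ``delta_active == delta_inactive`` (both finite).  ``metric`` is
    ``"linear"`` (differences in K_d units) or ``"log"`` (differences of
    log K_d).  As the contour value decreases the curve approaches the
    diagonal K_d,inactive = K_d,active.
    """
    if metric not in ("linear", "log"):
        raise ValueError("metric must be 'linear' or 'log'")
    ka_axis = (
        np.asarray(kd_active_axis, dtype=float)
        if kd_active_axis is not None
        else log_axis(domain[0], domain[1], n_points)
    )

    def gap_diff(ka: float, ki: float) -> float:
        if kd_overall(ka, ki, keq_free) < contour:
            return math.nan  # downhill of the contour: not part of the locus
        g = contour_gap_distances(ka, ki, contour, keq_free)
        if not (math.isfinite(g.delta_active) and math.isfinite(g.delta_inactive)):
            return math.nan
        if metric == "linear":
            return g.delta_active - g.delta_inactive
        return math.log(ka / (ka - g.delta_active)) - math.log(ki / (ki - g.delta_inactive))

    points = []
    ki_lo, ki_hi = ka_axis[0], ka_axis[-1]
    for ka in ka_axis:
        if kd_overall(ka, ki_hi, keq_free) <= contour:
            continue  # entire column at/below the contour

        def f(log_ki: float) -> float:
            return gap_diff(ka, math.exp(log_ki))

        # restrict to the part of the column uphill of the contour with finite gaps
        lo = math.log(ki_lo)
        hi = math.log(ki_hi)
        grid = np.linspace(lo, hi, 40)
        vals = np.array([f(g) for g in grid])
        ok = np.isfinite(vals)
        sign_change = None
        idx = np.flatnonzero(ok[:-1] & ok[1:] & (np.sign(vals[:-1]) != np.sign(vals[1:])))
        if len(idx):
            sign_change = idx[0]
        if sign_change is None:
            continue
        root = brentq(f, grid[sign_change], grid[sign_change + 1], rtol=1e-14)
        points.append((ka, math.exp(root)))

    if not points:
        warnings.warn(
            f"equidistant locus for contour {contour:.4g} is empty on the domain", stacklevel=2
        )
    return EquidistantCurve(contour=contour, points=np.array(points).reshape(-1, 2), metric=metric)


# ---------------------------------------------------------------------------
# plateaus

@dataclass
class PlateauMask:
    """Regions of the surface insensitive to conformation-specific improvements.

    The two log-sensitivities sum to one, so a surface point can be flat with
    respect to at most one axis; ``insensitive_active``/``insensitive_inactive``
    flag where the named axis' sensitivity falls below the threshold, and
    ``combined`` flags points insensitive to at least one axis.
    """

    insensitive_active: np.ndarray
    insensitive_inactive: np.ndarray
    threshold: float

    @property
    def combined(self) -> np.ndarray:
        return self.insensitive_active | self.insensitive_inactive


def plateau_mask(grid: BindingSurfaceGrid, threshold: float) -> PlateauMask:
    """Flag plateau regions by thresholding the analytic logarithmic sensitivities."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    s_active, s_inactive = log_sensitivities(
        grid.kd_active[np.newaxis, :], grid.kd_inactive[:, np.newaxis], grid.keq_free
    )
    return PlateauMask(
        insensitive_active=s_active < threshold,
        insensitive_inactive=s_inactive < threshold,
        threshold=threshold,
    )
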