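"""Synthetic single-molecule fluorescence traces from a two-state telegraph process.

A surface-tethered kinase molecule interconverts between an *active* and an
*inactive* activation-loop conformation.  The conformational dynamics are a
continuous-time two-state Markov chain: dwell times in the inactive state are
exponential with exit rate ``k_active`` (inactive -> active) and dwells in the
active state are exponential with exit rate ``k_inactive`` (active -> inactive).
A quenching dye pair renders one conformation bright and the other dark, so the
chain is observed as a telegraph signal between two intensity levels, sampled
by a camera that integrates over finite frames (default 80 ms, 500 frames).

Per-frame intensities scatter log-normally around the noiseless level, matching
the mixture model fitted downstream.  Transitions occurring inside a frame
produce intermediate levels via exact time-weighting of the sub-frame dwells.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ACTIVE",
    "INACTIVE",
    "TwoStateRates",
    "EmissionModel",
    "SimulationConfig",
    "IntensityTrace",
    "StateSegments",
    "EnsembleResult",
    "sample_state_path",
    "integrate_to_frames",
    "simulate_ensemble",
    "traces_to_frame",
    "frame_to_traces",
    "write_ensemble_csv",
    "read_traces_csv",
]

ACTIVE = 0
INACTIVE = 1

#: construct polarity flags: which conformation maps to the low intensity level
POLARITY_INACTIVE_LOW = "inactive_low"    # activation-loop label near N-lobe dye when inactive
POLARITY_INACTIVE_HIGH = "inactive_high"  # inverted reporter geometry


@dataclass(frozen=True)
class TwoStateRates:
    """Interconversion rate constants of the conformational two-state chain.

    Parameters
    ----------
    k_active : float
        Rate (s^-1) of inactive -> active transitions; the exit rate of the
        inactive state, so the inactive residence time is ``1 / k_active``.
    k_inactive : float
        Rate (s^-1) of active -> inactive transitions.  Zero is tolerated only
        to model an absorbing active state in degenerate simulations.
    """

    k_active: float
    k_inactive: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.k_active) and self.k_active > 0):
            raise ValueError(f"k_active must be positive and finite, got {self.k_active}")
        if not (math.isfinite(self.k_inactive) and self.k_inactive >= 0):
            raise ValueError(f"k_inactive must be >= 0 and finite, got {self.k_inactive}")

    @property
    def fraction_inactive(self) -> float:
        """Stationary probability of the inactive state, k_ina / (k_act + k_ina)."""
        return self.k_inactive / (self.k_active + self.k_inactive)

    def exit_rate(self, state: int) -> float:
        return self.k_active if state == INACTIVE else self.k_inactive


@dataclass(frozen=True)
class EmissionModel:
    """Two-level log-normal emission model for the quenching reporter.

    ``mode_high``/``mode_low`` are the modal intensities (a.u.) of the
    fluorescent and quenched levels; ``shape_high``/``shape_low`` the log-scale
    spreads of the per-frame scatter.  ``baseline`` is an additive background.
    Defaults give a ~3:1 mode ratio with peaks separated by ~7 shape widths,
    comfortably resolved by the downstream mixture fit.
    """

    mode_high: float = 3.0
    mode_low: float = 1.0
    shape_high: float = 0.15
    shape_low: float = 0.15
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if not self.mode_high > self.mode_low >= 0:
            raise ValueError("require mode_high > mode_low >= 0")
        if self.shape_high < 0 or self.shape_low < 0:
            raise ValueError("shape parameters must be >= 0")
        if self.baseline < 0:
            raise ValueError("baseline must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Full recipe for one simulated ensemble (camera + kinetics + emission)."""

    rates: TwoStateRates
    emission: EmissionModel = EmissionModel()
    frame_interval: float = 0.08   # s; 80 ms per frame
    n_frames: int = 500
    n_molecules: int = 500
    polarity: str = POLARITY_INACTIVE_LOW
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.n_frames < 1 or self.n_molecules < 1:
            raise ValueError("n_frames and n_molecules must be >= 1")
        if self.polarity not in (POLARITY_INACTIVE_LOW, POLARITY_INACTIVE_HIGH):
            raise ValueError(f"unknown polarity {self.polarity!r}")

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_interval


@dataclass
class StateSegments:
    """Piecewise-constant continuous-time state path.

    ``states[i]`` is occupied for ``durations[i]`` seconds; segments abut with
    no gaps starting at t = 0.
    """

    states: np.ndarray      # int array of ACTIVE/INACTIVE labels
    durations: np.ndarray   # float array, seconds
    total_duration: float

    def time_fraction(self, state: int) -> float:
        mask = self.states == state
        return float(self.durations[mask].sum() / self.durations.sum())

    @property
    def n_transitions(self) -> int:
        return len(self.states) - 1


@dataclass
class IntensityTrace:
    """One molecule's framewise fluorescence record."""

    molecule_id: int
    intensities: np.ndarray
    frame_interval: float
    true_inactive_fraction: np.ndarray | None = None  # synthetic ground truth

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if self.true_inactive_fraction is not None:
            f = np.asarray(self.true_inactive_fraction, dtype=float)
            if f.shape != self.intensities.shape:
                raise ValueError("true_inactive_fraction length mismatch")
            if f.min() < -1e-9 or f.max() > 1 + 1e-9:
                raise ValueError("true_inactive_fraction must lie in [0, 1]")
            self.true_inactive_fraction = np.clip(f, 0.0, 1.0)

    @property
    def n_frames(self) -> int:
        return len(self.intensities)


@dataclass
class EnsembleResult:
    """Traces plus the ground truth the generator knows about them."""

    traces: list[IntensityTrace]
    config: SimulationConfig
    true_fraction_inactive: float        # time-averaged over all simulated frames
    stationary_fraction_inactive: float  # k_inactive / (k_active + k_inactive)
    fraction_molecules_transitioning: float
    seed: int = field(default=0)

    def summary(self) -> dict:
        return {
            "n_molecules": len(self.traces),
            "n_frames": self.config.n_frames,
            "frame_interval": self.config.frame_interval,
            "seed": self.seed,
            "k_active": self.config.rates.k_active,
            "k_inactive": self.config.rates.k_inactive,
            "polarity": self.config.polarity,
            "true_fraction_inactive": self.true_fraction_inactive,
            "stationary_fraction_inactive": self.stationary_fraction_inactive,
            "fraction_molecules_transitioning": self.fraction_molecules_transitioning,
        }


def sample_state_path(
    rates: TwoStateRates,
    duration: float,
    rng: np.random.Generator | int | None = None,
    initial_state: str | int = "stationary",
) -> StateSegments:
    """Draw a continuous-time telegraph path of the conformational chain.

    Dwell durations in each state are exponential with that state's exit rate.
    ``initial_state`` is ``"stationary"`` (draw from the stationary
    distribution, the default since tethered molecules are observed at
    equilibrium) or an explicit ``ACTIVE``/``INACTIVE`` label.  The final
    segment is truncated at ``duration``.
    """
    if duration <= 0 or not math.isfinite(duration):
        raise ValueError(f"duration must be positive and finite, got {duration}")
    rng = np.random.default_rng(rng)

    if initial_state == "stationary":
        state = INACTIVE if rng.random() < rates.fraction_inactive else ACTIVE
    elif initial_state in (ACTIVE, INACTIVE):
        state = int(initial_state)
    else:
        raise ValueError(f"initial_state must be 'stationary', ACTIVE or INACTIVE, got {initial_state!r}")

    states: list[int] = []
    durations: list[float] = []
    t = 0.0
    while t < duration:
        rate = rates.exit_rate(state)
        if rate == 0.0:  # absorbing state
            dwell = duration - t
        else:
            dwell = rng.exponential(1.0 / rate)
        dwell = min(dwell, duration - t)
        states.append(state)
        durations.append(dwell)
        t += dwell
        state = ACTIVE if state == INACTIVE else INACTIVE

    return StateSegments(
        states=np.array(states, dtype=np.int8),
        durations=np.array(durations, dtype=float),
        total_duration=duration,
    )


def _frame_inactive_occupancy(path: StateSegments, n_frames: int, dt: float) -> np.ndarray:
    """Exact fraction of each frame interval spent in the inactive state.

    The cumulative inactive time is piecewise linear in t, so evaluating it at
    the frame edges by linear interpolation between segment breakpoints is
    exact, not an approximation.
    """
    edges = np.arange(n_frames + 1) * dt
    breakpoints = np.concatenate(([0.0], np.cumsum(path.durations)))
    cum_inactive = np.concatenate(
        ([0.0], np.cumsum(path.durations * (path.states == INACTIVE)))
    )
    occ = np.diff(np.interp(edges, breakpoints, cum_inactive)) / dt
    return np.clip(occ, 0.0, 1.0)


def integrate_to_frames(
    path: StateSegments,
    config: SimulationConfig,
    rng: np.random.Generator | int | None = None,
    molecule_id: int = 0,
) -> IntensityTrace:
    """Render a continuous state path into a camera-integrated intensity trace.

    Each frame's noiseless level is the time-weighted mixture of the two state
    intensities within that frame (a transition happens "within a single
    frame"); log-normal scatter, parameterized so the *mode* of the scattered
    intensity equals the noiseless level, is then applied.
    """
    dt = config.frame_interval
    if path.total_duration + 1e-12 < config.n_frames * dt:
        raise ValueError(
            f"state path ({path.total_duration:.3f} s) shorter than acquisition "
            f"window ({config.n_frames * dt:.3f} s)"
        )
    rng = np.random.default_rng(rng)
    em = config.emission

    occ_inactive = _frame_inactive_occupancy(path, config.n_frames, dt)
    frac_low = occ_inactive if config.polarity == POLARITY_INACTIVE_LOW else 1.0 - occ_inactive
    level = em.baseline + em.mode_low * frac_low + em.mode_high * (1.0 - frac_low)
    shape = em.shape_low * frac_low + em.shape_high * (1.0 - frac_low)
    # ln X ~ N(ln(level) + s^2, s)  =>  mode(X) = level; zero shape is exact
    noise = np.exp(shape**2 + shape * rng.standard_normal(config.n_frames))
    return IntensityTrace(
        molecule_id=molecule_id,
        intensities=level * noise,
        frame_interval=dt,
        true_inactive_fraction=occ_inactive,
    )


def simulate_ensemble(config: SimulationConfig) -> EnsembleResult:
    """Simulate ``config.n_molecules`` independent traces with one seeded generator.

    Returns the traces and the generator's ground truth: the time-averaged
    inactive occupancy over all frames, the stationary occupancy, and the
    fraction of molecules showing at least one transition within acquisition.
    """
    child_seeds = np.random.SeedSequence(config.seed).spawn(config.n_molecules)
    traces: list[IntensityTrace] = []
    occ_sum = 0.0
    n_transitioning = 0
    for mol, ss in enumerate(child_seeds):
        rng = np.random.default_rng(ss)
        path = sample_state_path(config.rates, config.duration, rng)
        trace = integrate_to_frames(path, config, rng, molecule_id=mol)
        traces.append(trace)
        occ_sum += float(trace.true_inactive_fraction.mean())
        if path.n_transitions >= 1:
            n_transitioning += 1
    return EnsembleResult(
        traces=traces,
        config=config,
        true_fraction_inactive=occ_sum / config.n_molecules,
        stationary_fraction_inactive=config.rates.fraction_inactive,
        fraction_molecules_transitioning=n_transitioning / config.n_molecules,
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# tabular I/O (CSV dialect: molecule_id, frame, intensity[, true_inactive_fraction])

def traces_to_frame(traces: Sequence[IntensityTrace]) -> pd.DataFrame:
    """Stack traces into the long-format trace table."""
    parts = []
    for tr in traces:
        d = {
            "molecule_id": tr.molecule_id,
            "frame": np.arange(tr.n_frames),
            "intensity": tr.intensities,
        }
        if tr.true_inactive_fraction is not None:
            d["true_inactive_fraction"] = tr.true_inactive_fraction
        parts.append(pd.DataFrame(d))
    return pd.concat(parts, ignore_index=True)


def frame_to_traces(df: pd.DataFrame, frame_interval: float) -> list[IntensityTrace]:
    traces = []
    for mol, grp in df.sort_values(["molecule_id", "frame"]).groupby("molecule_id"):
        truth = grp["true_inactive_fraction"].to_numpy() if "true_inactive_fraction" in grp else None
        traces.append(
            IntensityTrace(
                molecule_id=int(mol),
                intensities=grp["intensity"].to_numpy(),
                frame_interval=frame_interval,
                true_inactive_fraction=truth,
            )
        )
    return traces


def write_ensemble_csv(ensemble: EnsembleResult, path: str | Path) -> Path:
    """Write one trace CSV plus a JSON sidecar with config, seed and ground truth."""
    path = Path(path)
    traces_to_frame(ensemble.traces).to_csv(path, index=False)
    sidecar = path.with_suffix(".json")
    meta = ensemble.summary()
    meta["emission"] = {
        "mode_high": ensemble.config.emission.mode_high,
        "mode_low": ensemble.config.emission.mode_low,
        "shape_high": ensemble.config.emission.shape_high,
        "shape_low": ensemble.config.emission.shape_low,
        "baseline": ensemble.config.emission.baseline,
    }
    sidecar.write_text(json.dumps(meta, indent=2))
    return path


def read_traces_csv(path: str | Path, frame_interval: float | None = None) -> list[IntensityTrace]:
    """Read a trace CSV; frame_interval comes from the JSON sidecar if present."""
    path = Path(path)
    if frame_interval is None:
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            frame_interval = json.loads(sidecar.read_text())["frame_interval"]
        else:
            frame_interval = 0.08
    return frame_to_traces(pd.read_csv(path), frame_interval)
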