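"""Master-equation voltage-clamp simulation and derived macroscopic traces.

Within each constant-voltage epoch the occupancy obeys a linear master
equation dp/dt = p Q(v), solved exactly with the matrix exponential; the
propagator for the sampling step is computed once per epoch and reused, so
no solver tolerance is exposed.  Occupancy is continuous across epoch
boundaries and conserved throughout.

Macroscopic current is open-state occupancy times driving force:
I(t) = N * g * (P_IO * r_IO + P_AO * r_AO) * (v(t) - E_rev), with the
per-open-state relative conductances r_IO/r_AO acting as solution presets
(the Rb+ preset weights the intermediate-open state more, emulating its
higher Rb+ permeability).  Fluorescence reports VSD activation as a weighted
sum of intermediate- and activated-VSD occupancies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .kinetic_model import (
    ModelParameters,
    State,
    build_generator,
    reachable_states,
    steady_state,
)
from .protocol import Protocol

__all__ = [
    "Trajectory",
    "ConductanceSpec",
    "SOLUTIONS",
    "Trace",
    "CurrentTrace",
    "FluorescenceTrace",
    "integrate_occupancy",
    "current_from_trajectory",
    "fluorescence_from_trajectory",
    "delta_current",
    "simulate_current",
    "simulate_family",
]


class SimulationError(ValueError):
    """Invalid simulation input."""


@dataclass(frozen=True)
class Trajectory:
    """State-occupancy time course on the protocol's sampling grid."""

    time: np.ndarray  # ms
    occupancy: np.ndarray  # (n_samples, 5) probabilities
    protocol: Protocol
    label: str = ""

    def state(self, s: State) -> np.ndarray:
        return self.occupancy[:, int(s)]

    @property
    def open_probability(self) -> np.ndarray:
        return self.occupancy[:, State.IO] + self.occupancy[:, State.AO]


@dataclass(frozen=True)
class ConductanceSpec:
    """Macroscopic conductance model.

    g is the single-channel conductance in pS (default 0.18), E_rev the
    reversal potential in mV, N a channel-count scale (default 1, i.e.
    arbitrary units), and r_io/r_ao relative conductance factors for the two
    open states in the given external solution.
    """

    g: float = 0.18
    e_rev: float = -80.0
    n_channels: float = 1.0
    r_io: float = 1.0
    r_ao: float = 1.0

    def __post_init__(self) -> None:
        if not self.g > 0:
            raise SimulationError(f"conductance must be positive, got {self.g}")
        if self.r_io < 0 or self.r_ao < 0:
            raise SimulationError("relative conductance factors must be >= 0")


#: External-solution presets.  ND96 is the standard bath; the 100 mM K+ and
#: Rb+ solutions set E_rev ~ 0 mV, and the Rb+ preset carries the
#: state-specific tail-ratio emulation (IO conducts Rb+ ~3.1x, AO ~0.6x,
#: relative to K+).
SOLUTIONS: dict[str, ConductanceSpec] = {
    "ND96": ConductanceSpec(e_rev=-80.0),
    "100K": ConductanceSpec(e_rev=0.0, r_io=1.0, r_ao=1.0),
    "100Rb": ConductanceSpec(e_rev=0.0, r_io=3.1, r_ao=0.6),
}


@dataclass(frozen=True)
class Trace:
    """A time series with '#'-style metadata (CSV-dialect compatible)."""

    time: np.ndarray  # ms
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "values", values)
        if time.shape != values.shape:
            raise SimulationError("time and values must have identical shape")
        if values.size and not np.all(np.isfinite(values)):
            raise SimulationError("trace values must be finite")

    def epoch_boundaries(self) -> np.ndarray | None:
        raw = self.metadata.get("epoch_boundaries_ms")
        if raw is None:
            return None
        return np.array([float(x) for x in str(raw).split(";")])

    def crop(self, t0: float, t1: float) -> "Trace":
        """Sub-trace with t in [t0, t1], time re-zeroed at t0."""
        mask = (self.time >= t0 - 1e-9) & (self.time <= t1 + 1e-9)
        return replace(self, time=self.time[mask] - t0, values=self.values[mask])


class CurrentTrace(Trace):
    """Macroscopic current, in N*pS*mV arbitrary units."""


class FluorescenceTrace(Trace):
    """Delta F / F fluorescence signal (dimensionless)."""


def _expm(q: np.ndarray, dt: float) -> np.ndarray:
    from scipy.linalg import expm

    return expm(q * dt)


def integrate_occupancy(
    params: ModelParameters,
    protocol: Protocol,
    init: np.ndarray | None = None,
) -> Trajectory:
    """Integrate the master equation over a protocol.

    ``init`` defaults to the stationary occupancy at the holding potential
    (confined to the variant's reachable set).  A custom ``init`` must be a
    probability vector supported on the reachable set.
    """
    allowed = np.array([int(s) for s in reachable_states(params)])
    if init is None:
        p = steady_state(params, protocol.holding_v)
    else:
        p = np.asarray(init, dtype=float)
        if p.shape != (5,):
            raise SimulationError("init must be a length-5 occupancy vector")
        if p.min() < -1e-9 or abs(p.sum() - 1.0) > 1e-6:
            raise SimulationError("init must be a probability vector (sum 1, nonneg)")
        outside = np.delete(p, allowed)
        if outside.size and np.abs(outside).max() > 1e-9:
            raise SimulationError("init places occupancy on unreachable states")
        p = np.clip(p, 0.0, None)
        p = p / p.sum()

    t_grid = protocol.time_grid()
    bounds = protocol.boundaries()
    occ = np.empty((t_grid.size, 5))
    occ[0] = p

    tol = 1e-9
    cache: dict[tuple[int, float], np.ndarray] = {}

    def propagator(epoch_idx: int, dt: float) -> np.ndarray:
        key = (epoch_idx, round(dt, 9))
        mat = cache.get(key)
        if mat is None:
            q = build_generator(params, protocol.epochs[epoch_idx].v)
            mat = _expm(q, dt)
            cache[key] = mat
        return mat

    t_cur = 0.0
    epoch = 0
    for k in range(1, t_grid.size):
        ts = t_grid[k]
        # cross any epoch boundaries strictly inside (t_cur, ts)
        while epoch < len(bounds) - 1 and bounds[epoch] < ts - tol:
            if bounds[epoch] > t_cur + tol:
                p = p @ propagator(epoch, bounds[epoch] - t_cur)
            t_cur = bounds[epoch]
            epoch += 1
        if ts > t_cur + tol:
            p = p @ propagator(epoch, ts - t_cur)
            t_cur = ts
        occ[k] = p

    # guard against roundoff drift in the propagators
    occ = np.clip(occ, 0.0, None)
    occ /= occ.sum(axis=1, keepdims=True)
    return Trajectory(time=t_grid, occupancy=occ, protocol=protocol, label=params.label)


def _base_metadata(traj: Trajectory) -> dict:
    return {
        "condition": traj.label,
        "protocol": traj.protocol.name,
        "holding_v": traj.protocol.holding_v,
        "epoch_boundaries_ms": ";".join(f"{b:g}" for b in traj.protocol.boundaries()),
    }


def current_from_trajectory(
    traj: Trajectory,
    spec: ConductanceSpec | None = None,
    solution: str | None = None,
) -> CurrentTrace:
    """Macroscopic current I(t) = N*g*(P_IO*r_IO + P_AO*r_AO)*(v(t) - E_rev)."""
    if solution is not None:
        try:
            spec = SOLUTIONS[solution]
        except KeyError:
            raise SimulationError(
                f"unknown solution {solution!r}; known: {sorted(SOLUTIONS)}"
            ) from None
    if spec is None:
        spec = ConductanceSpec()
    v = traj.protocol.voltage_at(traj.time)
    g_open = traj.state(State.IO) * spec.r_io + traj.state(State.AO) * spec.r_ao
    current = spec.n_channels * spec.g * g_open * (v - spec.e_rev)
    meta = _base_metadata(traj)
    meta.update(kind="current", solution=solution or "ND96",
                e_rev=spec.e_rev, g_pS=spec.g)
    return CurrentTrace(time=traj.time, values=current, metadata=meta)


def fluorescence_from_trajectory(
    traj: Trajectory, w_i: float = 0.5, w_a: float = 1.0
) -> FluorescenceTrace:
    """VSD-activation fluorescence: dF/F = w_i*(P_IC+P_IO) + w_a*(P_AC+P_AO).

    The weights encode the partial (intermediate) vs full (activated)
    fluorophore dequenching; 0 <= w_i <= w_a keeps the signal monotone in
    VSD progression and bounded in [0, w_a].
    """
    if not 0 <= w_i <= w_a:
        raise SimulationError(f"weights must satisfy 0 <= w_i <= w_a, got {w_i}, {w_a}")
    f = w_i * (traj.state(State.IC) + traj.state(State.IO)) + w_a * (
        traj.state(State.AC) + traj.state(State.AO)
    )
    meta = _base_metadata(traj)
    meta.update(kind="fluorescence", w_i=w_i, w_a=w_a)
    return FluorescenceTrace(time=traj.time, values=f, metadata=meta)


def delta_current(trace_drug: Trace, trace_ctrl: Trace) -> CurrentTrace:
    """Pointwise drug-minus-control difference on a shared time grid."""
    if trace_drug.time.shape != trace_ctrl.time.shape or not np.allclose(
        trace_drug.time, trace_ctrl.time
    ):
        raise SimulationError("delta_current requires identical time grids")
    meta = dict(trace_ctrl.metadata)
    meta["condition"] = (
        f"delta({trace_drug.metadata.get('condition', '?')}"
        f"-{trace_ctrl.metadata.get('condition', '?')})"
    )
    meta["kind"] = "delta_current"
    return CurrentTrace(
        time=trace_drug.time,
        values=trace_drug.values - trace_ctrl.values,
        metadata=meta,
    )


def simulate_current(
    params: ModelParameters,
    protocol: Protocol,
    spec: ConductanceSpec | None = None,
    solution: str | None = None,
) -> CurrentTrace:
    """Convenience: integrate occupancy and convert to current in one call."""
    return current_from_trajectory(
        integrate_occupancy(params, protocol), spec=spec, solution=solution
    )


def simulate_family(
    params: ModelParameters,
    family,
    spec: ConductanceSpec | None = None,
    solution: str | None = None,
    modality: str = "current",
    w_i: float = 0.5,
    w_a: float = 1.0,
) -> list[Trace]:
    """Simulate every protocol in a family; returns one trace per member."""
    out: list[Trace] = []
    for proto in family:
        traj = integrate_occupancy(params, proto)
        if modality == "current":
            out.append(current_from_trajectory(traj, spec=spec, solution=solution))
        elif modality == "fluorescence":
            out.append(fluorescence_from_trajectory(traj, w_i=w_i, w_a=w_a))
        else:
            raise SimulationError(f"unknown modality {modality!r}")
    return out
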