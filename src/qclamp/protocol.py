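"""Piecewise-constant voltage-clamp protocols and the standard protocol library.

A protocol is a holding potential followed by an ordered list of constant
voltage epochs, sampled on a regular grid (default 1 kHz, i.e. 1 ms).  The
command voltage v(t) is right-continuous: a sample landing exactly on an
epoch boundary belongs to the later epoch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "VoltageEpoch",
    "Protocol",
    "ProtocolFamily",
    "make_standard_protocol",
    "family_sweep",
    "read_protocol",
    "write_protocol",
    "STANDARD_PROTOCOLS",
]


class ProtocolError(ValueError):
    """Invalid protocol definition."""


@dataclass(frozen=True)
class VoltageEpoch:
    """One constant-voltage segment: ``v`` in mV for ``duration`` ms."""

    v: float
    duration: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.v):
            raise ProtocolError(f"epoch voltage must be finite, got {self.v}")
        if not (self.duration > 0 and np.isfinite(self.duration)):
            raise ProtocolError(f"epoch duration must be positive, got {self.duration}")


@dataclass(frozen=True)
class Protocol:
    """A voltage-clamp command waveform.

    Parameters
    ----------
    epochs : tuple of VoltageEpoch
        The command sequence after leaving the holding potential.
    holding_v : float
        Holding potential in mV (default -80); used for initial conditions.
    sampling_interval : float
        Output sample spacing in ms (default 1, i.e. 1 kHz acquisition).
    name : str
        Optional label carried into trace metadata.
    """

    epochs: tuple[VoltageEpoch, ...]
    holding_v: float = -80.0
    sampling_interval: float = 1.0
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "epochs", tuple(self.epochs))
        if not self.epochs:
            raise ProtocolError("protocol needs at least one epoch")
        if not (self.sampling_interval > 0 and np.isfinite(self.sampling_interval)):
            raise ProtocolError("sampling_interval must be positive")
        if not np.isfinite(self.holding_v):
            raise ProtocolError("holding_v must be finite")

    @property
    def total_duration(self) -> float:
        return float(sum(e.duration for e in self.epochs))

    def boundaries(self) -> np.ndarray:
        """Cumulative epoch end times in ms, starting after t=0."""
        return np.cumsum([e.duration for e in self.epochs])

    def epoch_start(self, index: int) -> float:
        """Start time (ms) of epoch ``index`` (supports negative indexing)."""
        index = range(len(self.epochs))[index]
        return float(sum(e.duration for e in self.epochs[:index]))

    def time_grid(self) -> np.ndarray:
        """Sample times 0, dt, 2*dt, ... covering the whole protocol."""
        n = int(round(self.total_duration / self.sampling_interval))
        return np.arange(n + 1) * self.sampling_interval

    def voltage_at(self, t: np.ndarray | float) -> np.ndarray:
        """Right-continuous command voltage at time(s) ``t`` in ms."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        bounds = self.boundaries()
        vs = np.array([e.v for e in self.epochs])
        # side='right': t exactly at a boundary joins the later epoch
        idx = np.searchsorted(bounds, t, side="right")
        idx = np.minimum(idx, len(vs) - 1)  # final instant keeps last epoch's v
        return vs[idx]


@dataclass(frozen=True)
class ProtocolFamily:
    """A family of protocols differing in one epoch field (voltage or duration)."""

    base: Protocol
    epoch_index: int
    swept_field: str  # "v" or "duration"
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        if not self.values:
            raise ProtocolError("family needs at least one swept value")
        if self.swept_field not in ("v", "duration"):
            raise ProtocolError(f"swept_field must be 'v' or 'duration', got {self.swept_field!r}")
        if not -len(self.base.epochs) <= self.epoch_index < len(self.base.epochs):
            raise ProtocolError(f"epoch index {self.epoch_index} out of range")
        # validate eagerly so a bad value fails at construction
        _ = self.protocols()

    def protocols(self) -> tuple[Protocol, ...]:
        out = []
        for i, value in enumerate(self.values):
            epochs = list(self.base.epochs)
            epochs[self.epoch_index] = replace(
                epochs[self.epoch_index], **{self.swept_field: value}
            )
            name = f"{self.base.name}[{self.swept_field}={value:g}]"
            out.append(replace(self.base, epochs=tuple(epochs), name=name))
        return tuple(out)

    def __iter__(self):
        return iter(self.protocols())

    def __len__(self) -> int:
        return len(self.values)


def family_sweep(
    base: Protocol, epoch_index: int, field_name: str, values
) -> ProtocolFamily:
    """Sweep one epoch field of ``base`` over ``values`` (base is unmodified)."""
    return ProtocolFamily(base, epoch_index, field_name, tuple(values))


def _hook_durations() -> tuple[float, ...]:
    """Default pre-pulse durations: 12 log-spaced values, 30 ms to 4.355 s.

    The printed endpoints are kept exactly and the saturating 2.913 s duration
    is inserted (replacing the nearest log-spaced point); everything is
    rounded to the 1 ms grid.
    """
    durs = np.round(np.geomspace(30.0, 4355.0, 12))
    durs[np.argmin(np.abs(durs - 2913.0))] = 2913.0
    return tuple(float(d) for d in sorted(set(durs)))


def _iv_family(step_duration: float = 4000.0, tail_v: float = -40.0,
               tail_duration: float = 1000.0) -> ProtocolFamily:
    base = Protocol(
        epochs=(VoltageEpoch(40.0, step_duration), VoltageEpoch(tail_v, tail_duration)),
        name="iv_family",
    )
    return ProtocolFamily(base, 0, "v", tuple(np.arange(-120.0, 81.0, 20.0)))


STANDARD_PROTOCOLS = {
    # current families: test steps then a fixed tail for conductance
    "iv_family": _iv_family,
    # single +40 mV step, 4 s, tail at -40 mV
    "single_step_40mV_4s": lambda: Protocol(
        epochs=(VoltageEpoch(40.0, 4000.0), VoltageEpoch(-40.0, 1000.0)),
        name="single_step_40mV_4s",
    ),
    # low-voltage activation confines opening to the intermediate-open state
    "io_only_low_v": lambda: Protocol(
        epochs=(VoltageEpoch(-50.0, 5000.0), VoltageEpoch(-60.0, 2000.0)),
        name="io_only_low_v",
    ),
    # brief depolarization, too short for the activated-open state to develop
    "io_only_brief": lambda: Protocol(
        epochs=(VoltageEpoch(40.0, 100.0), VoltageEpoch(-60.0, 2000.0)),
        name="io_only_brief",
    ),
    # hook protocol: +60 mV pre-pulses of increasing duration, -120 mV test
    "hook_duration_family": lambda: ProtocolFamily(
        Protocol(
            epochs=(VoltageEpoch(60.0, 2913.0), VoltageEpoch(-120.0, 2000.0)),
            name="hook_duration_family",
        ),
        0,
        "duration",
        _hook_durations(),
    ),
    # Rb+/K+ tail measurement: +60 mV 5 s pre-pulse, tail at -60 mV 3 s
    "rbk_tail": lambda: Protocol(
        epochs=(VoltageEpoch(60.0, 5000.0), VoltageEpoch(-60.0, 3000.0)),
        name="rbk_tail",
    ),
    # fluorometry family: explicit 2 s holding baseline then the test step
    "vcf_family": lambda: ProtocolFamily(
        Protocol(
            epochs=(VoltageEpoch(-80.0, 2000.0), VoltageEpoch(40.0, 4000.0)),
            name="vcf_family",
        ),
        1,
        "v",
        tuple(np.arange(-120.0, 81.0, 20.0)),
    ),
}


def make_standard_protocol(name: str, **overrides):
    """Build a protocol (or family) from the standard library by name.

    Overrides are forwarded to the builder where supported (``iv_family``
    accepts ``step_duration``, ``tail_v``, ``tail_duration``).
    """
    try:
        builder = STANDARD_PROTOCOLS[name]
    except KeyError:
        raise ProtocolError(
            f"unknown protocol {name!r}; known: {sorted(STANDARD_PROTOCOLS)}"
        ) from None
    return builder(**overrides) if overrides else builder()


# JSON round-trip ---------------------------------------------------------

def _protocol_to_dict(p: Protocol) -> dict:
    return {
        "holding_v": p.holding_v,
        "sampling_interval_ms": p.sampling_interval,
        "name": p.name,
        "epochs": [{"v_mV": e.v, "duration_ms": e.duration} for e in p.epochs],
    }


def _protocol_from_dict(d: dict) -> Protocol:
    return Protocol(
        epochs=tuple(VoltageEpoch(e["v_mV"], e["duration_ms"]) for e in d["epochs"]),
        holding_v=d.get("holding_v", -80.0),
        sampling_interval=d.get("sampling_interval_ms", 1.0),
        name=d.get("name", ""),
    )


def write_protocol(obj: Protocol | ProtocolFamily, path) -> None:
    """Write a protocol or protocol family as JSON."""
    if isinstance(obj, ProtocolFamily):
        payload = {
            "base": _protocol_to_dict(obj.base),
            "swept_field": [obj.epoch_index, obj.swept_field],
            "values": list(obj.values),
        }
    else:
        payload = _protocol_to_dict(obj)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_protocol(path) -> Protocol | ProtocolFamily:
    """Read a protocol or protocol family from JSON."""
    d = json.loads(Path(path).read_text())
    if "base" in d:
        idx, fname = d["swept_field"]
        return ProtocolFamily(_protocol_from_dict(d["base"]), int(idx), fname,
                              tuple(d["values"]))
    return _protocol_from_dict(d)
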