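"""Synthetic TEVC / fluorometry datasets with known ground truth.

Wraps the simulator with a noise model emulating the statistical structure of
two-electrode voltage-clamp recordings (1 kHz sampling, white Gaussian
current noise scaled to the peak, constant leak offset) and voltage-clamp
fluorometry (additive Gaussian noise plus a slow photobleach drift).  Every
dataset is deterministic given its seed and carries the generating model,
protocol, conductance spec and noise-free traces, so each analysis procedure
can be validated by generate-and-refit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .kinetic_model import ModelParameters, apply_ml277, make_variant
from .protocol import Protocol, ProtocolFamily
from .simulator import (
    ConductanceSpec,
    CurrentTrace,
    FluorescenceTrace,
    Trace,
    current_from_trajectory,
    fluorescence_from_trajectory,
    integrate_occupancy,
)

__all__ = [
    "NoiseModel",
    "GroundTruth",
    "SyntheticDataset",
    "generate_dataset",
    "generate_condition_pair",
    "write_dataset",
]


class SyntheticDataError(ValueError):
    pass


@dataclass(frozen=True)
class NoiseModel:
    """Recording-noise specification.

    current_sigma / fluor_sigma are white Gaussian SDs expressed as a
    fraction of the noise-free trace's peak absolute value; leak_offset is a
    constant current offset; bleach_slope is a linear photobleach drift in
    dF/F per ms (negative values bleach downward).  The seed is mandatory
    whenever any noise term is nonzero.
    """

    current_sigma: float = 0.02
    leak_offset: float = 0.0
    fluor_sigma: float = 0.01
    bleach_slope: float = -1e-5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.current_sigma < 0 or self.fluor_sigma < 0:
            raise SyntheticDataError("noise sigmas must be >= 0")
        noisy = self.current_sigma > 0 or self.fluor_sigma > 0
        if noisy and self.seed is None:
            raise SyntheticDataError("seed is mandatory for nonzero noise")

    def with_seed(self, seed: int) -> "NoiseModel":
        return replace(self, seed=seed)


QUIET = NoiseModel(current_sigma=0.0, fluor_sigma=0.0, bleach_slope=0.0, seed=0)


@dataclass(frozen=True)
class GroundTruth:
    """Everything needed to regenerate a dataset bit-exactly."""

    params: ModelParameters
    protocols: tuple[Protocol, ...]
    conductance: ConductanceSpec
    noise: NoiseModel
    clean_traces: tuple[Trace, ...]


@dataclass(frozen=True)
class SyntheticDataset:
    traces: tuple[Trace, ...]
    ground_truth: GroundTruth

    def __len__(self) -> int:
        return len(self.traces)


def _as_protocols(protocol_or_family) -> tuple[Protocol, ...]:
    if isinstance(protocol_or_family, ProtocolFamily):
        return protocol_or_family.protocols()
    if isinstance(protocol_or_family, Protocol):
        return (protocol_or_family,)
    return tuple(protocol_or_family)


def _add_current_noise(trace: CurrentTrace, noise: NoiseModel, rng) -> CurrentTrace:
    values = trace.values + noise.leak_offset
    if noise.current_sigma > 0:
        peak = np.abs(trace.values).max()
        values = values + rng.normal(0.0, noise.current_sigma * max(peak, 1e-300),
                                     size=values.shape)
    meta = dict(trace.metadata)
    meta.update(noise_sigma=noise.current_sigma, leak_offset=noise.leak_offset)
    return CurrentTrace(time=trace.time, values=values, metadata=meta)


def _add_fluor_noise(trace: FluorescenceTrace, noise: NoiseModel, rng) -> FluorescenceTrace:
    values = trace.values + noise.bleach_slope * trace.time
    if noise.fluor_sigma > 0:
        peak = np.abs(trace.values).max()
        values = values + rng.normal(0.0, noise.fluor_sigma * max(peak, 1e-300),
                                     size=values.shape)
    meta = dict(trace.metadata)
    meta.update(noise_sigma=noise.fluor_sigma, bleach_slope=noise.bleach_slope)
    return FluorescenceTrace(time=trace.time, values=values, metadata=meta)


def generate_dataset(
    params: ModelParameters,
    protocol_or_family,
    spec: ConductanceSpec | None = None,
    noise: NoiseModel = QUIET,
    modality: str = "current",
    seed: int | None = None,
    solution: str = "ND96",
    w_i: float = 0.5,
    w_a: float = 1.0,
) -> SyntheticDataset:
    """Generate a noisy trace family with its ground truth.

    ``modality`` is "current", "fluorescence" or "both"; ``seed`` overrides
    the NoiseModel's seed.  With all noise terms zero the returned traces
    equal the simulator output exactly.
    """
    if modality not in ("current", "fluorescence", "both"):
        raise SyntheticDataError(f"unknown modality {modality!r}")
    if seed is not None:
        noise = noise.with_seed(seed)
    if spec is None:
        spec = ConductanceSpec()
    protocols = _as_protocols(protocol_or_family)
    rng = np.random.default_rng(noise.seed)

    clean: list[Trace] = []
    noisy: list[Trace] = []
    for proto in protocols:
        traj = integrate_occupancy(params, proto)
        if modality in ("current", "both"):
            tr = current_from_trajectory(traj, spec=spec)
            tr = replace(tr, metadata={**tr.metadata, "solution": solution,
                                       "seed": noise.seed})
            clean.append(tr)
            noisy.append(_add_current_noise(tr, noise, rng))
        if modality in ("fluorescence", "both"):
            fl = fluorescence_from_trajectory(traj, w_i=w_i, w_a=w_a)
            fl = replace(fl, metadata={**fl.metadata, "seed": noise.seed})
            clean.append(fl)
            noisy.append(_add_fluor_noise(fl, noise, rng))

    truth = GroundTruth(
        params=params,
        protocols=protocols,
        conductance=spec,
        noise=noise,
        clean_traces=tuple(clean),
    )
    return SyntheticDataset(traces=tuple(noisy), ground_truth=truth)


def generate_condition_pair(
    params: ModelParameters,
    modifier="ml277",
    protocol_or_family=None,
    spec: ConductanceSpec | None = None,
    noise: NoiseModel = QUIET,
    modality: str = "current",
    seed: int | None = None,
    **kwargs,
) -> tuple[SyntheticDataset, SyntheticDataset]:
    """Condition-matched (control, modified) dataset pair.

    ``modifier`` is "ml277", a variant name accepted by make_variant, a
    callable ModelParameters -> ModelParameters, or None for a null
    (control, control) pair.  Both datasets share the protocol, conductance
    spec and seed stream but draw independent noise realizations.
    """
    if protocol_or_family is None:
        raise SyntheticDataError("protocol_or_family is required")
    if modifier is None:
        mod_params = params
    elif callable(modifier):
        mod_params = modifier(params)
    elif modifier == "ml277":
        mod_params = apply_ml277(params)
    else:
        mod_params = make_variant(params, modifier)
    if seed is not None:
        noise = noise.with_seed(seed)
    base_seed = noise.seed if noise.seed is not None else 0
    # derive independent per-condition streams from one seed
    seq = np.random.SeedSequence(base_seed).spawn(2)
    ctrl = generate_dataset(
        params, protocol_or_family, spec, noise.with_seed(int(seq[0].generate_state(1)[0] % 2**31)),
        modality, solution=kwargs.get("solution", "ND96"),
        w_i=kwargs.get("w_i", 0.5), w_a=kwargs.get("w_a", 1.0),
    )
    drug = generate_dataset(
        mod_params, protocol_or_family, spec, noise.with_seed(int(seq[1].generate_state(1)[0] % 2**31)),
        modality, solution=kwargs.get("solution", "ND96"),
        w_i=kwargs.get("w_i", 0.5), w_a=kwargs.get("w_a", 1.0),
    )
    return ctrl, drug


def write_dataset(dataset: SyntheticDataset, path) -> None:
    """Write a dataset directory: traces/*.csv, ground_truth.json, index.csv."""
    import json

    from .cli_io import write_trace

    root = Path(path)
    (root / "traces").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (tr, clean) in enumerate(
        zip(dataset.traces, dataset.ground_truth.clean_traces)
    ):
        kind = tr.metadata.get("kind", "trace")
        name = f"{i:03d}_{kind}.csv"
        write_trace(tr, root / "traces" / name)
        write_trace(clean, root / "traces" / f"{i:03d}_{kind}_clean.csv")
        rows.append(
            {
                "index": i,
                "file": f"traces/{name}",
                "clean_file": f"traces/{i:03d}_{kind}_clean.csv",
                "kind": kind,
                "condition": tr.metadata.get("condition", ""),
                "protocol": tr.metadata.get("protocol", ""),
            }
        )
    import pandas as pd

    pd.DataFrame(rows).to_csv(root / "index.csv", index=False)
    gt = dataset.ground_truth
    from dataclasses import asdict

    payload = {
        "params": asdict(gt.params),
        "conductance": asdict(gt.conductance),
        "noise": asdict(gt.noise),
        "protocols": [
            {
                "holding_v": p.holding_v,
                "sampling_interval_ms": p.sampling_interval,
                "name": p.name,
                "epochs": [{"v_mV": e.v, "duration_ms": e.duration} for e in p.epochs],
            }
            for p in gt.protocols
        ],
    }
    (root / "ground_truth.json").write_text(json.dumps(payload, indent=2) + "\n")
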