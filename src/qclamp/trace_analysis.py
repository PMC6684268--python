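"""Measurement procedures applied to voltage-clamp and fluorometry traces.

Implements the standard electrophysiology analysis chain: multi-exponential
fits of activation currents (tau_f / tau_s), double-exponential decomposition
of hooked tail currents (the A2 component quantifies inactivation, i.e.
recovery through the intermediate-open state), isochronal tail-current G-V
construction with Boltzmann fits, photobleach baseline correction and F-V
construction for fluorometry, Rb+/K+ tail-current ratios, and percent current
increase between paired conditions.

All fits use deterministic multi-start nonlinear least squares (lmfit);
exponential components are relabelled so tau_f < tau_s, and ties are broken
by lowest residual then lowest tau_f, so repeated fits of the same data are
bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from lmfit import Parameters, minimize
from scipy.constants import R as GAS_CONSTANT
from scipy.constants import physical_constants

from .protocol import Protocol, ProtocolFamily
from .simulator import FluorescenceTrace, Trace

FARADAY = physical_constants["Faraday constant"][0]  # C/mol

#: Absolute temperature used in Boltzmann slopes (recordings at 21-23 C).
DEFAULT_T_KELVIN = 295.15

__all__ = [
    "FitError",
    "ExpFitResult",
    "HookFitResult",
    "HookDevelopment",
    "BoltzmannComponent",
    "BoltzmannFit",
    "XYCurve",
    "fit_exponentials",
    "fit_hook_tail",
    "hook_development",
    "build_gv",
    "fit_boltzmann",
    "debleach",
    "build_fv",
    "rb_k_ratio",
    "percent_increase",
    "tail_amplitude",
]


class FitError(RuntimeError):
    """Fit failed or input is unusable; carries the best residual seen."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


# ---------------------------------------------------------------------------
# result containers

@dataclass(frozen=True)
class ExpFitResult:
    """Multi-exponential fit of an activation current.

    Amplitudes follow the rising convention y(t) = C + sum A_i*(1-exp(-t/tau_i));
    components are ordered by ascending tau, so ``taus[0]`` is tau_f and
    ``taus[-1]`` is tau_s.
    """

    amplitudes: tuple[float, ...]
    taus: tuple[float, ...]
    offset: float
    residual_norm: float
    window: tuple[float, float]
    mode: str

    @property
    def tau_f(self) -> float:
        return self.taus[0]

    @property
    def tau_s(self) -> float:
        return self.taus[-1]


@dataclass(frozen=True)
class HookFitResult:
    """Double-exponential tail decomposition F(t) = A1*exp(-t/tau1) + A2*exp(-t/tau2) + C.

    (A1, tau1) is the deactivation component carrying the net decay; (A2, tau2)
    is the transient hook component, whose amplitude sign opposes A1 when a
    hook is present.  A2 == 0 flags a monotonic (hook-free) tail.
    """

    a1: float
    tau1: float
    a2: float
    tau2: float
    c: float
    residual_norm: float

    @property
    def has_hook(self) -> bool:
        return abs(self.a2) > 0.02 * abs(self.a1)


@dataclass(frozen=True)
class XYCurve:
    """An x-y relation (G-V, F-V, or A2 vs pre-pulse duration)."""

    x: np.ndarray
    y: np.ndarray
    normalized: bool = False
    ylabel: str = ""

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.ndim != 1 or x.shape != y.shape:
            raise FitError("curve x and y must be 1-d and the same length")
        if not np.all(np.diff(x) > 0):
            raise FitError("curve x values must be strictly increasing")
        if not np.all(np.isfinite(y)):
            raise FitError("curve y values must be finite")


@dataclass(frozen=True)
class HookDevelopment:
    """Saturating growth of the normalized hook amplitude with pre-pulse duration."""

    curve: XYCurve  # normalized |A2| vs pre-pulse duration (ms)
    tau: float  # development time constant (ms)
    y_inf: float  # fitted saturation level (normalized units)
    residual_norm: float


@dataclass(frozen=True)
class BoltzmannComponent:
    v_half: float  # mV
    z: float  # equivalent valence
    weight: float


@dataclass(frozen=True)
class BoltzmannFit:
    """One- or two-component Boltzmann fit of a G-V or F-V curve."""

    components: tuple[BoltzmannComponent, ...]
    residual_norm: float
    t_kelvin: float = DEFAULT_T_KELVIN

    @property
    def v_half(self) -> float:
        """Weight-averaged half-activation voltage (the single V1/2 for 1 component)."""
        w = np.array([c.weight for c in self.components])
        v = np.array([c.v_half for c in self.components])
        return float((w * v).sum() / w.sum())

    def predict(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        out = np.zeros_like(v)
        for comp in self.components:
            out += comp.weight * _boltzmann(v, comp.v_half, comp.z, self.t_kelvin)
        return out


# ---------------------------------------------------------------------------
# low-level fitting helpers

def _sum_exp(t: np.ndarray, params: Parameters, n: int) -> np.ndarray:
    y = np.full_like(t, params["c"].value)
    for i in range(n):
        y = y + params[f"a{i}"].value * np.exp(-t / params[f"tau{i}"].value)
    return y


def _fit_sum_exp(
    t: np.ndarray, y: np.ndarray, n: int, tau_starts: list[tuple[float, ...]]
):
    """Deterministic multi-start fit of y = c + sum a_i exp(-t/tau_i).

    Returns the lmfit result with the lowest chi-square; ties (within 1e-12
    relative) broken by the lowest smallest-tau.
    """
    span = t[-t.size // 5 :].mean() - t[: max(t.size // 5, 1)].mean()
    scale = np.ptp(y)
    if scale <= 0 or not np.isfinite(scale):
        raise FitError("degenerate flat trace")
    best = None
    best_key = None
    for taus0 in tau_starts:
        p = Parameters()
        p.add("c", value=float(y[-1]))
        for i, tau0 in enumerate(taus0):
            p.add(f"tau{i}", value=float(tau0), min=1e-6, max=1e7)
            p.add(f"a{i}", value=float(y[0] - y[-1]) / n)
        try:
            res = minimize(
                lambda pars: _sum_exp(t, pars, n) - y, p, method="leastsq"
            )
        except Exception:
            continue
        if not res.success:
            continue
        tau_min = min(res.params[f"tau{i}"].value for i in range(n))
        key = (res.chisqr, tau_min)
        if best is None or key[0] < best_key[0] * (1 - 1e-12) or (
            abs(key[0] - best_key[0]) <= best_key[0] * 1e-12 and key[1] < best_key[1]
        ):
            best, best_key = res, key
    if best is None:
        raise FitError("exponential fit did not converge from any start")
    return best


def _exp_tau_grid(span: float, n: int) -> list[tuple[float, ...]]:
    """Eight deterministic tau starting points spanning decades of the window."""
    singles = [span / 300, span / 100, span / 30, span / 10, span / 3, span,
               3 * span, 10 * span]
    if n == 1:
        return [(tau,) for tau in singles]
    pairs = []
    for i in range(0, len(singles) - 2, 1):
        pairs.append((singles[i], singles[i + 2]))
    pairs.append((singles[0], singles[4]))
    pairs.append((singles[1], singles[5]))
    return pairs[:8]


# ---------------------------------------------------------------------------
# exponential activation fits

def fit_exponentials(
    trace: Trace,
    window: tuple[float, float] | None = None,
    n_components: int = 2,
    mode: str = "joint",
    split: float = 200.0,
) -> ExpFitResult:
    """Fit activation kinetics with one or two exponential components.

    ``joint`` mode fits all components simultaneously over the window;
    ``windowed`` mode (used when a drug changes only the slow component and
    the fast/slow phases are fitted separately) fits a single exponential on
    [t0, t0+split] for tau_f and another on [t0+split, t1] for tau_s.
    Amplitudes are reported in the rising convention
    y = C + sum A_i*(1 - exp(-t/tau_i)); the fit itself is sign-agnostic, so
    decaying traces work identically with negative amplitudes.
    """
    if n_components not in (1, 2):
        raise FitError("n_components must be 1 or 2")
    if window is None:
        window = (float(trace.time[0]), float(trace.time[-1]))
    t0, t1 = window
    mask = (trace.time >= t0 - 1e-9) & (trace.time <= t1 + 1e-9)
    t = trace.time[mask] - t0
    y = trace.values[mask]
    if t.size < 10 * n_components:
        raise FitError(f"window has {t.size} samples; need >= {10 * n_components} per component")

    if mode == "joint" or n_components == 1:
        span = max(t[-1], 10 * (t[1] - t[0]))
        res = _fit_sum_exp(t, y, n_components, _exp_tau_grid(span, n_components))
        taus = [res.params[f"tau{i}"].value for i in range(n_components)]
        amps = [-res.params[f"a{i}"].value for i in range(n_components)]
        order = np.argsort(taus)
        taus = [taus[i] for i in order]
        amps = [amps[i] for i in order]
        c = res.params["c"].value + sum(-a for a in amps)
        return ExpFitResult(
            amplitudes=tuple(amps),
            taus=tuple(taus),
            offset=float(c),
            residual_norm=float(np.sqrt(res.chisqr)),
            window=(t0, t1),
            mode="joint",
        )
    if mode != "windowed":
        raise FitError(f"unknown fit mode {mode!r}")

    early = fit_exponentials(trace, (t0, t0 + split), 1, "joint")
    late = fit_exponentials(trace, (t0 + split, t1), 1, "joint")
    taus = (early.taus[0], late.taus[0])
    amps = (early.amplitudes[0], late.amplitudes[0])
    if taus[0] > taus[1]:
        taus, amps = taus[::-1], amps[::-1]
    return ExpFitResult(
        amplitudes=amps,
        taus=taus,
        offset=early.offset,
        residual_norm=float(np.hypot(early.residual_norm, late.residual_norm)),
        window=(t0, t1),
        mode="windowed",
    )


# ---------------------------------------------------------------------------
# hook (inactivation) analysis

def fit_hook_tail(trace: Trace, blank: float = 2.0) -> HookFitResult:
    """Decompose a tail-current epoch into deactivation and hook components.

    The trace must be the tail epoch (time starting at repolarization); the
    first ``blank`` ms are discarded as capacitive transient, but amplitudes
    refer to t = 0.  The component whose amplitude sign opposes the net decay
    (producing the transient rise in current magnitude) is labelled (A2,
    tau2); when a double exponential does not improve on a single one, the
    tail is monotonic and A2 = 0 is reported.
    """
    if blank < 0:
        raise FitError("blank must be >= 0")
    mask = trace.time >= blank - 1e-9
    t = trace.time[mask]
    y = trace.values[mask]
    if t.size < 20:
        raise FitError(f"only {t.size} usable samples after blanking; need >= 20")

    span = max(t[-1] - t[0], 10 * (t[1] - t[0]))
    single = _fit_sum_exp(t, y, 1, _exp_tau_grid(span, 1))
    double = _fit_sum_exp(t, y, 2, _exp_tau_grid(span, 2))

    improvement = 1.0 - double.chisqr / single.chisqr if single.chisqr > 0 else 1.0
    tau_a, tau_b = double.params["tau0"].value, double.params["tau1"].value
    degenerate = abs(math.log(tau_a / tau_b)) < 0.05  # taus within ~5%: one component
    if improvement < 1e-3 or degenerate:
        return HookFitResult(
            a1=float(single.params["a0"].value),
            tau1=float(single.params["tau0"].value),
            a2=0.0,
            tau2=float(single.params["tau0"].value),
            c=float(single.params["c"].value),
            residual_norm=float(np.sqrt(single.chisqr)),
        )

    comps = sorted(
        [
            (double.params[f"a{i}"].value, double.params[f"tau{i}"].value)
            for i in range(2)
        ],
        key=lambda at: abs(at[0]),
        reverse=True,
    )
    c = double.params["c"].value
    net_sign = math.copysign(1.0, np.mean(y) - c)
    opposing = [at for at in comps if math.copysign(1.0, at[0]) != net_sign]
    if opposing:
        hook = opposing[0]
        deact = next(at for at in comps if at is not hook)
    else:
        # both components decay with the net sign: a monotonic (multi-phase)
        # deactivation with no transient rise, hence zero hook amplitude
        deact, minor = comps
        hook = (0.0, minor[1])
    return HookFitResult(
        a1=float(deact[0]),
        tau1=float(deact[1]),
        a2=float(hook[0]),
        tau2=float(hook[1]),
        c=float(c),
        residual_norm=float(np.sqrt(double.chisqr)),
    )


def hook_development(
    durations, fits: list[HookFitResult]
) -> HookDevelopment:
    """Saturation of normalized |A2| with pre-pulse duration.

    ``durations`` are pre-pulse durations in ms; A2 amplitudes are normalized
    to the family maximum and fitted with y(t) = y_inf*(1 - exp(-t/tau)).
    """
    durations = np.asarray(durations, dtype=float)
    if durations.size != len(fits):
        raise FitError("durations and fits must have the same length")
    if durations.size < 4:
        raise FitError("need at least 4 pre-pulse durations")
    a2 = np.array([abs(f.a2) for f in fits])
    a1 = np.array([abs(f.a1) for f in fits])
    if a2.max() <= 0 or a2.max() < 0.02 * a1.max():
        raise FitError("no hook detected: A2 is zero across the family")
    order = np.argsort(durations)
    x = durations[order]
    y = a2[order] / a2.max()

    best = None
    for tau0 in (x.max() / 30, x.max() / 10, x.max() / 3, x.max()):
        p = Parameters()
        p.add("y_inf", value=1.0, min=0)
        p.add("tau", value=float(tau0), min=1e-6)
        try:
            res = minimize(
                lambda pars: pars["y_inf"].value * (1 - np.exp(-x / pars["tau"].value)) - y,
                p,
                method="leastsq",
            )
        except Exception:
            continue
        if res.success and (best is None or res.chisqr < best.chisqr):
            best = res
    if best is None:
        raise FitError("hook-development fit did not converge")
    curve = XYCurve(x=x, y=y, normalized=True, ylabel="normalized A2")
    return HookDevelopment(
        curve=curve,
        tau=float(best.params["tau"].value),
        y_inf=float(best.params["y_inf"].value),
        residual_norm=float(np.sqrt(best.chisqr)),
    )


# ---------------------------------------------------------------------------
# conductance-voltage analysis

def tail_amplitude(
    trace: Trace, tail_start: float, blank: float = 2.0, window: float = 5.0
) -> float:
    """Isochronal tail amplitude: mean over [tail_start+blank, +blank+window]."""
    t0 = tail_start + blank
    mask = (trace.time >= t0 - 1e-9) & (trace.time <= t0 + window + 1e-9)
    if not mask.any():
        raise FitError("tail measurement window contains no samples")
    return float(trace.values[mask].mean())


def _family_protocols(family) -> tuple[Protocol, ...]:
    if isinstance(family, ProtocolFamily):
        return family.protocols()
    return tuple(family)


def build_gv(
    traces: list[Trace],
    family: ProtocolFamily,
    tail_epoch: int = -1,
    blank: float = 2.0,
    window: float = 5.0,
    normalize: bool = True,
) -> XYCurve:
    """Conductance-voltage relation from isochronal tail-current amplitudes.

    Each family member must end with the same fixed tail epoch; conductance
    at each step voltage is indexed by the tail amplitude measured ``blank``
    ms after repolarization, averaged over ``window`` ms.
    """
    protocols = _family_protocols(family)
    if len(traces) != len(protocols):
        raise FitError("one trace per family member required")
    if any(len(p.epochs) < 2 for p in protocols):
        raise FitError("family protocols have no tail epoch")
    tail_vs = {p.epochs[tail_epoch].v for p in protocols}
    if len(tail_vs) != 1:
        raise FitError("family members have differing tail epochs")
    g = [
        tail_amplitude(tr, p.epoch_start(tail_epoch), blank, window)
        for tr, p in zip(traces, protocols)
    ]
    x = np.asarray(family.values, dtype=float)
    order = np.argsort(x)
    y = np.asarray(g)[order]
    if normalize:
        ymax = np.abs(y).max()
        if ymax == 0:
            raise FitError("all tail amplitudes are zero; cannot normalize")
        y = y / ymax
    return XYCurve(x=x[order], y=y, normalized=normalize, ylabel="conductance")


def _boltzmann(v: np.ndarray, v_half: float, z: float, t_kelvin: float) -> np.ndarray:
    # V in mV -> volts inside the exponent
    return 1.0 / (1.0 + np.exp(-z * FARADAY * (v - v_half) * 1e-3 / (GAS_CONSTANT * t_kelvin)))


def fit_boltzmann(
    curve: XYCurve, n_components: int = 1, t_kelvin: float = DEFAULT_T_KELVIN
) -> BoltzmannFit:
    """Fit a G-V or F-V curve with one or two Boltzmann components.

    Each component is weight / (1 + exp(-zF(V - V1/2)/RT)) with V in mV and
    weights summing to the curve amplitude.  Multi-start over V1/2 and z;
    components are returned ordered by ascending V1/2.
    """
    if n_components not in (1, 2):
        raise FitError("n_components must be 1 or 2")
    v, y = curve.x, curve.y
    if v.size < (5 if n_components == 1 else 8):
        raise FitError("too few points for the requested Boltzmann fit")
    amp = float(np.abs(y).max())
    if amp == 0 or np.ptp(y) < 1e-12:
        raise FitError("flat curve; cannot fit a Boltzmann")

    def model(pars) -> np.ndarray:
        out = np.zeros_like(v)
        for i in range(n_components):
            out = out + pars[f"w{i}"].value * _boltzmann(
                v, pars[f"vh{i}"].value, pars[f"z{i}"].value, t_kelvin
            )
        return out

    quantiles = np.quantile(v, [0.25, 0.5, 0.75])
    starts = []
    for z0 in (1.0, 2.0, 4.0):
        for vh0 in quantiles:
            starts.append((vh0, z0))
    best = None
    for vh0, z0 in starts:
        p = Parameters()
        for i in range(n_components):
            offset = 30.0 * i  # separate the two components' initial centres
            p.add(f"vh{i}", value=float(vh0) + offset, min=v.min() - 200, max=v.max() + 200)
            p.add(f"z{i}", value=z0, min=0.05, max=30)
            p.add(f"w{i}", value=amp / n_components, min=1e-9)
        try:
            res = minimize(lambda pars: model(pars) - y, p, method="leastsq")
        except Exception:
            continue
        if res.success and (best is None or res.chisqr < best.chisqr * (1 - 1e-12)):
            best = res
    if best is None:
        raise FitError("Boltzmann fit did not converge from any start")
    comps = sorted(
        (
            BoltzmannComponent(
                v_half=float(best.params[f"vh{i}"].value),
                z=float(best.params[f"z{i}"].value),
                weight=float(best.params[f"w{i}"].value),
            )
            for i in range(n_components)
        ),
        key=lambda c: c.v_half,
    )
    return BoltzmannFit(
        components=tuple(comps),
        residual_norm=float(np.sqrt(best.chisqr)),
        t_kelvin=t_kelvin,
    )


# ---------------------------------------------------------------------------
# fluorometry analysis

def debleach(
    trace: FluorescenceTrace,
    holding_window: float = 2000.0,
    baseline: str = "linear",
) -> FluorescenceTrace:
    """Photobleach baseline correction for a fluorometry trace.

    A baseline (linear by default, single-exponential optional) is fitted on
    the first ``holding_window`` ms of the trace -- which must lie at the
    holding potential, before the test pulse -- then extrapolated over the
    whole trace and subtracted, so the corrected holding segment averages to
    zero.
    """
    t, y = trace.time, trace.values
    if t[-1] < holding_window or (t <= holding_window).sum() < 10:
        raise FitError("holding segment shorter than the baseline window")
    mask = t <= holding_window + 1e-9
    th, yh = t[mask], y[mask]
    if baseline == "linear":
        coeffs = np.polyfit(th, yh, 1)
        base = np.polyval(coeffs, t)
    elif baseline == "exponential":
        if np.ptp(yh) < 1e-15:  # flat baseline: exponential model is degenerate
            base = np.full_like(t, yh.mean())
        else:
            res = _fit_sum_exp(th, yh, 1, _exp_tau_grid(float(th[-1] - th[0]), 1))
            base = res.params["c"].value + res.params["a0"].value * np.exp(
                -t / res.params["tau0"].value
            )
    else:
        raise FitError(f"unknown baseline model {baseline!r}")
    meta = dict(trace.metadata)
    meta["debleached"] = baseline
    return FluorescenceTrace(time=t, values=y - base, metadata=meta)


def build_fv(
    traces: list[FluorescenceTrace],
    family: ProtocolFamily,
    pulse_epoch: int | None = None,
) -> XYCurve:
    """F-V relation: end-of-test-pulse dF/F per voltage, normalized to the maximum."""
    protocols = _family_protocols(family)
    if not traces:
        raise FitError("empty trace family")
    if len(traces) != len(protocols):
        raise FitError("one trace per family member required")
    if pulse_epoch is None:
        pulse_epoch = family.epoch_index if isinstance(family, ProtocolFamily) else -1
    vals = []
    for tr, p in zip(traces, protocols):
        t_end = p.epoch_start(pulse_epoch) + p.epochs[pulse_epoch].duration
        idx = int(np.argmin(np.abs(tr.time - t_end)))
        vals.append(tr.values[idx])
    x = np.asarray(family.values, dtype=float)
    order = np.argsort(x)
    y = np.asarray(vals)[order]
    ymax = np.abs(y).max()
    if ymax == 0:
        raise FitError("all end-pulse fluorescence values are zero")
    return XYCurve(x=x[order], y=y / ymax, normalized=True, ylabel="dF/F")


# ---------------------------------------------------------------------------
# ratios and paired-condition measures

def rb_k_ratio(
    trace_rb: Trace,
    trace_k: Trace,
    tail_start: float,
    blank: float = 2.0,
    window: float = 5.0,
) -> float:
    """Ratio of Rb+ to K+ tail-current amplitudes (same rule as build_gv)."""
    if trace_rb.time.shape != trace_k.time.shape or not np.allclose(
        trace_rb.time, trace_k.time
    ):
        raise FitError("Rb and K traces must share the protocol time grid")
    amp_k = tail_amplitude(trace_k, tail_start, blank, window)
    amp_rb = tail_amplitude(trace_rb, tail_start, blank, window)
    if abs(amp_k) < 1e-300:
        raise FitError("zero-amplitude K+ tail; ratio undefined")
    return amp_rb / amp_k


def percent_increase(
    trace_ctrl: Trace,
    trace_drug: Trace,
    epoch_end: float | None = None,
    window: float = 100.0,
) -> float:
    """Percent current increase, measured at the end of the test pulse.

    The measurement is the mean over the last ``window`` ms before
    ``epoch_end`` (default: the first epoch boundary recorded in the trace
    metadata, i.e. the end of the test step).
    """
    if trace_ctrl.time.shape != trace_drug.time.shape or not np.allclose(
        trace_ctrl.time, trace_drug.time
    ):
        raise FitError("paired traces must share the protocol time grid")
    if epoch_end is None:
        bounds = trace_ctrl.epoch_boundaries()
        epoch_end = float(bounds[0]) if bounds is not None else float(trace_ctrl.time[-1])
    mask = (trace_ctrl.time >= epoch_end - window - 1e-9) & (
        trace_ctrl.time <= epoch_end + 1e-9
    )
    if not mask.any():
        raise FitError("measurement window contains no samples")
    i_ctrl = trace_ctrl.values[mask].mean()
    i_drug = trace_drug.values[mask].mean()
    if abs(i_ctrl) < 1e-300:
        raise FitError("zero control current; percent increase undefined")
    return 100.0 * (i_drug - i_ctrl) / i_ctrl
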