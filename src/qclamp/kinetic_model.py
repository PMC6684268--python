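"""Five-state kinetic model of KCNQ1 two-open-state gating.

The scheme couples stepwise voltage-sensor (VSD) activation to pore opening:

        RC <--> IC <--> AC        (closed pore; VSD resting/intermediate/activated)
                |        |
                k3/k4    k1/k2    (voltage-independent E-M coupling)
                |        |
                IO <--> AO        (open pore at intermediate/activated VSD)

VSD transitions (RC<->IC, IC<->AC) and the open-state transition IO<->AO are
voltage dependent with single-exponential rate laws; the vertical E-M coupling
rates k1..k4 are constants.  There is no direct RC -> open transition.  The
IC-AC-AO-IO loop must satisfy detailed balance; because the IC<->AC and IO<->AO
rate laws share their slope factors, the loop product ratio is voltage
independent and reduces to a product of the prefactors and coupling constants.

The ML277 modification rule halves the AO-exit rates: k2 -> k2/2 with c3
rebalanced so the loop stays in detailed balance (equivalent to halving beta3
at every voltage).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import null_space
from scipy.sparse.csgraph import connected_components

__all__ = [
    "State",
    "STATE_NAMES",
    "RateLaw",
    "ModelParameters",
    "LoopBalanceReport",
    "CONTROL_PARAMETERS",
    "VARIANTS",
    "evaluate_rate",
    "build_generator",
    "loop_balance_report",
    "balanced_c3",
    "apply_ml277",
    "make_variant",
    "reachable_states",
    "steady_state",
]


class ModelError(ValueError):
    """Invalid model parameters or a degenerate kinetic scheme."""


class State(enum.IntEnum):
    """The five gating states (VSD conformation x pore)."""

    RC = 0  # resting closed
    IC = 1  # intermediate closed
    AC = 2  # activated closed
    IO = 3  # intermediate open
    AO = 4  # activated open


STATE_NAMES: tuple[str, ...] = tuple(s.name for s in State)

OPEN_STATES: tuple[State, State] = (State.IO, State.AO)


@dataclass(frozen=True)
class RateLaw:
    """Single-exponential voltage dependence r(v) = prefactor*exp(direction*v/slope).

    Parameters
    ----------
    prefactor : float
        Rate at 0 mV, in ms^-1 (the a_i / c_i constants).
    slope : float
        Voltage scale in mV (m, n, b or d).
    direction : int
        +1 for forward (depolarization-favoured alpha) rates, -1 for backward
        (beta) rates.
    """

    prefactor: float
    slope: float
    direction: int = 1

    def __post_init__(self) -> None:
        if not (self.prefactor > 0 and math.isfinite(self.prefactor)):
            raise ModelError(f"rate prefactor must be positive, got {self.prefactor}")
        if not (self.slope > 0 and math.isfinite(self.slope)):
            raise ModelError(f"rate slope must be positive, got {self.slope}")
        if self.direction not in (-1, 1):
            raise ModelError(f"direction must be +1 or -1, got {self.direction}")


def evaluate_rate(law: RateLaw, v: float) -> float:
    """Evaluate a voltage-dependent rate law at membrane voltage ``v`` (mV)."""
    if not math.isfinite(v):
        raise ModelError(f"voltage must be finite, got {v}")
    return law.prefactor * math.exp(law.direction * v / law.slope)


# Variant tags and the state set each confines the chain to.  The VSD-locked
# variants (charge-reversal mutations) freeze the sensor in one conformation;
# the coupling-ablated variants remove the corresponding open state, since the
# pore can no longer open while the VSD sits in that conformation.
VARIANTS: dict[str, tuple[State, ...]] = {
    "intermediate_locked": (State.IC, State.IO),
    "activated_locked": (State.AC, State.AO),
    "no_AO_coupling": (State.RC, State.IC, State.AC, State.IO),
    "no_IO_coupling": (State.RC, State.IC, State.AC, State.AO),
}


@dataclass(frozen=True)
class ModelParameters:
    """Complete rate parameterization of the five-state scheme.

    Prefactors a1..a3, c1..c3 are in ms^-1, slope factors m, n, b, d in mV.
    alpha2/alpha3 share slope ``b`` and beta2/beta3 share slope ``d``; this
    shared-slope structure is what makes the loop balance voltage independent.
    Coupling constants k1 (AC->AO), k2 (AO->AC), k3 (IC->IO), k4 (IO->IC) are
    voltage independent, in ms^-1.
    """

    a1: float = 0.00070
    c1: float = 0.0020
    m: float = 46.0
    n: float = 31.2
    a2: float = 0.0047
    c2: float = 0.00017
    a3: float = 0.15
    c3: float = 0.048
    b: float = 37.7
    d: float = 41.5
    k1: float = 0.89
    k2: float = 853.08
    k3: float = 0.96
    k4: float = 103.82
    label: str = "control"
    variant: str | None = None

    def __post_init__(self) -> None:
        for name in ("a1", "c1", "a2", "c2", "a3", "c3", "m", "n", "b", "d"):
            value = getattr(self, name)
            if not (value > 0 and math.isfinite(value)):
                raise ModelError(f"parameter {name} must be positive, got {value}")
        for name in ("k1", "k2", "k3", "k4"):
            value = getattr(self, name)
            if not (value >= 0 and math.isfinite(value)):
                raise ModelError(f"coupling rate {name} must be >= 0, got {value}")
            if value == 0 and name in ("k2", "k4"):
                raise ModelError(f"coupling rate {name} must be positive")
        if self.variant is not None and self.variant not in VARIANTS:
            raise ModelError(
                f"unknown variant {self.variant!r}; expected one of {sorted(VARIANTS)}"
            )

    # rate-law accessors -------------------------------------------------
    @property
    def alpha1(self) -> RateLaw:
        return RateLaw(self.a1, self.m, +1)

    @property
    def beta1(self) -> RateLaw:
        return RateLaw(self.c1, self.n, -1)

    @property
    def alpha2(self) -> RateLaw:
        return RateLaw(self.a2, self.b, +1)

    @property
    def beta2(self) -> RateLaw:
        return RateLaw(self.c2, self.d, -1)

    @property
    def alpha3(self) -> RateLaw:
        return RateLaw(self.a3, self.b, +1)

    @property
    def beta3(self) -> RateLaw:
        return RateLaw(self.c3, self.d, -1)


#: The printed control parameterization.
CONTROL_PARAMETERS = ModelParameters()


def reachable_states(params: ModelParameters) -> tuple[State, ...]:
    """States the chain can occupy for this parameter set's variant tag."""
    if params.variant is None:
        return tuple(State)
    return VARIANTS[params.variant]


def build_generator(params: ModelParameters, v: float) -> np.ndarray:
    """Build the 5x5 generator (Q-matrix) at membrane voltage ``v`` (mV).

    Entry (i, j), i != j, is the transition rate i -> j in ms^-1; diagonal
    entries are negative row sums so every row sums to zero.  Only the ten
    edges of the scheme are populated; for variant-tagged parameter sets,
    edges touching unreachable states are omitted.
    """
    if not math.isfinite(v):
        raise ModelError(f"voltage must be finite, got {v}")
    allowed = set(reachable_states(params))
    edges: list[tuple[State, State, float]] = [
        (State.RC, State.IC, evaluate_rate(params.alpha1, v)),
        (State.IC, State.RC, evaluate_rate(params.beta1, v)),
        (State.IC, State.AC, evaluate_rate(params.alpha2, v)),
        (State.AC, State.IC, evaluate_rate(params.beta2, v)),
        (State.IC, State.IO, params.k3),
        (State.IO, State.IC, params.k4),
        (State.AC, State.AO, params.k1),
        (State.AO, State.AC, params.k2),
        (State.IO, State.AO, evaluate_rate(params.alpha3, v)),
        (State.AO, State.IO, evaluate_rate(params.beta3, v)),
    ]
    q = np.zeros((5, 5))
    for src, dst, rate in edges:
        if src in allowed and dst in allowed:
            q[src, dst] = rate
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


@dataclass(frozen=True)
class LoopBalanceReport:
    """Detailed-balance diagnostics for the IC-AC-AO-IO cycle.

    ``forward_product`` is a2*k1*c3*k4 (IC->AC->AO->IO->IC) and
    ``reverse_product`` is k3*a3*k2*c2; the voltage factors cancel exactly
    when alpha2/alpha3 share slope b and beta2/beta3 share slope d, which
    ``slope_consistent`` records.  ``has_cycle`` is False when a coupling
    edge is zero (open loop), in which case the products are meaningless.
    """

    forward_product: float
    reverse_product: float
    ratio: float
    slope_consistent: bool
    has_cycle: bool


def loop_balance_report(params: ModelParameters) -> LoopBalanceReport:
    """Report the detailed-balance closure of the four-state cycle."""
    if min(params.k1, params.k2, params.k3, params.k4) == 0:
        return LoopBalanceReport(math.nan, math.nan, math.nan, True, has_cycle=False)
    forward = params.a2 * params.k1 * params.c3 * params.k4
    reverse = params.k3 * params.a3 * params.k2 * params.c2
    # shared slopes are structural in ModelParameters (alpha2/alpha3 both use
    # b, beta2/beta3 both use d), so consistency always holds here; kept as an
    # explicit field for parameter sets read from file with a free slope.
    return LoopBalanceReport(forward, reverse, forward / reverse, True, has_cycle=True)


def balanced_c3(params: ModelParameters, k2_new: float) -> float:
    """The unique c3 restoring detailed balance after changing k2 to ``k2_new``.

    Solves forward == reverse for c3:  c3 = k3*a3*k2_new*c2 / (a2*k1*k4).
    Linear in ``k2_new``; with ``k2_new == params.k2`` this returns the c3
    implied by the other seven loop constants.
    """
    denom = params.a2 * params.k1 * params.k4
    if denom == 0 or min(params.k3, params.a3, params.c2) == 0:
        raise ModelError("degenerate model: loop constants must be nonzero")
    if not (k2_new > 0 and math.isfinite(k2_new)):
        raise ModelError(f"k2_new must be positive, got {k2_new}")
    return params.k3 * params.a3 * k2_new * params.c2 / denom


def apply_ml277(params: ModelParameters) -> ModelParameters:
    """Apply the ML277 modification: halve k2 and rebalance c3.

    ML277 stabilizes the activated-open state by slowing both AO-exit rates;
    halving c3 halves beta3 at every voltage, and the rebalanced value keeps
    the cycle in detailed balance.  When a coupling-ablated variant has
    broken the cycle there is no balance constraint and c3 is halved
    directly (the same operation, since rebalancing is linear in k2).
    """
    if params.k2 == 0:
        raise ModelError("k2 must be nonzero to apply the ML277 rule")
    k2_new = params.k2 / 2.0
    if min(params.k1, params.k3) == 0:
        c3_new = params.c3 / 2.0
    else:
        c3_new = balanced_c3(params, k2_new)
    return replace(
        params,
        k2=k2_new,
        c3=c3_new,
        label=f"{params.label}+ML277",
    )


def make_variant(params: ModelParameters, variant: str) -> ModelParameters:
    """Build a mutant-emulating parameter set.

    ``intermediate_locked`` (E1R/R2E-like) confines the chain to {IC, IO};
    ``activated_locked`` (E1R/R4E-like) to {AC, AO};
    ``no_AO_coupling`` (S338F-like) removes the activated-open state and sets
    k1 = 0; ``no_IO_coupling`` (F351A-like) removes the intermediate-open
    state and sets k3 = 0.  The tag is consumed by the simulator's
    initial-condition logic (occupancy confined to the reachable set).
    """
    if variant not in VARIANTS:
        raise ModelError(f"unknown variant {variant!r}; expected one of {sorted(VARIANTS)}")
    updates: dict[str, object] = {"variant": variant, "label": f"{params.label}:{variant}"}
    if variant == "no_AO_coupling":
        updates["k1"] = 0.0
    elif variant == "no_IO_coupling":
        updates["k3"] = 0.0
    return replace(params, **updates)


def steady_state(params: ModelParameters, v: float) -> np.ndarray:
    """Stationary occupancy of the (reachable) chain at voltage ``v``.

    Returns a length-5 probability vector; states outside the variant's
    reachable set carry exactly zero probability.  Computed as the normalized
    left null vector of the generator restricted to the reachable set.
    """
    allowed = list(reachable_states(params))
    q = build_generator(params, v)
    sub = q[np.ix_(allowed, allowed)]
    # a unique stationary law needs the reachable chain strongly connected
    n_comp, comp = connected_components(sub != 0, directed=True, connection="strong")
    if n_comp > 1:
        groups = [
            [State(allowed[i]).name for i in range(len(allowed)) if comp[i] == c]
            for c in range(n_comp)
        ]
        raise ModelError(
            "no unique stationary distribution: disconnected state groups "
            + "; ".join("{" + ",".join(g) + "}" for g in groups)
        )
    ns = null_space(sub.T)
    if ns.shape[1] != 1:
        raise ModelError("generator null space is not one-dimensional")
    pi = ns[:, 0]
    pi = pi / pi.sum()
    if pi.min() < -1e-12:
        raise ModelError("stationary solve produced negative probabilities")
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    out = np.zeros(5)
    out[allowed] = pi
    return out
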