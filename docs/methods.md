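# Methods

## The gating model

`qclamp` implements a five-state Markov model of KCNQ1 (Kv7.1) channel
gating in which the pore can open at two distinct conformations of the
voltage-sensing domain (VSD):

```
    RC  <-- α1/β1 -->  IC  <-- α2/β2 -->  AC        closed pore
                        |                  |
                      k3 | k4            k1 | k2     E-M coupling
                        |                  |
                        IO  <-- α3/β3 -->  AO        open pore
```

RC/IC/AC are closed states with the VSD resting, intermediate and
activated; IO and AO are the intermediate-open and activated-open states.
There is no direct transition from RC to an open state.  Horizontal
transitions are voltage dependent with single-exponential rate laws

    α1 = a1·exp(v/m),   β1 = c1·exp(−v/n)
    αi = ai·exp(v/b),   βi = ci·exp(−v/d)    (i = 2, 3)

with v in mV; the vertical electro-mechanical (E-M) coupling rates k1
(AC→AO), k2 (AO→AC), k3 (IC→IO), k4 (IO→IC) are voltage independent.  The
default parameter set (ms⁻¹ and mV) is

    a1 = 0.00070  a2 = 0.0047  a3 = 0.15
    c1 = 0.0020   c2 = 0.00017 c3 = 0.048
    m = 46.0  n = 31.2  b = 37.7  d = 41.5
    k1 = 0.89  k2 = 853.08  k3 = 0.96  k4 = 103.82

### Detailed balance

The IC–AC–AO–IO cycle must satisfy detailed balance.  Because α2 and α3
share the slope `b` and β2 and β3 share `d`, the voltage factors cancel
around the loop and the balance condition reduces to a relation between
constants:

    a2·k1·c3·k4 = k3·a3·k2·c2

The default set closes this loop to about 0.2% (both products ≈ 0.0209);
`loop_balance_report` exposes the two products and their ratio, and the
package treats ratios within 1% as balanced.  Two structural assignments
are hard-coded because only they are consistent with balance: k3 = IC→IO
and k4 = IO→IC (the reverse assignment misses balance by four orders of
magnitude), and α2 = IC↔AC as the in-loop VSD transition sharing slopes
with α3/β3.  The E-M coupling constants carry no printed units; ms⁻¹ is
assumed for dimensional consistency with the a/c prefactors and recorded
in parameter-file metadata.

### The ML277 rule

The activator ML277 is modelled as a stabilization of the AO state: both
AO-exit rates are halved.  `apply_ml277` sets k2 → k2/2 and rebalances
c3 through the detailed-balance relation, c3 → (k3·a3·(k2/2)·c2)/(a2·k1·k4)
≈ 0.024 ms⁻¹, which is the same operation as halving β3 at every voltage.
For coupling-ablated variants whose cycle is open there is no balance
constraint and c3 is halved directly (rebalancing is linear in k2, so the
two rules coincide wherever both are defined).

### Mutant-emulating variants

Four variants reproduce the phenomenology of the classical KCNQ1 open-state
isolation mutants as state-space restrictions (no mutant energetics are
modelled):

- `intermediate_locked` (E1R/R2E-like): chain confined to {IC, IO} — the
  VSD is frozen at the intermediate state, constitutive IO opening.
- `activated_locked` (E1R/R4E-like): confined to {AC, AO}; the open
  probability is the two-state equilibrium k1/(k1+k2) ≈ 1.04×10⁻³ at every
  voltage.
- `no_AO_coupling` (S338F-like): the AO state is removed and k1 = 0 — the
  pore cannot open while the VSD is activated.
- `no_IO_coupling` (F351A-like): the IO state is removed and k3 = 0.

Removing the open state (rather than only zeroing the coupling constant)
is deliberate: with k1 = 0 alone AO would remain reachable through the
IO→AO transition, and the variants are meant to isolate one open state.

## Simulation

Within each constant-voltage epoch the master equation dp/dt = p·Q(v) is
linear with constant coefficients, so occupancy is propagated by the exact
matrix exponential of the 5×5 generator; the propagator for the 1 ms
sampling step (1 kHz, matching two-electrode voltage-clamp acquisition) is
computed once per epoch and reused.  No solver tolerance exists.  The
command voltage is right-continuous: samples on an epoch boundary belong to
the later epoch.  Initial conditions default to the stationary occupancy at
the holding potential (−80 mV), restricted to a variant's reachable set.

Macroscopic current is I(t) = N·g·(P_IO·r_IO + P_AO·r_AO)·(v − E_rev) with
single-channel conductance g = 0.18 pS and E_rev = −80 mV by default.  The
channel count N defaults to 1, so traces are in arbitrary units
proportional to pS·mV — the channel count per cell is unknown, and every
analysis in the package is ratio- or shape-based.  The per-open-state
relative conductances r_IO/r_AO are solution presets: the "100K" solution
is (E_rev = 0, 1, 1) and "100Rb" is (E_rev = 0, r_IO = 3.1, r_AO = 0.6),
encoding the higher Rb⁺ permeability of the IO state.  These factors are an
emulation device for the Rb/K tail-ratio measurement, not part of the
kinetic model.

Fluorometry signals are modelled as ΔF/F(t) = w_I·(P_IC+P_IO) +
w_A·(P_AC+P_AO) with default weights (0.5, 1): the fluorophore dequenches
partially at the intermediate VSD conformation and fully at the activated
one.  The signal is bounded in [0, w_A] and reports VSD activation only.

The slowest relaxation of the default generator at +40 mV is about 0.6 s,
so a 4 s pulse ends within ~2×10⁻³ of the stationary law and an 8 s pulse
within 10⁻⁴ — worth knowing when comparing end-pulse measures with true
steady-state quantities.

## Analysis procedures

All fits are deterministic multi-start nonlinear least squares (lmfit,
Levenberg–Marquardt), with eight τ starting points spanning decades of the
fit window; ties are broken by lowest residual, then lowest fast τ, so
repeated fits of identical data are bit-identical.

- **Activation kinetics** — one or two exponentials, reported in the rising
  convention y = C + ΣA_i(1−exp(−t/τ_i)) with components relabelled so
  τ_f < τ_s.  `windowed` mode fits single exponentials on an early and a
  late window (default split 200 ms) for conditions where only the slow
  component changes; the split is configurable since no standard value
  exists.
- **Hook decomposition** — tail epochs are fitted with
  F(t) = A1·exp(−t/τ1) + A2·exp(−t/τ2) + C after a 2 ms capacitive blank.
  The component whose sign opposes the net decay is the hook (A2, τ2); if a
  double exponential does not improve on a single one, or both components
  share the net-decay sign (a multi-phase but monotonic deactivation),
  A2 = 0 is reported.  The hook quantifies recovery from the
  low-open-probability AO state through the higher-open-probability IO
  state upon hyperpolarization.
- **Hook development** — |A2| across a pre-pulse-duration family is
  normalized to its per-condition maximum and fitted with
  y = y∞·(1−exp(−t/τ)).  In the simulated model the onset is
  delayed-sigmoidal (A2 is exactly zero below ~0.5 s pre-pulses), so the
  single exponential is a summary description: at the default +60 mV
  pre-pulse family it captures the development with R² ≈ 0.9 and a maximum
  pointwise deviation of ~0.16 normalized units.
- **G-V curves** — isochronal tail-current amplitudes at the fixed tail
  step, measured as the mean over a 5 ms window starting 2 ms after
  repolarization (both configurable; no published windows exist for these
  measurements, so the defaults are this package's own convention).
- **Boltzmann fits** — one or two components of
  w/(1+exp(−zF(V−V½)/RT)) with T = 295.15 K (recordings at 21–23 °C) and
  CODATA F, R.  Components are reported in ascending V½ order.
- **Photobleach correction** — a linear (optionally exponential) baseline
  fitted on the first 2 s of the holding segment is extrapolated over the
  whole trace and subtracted.
- **F-V curves** — end-of-test-pulse ΔF/F normalized to the family maximum.
- **Rb/K ratio and percent increase** — tail-amplitude ratio under the two
  solution presets (same measurement rule as G-V), and
  100·(I_drug−I_ctrl)/I_ctrl over the last 100 ms of the test pulse.

## Synthetic data

`generate_dataset` wraps the simulator with a recording-noise model:
white Gaussian current noise with SD a fraction (default 2%) of the clean
trace's peak, an optional constant leak offset, and for fluorescence a
linear photobleach drift (default −10⁻⁵ ΔF/F per ms over the trace) plus
Gaussian noise (default 1%).  Noise is white: the 2 kHz Bessel filtering of
real recordings is not emulated, so sample-to-sample correlations of real
data are absent and fit tolerances are calibrated at the unfiltered noise
level.  A linear drift is the minimal structure that exercises the baseline
correction.  Datasets are deterministic given their seed, and
`generate_condition_pair` derives two independent noise streams from one
seed for matched control/drug (or control/variant) recordings.

What passing generate-and-refit tests do show: the analysis chain recovers
the generating kinetics at realistic noise levels.  What they do not show:
robustness to cell-to-cell variability, rundown, endogenous conductances,
series-resistance or liquid-junction artifacts — none of which are
modelled.

## Numerical choices and degenerate inputs

- Generator rows sum to zero by construction; occupancy is clipped and
  renormalized after propagation to absorb ~10⁻¹⁶-level roundoff.
- Stationary distributions come from the null space of the generator
  restricted to the reachable state set, with an explicit
  strong-connectivity check that names disconnected state groups.
- Hook fits collapse to the single-exponential result when the two τs are
  within ~5% of each other or the residual improvement is below 0.1%.
- Flat traces, too-short windows, empty families and zero-amplitude
  denominators raise typed errors (`ModelError`, `FitError`, ...) rather
  than returning garbage.
- The simulator's correctness oracle in the test suite is a classical RK4
  integrator at a 1 µs step.  The stiffest default rate (k2 ≈ 853 ms⁻¹)
  puts coarser steps outside RK4's stability region; for this linear
  system one RK4 step is exactly multiplication by the degree-4 Taylor
  polynomial of the propagator, which is how the oracle is implemented.

## Problem sizes

The shipped tests and the acceptance script use the protocol library at
its printed durations (4–8 s pulses at 1 kHz), 11-voltage families,
12-duration hook families, and 100-seed Monte-Carlo recovery runs — sizes
chosen so the whole pipeline exercises every procedure at full protocol
length while a complete run stays in the minutes range on one CPU.

## Known limitations

- The model treats the channel as a single gating unit; the four-subunit
  architecture with four VSDs is deliberately not expanded.
- Parameters are used as printed; refitting rates to trace data is out of
  scope.
- The ML277 rule reproduces the equilibrium drug phenotype (enhanced AO
  occupancy and current, right-shifted G-V, unchanged F-V) but not the
  experimentally observed slowing of activation/deactivation kinetics; in
  the model the hook development becomes slightly faster under the rule,
  whereas recordings show it slowing.
- At depolarized potentials the default parameter set occupies AO much
  more than IO, so occupancy-weighted mixtures (e.g. the simulated Rb/K
  tail ratio ≈ 0.72) are AO-weighted even though real KCNQ1 currents are
  predominantly IO-type; the Rb/K machinery is therefore validated on its
  construction (bounds and direction of change) rather than on absolute
  experimental ratios.
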