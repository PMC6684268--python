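import numpy as np
import pytest

from qclamp.kinetic_model import apply_ml277, make_variant
from qclamp.protocol import Protocol, VoltageEpoch, family_sweep, make_standard_protocol
from qclamp.simulator import (
    CurrentTrace,
    FluorescenceTrace,
    Trace,
    fluorescence_from_trajectory,
    integrate_occupancy,
    simulate_current,
    simulate_family,
)
from qclamp.trace_analysis import (
    FitError,
    XYCurve,
    build_fv,
    build_gv,
    debleach,
    fit_boltzmann,
    fit_exponentials,
    fit_hook_tail,
    hook_development,
    percent_increase,
    rb_k_ratio,
    tail_amplitude,
)


def rising_double_exp(t, tau_f=48.0, tau_s=600.0, a_f=1.0, a_s=0.5, c=0.0):
    return c + a_f * (1 - np.exp(-t / tau_f)) + a_s * (1 - np.exp(-t / tau_s))


class TestExponentialFits:
    def test_noise_free_double_exponential_recovery(self):
        t = np.arange(0.0, 4000.0)
        trace = Trace(time=t, values=rising_double_exp(t))
        fit = fit_exponentials(trace, n_components=2, mode="joint")
        assert fit.tau_f == pytest.approx(48.0, rel=0.01)
        assert fit.tau_s == pytest.approx(600.0, rel=0.01)
        assert fit.amplitudes[1] / fit.amplitudes[0] == pytest.approx(0.5, rel=0.01)

    def test_single_exponential_recovery(self):
        t = np.arange(0.0, 2000.0)
        trace = Trace(time=t, values=2.0 * (1 - np.exp(-t / 150.0)) + 0.3)
        fit = fit_exponentials(trace, n_components=1)
        assert fit.taus[0] == pytest.approx(150.0, rel=1e-3)
        assert fit.residual_norm < 1e-8

    def test_noisy_recovery_within_five_percent(self):
        t = np.arange(0.0, 4000.0)
        clean = rising_double_exp(t)
        rng = np.random.default_rng(42)
        for _ in range(5):
            noisy = clean + rng.normal(0, 0.02 * np.ptp(clean), t.size)
            fit = fit_exponentials(Trace(time=t, values=noisy), n_components=2)
            assert fit.tau_f == pytest.approx(48.0, rel=0.05)
            assert fit.tau_s == pytest.approx(600.0, rel=0.05)

    def test_windowed_mode_orders_components(self):
        t = np.arange(0.0, 4000.0)
        trace = Trace(time=t, values=rising_double_exp(t))
        fit = fit_exponentials(trace, n_components=2, mode="windowed", split=200.0)
        assert fit.mode == "windowed"
        assert 0 < fit.tau_f < fit.tau_s

    def test_decaying_trace_fits_with_negative_amplitude(self):
        t = np.arange(0.0, 1000.0)
        trace = Trace(time=t, values=3.0 * np.exp(-t / 120.0))
        fit = fit_exponentials(trace, n_components=1)
        assert fit.taus[0] == pytest.approx(120.0, rel=1e-3)
        assert fit.amplitudes[0] < 0  # falls by |A| from its start

    def test_flat_trace_rejected(self):
        t = np.arange(0.0, 100.0)
        with pytest.raises(FitError):
            fit_exponentials(Trace(time=t, values=np.ones_like(t)), n_components=1)

    def test_too_few_samples_rejected(self):
        t = np.arange(0.0, 12.0)
        with pytest.raises(FitError, match="samples"):
            fit_exponentials(Trace(time=t, values=np.exp(-t)), n_components=2)

    def test_deterministic_relabelling(self):
        t = np.arange(0.0, 4000.0)
        rng = np.random.default_rng(3)
        noisy = rising_double_exp(t) + rng.normal(0, 0.01, t.size)
        trace = Trace(time=t, values=noisy)
        fits = [fit_exponentials(trace, n_components=2) for _ in range(2)]
        assert fits[0] == fits[1]


def hook_waveform(t, a1=-1.0, tau1=300.0, a2=0.4, tau2=40.0, c=0.0):
    return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2) + c


class TestHookFit:
    def test_generate_and_refit_with_noise(self):
        t = np.arange(0.0, 2000.0)
        rng = np.random.default_rng(11)
        y = hook_waveform(t) + rng.normal(0, 0.01, t.size)
        fit = fit_hook_tail(Trace(time=t, values=y))
        assert fit.a1 == pytest.approx(-1.0, rel=0.05)
        assert fit.tau1 == pytest.approx(300.0, rel=0.05)
        assert fit.a2 == pytest.approx(0.4, rel=0.05)
        assert fit.tau2 == pytest.approx(40.0, rel=0.05)
        assert fit.has_hook

    def test_monotonic_tail_reports_no_hook(self):
        t = np.arange(0.0, 1000.0)
        fit = fit_hook_tail(Trace(time=t, values=-2.0 * np.exp(-t / 250.0)))
        assert abs(fit.a2) < 0.02 * abs(fit.a1)
        assert not fit.has_hook

    def test_simulated_control_tail_shows_hook(self, control):
        proto = Protocol(epochs=(VoltageEpoch(60.0, 2913.0), VoltageEpoch(-120.0, 2000.0)))
        trace = simulate_current(control, proto)
        tail = trace.crop(proto.epoch_start(-1), proto.total_duration)
        fit = fit_hook_tail(tail)
        assert abs(fit.a2) > 0.05 * abs(fit.a1)
        # the tail current magnitude rises before it decays
        mag = np.abs(tail.values[2:])
        assert mag.argmax() > 2

    def test_too_short_tail_rejected(self):
        t = np.arange(0.0, 15.0)
        with pytest.raises(FitError, match="usable samples"):
            fit_hook_tail(Trace(time=t, values=np.exp(-t / 5.0)))


class TestHookDevelopment:
    def saturating_family(self, tau=560.0):
        durations = np.array([30.0, 100.0, 300.0, 700.0, 1500.0, 2913.0, 4355.0])
        t = np.arange(0.0, 2000.0)
        fits = []
        for dur in durations:
            a2 = 0.4 * (1 - np.exp(-dur / tau))
            y = hook_waveform(t, a2=a2)
            fits.append(fit_hook_tail(Trace(time=t, values=y)))
        return durations, fits

    def test_development_constant_recovery(self):
        durations, fits = self.saturating_family(tau=560.0)
        dev = hook_development(durations, fits)
        assert dev.tau == pytest.approx(560.0, rel=0.05)
        assert dev.curve.y.max() == 1.0  # normalized to the family maximum

    def test_hookless_family_rejected(self):
        t = np.arange(0.0, 1000.0)
        fits = [
            fit_hook_tail(Trace(time=t, values=-np.exp(-t / 250.0)))
            for _ in range(5)
        ]
        with pytest.raises(FitError, match="no hook"):
            hook_development([30.0, 100.0, 300.0, 1000.0, 3000.0], fits)

    def test_too_few_durations_rejected(self):
        durations, fits = self.saturating_family()
        with pytest.raises(FitError):
            hook_development(durations[:3], fits[:3])


class TestGV:
    def test_control_gv_shape(self, control, iv_family):
        traces = simulate_family(control, iv_family)
        gv = build_gv(traces, iv_family)
        assert gv.x[0] == -120.0 and gv.x[-1] == 80.0
        assert abs(gv.y[0]) < 0.05  # closed at hyperpolarized voltages
        assert np.all(np.diff(gv.y[:7]) > 0)  # rising through -120..0 mV
        assert gv.y.max() == pytest.approx(1.0)

    def test_drug_raises_absolute_conductance(self, control, ml277, iv_family):
        g_ctrl = build_gv(simulate_family(control, iv_family), iv_family, normalize=False)
        g_drug = build_gv(simulate_family(ml277, iv_family), iv_family, normalize=False)
        ratio = g_drug.y[-1] / g_ctrl.y[-1]
        assert 1.3 < ratio < 2.2

    def test_missing_tail_rejected(self, control):
        base = Protocol(epochs=(VoltageEpoch(40.0, 200.0),))
        fam = family_sweep(base, 0, "v", [-40.0, 0.0, 40.0, 80.0, 120.0])
        traces = simulate_family(control, fam)
        with pytest.raises(FitError, match="tail"):
            build_gv(traces, fam)


class TestBoltzmann:
    voltages = np.arange(-120.0, 81.0, 20.0)

    def single(self, v_half=-26.8, z=2.0):
        from qclamp.trace_analysis import _boltzmann

        return XYCurve(x=self.voltages, y=_boltzmann(self.voltages, v_half, z, 295.15))

    def test_single_component_recovery(self):
        fit = fit_boltzmann(self.single(), n_components=1)
        comp = fit.components[0]
        assert comp.v_half == pytest.approx(-26.8, abs=0.5)
        assert comp.z == pytest.approx(2.0, rel=0.02)

    def test_translation_equivariance(self):
        base = fit_boltzmann(self.single(v_half=-26.8))
        shifted = XYCurve(x=self.voltages + 10.0, y=self.single(v_half=-26.8).y)
        fit = fit_boltzmann(shifted)
        assert fit.components[0].v_half - base.components[0].v_half == pytest.approx(
            10.0, abs=1e-6
        )

    def test_double_component_recovery(self):
        from qclamp.trace_analysis import _boltzmann

        y = 0.4 * _boltzmann(self.voltages, -50.0, 2.5, 295.15) + 0.6 * _boltzmann(
            self.voltages, -20.0, 1.5, 295.15
        )
        fit = fit_boltzmann(XYCurve(x=self.voltages, y=y), n_components=2)
        v_halves = sorted(c.v_half for c in fit.components)
        assert v_halves[0] == pytest.approx(-50.0, abs=2.0)
        assert v_halves[1] == pytest.approx(-20.0, abs=2.0)

    def test_flat_curve_rejected(self):
        with pytest.raises(FitError):
            fit_boltzmann(XYCurve(x=self.voltages, y=np.ones(11) * 0.5))

    def test_too_few_points_rejected(self):
        c = self.single()
        with pytest.raises(FitError):
            fit_boltzmann(XYCurve(x=c.x[:4], y=c.y[:4]), n_components=1)


class TestDebleach:
    def vcf_trace(self, control, v=40.0):
        proto = Protocol(epochs=(VoltageEpoch(-80.0, 2000.0), VoltageEpoch(v, 4000.0)))
        traj = integrate_occupancy(control, proto)
        return fluorescence_from_trajectory(traj), proto

    def test_pure_drift_removed_entirely(self):
        t = np.arange(0.0, 6000.0)
        trace = FluorescenceTrace(time=t, values=-2e-5 * t + 0.1)
        out = debleach(trace)
        assert np.abs(out.values).max() < 1e-10

    def test_step_amplitude_preserved(self, control):
        trace, proto = self.vcf_trace(control)
        drifted = FluorescenceTrace(
            time=trace.time,
            values=trace.values - 3e-5 * trace.time + 0.05,
            metadata=trace.metadata,
        )
        out = debleach(drifted)
        true_step = trace.values[-1] - trace.values[:2000].mean()
        rec_step = out.values[-1] - out.values[:2000].mean()
        assert rec_step == pytest.approx(true_step, rel=0.02)

    def test_drift_free_identity_up_to_constant(self, control):
        trace, _ = self.vcf_trace(control)
        out = debleach(trace)
        holding_mean = trace.values[:2000].mean()
        assert np.abs(out.values - (trace.values - holding_mean)).max() < 1e-6
        assert abs(out.values[:2000].mean()) < 1e-9

    def test_exponential_baseline_mode(self):
        t = np.arange(0.0, 6000.0)
        drift = 0.2 * np.exp(-t / 5000.0)
        out = debleach(FluorescenceTrace(time=t, values=drift), baseline="exponential")
        assert np.abs(out.values[:2000]).max() < 1e-6

    def test_short_holding_rejected(self):
        t = np.arange(0.0, 1500.0)
        with pytest.raises(FitError, match="holding"):
            debleach(FluorescenceTrace(time=t, values=np.zeros_like(t)))


class TestFV:
    def test_equal_weights_match_vsd_progress(self, control):
        from qclamp.kinetic_model import State

        fam = make_standard_protocol("vcf_family")
        trajs = [integrate_occupancy(control, p) for p in fam]
        traces = [fluorescence_from_trajectory(tr, w_i=1.0, w_a=1.0) for tr in trajs]
        fv = build_fv(traces, fam)
        expected = np.array([1.0 - tr.occupancy[-1, State.RC] for tr in trajs])
        expected = expected / expected.max()
        assert np.allclose(fv.y, expected, atol=1e-9)
        assert fv.y.max() == pytest.approx(1.0)

    def test_drug_leaves_fv_unchanged(self, control, ml277):
        fam = make_standard_protocol("vcf_family")
        fv_ctrl = build_fv(simulate_family(control, fam, modality="fluorescence"), fam)
        fv_drug = build_fv(simulate_family(ml277, fam, modality="fluorescence"), fam)
        assert np.abs(fv_ctrl.y - fv_drug.y).max() < 0.05

    def test_empty_family_rejected(self):
        fam = make_standard_protocol("vcf_family")
        with pytest.raises(FitError, match="empty"):
            build_fv([], fam)


class TestRatiosAndIncrease:
    def test_identical_traces_ratio_one(self, control):
        proto = make_standard_protocol("rbk_tail")
        trace = simulate_current(control, proto, solution="100K")
        assert rb_k_ratio(trace, trace, proto.epoch_start(-1)) == pytest.approx(1.0)

    def test_scaled_trace_recovers_scale(self, control):
        from dataclasses import replace

        proto = make_standard_protocol("rbk_tail")
        trace_k = simulate_current(control, proto, solution="100K")
        trace_rb = replace(trace_k, values=3.1 * trace_k.values)
        assert rb_k_ratio(trace_rb, trace_k, proto.epoch_start(-1)) == pytest.approx(3.1)

    def test_solution_presets_bounded_by_state_ratios(self, control):
        # the tail is an occupancy-weighted mixture of the IO (3.1) and AO
        # (0.6) conductance ratios, so the measured ratio must lie between
        proto = make_standard_protocol("rbk_tail")
        trace_k = simulate_current(control, proto, solution="100K")
        trace_rb = simulate_current(control, proto, solution="100Rb")
        ratio = rb_k_ratio(trace_rb, trace_k, proto.epoch_start(-1))
        assert 0.6 < ratio < 3.1

    def test_drug_lowers_rbk_ratio(self, control, ml277):
        proto = make_standard_protocol("rbk_tail")

        def ratio(params):
            k = simulate_current(params, proto, solution="100K")
            rb = simulate_current(params, proto, solution="100Rb")
            return rb_k_ratio(rb, k, proto.epoch_start(-1))

        assert ratio(ml277) < ratio(control)

    def test_percent_increase_basics(self, control, step_protocol):
        from dataclasses import replace

        trace = simulate_current(control, step_protocol)
        assert percent_increase(trace, trace) == pytest.approx(0.0)
        doubled = replace(trace, values=2.0 * trace.values)
        assert percent_increase(trace, doubled) == pytest.approx(100.0)

    def test_activated_locked_drug_increase(self, control, step_protocol):
        var = make_variant(control, "activated_locked")
        i_ctrl = simulate_current(var, step_protocol)
        i_drug = simulate_current(apply_ml277(var), step_protocol)
        # two-state equilibrium k1/(k1+k2/2) vs k1/(k1+k2) from the printed set
        assert percent_increase(i_ctrl, i_drug) == pytest.approx(99.8, abs=0.5)

    def test_tail_window_must_contain_samples(self, control):
        proto = make_standard_protocol("rbk_tail")
        trace = simulate_current(control, proto)
        with pytest.raises(FitError):
            tail_amplitude(trace, proto.total_duration + 100.0)
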