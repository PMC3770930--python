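"""Dual-cycle collection/release dynamics and the drift-diffusion oracle."""

import dataclasses
import math

import numpy as np
import pytest
from scipy.optimize import curve_fit

from depspec.dualcycle import (CycleSpec, DiffusionSpec, FluorescenceMap,
                               am_bandwidth, boltzmann_steady_number,
                               css_state, cycle_amplitude, default_kinetics,
                               dep_force_scale, detect_css, duty_cycle,
                               fluorescence_from_number,
                               modulation_frequency, simulate_mde_1d,
                               simulate_number, switch_envelope)
from depspec.exceptions import ConvergenceError

ALWAYS_ON = CycleSpec(1e9, 0.0, 1e9, 0.0)


class TestTiming:
    @pytest.mark.parametrize("t_on,t_off,expected",
                             [(15, 10, 0.6), (7, 10, 7 / 17), (0, 10, 0.0)])
    def test_duty_cycle(self, t_on, t_off, expected):
        assert duty_cycle(t_on, t_off) == pytest.approx(expected)

    def test_zero_period_rejected(self):
        with pytest.raises(ValueError):
            duty_cycle(0.0, 0.0)

    def test_modulation_frequency(self, protocol):
        assert modulation_frequency(protocol) == pytest.approx(0.020)
        fast = CycleSpec(0.25, 0.25, 0.25, 0.25)
        assert modulation_frequency(fast) == pytest.approx(1.0)
        assert modulation_frequency(protocol.scaled(2.0)) == pytest.approx(0.010)

    def test_envelope_conventions(self, protocol):
        assert switch_envelope(0.0, protocol) == "cycle1_on"
        assert switch_envelope(protocol.T1, protocol) == "cycle2_on"
        assert switch_envelope(20.0, protocol) == "off"
        # measure of the on-supports over one period
        t = np.arange(0, protocol.T, 0.01)
        on = np.isin(switch_envelope(t, protocol), ["cycle1_on", "cycle2_on"])
        assert on.mean() * protocol.T == pytest.approx(30.0, abs=0.02)
        # the two on-supports are disjoint
        lab = switch_envelope(t, protocol)
        assert not np.any((lab == "cycle1_on") & (lab == "cycle2_on"))


class TestSimulateNumber:
    def test_continuity_across_phase_boundaries(self, protocol, kinetics):
        tr = simulate_number(protocol, kinetics, 3, 0.05)
        # largest jump bounded by the fastest possible slope * dt
        max_rate = sum(w / t for w, t in zip(kinetics.weights_c, kinetics.tau_c))
        assert np.max(np.abs(np.diff(tr.values))) <= 2 * max_rate * 0.05

    def test_initial_collection_rate(self, protocol, kinetics):
        tr = simulate_number(protocol, kinetics, 1, 0.001)
        slope = (tr.values[1] - tr.values[0]) / 0.001
        analytic = kinetics.dn1 * sum(
            w / t for w, t in zip(kinetics.weights_c, kinetics.tau_c))
        assert slope == pytest.approx(analytic, rel=1e-3)

    def test_relaxation_to_phase_steady_state(self, kinetics):
        # on-phase much longer than 5*max(tau): approaches dn1 to <1%
        slow = CycleSpec(150.0, 150.0, 150.0, 150.0)
        tr = simulate_number(slow, kinetics, 1, 0.3)
        i_end = int(150.0 / 0.3)
        assert tr.values[i_end] == pytest.approx(kinetics.dn1, rel=0.01)

    def test_second_cycle_scale(self, full_release, kinetics):
        # dn2 = 0.3*dn1 with full release between cycles: slope ratio = 0.3
        tr = simulate_number(full_release, kinetics, 1, 0.1)
        i2 = round(full_release.T1 / 0.1)
        s1 = tr.values[1] - tr.values[0]
        s2 = tr.values[i2 + 1] - tr.values[i2]
        assert s2 / s1 == pytest.approx(0.3, rel=1e-6)

    def test_coarse_dt_rejected(self, protocol, kinetics):
        with pytest.raises(ValueError, match="coarse"):
            simulate_number(protocol, kinetics, 1, 1.0)

    def test_time_rescaling_invariance(self, protocol, kinetics):
        a = simulate_number(protocol, kinetics, 2, 0.1)
        b = simulate_number(protocol.scaled(2.0), kinetics.rescaled_time(2.0),
                            2, 0.2)
        np.testing.assert_allclose(a.values, b.values, atol=1e-14)


class TestAmplitudeAndCSS:
    def test_constant_trace_amplitude_zero(self, protocol):
        from depspec.dualcycle import Trace
        t = np.arange(0, 2 * protocol.T + 0.05, 0.1)
        tr = Trace(t, np.full_like(t, 3.0), protocol)
        assert cycle_amplitude(tr, 0, 1) == 0.0

    def test_full_relaxation_amplitude_reaches_transition(self, kinetics):
        slow = CycleSpec(200.0, 200.0, 200.0, 200.0)
        tr = simulate_number(slow, kinetics, 2, 0.3, ic=css_state(slow, kinetics))
        assert cycle_amplitude(tr, 0, 1) == pytest.approx(kinetics.dn1, rel=0.01)
        assert cycle_amplitude(tr, 0, 2) == pytest.approx(kinetics.dn2, rel=0.01)

    def test_amplitude_monotone_in_modulation_frequency(self, protocol, kinetics):
        amps = []
        for f_m in [0.002, 0.01, 0.02, 0.1, 0.5]:
            spec = protocol.scaled(1.0 / (f_m * protocol.T))
            tr = simulate_number(spec, kinetics, 1,
                                 min(0.3, spec.T / 400),
                                 ic=css_state(spec, kinetics))
            amps.append(cycle_amplitude(tr, 0, 1))
        assert all(a >= b - 1e-9 for a, b in zip(amps, amps[1:]))

    def test_incomplete_cycle_rejected(self, protocol, kinetics):
        tr = simulate_number(protocol, kinetics, 1, 0.1)
        with pytest.raises(ValueError):
            cycle_amplitude(tr, 1, 2)

    def test_css_fixed_point_detected_immediately(self, protocol, kinetics):
        x0 = css_state(protocol, kinetics)
        tr = simulate_number(protocol, kinetics, 3, 0.1, ic=x0)
        assert detect_css(tr, protocol) == 0
        # fixed point: boundary values identical across cycles
        per = round(protocol.T / 0.1)
        assert tr.values[0] == pytest.approx(tr.values[per], abs=1e-12)

    def test_uniform_start_has_transient(self, protocol, kinetics):
        tr = simulate_number(protocol, kinetics, 6, 0.1)
        assert detect_css(tr, protocol) >= 1

    def test_nonconvergent_trace_flagged(self, protocol, kinetics):
        tr = simulate_number(protocol, kinetics, 2, 0.1)
        with pytest.raises(ConvergenceError):
            detect_css(tr, protocol, tol=1e-15)


class TestBandwidth:
    def test_subsecond_kinetics_bandwidth_order_1hz(self, protocol):
        kin = dataclasses.replace(default_kinetics(),
                                  tau_c=(0.3, 2.0), tau_r=(0.3, 2.0))
        b = am_bandwidth(kin, protocol)
        assert 0.5 < b < 15.0

    def test_halving_taus_doubles_bandwidth(self, protocol):
        kin = dataclasses.replace(default_kinetics(),
                                  tau_c=(0.3, 2.0), tau_r=(0.3, 2.0))
        b1 = am_bandwidth(kin, protocol)
        b2 = am_bandwidth(kin.rescaled_time(0.5), protocol)
        assert b2 / b1 == pytest.approx(2.0, rel=5e-3)

    def test_stricter_cutoff_shrinks_bandwidth(self, protocol):
        kin = dataclasses.replace(default_kinetics(),
                                  tau_c=(0.3, 2.0), tau_r=(0.3, 2.0))
        assert am_bandwidth(kin, protocol, cutoff=0.9) < \
            am_bandwidth(kin, protocol, cutoff=0.1)


class TestFluorescence:
    def test_intercept_gradient_and_saturation(self):
        fmap = FluorescenceMap(k_f=100.0, k_fc=50.0, saturation=500.0)
        assert fmap(0.0) == 50.0
        n = 1e-4
        assert (fmap(n) - 50.0) / n == pytest.approx(100.0, rel=1e-6)
        assert fmap(1e9) == pytest.approx(500.0, rel=1e-6)
        assert np.all(np.diff(fmap(np.linspace(0, 100, 500))) >= 0)

    def test_applies_to_trace(self, protocol, kinetics):
        tr = simulate_number(protocol, kinetics, 1, 0.1)
        out = fluorescence_from_number(tr, FluorescenceMap(10.0, 5.0, 1e6))
        assert out.values[0] == pytest.approx(5.0)
        assert len(out) == len(tr)


class TestForceScale:
    def test_zero_cm_zero_force(self):
        assert dep_force_scale(1e-7, 78.0, 0.0, 1e15) == 0.0

    def test_radius_cubed_law(self):
        f1 = dep_force_scale(1e-7, 78.0, 0.5, 1e15)
        f2 = dep_force_scale(2e-7, 78.0, 0.5, 1e15)
        assert f2 / f1 == pytest.approx(8.0)

    def test_force_ratio_is_cm_ratio(self):
        f1 = dep_force_scale(1e-7, 78.0, 0.7, 1e15)
        f2 = dep_force_scale(1e-7, 78.0, 0.21, 1e15)
        assert f2 / f1 == pytest.approx(0.3)


class TestDriftDiffusionOracle:
    def test_zero_force_uniform_profile_static(self):
        diff = DiffusionSpec(1.0, 0.0, 1.0, 1.0, capture_height=0.2, n_grid=100)
        tr, (_, c) = simulate_mde_1d(diff, ALWAYS_ON, 0.5, dt=1e-3)
        assert np.allclose(tr.values, 0.2, atol=1e-10)
        assert c.std() < 1e-10

    def test_number_conservation(self):
        diff = DiffusionSpec(1.0, 4.0, 1.0, 1.0, capture_height=0.2, n_grid=150)
        spec = CycleSpec(0.2, 0.1, 0.2, 0.1)
        _, (_, c) = simulate_mde_1d(diff, spec, 1.2, dt=5e-4)
        assert c.sum() * (1.0 / 150) == pytest.approx(1.0, rel=1e-6)

    def test_long_time_matches_boltzmann_closed_form(self):
        diff = DiffusionSpec(1.0, 4.0, 1.0, 1.0, capture_height=0.2, n_grid=200)
        tr, (y, c) = simulate_mde_1d(diff, ALWAYS_ON, 3.0, dt=1e-3)
        assert tr.values[-1] == pytest.approx(boltzmann_steady_number(diff), rel=0.01)
        # profile itself is exponential exp(-F y / kT)
        fit = np.polyfit(y, np.log(c), 1)
        assert fit[0] == pytest.approx(-4.0, rel=0.01)

    def test_boltzmann_limits(self):
        diff0 = DiffusionSpec(1.0, 0.0, 1.0, 1.0, capture_height=0.3)
        assert boltzmann_steady_number(diff0) == pytest.approx(0.3)
        strong = DiffusionSpec(1.0, 500.0, 1.0, 1.0, capture_height=0.3)
        assert boltzmann_steady_number(strong) == pytest.approx(1.0, rel=1e-9)

    def test_collection_transient_fits_two_mode_series(self):
        # justifies the exponential-series KineticModel
        diff = DiffusionSpec(1.0, 4.0, 1.0, 1.0, capture_height=0.2, n_grid=150)
        tr, _ = simulate_mde_1d(diff, ALWAYS_ON, 2.0, dt=1e-3)
        t, n = tr.times, tr.values

        def two_mode(t, dn, a, tau1, tau2):
            return n[0] + dn * (a * (1 - np.exp(-t / tau1))
                                + (1 - a) * (1 - np.exp(-t / tau2)))

        popt, _ = curve_fit(two_mode, t, n, p0=[0.4, 0.7, 0.05, 0.5],
                            maxfev=20000)
        resid = n - two_mode(t, *popt)
        r2 = 1 - (resid**2).sum() / ((n - n.mean())**2).sum()
        assert r2 > 0.99
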