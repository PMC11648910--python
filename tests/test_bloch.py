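"""Bloch-McConnell propagation: closed forms, ODE oracle, dip structure."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from foldcest import synthetic
from foldcest.bloch import (
    CESTExperiment,
    SpinSystem,
    evolution_matrix,
    ppm_to_hz,
    propagate,
    simulate_profile,
)
from foldcest.exchange import KineticNetwork, make_ff_model


def _experiment(b1=52.1, t_ex=0.4, offsets=None, nucleus="15N", carrier=119.0,
                **kw):
    if offsets is None:
        half = ppm_to_hz(14.0, nucleus, 700.0)
        offsets = np.linspace(-half, half, 61)
    return CESTExperiment(b1=b1, t_ex=t_ex, spectrometer_1h_freq=700.0,
                          carrier=carrier, offsets=offsets, nucleus=nucleus,
                          **kw)


class TestPpmToHz:
    @pytest.mark.parametrize("ppm,nucleus,freq,expected", [
        (0.0, "13C", 500.0, 0.0),
        (1.0, "1H", 700.0, 700.0),
        (1.0, "15N", 700.0, 70.957),
    ])
    def test_conversions(self, ppm, nucleus, freq, expected):
        assert ppm_to_hz(ppm, nucleus, freq) == pytest.approx(expected,
                                                              rel=1e-4)

    def test_unknown_nucleus(self):
        with pytest.raises(ValueError, match="nucleus"):
            ppm_to_hz(1.0, "31P", 700.0)


class TestEvolutionMatrix:
    def test_dimension_is_3n_plus_1(self, scenario_a_network):
        spin = SpinSystem("s", "15N", 119.0,
                          {"I1": 1.0, "I2": 2.0, "U": -3.0})
        A = evolution_matrix(spin, scenario_a_network, 50.0, 100.0,
                             carrier=119.0)
        assert A.shape == (13, 13)
        assert np.all(A[-1] == 0.0)  # augmented row

    def test_no_rf_no_exchange_decouples_z(self):
        net = KineticNetwork(("F",), np.array([1.0]), {})
        spin = SpinSystem("s", "15N", 119.0, {}, r1=2.0, r2=20.0)
        A = evolution_matrix(spin, net, 0.0, 37.0, carrier=119.0)
        # z row/column touch only z and the equilibrium-return term
        assert A[2, 0] == A[2, 1] == A[0, 2] == A[1, 2] == 0.0
        assert A[2, 2] == pytest.approx(-2.0)
        assert A[2, 3] == pytest.approx(2.0)

    def test_equilibrium_stationary_without_rf(self, scenario_a_network):
        spin = SpinSystem("s", "15N", 119.0,
                          {"I1": 1.4, "I2": 2.3, "U": -3.1})
        A = evolution_matrix(spin, scenario_a_network, 0.0, 250.0,
                             carrier=119.0)
        v = np.zeros(13)
        v[2:12:3] = scenario_a_network.populations
        v[-1] = 1.0
        for t_ex in (0.05, 0.4, 2.0):
            out = propagate(A, v, t_ex)
            assert np.abs(out - v).max() < 1e-10

    def test_missing_delta_omega_is_configuration_error(self, scenario_a_network):
        spin = SpinSystem("s", "15N", 119.0, {"I2": 2.0})
        with pytest.raises(ValueError, match="delta_omega"):
            evolution_matrix(spin, scenario_a_network, 50.0, 0.0, carrier=119.0)


class TestPropagate:
    def test_zero_time_identity(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(7, 7))
        v = rng.normal(size=7)
        np.testing.assert_array_equal(propagate(A, v, 0.0), v)

    def test_on_resonance_nutation_closed_form(self):
        """Relaxation-free on-resonance spin nutates as cos(2 pi B1 t)."""
        net = KineticNetwork(("F",), np.array([1.0]), {})
        spin = SpinSystem("s", "15N", 119.0, {}, r1=1e-12, r2=1e-12)
        A = evolution_matrix(spin, net, 50.0, 0.0, carrier=119.0)
        v = np.array([0.0, 0.0, 1.0, 1.0])
        for t_ex in (0.005, 0.013, 0.02):
            out = propagate(A, v, t_ex)
            assert out[2] == pytest.approx(np.cos(2 * np.pi * 50.0 * t_ex),
                                           abs=1e-9)

    def test_matches_ode_integration_oracle(self):
        """Matrix exponential vs adaptive ODE integration on >= 20 instances."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            pops = rng.dirichlet([20, 1, 1, 1])
            net = make_ff_model("four_state", {
                "kex_FI1": rng.uniform(10, 3000),
                "kex_FI2": rng.uniform(10, 3000),
                "kex_I1I2": rng.uniform(10, 3000),
                "kex_I1U": rng.uniform(10, 12000),
                "p_I1": pops[1], "p_I2": pops[2], "p_U": pops[3]})
            spin = SpinSystem("s", "15N", 119.0 + rng.uniform(-2, 2),
                              {s: rng.uniform(-6, 6) for s in ("I1", "I2", "U")},
                              r1=rng.uniform(1, 4), r2=rng.uniform(5, 50))
            A = evolution_matrix(spin, net, rng.uniform(10, 200),
                                 rng.uniform(-800, 800), carrier=119.0)
            v = np.zeros(13)
            v[2:12:3] = net.populations
            v[-1] = 1.0
            ref = solve_ivp(lambda t, y: A @ y, (0.0, 0.4), v,
                            rtol=1e-11, atol=1e-13).y[:, -1]
            assert np.abs(propagate(A, v, 0.4) - ref).max() < 1e-8


class TestSimulateProfile:
    def test_off_resonance_pure_r1_decay(self):
        """Far off resonance the profile is just longitudinal relaxation."""
        net = make_ff_model("two_state", {"kex_FI2": 0.0, "p_I2": 1e-9})
        exp = _experiment(b1=10.0, offsets=np.array([5000.0, 8000.0]))
        spin = SpinSystem("s", "15N", 119.0, {"I2": 0.5}, r1=2.0, r2=20.0)
        prof = simulate_profile(spin, net, exp)
        np.testing.assert_allclose(prof.intensities,
                                   np.exp(-2.0 * 0.4), rtol=0.01)

    def test_slow_exchange_dips_at_both_resonances(self, two_state_net):
        """kex << 2 pi dW_hz: local minima at the F and minor shifts."""
        net = make_ff_model("two_state", {"kex_FI2": 30.0, "p_I2": 0.05},
                            temperature=293.15)
        spin = SpinSystem("s", "15N", 119.0, {"I2": 4.0}, r1=2.0, r2=20.0)
        exp = _experiment(b1=20.0)
        prof = simulate_profile(spin, net, exp)
        step = exp.offsets[1] - exp.offsets[0]
        minima = [exp.offsets[i] for i in range(1, 60)
                  if prof.intensities[i] < prof.intensities[i - 1]
                  and prof.intensities[i] < prof.intensities[i + 1]]
        assert any(abs(m - 0.0) <= step for m in minima)  # F resonance
        assert any(abs(m - ppm_to_hz(4.0, "15N", 700.0)) <= step
                   for m in minima)  # minor resonance

    def test_minor_dip_visible_at_i2_resonance(self, scenario_a_network):
        """A large-dW spin shows a resolved I2 dip at moderate B1.

        The I2 line is exchange-broadened by k_I2->F ~ 400 s^-1 and rides
        on the sloping tail of the main dip, so the local minimum sits
        slightly inside the exact I2 resonance; it must still be a genuine
        local minimum at least 0.5% deeper than the neighboring baseline.
        """
        spin = SpinSystem("s56", "15N", 119.0,
                          {"I1": 1.0, "I2": 7.0, "U": -2.0},
                          r1=2.0, r2=10.0)
        exp = _experiment(b1=52.1)
        prof = simulate_profile(spin, scenario_a_network, exp)
        i2_hz = ppm_to_hz(7.0, "15N", 700.0)
        i = int(np.argmin(np.abs(exp.offsets - i2_hz)))
        window = prof.intensities[i - 3:i + 3]
        j = i - 3 + int(np.argmin(window))
        assert prof.intensities[j] < prof.intensities[j - 1]
        assert prof.intensities[j] < prof.intensities[j + 1]
        # neighboring baseline: the ridge between the main and I2 dips
        inward_ridge = prof.intensities[i - 8:j].max()
        assert prof.intensities[j] < inward_ridge - 0.005
        assert prof.intensities[j] < prof.intensities[i + 5] - 0.005

    def test_intensity_bounded_by_total_magnetization(self, scenario_a_network):
        spin = SpinSystem("s", "15N", 119.0,
                          {"I1": -2.0, "I2": 3.0, "U": 5.0})
        for b1 in (26.0, 208.3):
            prof = simulate_profile(spin, scenario_a_network, _experiment(b1=b1))
            assert np.abs(prof.intensities).max() <= \
                1.0 / scenario_a_network.populations[0] + 1e-12

    def test_mirror_symmetry_under_sign_flip(self, scenario_a_network):
        """Negating every dW and reflecting offsets about the F resonance
        reproduces the profile."""
        exp = _experiment(b1=52.1)  # grid symmetric about carrier = omega_F
        spin = SpinSystem("s", "15N", 119.0,
                          {"I1": 1.3, "I2": -2.7, "U": 4.1})
        flipped = SpinSystem("s", "15N", 119.0,
                             {k: -v for k, v in spin.delta_omega.items()})
        a = simulate_profile(spin, scenario_a_network, exp).intensities
        b = simulate_profile(flipped, scenario_a_network, exp).intensities
        np.testing.assert_allclose(a, b[::-1], atol=1e-10)

    def test_fast_exchange_single_population_weighted_dip(self):
        net = make_ff_model("two_state", {"kex_FI2": 1e5, "p_I2": 0.3})
        spin = SpinSystem("s", "15N", 119.0, {"I2": 2.0}, r1=2.0, r2=20.0)
        exp = _experiment(b1=26.0)
        prof = simulate_profile(spin, net, exp)
        argmin = exp.offsets[np.argmin(prof.intensities)]
        expected = ppm_to_hz(0.3 * 2.0, "15N", 700.0)
        step = exp.offsets[1] - exp.offsets[0]
        assert abs(argmin - expected) <= step

    def test_four_state_reduces_to_two_state(self):
        """Vanishing I1 and U populations recover the F<->I2 profile."""
        exp = _experiment(b1=52.1)
        spin2 = SpinSystem("s", "15N", 119.0, {"I2": 3.0})
        net2 = make_ff_model("two_state", {"kex_FI2": 406.0, "p_I2": 0.0083})
        ref = simulate_profile(spin2, net2, exp).intensities
        spin4 = SpinSystem("s", "15N", 119.0, {"I1": 1.0, "I2": 3.0, "U": -4.0})
        prev = np.inf
        for eps in (1e-3, 1e-4, 1e-5):
            net4 = make_ff_model("four_state", {
                "kex_FI1": 784.0, "kex_FI2": 406.0, "kex_I1I2": 1600.0,
                "kex_I1U": 11000.0, "p_I1": eps, "p_I2": 0.0083, "p_U": eps})
            diff = np.abs(simulate_profile(spin4, net4, exp).intensities
                          - ref).max()
            assert diff < prev
            prev = diff
        assert prev < 1e-3

    def test_b1_inhomogeneity_averaging(self, two_state_net):
        spin = SpinSystem("s", "15N", 119.0, {"I2": 3.0})
        ideal = simulate_profile(spin, two_state_net, _experiment())
        smeared = simulate_profile(spin, two_state_net,
                                   _experiment(b1_inhomogeneity=0.1))
        assert not np.allclose(ideal.intensities, smeared.intensities)
        assert np.abs(smeared.intensities).max() <= 1.0 / 0.979 + 1e-9

    def test_negative_t_ex_rejected(self):
        with pytest.raises(ValueError, match="T_EX"):
            _experiment(t_ex=-0.1)
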