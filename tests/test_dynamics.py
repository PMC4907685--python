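"""State equations, sigmoid, noise synthesis and simulation oracles."""

import numpy as np
import pytest
import scipy.signal
from hypothesis import given, strategies as st

from m1dcm.config import default_params
from m1dcm.dynamics import (
    NeuralState,
    fixed_point,
    generate_endogenous_noise,
    ode_rhs,
    sigmoid_firing,
    sigmoid_firing_derivative,
    simulate_time_series,
)
from m1dcm.errors import InstabilityError, ParameterError
from m1dcm.params import NoiseSpec

from conftest import make_single_population


class TestSigmoid:
    def test_zero_centred(self):
        assert sigmoid_firing(0.0) == 0.0

    def test_known_value_at_default_slope(self):
        # 1/(1+e^-1) - 1/2 for v=1.5 at slope 2/3
        assert sigmoid_firing(1.5, slope=2.0 / 3.0) == pytest.approx(
            0.23105857863000487, abs=1e-12
        )

    def test_limits(self):
        assert sigmoid_firing(1e3) == pytest.approx(0.5, abs=1e-12)
        assert sigmoid_firing(-1e3) == pytest.approx(-0.5, abs=1e-12)

    @given(st.floats(-50, 50), st.floats(0.05, 5.0))
    def test_odd_function(self, v, slope):
        assert sigmoid_firing(-v, slope) == pytest.approx(
            -sigmoid_firing(v, slope), abs=1e-12
        )

    @given(st.floats(-30, 30), st.floats(0.05, 1.0))
    def test_strictly_increasing_and_bounded(self, v, slope):
        s = sigmoid_firing(v, slope)
        assert -0.5 < s < 0.5
        assert sigmoid_firing_derivative(v, slope) > 0

    def test_rejects_nonpositive_slope(self):
        with pytest.raises(ParameterError):
            sigmoid_firing(1.0, slope=0.0)


class TestOdeRhs:
    def test_origin_is_equilibrium_of_noise_free_system(self, winning_model):
        params = default_params(winning_model).synaptic
        state = NeuralState(np.zeros(4), np.zeros(4))
        d = ode_rhs(state, params, winning_model)
        assert np.allclose(d.xv, 0) and np.allclose(d.xI, 0)

    def test_single_population_steady_state(self):
        model, fp = make_single_population(kappa=0.25)
        u0 = 0.4
        eq = fixed_point(model, fp.synaptic, mean_input=np.array([u0]))
        assert eq.xv[0] == pytest.approx(u0 / 0.25, rel=1e-10)
        d = ode_rhs(eq, fp.synaptic, model, exogenous=np.array([u0]))
        assert np.max(np.abs(np.r_[d.xv, d.xI])) < 1e-10

    @pytest.mark.parametrize("kappa", [0.1, 0.25, 0.5])
    def test_impulse_response_peaks_at_inverse_kappa(self, kappa):
        # response to a unit input impulse is kappa*t*exp(-kappa*t):
        # peak value 1/e at t = 1/kappa, for any kappa
        model, fp = make_single_population(kappa=kappa)
        dt = 0.01
        n = int(50 / kappa / dt)
        x = np.array([0.0, kappa])  # state just after the impulse
        xs = [x[0]]
        for _ in range(n):
            # RK4 on the noise-free linear system
            def f(s):
                return np.array(
                    [s[1], -2 * kappa * s[1] - kappa**2 * s[0]]
                )
            k1 = f(x); k2 = f(x + dt / 2 * k1)
            k3 = f(x + dt / 2 * k2); k4 = f(x + dt * k3)
            x = x + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            xs.append(x[0])
        xs = np.array(xs)
        t_peak = np.argmax(xs) * dt
        assert t_peak == pytest.approx(1.0 / kappa, rel=1e-2)
        assert xs.max() == pytest.approx(np.exp(-1.0), rel=1e-4)


class TestFixedPoint:
    def test_zero_input_returns_origin(self, winning_model):
        params = default_params(winning_model).synaptic
        eq = fixed_point(winning_model, params)
        assert np.all(eq.xv == 0) and np.all(eq.xI == 0)

    def test_residual_below_contract(self, winning_model):
        params = default_params(winning_model).synaptic
        u = np.array([1e-3, 2e-3, -1e-3, 0.0])
        eq = fixed_point(winning_model, params, mean_input=u)
        d = ode_rhs(eq, params, winning_model, exogenous=u)
        assert np.max(np.abs(np.r_[d.xv, d.xI])) < 1e-10

    def test_noise_free_system_stays_at_fixed_point(self, winning_model):
        params = default_params(winning_model).synaptic
        silent = NoiseSpec(white_amplitude=0.0, pink_amplitude=0.0,
                           input_gains=np.ones(3), seed=0)
        sim = simulate_time_series(winning_model, params, silent,
                                   duration=10.0, dt=1.0)
        assert np.max(np.abs(sim.voltages)) < 1e-6


class TestNoiseGenerator:
    def test_same_seed_reproduces_series(self):
        spec = NoiseSpec(seed=7, input_gains=np.ones(3))
        a = generate_endogenous_noise(4096, 1.0, spec)
        b = generate_endogenous_noise(4096, 1.0, spec)
        assert np.array_equal(a, b)

    def test_white_spectrum_flat_within_three_se(self):
        spec = NoiseSpec(white_amplitude=2.0, pink_amplitude=0.0,
                         input_gains=np.ones(1), seed=1, cutoff_hz=None)
        series = generate_endogenous_noise(2048, 1.0, spec, n_realisations=250)
        f, pxx = scipy.signal.periodogram(series[:, 0, :], fs=1000.0, axis=-1)
        sel = (f >= 5) & (f <= 45)
        mean = pxx[:, sel].mean(axis=0)
        se = pxx[:, sel].std(axis=0, ddof=1) / np.sqrt(series.shape[0])
        assert np.all(np.abs(mean - 2.0) < 3 * se)

    def test_pink_spectrum_log_log_slope(self):
        spec = NoiseSpec(white_amplitude=0.0, pink_amplitude=1.0,
                         input_gains=np.ones(1), seed=5, cutoff_hz=None)
        series = generate_endogenous_noise(4096, 1.0, spec, n_realisations=300)
        f, pxx = scipy.signal.periodogram(series[:, 0, :], fs=1000.0, axis=-1)
        sel = (f >= 5) & (f <= 45)
        slope = np.polyfit(np.log(f[sel]), np.log(pxx[:, sel].mean(axis=0)), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.05)

    def test_rejects_bad_arguments(self):
        spec = NoiseSpec()
        with pytest.raises(ParameterError):
            generate_endogenous_noise(1, 1.0, spec)
        with pytest.raises(ParameterError):
            generate_endogenous_noise(100, 0.0, spec)


class TestSimulation:
    def test_step_halving_changes_traces_below_one_percent_rms(
        self, winning_model
    ):
        params = default_params(winning_model).synaptic
        noise = default_params(winning_model).noise
        noise.seed = 11
        # one physical forcing realisation, sampled at the finer half-step
        forcing = generate_endogenous_noise(4 * 4000 + 1, 0.25, noise)
        a = simulate_time_series(winning_model, params, noise, duration=4.0,
                                 dt=1.0, layer_forcing=forcing[:, ::2])
        b = simulate_time_series(winning_model, params, noise, duration=4.0,
                                 dt=0.5, layer_forcing=forcing)
        coarse = a.voltages
        fine = b.voltages[:, ::2]
        rms = np.sqrt(np.mean((coarse - fine) ** 2))
        scale = np.sqrt(np.mean(fine**2))
        assert rms / scale < 0.01

    def test_default_circuit_bounded_over_long_run(self, winning_model):
        params = default_params(winning_model)
        params.noise.seed = 1
        sim = simulate_time_series(winning_model, params.synaptic, params.noise,
                                   duration=60.0, dt=1.0)
        assert np.isfinite(sim.voltages).all()
        assert np.max(np.abs(sim.voltages)) < 1.0  # mV, small-signal regime

    def test_divergence_raises_instability_error(self, winning_model):
        params = default_params(winning_model)
        params.synaptic.gamma = np.full(14, 1.5)  # far beyond critical gain
        params.noise.seed = 0
        with pytest.raises(InstabilityError):
            simulate_time_series(winning_model, params.synaptic, params.noise,
                                 duration=20.0, dt=1.0, bound=1.0)

    def test_single_population_spectrum_matches_alpha_kernel(self):
        # |kappa/(i*omega+kappa)^2|^2 * S_in against a long periodogram
        kappa = 0.25
        model, fp = make_single_population(kappa=kappa)
        noise = NoiseSpec(white_amplitude=1e-6, pink_amplitude=0.0,
                          input_gains=np.ones(1), seed=21)
        sim = simulate_time_series(model, fp.synaptic, noise, duration=8.0,
                                   dt=1.0, n_realisations=150)
        f, pxx = scipy.signal.welch(sim.voltages[:, 0, :], fs=1000.0,
                                    nperseg=2000, axis=-1)
        sel = (f >= 5) & (f <= 45)
        omega = 2 * np.pi * f[sel] / 1000.0
        theory = kappa**2 / (omega**2 + kappa**2) ** 2 * 1e-6
        mean = pxx[:, sel].mean(axis=0)
        se = pxx[:, sel].std(axis=0, ddof=1) / np.sqrt(pxx.shape[0])
        assert np.all(np.abs(mean - theory) < 3 * se + 0.02 * theory)
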