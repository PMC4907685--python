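"""Linearised spectral prediction: Jacobian, transfer functions, psd."""

import numpy as np
import pytest

from m1dcm.config import default_frequency_grid, default_params
from m1dcm.dynamics import NeuralState, ode_rhs
from m1dcm.errors import BandError, DesignError, StabilityError
from m1dcm.model_space import default_design, winning_m1_model
from m1dcm.params import ConditionBeta
from m1dcm.spectral import (
    condition_sweep,
    predict_psd,
    system_jacobian,
    transfer_functions,
)

from conftest import make_single_population


class TestJacobian:
    def test_decoupled_populations_have_block_structure(self, winning_model):
        params = default_params(winning_model).synaptic
        params.base_strength = np.zeros(14)
        jac = system_jacobian(winning_model, params)
        n = 4
        for i, k in enumerate(params.kappa):
            assert jac.J[i, n + i] == 1.0
            assert jac.J[n + i, i] == pytest.approx(-k**2)
            assert jac.J[n + i, n + i] == pytest.approx(-2 * k)
        off = jac.J.copy()
        for i in range(n):
            off[i, n + i] = off[n + i, i] = off[n + i, n + i] = 0.0
        assert np.all(off == 0)

    def test_matches_finite_difference_of_rhs(self, winning_model):
        params = default_params(winning_model).synaptic
        jac = system_jacobian(winning_model, params)
        x0 = np.zeros(8)
        h = 1e-6
        J_fd = np.empty((8, 8))
        for j in range(8):
            xp, xm = x0.copy(), x0.copy()
            xp[j] += h
            xm[j] -= h
            dp = ode_rhs(NeuralState(xp[:4], xp[4:]), params, winning_model)
            dm = ode_rhs(NeuralState(xm[:4], xm[4:]), params, winning_model)
            J_fd[:, j] = (dp.stacked() - dm.stacked()) / (2 * h)
        assert np.max(np.abs(jac.J - J_fd)) / np.max(np.abs(J_fd)) < 1e-6

    def test_zero_delays_give_identity_correction(self, winning_model):
        params = default_params(winning_model).synaptic
        params.delays = np.zeros_like(params.delays)
        jac = system_jacobian(winning_model, params)
        assert np.array_equal(jac.Q, jac.J)

    def test_delay_correction_changes_q(self, winning_model):
        params = default_params(winning_model).synaptic
        jac = system_jacobian(winning_model, params)
        assert not np.allclose(jac.Q, jac.J)
        assert jac.is_stable


class TestTransferFunctions:
    def test_single_population_lorentzian_squared(self):
        kappa = 0.25
        model, fp = make_single_population(kappa=kappa)
        jac = system_jacobian(model, fp.synaptic)
        freqs = default_frequency_grid()
        H = transfer_functions(jac, model, fp.synaptic, fp.observation, freqs)
        omega = 2 * np.pi * freqs / 1000.0
        theory = kappa**2 / (omega**2 + kappa**2) ** 2
        assert np.allclose(np.abs(H[:, 0]) ** 2, theory, rtol=1e-10)

    def test_realness_symmetry(self, winning_model, winning_params):
        jac = system_jacobian(winning_model, winning_params.synaptic)
        freqs = np.array([10.0, 20.0, 35.0])
        Hp = transfer_functions(jac, winning_model, winning_params.synaptic,
                                winning_params.observation, freqs)
        Hm = transfer_functions(jac, winning_model, winning_params.synaptic,
                                winning_params.observation, -freqs)
        assert np.allclose(Hm, np.conj(Hp), atol=1e-12)

    def test_gain_scales_power_quadratically(self, winning_model, winning_params):
        import copy

        jac = system_jacobian(winning_model, winning_params.synaptic)
        freqs = default_frequency_grid()
        H1 = transfer_functions(jac, winning_model, winning_params.synaptic,
                                winning_params.observation, freqs)
        obs2 = copy.deepcopy(winning_params.observation)
        obs2.gain *= 3.0
        H2 = transfer_functions(jac, winning_model, winning_params.synaptic,
                                obs2, freqs)
        assert np.allclose(np.abs(H2) ** 2, 9.0 * np.abs(H1) ** 2, rtol=1e-12)

    def test_unstable_system_raises_with_eigenvalues(self, winning_model):
        params = default_params(winning_model).synaptic
        params.gamma = np.full(14, 1.0)
        jac = system_jacobian(winning_model, params)
        with pytest.raises(StabilityError, match="eigenvalue"):
            transfer_functions(jac, winning_model, params,
                               default_params(winning_model).observation,
                               default_frequency_grid())


class TestPredictPsd:
    def test_rest_equals_unmodulated_prediction(self, winning_model, winning_params):
        import copy

        p = copy.deepcopy(winning_params)
        p.condition_betas["grip"] = ConditionBeta(np.zeros(14), np.zeros(3))
        rest = predict_psd(winning_model, p, condition="rest")
        grip_zero_beta = predict_psd(winning_model, p, condition="grip")
        assert np.array_equal(rest.psd, grip_zero_beta.psd)

    def test_psd_real_nonnegative_increasing_grid(self, winning_model, winning_params):
        pred = predict_psd(winning_model, winning_params)
        assert np.isrealobj(pred.psd)
        assert np.all(pred.psd >= 0)
        assert np.all(np.diff(pred.freqs) > 0)

    def test_out_of_band_frequencies_rejected(self, winning_model, winning_params):
        with pytest.raises(BandError):
            predict_psd(winning_model, winning_params,
                        freqs=np.array([2.0, 10.0]))
        with pytest.raises(BandError):
            predict_psd(winning_model, winning_params,
                        freqs=np.array([10.0, 60.0]))

    def test_gamma_zero_recovers_prior_spectrum_exactly(
        self, winning_model, winning_params, forward_op
    ):
        # the identifiable parameterisation: fixed baselines, gamma = 0
        pred = predict_psd(winning_model, winning_params)
        via_operator = forward_op.psd(np.zeros(forward_op.layout.size))
        assert np.allclose(pred.psd, via_operator[0], rtol=1e-12)

    def test_rest_peak_in_beta_band(self, winning_model, winning_params, grid):
        pred = predict_psd(winning_model, winning_params)
        peak = grid[np.argmax(pred.psd)]
        assert 15.0 <= peak <= 30.0

    def test_first_order_delay_perturbation_grows_with_frequency(
        self, winning_model
    ):
        import copy

        p0 = default_params(winning_model)
        p1 = copy.deepcopy(p0)
        p0.synaptic.delays = np.zeros_like(p0.synaptic.delays)
        a = predict_psd(winning_model, p0, with_channel_noise=False).psd
        b = predict_psd(winning_model, p1, with_channel_noise=False).psd
        rel = np.abs(np.log(b) - np.log(a))
        grid = default_frequency_grid()
        assert rel[grid == 10.0][0] < rel[grid == 45.0][0]


class TestConditionSweep:
    def test_no_modulation_gives_identical_conditions(
        self, winning_model, winning_params
    ):
        design = default_design(winning_model)
        sweep = condition_sweep(winning_model, winning_params, design)
        assert set(sweep) == {"rest", "grip", "post_grip"}
        assert np.array_equal(sweep["rest"].psd, sweep["grip"].psd)
        assert np.array_equal(sweep["rest"].psd, sweep["post_grip"].psd)

    def test_grip_modulators_reduce_beta_power(self, winning_model, grid):
        import copy

        p = copy.deepcopy(default_params(winning_model))
        beta = np.zeros(14)
        for e in [("DP", "SP"), ("SP", "MP"), ("MP", "SP"), ("MP", "MP")]:
            beta[winning_model.connection_index(*e)] = 0.3
        p.condition_betas["grip"] = ConditionBeta(beta, np.zeros(3))
        sweep = condition_sweep(winning_model, p, default_design(winning_model))
        band = (grid >= 15) & (grid <= 30)
        rest_power = np.trapezoid(sweep["rest"].psd[band], grid[band])
        grip_power = np.trapezoid(sweep["grip"].psd[band], grid[band])
        assert grip_power < rest_power

    def test_post_grip_input_increase_raises_beta_power(
        self, winning_model, grid
    ):
        import copy

        p = copy.deepcopy(default_params(winning_model))
        inputs = np.zeros(3)
        inputs[[0, 2]] = 0.3  # Es and Ed
        p.condition_betas["post_grip"] = ConditionBeta(np.zeros(14), inputs)
        sweep = condition_sweep(winning_model, p, default_design(winning_model))
        band = (grid >= 15) & (grid <= 30)
        rest_power = np.trapezoid(sweep["rest"].psd[band], grid[band])
        post_power = np.trapezoid(sweep["post_grip"].psd[band], grid[band])
        assert post_power >= rest_power

    def test_unknown_condition_label_rejected(self, winning_model, winning_params):
        from m1dcm.model_space import ConditionModulationDesign

        with pytest.raises(DesignError):
            design = ConditionModulationDesign(conditions=("rest", "hop"))
            condition_sweep(winning_model, winning_params, design)


class TestLaminarConstraint:
    def test_superficial_population_peaks_above_deep(self, winning_model,
                                                     winning_params, grid):
        pred = predict_psd(winning_model, winning_params,
                           with_population_psd=True)
        sp = grid[np.argmax(pred.population_psd[0])]
        dp = grid[np.argmax(pred.population_psd[2])]
        assert sp > dp
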