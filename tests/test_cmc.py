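"""Microcircuit model: kernels, sigmoid, dynamics and ERP integration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from nvcdcm import cmc
from nvcdcm.errors import IntegrationError, ParameterError, ShapeError


def one_region_setup():
    arch = cmc.CMCArchitecture(1, np.zeros((1, 1), bool), np.zeros((1, 1), bool),
                               np.array([True]))
    design = cmc.ConditionDesign(("base",), np.zeros((1, 0)))
    mod = cmc.ModulationSpec(np.zeros(0, bool), np.zeros(0, bool),
                             np.zeros((1, 4), bool))
    params = cmc.CMCParameters(theta_Af=np.zeros(0), theta_Ab=np.zeros(0),
                               theta_B=np.zeros((0, 0)), theta_C=np.zeros(1))
    return arch, design, mod, params


def two_region_chain():
    """Forward R1 -> R2, no backward edge, input to R1 only."""
    fwd = np.zeros((2, 2), bool)
    fwd[1, 0] = True
    arch = cmc.CMCArchitecture(2, fwd, np.zeros((2, 2), bool),
                               np.array([True, False]))
    design = cmc.ConditionDesign(("base",), np.zeros((1, 0)))
    mod = cmc.ModulationSpec(np.zeros(1, bool), np.zeros(0, bool),
                             np.zeros((2, 4), bool))
    params = cmc.CMCParameters(theta_Af=np.zeros(1), theta_Ab=np.zeros(0),
                               theta_B=np.zeros((0, 0)), theta_C=np.zeros(1))
    return arch, design, mod, params


class TestSynapticKernel:
    def test_vanishes_at_origin_and_for_negative_times(self):
        assert cmc.synaptic_kernel(0.0, 16.0) == 0.0
        assert cmc.synaptic_kernel(-0.5, 16.0) == 0.0

    @pytest.mark.parametrize("kappa", [16.0, 32.0, 128.0, 256.0])
    def test_peak_location_and_height(self, kappa):
        # d/dt (t k e^{-tk}) = 0 at t = 1/k, value e^{-1}; confirm by grid
        t = np.linspace(0, 10.0 / kappa, 20001)
        h = cmc.synaptic_kernel(t, kappa)
        assert t[np.argmax(h)] == pytest.approx(1.0 / kappa, abs=2e-4 / kappa)
        assert h.max() == pytest.approx(np.exp(-1.0), abs=1e-6)

    @pytest.mark.parametrize("kappa", [16.0, 256.0])
    def test_integral_is_inverse_rate(self, kappa):
        val, _ = quad(lambda t: cmc.synaptic_kernel(t, kappa), 0, 50.0 / kappa)
        assert val == pytest.approx(1.0 / kappa, abs=1e-6)

    def test_rejects_nonpositive_rate(self):
        with pytest.raises(ParameterError):
            cmc.synaptic_kernel(0.1, 0.0)


class TestFiringSigmoid:
    def test_zero_at_rest(self):
        assert cmc.firing_sigmoid(0.0) == 0.0

    def test_closed_form_value(self):
        expected = 1.0 / (1.0 + np.exp(-2.0)) - 0.5
        assert cmc.firing_sigmoid(2.0) == pytest.approx(expected, abs=1e-12)
        assert cmc.firing_sigmoid(2.0) == pytest.approx(0.38079708, abs=1e-6)

    @given(st.floats(-30, 30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_odd_symmetry_with_zero_threshold(self, v):
        assert cmc.firing_sigmoid(-v) == pytest.approx(-cmc.firing_sigmoid(v),
                                                       abs=1e-12)


class TestGaussianInput:
    def test_peak_and_dispersion_points(self):
        assert cmc.gaussian_input(0.07, 0.07, 0.016) == 1.0
        for t in (0.07 - 0.016, 0.07 + 0.016):
            assert cmc.gaussian_input(t, 0.07, 0.016) == pytest.approx(
                np.exp(-0.5), abs=1e-12)

    def test_integral_matches_closed_form(self):
        val, _ = quad(lambda t: cmc.gaussian_input(t, 0.07, 0.016), -1, 1)
        assert val == pytest.approx(0.016 * np.sqrt(2 * np.pi), rel=1e-9)

    def test_rejects_nonpositive_dispersion(self):
        with pytest.raises(ParameterError):
            cmc.gaussian_input(0.0, 0.07, 0.0)


class TestDerivatives:
    def test_rest_with_zero_input_is_fixed_point(self):
        arch, design, mod, params = one_region_setup()
        d = cmc.cmc_derivatives(np.zeros((1, 4, 2)), params, arch, u=0.0,
                                design=design, modulation=mod)
        assert np.all(d == 0.0)

    def test_input_enters_spiny_stellates_only(self):
        arch, design, mod, params = one_region_setup()
        d = cmc.cmc_derivatives(np.zeros((1, 4, 2)), params, arch, u=1.0,
                                design=design, modulation=mod)
        accel = d[0, :, 1]
        assert accel[0] != 0.0
        assert np.all(accel[1:] == 0.0)

    def test_forward_edge_targets_ss_and_dp_of_receiving_region(self):
        arch, design, mod, params = two_region_chain()
        state = np.zeros((2, 4, 2))
        state[0, 1, 0] = 0.5  # depolarise sp of the source region
        d = cmc.cmc_derivatives(state, params, arch, u=0.0, design=design,
                                modulation=mod)
        base = cmc.cmc_derivatives(np.zeros((2, 4, 2)), params, arch, u=0.0,
                                   design=design, modulation=mod)
        delta = d[1, :, 1] - base[1, :, 1]
        # hand evaluation: distal sp firing feeds ss and dp of the target
        sig = cmc.firing_sigmoid(0.5)
        expect_ss = params.kappa_scale[0] ** 2 * params.extrinsic_scale[0] * sig
        expect_dp = params.kappa_scale[3] ** 2 * params.extrinsic_scale[1] * sig
        assert delta[0] == pytest.approx(expect_ss, rel=1e-12)
        assert delta[3] == pytest.approx(expect_dp, rel=1e-12)
        assert delta[1] == 0.0 and delta[2] == 0.0

    def test_dimension_mismatch_raises(self):
        arch, design, mod, params = one_region_setup()
        with pytest.raises(ShapeError):
            cmc.cmc_derivatives(np.zeros((2, 4, 2)), params, arch, u=0.0,
                                design=design, modulation=mod)


class TestConditionEffects:
    def setup_method(self):
        fwd = np.zeros((2, 2), bool)
        fwd[1, 0] = True
        bwd = np.zeros((2, 2), bool)
        bwd[0, 1] = True
        self.arch = cmc.CMCArchitecture(2, fwd, bwd, np.array([True, False]))
        self.design = cmc.ConditionDesign.roving_oddball()
        self.mod = cmc.ModulationSpec.extrinsic_and_sp_self(self.arch)

    def test_baseline_condition_leaves_parameters_unchanged(self):
        p = cmc.CMCParameters.zeros(self.arch, self.design, self.mod)
        p.theta_B[:] = 0.7
        eff = cmc.apply_condition_effects(p, 0, self.design, self.mod)
        assert np.array_equal(eff.theta_Af, p.theta_Af)
        assert np.array_equal(eff.theta_Ab, p.theta_Ab)
        assert np.all(eff.self_shift == 0.0)

    def test_zero_effects_make_all_conditions_identical(self):
        p = cmc.CMCParameters.zeros(self.arch, self.design, self.mod)
        ref = cmc.effective_gain_arrays(p, self.arch, self.design, 0, self.mod)
        for c in range(1, 4):
            got = cmc.effective_gain_arrays(p, self.arch, self.design, c, self.mod)
            for a, b in zip(ref, got):
                assert np.array_equal(a, b)

    def test_log_two_effect_doubles_forward_gain(self):
        p = cmc.CMCParameters.zeros(self.arch, self.design, self.mod)
        p.theta_B[0, 0] = np.log(2.0)  # first effect, forward edge
        _, _, Af_base, _, _ = cmc.effective_gain_arrays(
            p, self.arch, self.design, 0, self.mod)
        _, _, Af_dr, _, _ = cmc.effective_gain_arrays(
            p, self.arch, self.design, 1, self.mod)
        i, j = self.arch.forward_edges[0]
        assert Af_dr[i, j] == pytest.approx(2.0 * Af_base[i, j], rel=1e-12)


class TestIntegrateERP:
    def test_zero_input_gain_gives_identically_zero_trajectory(self):
        arch, design, mod, params = one_region_setup()
        params.theta_C[:] = -1000.0  # exp underflows to exactly zero
        traj = cmc.integrate_erp(params, arch, design, 0, mod)
        assert np.all(traj.V == 0.0)

    def test_prior_mean_response_is_finite_and_damped(self):
        arch, design, mod, params = one_region_setup()
        traj = cmc.integrate_erp(params, arch, design, 0, mod)
        assert np.all(np.isfinite(traj.V))
        peak = np.abs(traj.V).max()
        assert peak > 0
        late = np.abs(traj.V[-1]).max()
        assert late < 0.05 * peak

    def test_near_linear_regime_response_scales_with_input(self):
        arch, design, mod, params = one_region_setup()
        t1 = cmc.integrate_erp(params, arch, design, 0, mod)
        params2 = cmc.CMCParameters(theta_Af=np.zeros(0), theta_Ab=np.zeros(0),
                                    theta_B=np.zeros((0, 0)),
                                    theta_C=np.array([np.log(2.0)]))
        t2 = cmc.integrate_erp(params2, arch, design, 0, mod)
        rel = (np.linalg.norm(t2.V - 2 * t1.V) / np.linalg.norm(2 * t1.V))
        assert rel < 1e-3

    def test_substep_refinement_changes_little(self):
        arch, design, mod, params = one_region_setup()
        a = cmc.integrate_erp(params, arch, design, 0, mod, n_sub=5)
        b = cmc.integrate_erp(params, arch, design, 0, mod, n_sub=10)
        rel = np.linalg.norm(a.V - b.V) / np.linalg.norm(b.V)
        assert rel < 1e-4

    def test_afferent_components_sum_to_forcing(self, truth):
        traj = cmc.integrate_erp(truth.neuronal, truth.arch, truth.design, 1,
                                 truth.modulation)
        kappa, a_eff, Af, Ab, C = cmc.effective_gain_arrays(
            truth.neuronal, truth.arch, truth.design, 1, truth.modulation)
        u = cmc.gaussian_input(traj.times, truth.neuronal.input_onset,
                               truth.neuronal.input_dispersion)
        for p in range(4):
            summed = traj.forcing(p)
            direct = np.stack([
                cmc._forcing(traj.V[t], truth.neuronal, a_eff, Af, Ab, C, u[t])[:, p]
                for t in range(len(traj.times))
            ])
            assert np.max(np.abs(summed - direct)) < 1e-10

    def test_unstable_parameters_raise_integration_error(self):
        arch, design, mod, params = one_region_setup()
        # rate constants far beyond the integrator's stability limit
        params.theta_kappa = np.full(4, 5.0)
        with np.errstate(all="ignore"), pytest.raises(IntegrationError) as err:
            cmc.integrate_erp(params, arch, design, 0, mod)
        assert err.value.block == "neuronal"


class TestArchitectureValidation:
    def test_nonzero_diagonal_rejected(self):
        m = np.eye(2, dtype=bool)
        with pytest.raises(Exception):
            cmc.CMCArchitecture(2, m, np.zeros((2, 2), bool),
                                np.array([True, False]))

    def test_no_input_region_rejected(self):
        with pytest.raises(Exception):
            cmc.CMCArchitecture(1, np.zeros((1, 1), bool),
                                np.zeros((1, 1), bool), np.array([False]))
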