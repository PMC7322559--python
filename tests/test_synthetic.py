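"""Synthetic dataset generation and full multimodal pipeline closure."""

import numpy as np
import pytest

import nvcdcm as nd
from nvcdcm import nvc
from nvcdcm.errors import ValidationError
from tests.conftest import Q1_PARTITION, Q4_PARTITION, REDUCED_SPECS


class TestSchedule:
    def test_zero_deviant_fraction_yields_no_deviants(self):
        sched = nd.generate_schedule(n_blocks=4, tones_per_block=10,
                                     deviant_fraction=0.0, seed=0)
        assert sched.onsets["DR"].size == 0
        assert sched.onsets["DC"].size == 0

    def test_event_counts_are_conserved(self):
        sched = nd.generate_schedule(n_blocks=6, tones_per_block=9, seed=1)
        assert sum(sched.counts().values()) == 6 * 9

    def test_fixed_seed_reproduces_schedule_exactly(self):
        a = nd.generate_schedule(seed=7)
        b = nd.generate_schedule(seed=7)
        for c in a.condition_names:
            assert np.array_equal(a.onsets[c], b.onsets[c])

    def test_onsets_lie_within_run(self):
        sched = nd.generate_schedule(n_blocks=5, tones_per_block=8, seed=2)
        for c in sched.condition_names:
            if sched.onsets[c].size:
                assert sched.onsets[c].min() >= 0
                assert sched.onsets[c].max() < sched.duration

    def test_invalid_deviant_fraction_rejected(self):
        with pytest.raises(ValidationError):
            nd.generate_schedule(deviant_fraction=1.5)


class TestArchitectures:
    def test_five_region_hierarchy_is_valid_and_integrates(self):
        arch = nd.synthetic.five_region_architecture()
        assert arch.n_regions == 5
        assert len(arch.forward_edges) == 3
        assert len(arch.backward_edges) == 3
        assert arch.input_regions.sum() == 2
        from nvcdcm import cmc
        design = nd.synthetic.cmc.ConditionDesign.roving_oddball()
        mod = cmc.ModulationSpec.extrinsic_and_sp_self(arch)
        params = cmc.CMCParameters.zeros(arch, design, mod)
        params.theta_C = np.zeros(arch.n_inputs)
        traj = cmc.integrate_erp(params, arch, design, 0, mod)
        assert np.all(np.isfinite(traj.V))
        assert np.abs(traj.V[-1]).max() < 0.05 * np.abs(traj.V).max()


class TestERPSimulation:
    def test_infinite_snr_returns_noiseless_prediction(self, truth):
        a = nd.simulate_erp_dataset(truth, snr=np.inf, seed=0)
        b = nd.simulate_erp_dataset(truth, snr=np.inf, seed=99)
        for c in a.condition_names:
            assert np.array_equal(a.data[c], b.data[c])
        assert a.noise_sd == 0.0

    def test_empirical_noise_level_matches_nominal(self, truth):
        """Monte-Carlo check: the realised noise standard deviation across
        twenty seeds stays within 5% of the requested level."""
        clean = nd.simulate_erp_dataset(truth, snr=np.inf, seed=0)
        sds = []
        for seed in range(20):
            noisy = nd.simulate_erp_dataset(truth, snr=10, seed=seed)
            resid = np.concatenate([
                (noisy.data[c] - clean.data[c]).ravel()
                for c in noisy.condition_names])
            sds.append(resid.std())
        assert np.mean(sds) == pytest.approx(noisy.noise_sd, rel=0.05)

    def test_without_condition_effects_all_conditions_coincide(self, truth):
        from dataclasses import replace
        flat = replace(truth.neuronal, theta_B=np.zeros_like(
            truth.neuronal.theta_B))
        t = replace(truth, neuronal=flat)
        ds = nd.simulate_erp_dataset(t, snr=np.inf, seed=0)
        ref = ds.data[ds.condition_names[0]]
        for c in ds.condition_names[1:]:
            assert np.allclose(ds.data[c], ref, atol=1e-12)


class TestBOLDSimulation:
    def test_zero_weights_give_pure_noise_around_zero(self, truth, schedule):
        from dataclasses import replace
        t = replace(truth, nvc_params=nvc.NVCParameters(
            np.zeros_like(truth.nvc_params.beta)))
        bold, noiseless, _ = nd.simulate_bold_dataset(t, schedule, snr=10,
                                                      seed=3)
        assert np.all(noiseless == 0.0)
        assert np.all(bold == 0.0)  # noise scales with the (zero) signal

    def test_noiseless_output_equals_forward_prediction(self, truth, schedule):
        bold, noiseless, template = nd.simulate_bold_dataset(
            truth, schedule, snr=np.inf, seed=4)
        z = nd.shift_and_sum(template, schedule)
        zj = nvc.combine_drives(z, template.channel_names, truth.nvc_params,
                                truth.nvc_spec, dt=schedule.dt)
        direct = nd.predict_bold(zj, truth.haemo, dt=schedule.dt,
                                 tr=schedule.tr)
        assert np.array_equal(bold, direct)
        assert np.array_equal(noiseless, direct)

    def test_weight_scaling_is_exact_on_drives_and_near_linear_on_bold(
            self, truth, schedule):
        template = nd.synthetic.drive_templates(truth)
        z = nd.shift_and_sum(template, schedule)
        spec = truth.nvc_spec
        p1 = nvc.NVCParameters(0.1 * truth.nvc_params.beta)
        p2 = nvc.NVCParameters(0.2 * truth.nvc_params.beta)
        z1 = nvc.combine_drives(z, template.channel_names, p1, spec,
                                dt=schedule.dt)
        z2 = nvc.combine_drives(z, template.channel_names, p2, spec,
                                dt=schedule.dt)
        assert np.allclose(z2, 2.0 * z1, atol=1e-12)  # exact on the combine
        y1 = nd.predict_bold(z1, truth.haemo, dt=schedule.dt, tr=schedule.tr)
        y2 = nd.predict_bold(z2, truth.haemo, dt=schedule.dt, tr=schedule.tr)
        ratio = np.linalg.norm(y2) / np.linalg.norm(y1)
        assert ratio == pytest.approx(2.0, rel=0.02)  # Balloon is mildly nonlinear


class TestGroundTruthSerialisation:
    def test_json_round_trip_regenerates_identical_data(self, truth, schedule):
        clone = nd.GroundTruth.from_json(truth.to_json())
        b1, _, _ = nd.simulate_bold_dataset(truth, schedule, snr=10, seed=5)
        b2, _, _ = nd.simulate_bold_dataset(clone, schedule, snr=10, seed=5)
        assert np.array_equal(b1, b2)
        e1 = nd.simulate_erp_dataset(truth, snr=10, seed=5)
        e2 = nd.simulate_erp_dataset(clone, snr=10, seed=5)
        for c in e1.condition_names:
            assert np.array_equal(e1.data[c], e2.data[c])


class TestPipelineClosure:
    def test_full_multimodal_chain_recovers_generating_family(self, schedule):
        """ERP inversion -> posterior drive functions -> fMRI inversion
        recovers the generating neurovascular family (parameterisation and
        form factors) in at least nine of ten seeded replicates."""
        wins = 0
        n_rep = 10
        for r in range(n_rep):
            m = r % 4
            gen_spec = REDUCED_SPECS[m]
            truth = nd.default_ground_truth(seed=0, nvc_spec=gen_spec)
            erp = nd.simulate_erp_dataset(truth, snr=10, seed=200 + r)
            inv = nd.invert_erp(erp, truth.arch, truth.design,
                                truth.gain_model, modulation=truth.modulation,
                                max_iter=32)
            post_params = inv.posterior_params()
            bold, _, _ = nd.simulate_bold_dataset(truth, schedule, snr=10,
                                                  seed=300 + r)
            templates = {
                st: nd.compute_condition_drives(
                    post_params, truth.arch, truth.design, signal_type=st,
                    modulation=truth.modulation)
                for st in ("pre", "post")
            }
            fits = nd.fit_model_space(bold, templates, schedule,
                                      REDUCED_SPECS, max_iter=48)
            F = np.array([f.free_energy for f in fits])
            q1 = nd.family_posterior(F, Q1_PARTITION)
            q4 = nd.family_posterior(F, Q4_PARTITION)
            ok = (max(q1, key=q1.get) == gen_spec.parameterisation
                  and max(q4, key=q4.get) == gen_spec.form)
            wins += ok
        assert wins >= 9
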