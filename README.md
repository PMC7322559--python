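# nvcdcm — multimodal dynamic causal modelling of neurovascular coupling

What drives the BOLD signal — presynaptic or postsynaptic activity? Local
populations or distal afferents? Is the coupling instantaneous or delayed
by vasoactive-agent kinetics? `nvcdcm` is a Python toolkit for asking such
questions with combined M/EEG and fMRI data from the same paradigm. It
fits a laminar neural mass model to event-related electromagnetic
responses, turns the fitted model into condition-specific *neuronal drive
functions*, feeds those drives into a factorial space of neurovascular +
haemodynamic models fitted to region-wise BOLD time series, and compares
the candidate models by their Bayesian evidence.

It is aimed at researchers modelling neurovascular function — e.g.
studying how ageing, disease or pharmacology alters the coupling between
neuronal activity and haemodynamics — who want hypothesis tests that are
not confounded by uncertainty in the neuronal parameters.

## The model chain

1. **Neuronal**: a canonical microcircuit per region — spiny stellate
   (ss), superficial pyramidal (sp), inhibitory interneuron (ii) and deep
   pyramidal (dp) populations with second-order synaptic dynamics
   (1 + κ⁻¹ d/dt)² V = f(V, u), a baseline-deviation firing sigmoid σ(V),
   log-normal gains and condition-specific gain modulations (B) declared
   in a between-trial-effects matrix. Fitted to per-condition ERP sensor
   data (reduced to principal modes) by variational Laplace.
2. **Drives**: per condition, the fitted circuit's per-trial pre- or
   postsynaptic responses z_ij(t) are shifted to every event onset of the
   fMRI run and summed.
3. **Neurovascular**: z_j(t) = Σᵢ β_ij z_ij(t), optionally convolved with
   the delay kernel (t/τ_nc)·e^(−t/τ_nc), τ_nc ≈ 0.7 s.
4. **Haemodynamic/BOLD**: the Balloon model
   ḣ_s = z − η h_s − χ(h_in − 1), ḣ_in = h_s,
   τ_h ḣ_v = h_in − h_v^{1/α}, τ_h ḣ_q = h_in E(h_in, E₀)/E₀ − h_v^{1/α} h_q/h_v,
   y = V₀(k₁(1 − h_q) + k₂(1 − h_q/h_v) + k₃(1 − h_v)).
5. **Comparison**: sixteen models crossing parameterisation
   (pre / decomposed-pre / post) × distal afferents (in/out) ×
   region-specific vs shared β × direct vs delay, scored by free energy;
   family-wise posteriors answer each factor-level question; Bayesian
   model reduction prunes non-contributing parameters analytically.

A synthetic-data module generates complete multimodal datasets (event
schedules for a four-condition roving-oddball design, ERP sensor data,
region BOLD series) from known ground truth, so the whole pipeline is
testable without any recordings.

## Worked example

Simulate a two-region multimodal dataset, fit the neuronal model to the
ERPs, and compare four neurovascular hypotheses on the BOLD data:

```python
import numpy as np
import nvcdcm as nd
from nvcdcm import nvc

truth = nd.default_ground_truth(seed=0)          # generating model: pre/direct
schedule = nd.generate_schedule(n_blocks=16, tones_per_block=12,
                                tone_interval=0.6, seed=11)
erp = nd.simulate_erp_dataset(truth, snr=10, seed=1)
inv = nd.invert_erp(erp, truth.arch, truth.design, truth.gain_model,
                    modulation=truth.modulation)
print(f"ERP inversion: F = {inv.free_energy:.1f}, converged = {inv.result.converged}")
post = inv.posterior_blocks()
print(f"forward log-gain: true 0.50, posterior {post['theta_Af'][0]:.2f}")

bold, _, _ = nd.simulate_bold_dataset(truth, schedule, snr=10, seed=2)
templates = {st: nd.compute_condition_drives(inv.posterior_params(),
                                             truth.arch, truth.design,
                                             signal_type=st,
                                             modulation=truth.modulation)
             for st in ("pre", "post")}
specs = [nvc.NVCModelSpec("pre", "exclude", False, "direct"),
         nvc.NVCModelSpec("post", "na", False, "direct"),
         nvc.NVCModelSpec("pre", "exclude", False, "delay"),
         nvc.NVCModelSpec("post", "na", False, "delay")]
fits = nd.fit_model_space(bold, templates, schedule, specs)
F = np.array([f.free_energy for f in fits])
comp = nd.compare_models(F)
for s, Fi, p in zip(specs, F, comp.probabilities):
    print(f"  {s.parameterisation:>4s}/{s.form:<6s} F = {Fi:9.1f}  p = {p:.3f}")
q1 = nd.family_posterior(F, {"pre": [0, 2], "post": [1, 3]})
q4 = nd.family_posterior(F, {"direct": [0, 1], "delay": [2, 3]})
print("family posterior (parameterisation):", {k: round(v, 4) for k, v in q1.items()})
print("family posterior (form):            ", {k: round(v, 4) for k, v in q4.items()})
best = fits[int(np.argmax(F))]
print("explained variance (%):",
      np.round(best.explained_variance(
          bold, templates[best.spec.parameterisation], schedule), 1))
```

Output from this exact script:

```
ERP inversion: F = 140839.2, converged = True
forward log-gain: true 0.50, posterior 0.55
   pre/direct F =    1141.2  p = 1.000
  post/direct F =    1062.7  p = 0.000
   pre/delay  F =    1081.1  p = 0.000
  post/delay  F =     979.8  p = 0.000
family posterior (parameterisation): {'pre': 1.0, 'post': 0.0}
family posterior (form):             {'direct': 1.0, 'delay': 0.0}
explained variance (%): [98.5 97.6]
```

The ERP stage recovers the generating forward connectivity; on the fMRI
side the generating hypothesis (instantaneous coupling to presynaptic
drives) wins both family comparisons outright — a log Bayes factor of
about 60 over the nearest competitor — and the winning model explains
~98% of the variance of the simulated region time series.

A command-line surface wraps the same stages for file-based workflows:

```
nvcdcm simulate --out ds --seed 3
nvcdcm invert-erp --data ds --out erp.json
nvcdcm drives --data ds --posterior erp.json --signal-type pre --out drives.csv
nvcdcm invert-fmri --data ds --posterior erp.json --options pre,s,int --form direct --out fit.json
nvcdcm model-space
```

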