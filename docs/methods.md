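# Methods

`nvcdcm` implements a multimodal dynamic-causal-modelling pipeline for
testing hypotheses about neurovascular coupling: a neural mass model is
fitted to event-related electromagnetic data, the fitted model generates
condition-specific *neuronal drive functions*, and those drives feed a
factorial family of neurovascular + haemodynamic models fitted to
region-wise fMRI time series. Hypotheses are adjudicated by (family-wise)
Bayesian model comparison on the variational free energy, with Bayesian
model reduction for parameter-level pruning. This note records the models,
the numerical choices, and the places where the design was genuinely open.

## Neuronal model

Each region is a canonical microcircuit of four populations — spiny
stellate (ss), superficial pyramidal (sp), inhibitory interneurons (ii),
deep pyramidal (dp). Population depolarisation obeys

    (1 + (1/κ_i) d/dt)² V_i = f_i(V, u)
    σ(V) = 1/(1 + e^{−a_s(V−V_th)}) − 1/(1 + e^{a_s V_th}),   a_s = 1, V_th = 0

with f_i the population-specific signed mixture of local firing (intrinsic
gains a), distal firing routed through forward/backward adjacencies (Af,
Ab), and a Gaussian input bump u(t) (default onset 0.070 s, dispersion
0.016 s) entering ss with gain C. All gains are log-normal, effective =
exp(θ)·scale; condition effects (B) add to the log-gains of extrinsic
connections and self-inhibition per a between-trial-effects (BTF) design
matrix whose baseline row is zero. With the default parameterisation the
sigmoid's firing deviation spans (−½, ½); its maximum is conventionally
absorbed into the connectivity scales.

Fixed scale conventions (all overridable on `CMCParameters`):

- Rate constants κ = [256, 128, 16, 32] /s assigned to (ss, sp, ii, dp) —
  fast granular/supragranular, slow interneuron and infragranular kinetics.
- Intrinsic gain scales [2, 1, 1, 1]·512 assigned to four connection
  classes: recurrent self-inhibition (2·512), excitation from spiny
  stellates, excitation from pyramidal cells, inhibition from interneurons
  (512 each). The doubled self-inhibition class is load-bearing: if all
  classes carry equal weight the linearised circuit has an exactly neutral
  mode (a zero eigenvalue of the intrinsic coupling matrix), so responses
  never return to baseline; doubling the self-inhibition restores a strict
  spiral sink at rest.
- Extrinsic rate scales [256, 128, 256, 128] for (forward→ss, forward→dp,
  backward→sp, backward→ii). The extrinsic adjacency as written is 0/1
  with a log-scaling, which would leave distal input three orders of
  magnitude below intrinsic gains and the network effectively
  disconnected; the chosen scale is half the base intrinsic rate, the
  largest round value that keeps a reciprocally connected two-region loop
  well inside its stability margin across the prior range of condition
  effects (verified by eigenvalue scans of the linearised 16-state system).

### Integration

Fixed-step RK4. The output grid is 1 ms over the 0–0.4 s peristimulus
window, but the coupled system's oscillatory modes run at κ√(a σ′), i.e.
several kilohertz at the prior gains — far above the rate constants
themselves — so RK4 is only stable with substeps of ~0.2 ms. The default
is 5 substeps per output sample (stability margin ≈ 2× in gain excursions;
halving the substep changes trajectories by < 1e−7 relative norm).
Trajectories that still leave the finite range (e.g. rate scalings far
outside the prior) raise an `IntegrationError` naming the neuronal block.

Every signed afferent term of f_i is recomputed on the output grid after
integration and stored with the trajectory, so presynaptic drive functions
can be assembled without re-integration; their per-population sums
reproduce f_i to 1e−10.

## Electromagnetic observation and ERP inversion

Sensor data are a linear mixture: per region, populations are combined by
a contribution vector Ψ (prior mean (0, 1, 0, 0) — superficial pyramidal
dominance — variance 1/16), scaled by a spatial-basis expansion (default:
a single unit pattern with fixed coefficient) and projected through a gain
matrix. Head-model lead fields are out of scope; synthetic gain matrices
use seeded random orthonormal columns. Observed and predicted responses
are reduced to the eight principal sensor modes of the observed data (the
projection is computed once from the data, never refreshed, so both live
in one fixed feature space).

Priors on the neuronal block: extrinsic and condition-effect log-gains
N(0, 1/8); input gain N(0, 1/32); input onset N(0.070, 0.016²) with the
dispersion fixed at 0.016 s; rate constants and intrinsic gains fixed at
their scales (zero prior variance removes a parameter from the estimation
vector).

## Neuronal drives

For each condition the microcircuit is integrated at the posterior means,
and per-trial templates are assembled in three parameterisations:
postsynaptic (the four V_i), presynaptic (signed afferent sums per
population, with extrinsic afferents kept as four separate channels), and
decomposed presynaptic (three pooled channels: excitatory = intrinsic
terms from ss/sp/dp sources plus the exogenous input, inhibitory =
interneuron and self-inhibition terms, extrinsic = distal terms; grouping
by *source* population is a convention — the printed equations make the
dp→ii term negative, yet its source is excitatory). Presynaptic channels
stay signed; an option rectifies them if desired, but signed channels are
the default since the coupling weights are unconstrained in sign. An
exclusion vector O zeroes populations; its command-line order follows the
field's established convention (sp, ii, ss, dp) and is mapped internally
to (ss, sp, ii, dp).

Templates are resampled from the 1 ms grid to the fMRI microtime grid by
integral-preserving bin averaging, then shifted to each event onset and
summed (linear superposition; overlaps add). All templates are divided by
one global constant — the peak magnitude on the fine grid, shared across
conditions, regions and channels so relative amplitudes are untouched —
which puts the coupling weights on the scale of their shrinkage prior.

The microtime step defaults to 0.05 s: at 0.1 s the 0.4 s templates carry
only four samples and halving the step still moves the TR-sampled BOLD by
~2e−3 relative norm, whereas from 0.05 s the refinement error is below
1e−4.

## Neurovascular coupling and the model space

The regional neurovascular signal is z_j(t) = Σ_i β_ij z_ij(t) (direct
form) or that sum convolved with the delay kernel f_nc(t) =
(t/τ_nc) e^{−t/τ_nc} (delay form; τ_nc = 0.7·exp(θ) s, priors β ~
N(0, 1/16), θ_τ ~ N(0, 1/16)). The kernel is deliberately *not*
normalised — its area is τ_nc, exactly as written — because normalising
would silently rescale the β posteriors; consequently the delay form tends
to τ_nc times the direct form (not the direct form itself) as τ_nc → 0.
The discrete convolution uses point samples × dt, truncated at 8 τ_nc
(omitted mass < 3e−3); when τ_nc falls below two microtime steps the
weights switch to exact per-bin integrals of the kernel so no mass is
lost.

Sixteen candidate models cross four factors: parameterisation
(presynaptic per population / presynaptic decomposed / postsynaptic),
distal afferents (included as separate β-weighted channels / excluded;
not applicable to postsynaptic models), region-specific versus shared β,
and direct versus delayed form. Family comparisons pool posterior model
probabilities per factor level under a prior uniform over families and
uniform within each family (correcting for unequal family sizes);
postsynaptic models are simply not applicable to the distal factor and are
excluded from that partition.

## Haemodynamics and BOLD

The regional signal drives the vasodilatory/Balloon system

    ḣ_s  = z − η h_s − χ (h_in − 1)
    ḣ_in = h_s
    ḣ_v  = (h_in − h_v^{1/α}) / τ_h
    ḣ_q  = (h_in (1 − (1−E₀)^{1/h_in})/E₀ − h_v^{1/α} h_q/h_v) / τ_h
    y    = V₀ (k₁(1 − h_q) + k₂(1 − h_q/h_v) + k₃(1 − h_v))

with k₁ = 6.9 E₀, k₂ = ε E₀, k₃ = 1 − ε, scales η = 0.64/s, χ = 0.32/s,
τ_h = 2.0 s, α = 0.32, ε = 1.0, E₀ = 0.40, V₀ = 0.08 (a config override
accommodates the newer, lower estimates of resting blood volume). η, τ_h
and ε are estimated per region (priors N(0, 1/256) on the log-scalings);
χ, α, E₀ are fixed. The linearised signal/inflow pair is a damped
oscillator with undamped natural frequency √χ/2π ≈ 0.09 Hz — the ~0.1 Hz
vasomotor resonance.

Integration: RK4 on the microtime grid with the drive held
piecewise-constant per step, and the positive states (h_in, h_v, h_q)
integrated in log space so trajectories cannot leave the positive orthant.
The initial condition is exact rest (0, 1, 1, 1); BOLD is sampled at
t = 0, TR, 2 TR, …. An optional discrete-cosine confound set (off by
default) absorbs slow drifts.

## Inference

`variational_laplace` maximises the Laplace free energy under a Gaussian
posterior by Gauss–Newton ascent with Levenberg–Marquardt damping;
derivatives are central finite differences (step 1e−3 on the
dimensionless log-scalings). Observation noise is i.i.d. within each data
stream (one stream for ERP features, one per region for fMRI) with a
log-precision hyperparameter updated by damped Newton steps under a
Gaussian hyperprior, default N(0, 64) — wide enough that precisions from
~e^{−16} to ~e^{16} carry no meaningful penalty, since realistic synthetic
data put the true log-precision anywhere between 4 and 25. Convergence is
declared after three consecutive accepted steps improving F by less than
0.01, with at most 64 iterations; a failed line search at a maximum
terminates early. On linear-Gaussian problems the scheme reproduces the
conjugate posterior and the exact log evidence to 1e−6, which the test
suite uses as an oracle.

The generators are strongly nonlinear and their free-energy landscapes
multimodal, so both inversions start from the best of a small set of
seeded prior draws (16 for ERP, 8 for fMRI) scored by prior-penalised sum
of squares. The draws use a fixed internal seed: results remain
bit-reproducible for a given configuration.

Bayesian model reduction computes the evidence and posterior of a model
with modified priors analytically from the full posterior; greedy pruning
switches off candidate parameters (prior pinned at zero with variance
1e−8) best-first while the reduction does not decrease F, and reports
per-parameter presence log-odds against the final model. Fixed-effects
model comparison is a softmax of free energies under uniform model priors.

## Synthetic data

The generator emulates a four-condition roving-oddball study: blocks of
tones are computer- ("respond") or subject-controlled ("control"), each
tone is independently a deviant with probability 0.25, giving conditions
SR/DR/SC/DC with SR as baseline and one BTF effect column per non-baseline
condition. Defaults: 40 blocks × 15 tones at 0.6 s intervals with a 3 s
cue/inter-block gap (an 8-minute run), TR 2 s, amplitude SNR 10 for both
modalities (noise sd = sd(signal)/SNR, pooled over sensors for ERP,
per region for fMRI). Note one consequence of the relative-noise
convention: a simulation whose coupling weights are all zero produces
exactly zero data, not noise.

The default network is a desk-scale two-region hierarchy (forward R1→R2,
backward R2→R1) standing in for the five-region bilateral auditory network
of the empirical design; a five-region architecture is shipped. Both
regions receive the exogenous input, as in a bilateral sensory hierarchy —
this also keeps every parameter class identifiable from the sensor data,
which is the point of a ground-truth testbed (with input to one region
only, the higher region's condition effects are visible only through the
weak extrinsic relay and shrink to their priors). The default condition
effects modulate the extrinsic gains and the sp self-inhibition of each
region (|θ_B| between 0.2 and 0.5, i.e. 20–65% gain changes — typical
fitted effect sizes for this model family); the machinery accepts
arbitrary modulation masks including the full extrinsic + all-self set
used in empirical work. True coupling weights sit at the scale of their
shrinkage prior with signs matched to the drive-channel polarities so the
net BOLD response is positive (~1–2% signal change).

What the generator does not emulate: single-trial variability (drives are
stereotyped per condition by design), realistic MEG forward physics and
sensor-noise correlations, fMRI drift/motion/physiological noise (an AR(1)
switch exists but white noise is the default), and any mismatch between
the neuronal model family and the data-generating process. Passing
recovery tests therefore demonstrates internal consistency of the
estimation machinery at realistic effect sizes and noise levels — not that
the model family is correct for real recordings.

## Test problem sizes

The test suite scales the study down to keep a full run at desk scale: the
recovery studies use 16-block schedules (~2.7 min of fMRI), 16 sensors,
and 10–20 seeded replicates per study, with the reduced four-model space
(pre/post × direct/delay, shared weights) for generating data. These are
the package's reference conditions for its own validation; the full
16-model space and 8-minute default run remain the library defaults.

## Known limitations

- Single haemodynamic compartment per region; no laminar variants.
- Fixed-form Gaussian posteriors; no sampling-based checks of the Laplace
  approximation.
- The presynaptic drive channels of a single region are strongly
  correlated once convolved with the sluggish haemodynamics, so individual
  β are identified mainly through condition-amplitude differences;
  posteriors remain calibrated but can be wide along near-collinear
  directions, and greedy pruning can legitimately remove a correlated pair
  rather than the single null weight.
- Group-level (hierarchical) inference is out of scope.
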