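"""Ground-truth simulation of multimodal (ERP + BOLD) datasets.

Emulates a four-condition roving-oddball study: blocks of tones are either
subject-controlled ("C") or computer-controlled ("R"), and each tone is a
standard or a deviant, giving conditions SR, DR, SC, DC with SR as baseline.
The same ground-truth neuronal parameters generate the event-related sensor
data (through the microcircuit and a synthetic lead field) and the region
BOLD series (through drive functions, neurovascular coupling and the
Balloon model), so every stage of the estimation pipeline can be tested
against known parameters.

The default network is a desk-scale two-region hierarchy (one forward, one
backward connection, input to the lower region); a five-region variant
mirroring a bilateral auditory hierarchy is also provided.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import cmc, nvc
from .drives import DriveSignal, EventSchedule, compute_condition_drives, shift_and_sum
from .errors import ValidationError
from .haemo import HaemoParameters, predict_bold
from .meg import ERPDataset, GainModel, predict_sensors


def two_region_architecture() -> cmc.CMCArchitecture:
    """Two-region hierarchy: forward R1 -> R2, backward R2 -> R1.

    Both regions receive the exogenous input (as in a bilateral sensory
    hierarchy), which keeps every parameter class of the estimation problem
    driven by data: the higher region's intrinsic condition effects would
    otherwise be visible only through the weak extrinsic relay.
    """
    fwd = np.zeros((2, 2), bool)
    fwd[1, 0] = True
    bwd = np.zeros((2, 2), bool)
    bwd[0, 1] = True
    return cmc.CMCArchitecture(2, fwd, bwd, np.array([True, True]),
                               region_names=("R1", "R2"))


def five_region_architecture() -> cmc.CMCArchitecture:
    """Bilateral auditory-hierarchy layout: HG -> PT bilaterally, right
    PT -> IFG, with reciprocal backward connections; inputs to both HG."""
    names = ("lHG", "rHG", "lPT", "rPT", "rIFG")
    fwd = np.zeros((5, 5), bool)
    bwd = np.zeros((5, 5), bool)
    for src, dst in ((0, 2), (1, 3), (3, 4)):
        fwd[dst, src] = True
        bwd[src, dst] = True
    return cmc.CMCArchitecture(5, fwd, bwd,
                               np.array([True, True, False, False, False]),
                               region_names=names)


@dataclass
class GroundTruth:
    """Everything needed to regenerate a synthetic dataset bit-for-bit."""

    arch: cmc.CMCArchitecture
    design: cmc.ConditionDesign
    modulation: cmc.ModulationSpec
    neuronal: cmc.CMCParameters
    gain_model: GainModel
    nvc_spec: nvc.NVCModelSpec
    nvc_params: nvc.NVCParameters
    haemo: HaemoParameters
    erp_snr: float = 10.0
    bold_snr: float = 10.0
    seed: int = 0

    def to_json(self) -> str:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            if isinstance(x, dict):
                return {k: conv(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [conv(v) for v in x]
            return x

        payload = {
            "arch": conv({
                "n_regions": self.arch.n_regions,
                "forward_mask": self.arch.forward_mask.astype(int),
                "backward_mask": self.arch.backward_mask.astype(int),
                "input_regions": self.arch.input_regions.astype(int),
                "region_names": self.arch.region_names,
            }),
            "design": conv({
                "condition_names": self.design.condition_names,
                "btf": self.design.btf,
                "baseline_index": self.design.baseline_index,
            }),
            "modulation": conv({
                "forward": self.modulation.forward.astype(int),
                "backward": self.modulation.backward.astype(int),
                "self_inhibition": self.modulation.self_inhibition.astype(int),
            }),
            "neuronal": conv({k: v for k, v in asdict(self.neuronal).items()
                              if v is not None}),
            "gain_model": conv({
                "gain": self.gain_model.gain,
                "spatial_basis": self.gain_model.spatial_basis,
                "theta": self.gain_model.theta,
                "psi": self.gain_model.psi,
            }),
            "nvc_spec": conv(asdict(self.nvc_spec)),
            "nvc_params": conv(asdict(self.nvc_params)),
            "haemo": conv(asdict(self.haemo)),
            "erp_snr": self.erp_snr,
            "bold_snr": self.bold_snr,
            "seed": self.seed,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        arch = cmc.CMCArchitecture(
            d["arch"]["n_regions"],
            np.array(d["arch"]["forward_mask"], bool),
            np.array(d["arch"]["backward_mask"], bool),
            np.array(d["arch"]["input_regions"], bool),
            region_names=tuple(d["arch"]["region_names"]),
        )
        design = cmc.ConditionDesign(tuple(d["design"]["condition_names"]),
                                     np.array(d["design"]["btf"]),
                                     d["design"]["baseline_index"])
        modulation = cmc.ModulationSpec(
            np.array(d["modulation"]["forward"], bool),
            np.array(d["modulation"]["backward"], bool),
            np.array(d["modulation"]["self_inhibition"], bool),
        )
        nd = d["neuronal"]
        neuronal = cmc.CMCParameters(
            theta_kappa=nd["theta_kappa"], theta_a=nd["theta_a"],
            theta_Af=nd["theta_Af"], theta_Ab=nd["theta_Ab"],
            theta_B=nd["theta_B"], theta_C=nd["theta_C"],
            input_onset=nd["input_onset"],
            input_dispersion=nd["input_dispersion"],
            kappa_scale=nd["kappa_scale"], intrinsic_scale=nd["intrinsic_scale"],
        )
        gm = GainModel(np.array(d["gain_model"]["gain"]),
                       np.array(d["gain_model"]["spatial_basis"]),
                       np.array(d["gain_model"]["theta"]),
                       np.array(d["gain_model"]["psi"]))
        sd = d["nvc_spec"]
        spec = nvc.NVCModelSpec(sd["parameterisation"], sd["distal"],
                                sd["region_specific"], sd["form"],
                                tuple(sd["exclusion_mask"]))
        nvc_params = nvc.NVCParameters(np.array(d["nvc_params"]["beta"]),
                                       d["nvc_params"]["theta_tau_nc"])
        hd = d["haemo"]
        haemo = HaemoParameters(
            theta_eta=hd["theta_eta"], theta_chi=hd["theta_chi"],
            theta_tau_h=hd["theta_tau_h"], theta_alpha=hd["theta_alpha"],
            theta_epsilon=hd["theta_epsilon"], theta_e0=hd["theta_e0"],
            v0=hd["v0"],
        )
        return cls(arch, design, modulation, neuronal, gm, spec, nvc_params,
                   haemo, d["erp_snr"], d["bold_snr"], d["seed"])


def default_ground_truth(seed: int = 0, n_sensors: int = 16,
                         nvc_spec: nvc.NVCModelSpec | None = None,
                         beta=None) -> GroundTruth:
    """Two-region truth with fixed, realistic effect sizes.

    Condition effects are moderate log-gain changes (|theta_B| in 0.2-0.5,
    i.e. 20-65% gain changes), coupling weights sit at the scale of their
    shrinkage prior and the haemodynamic constants deviate mildly from their
    canonical values across regions.
    """
    arch = two_region_architecture()
    design = cmc.ConditionDesign.roving_oddball()
    modulation = cmc.ModulationSpec.extrinsic_and_sp_self(arch)
    neuronal = cmc.CMCParameters(
        theta_Af=np.array([0.5]),
        theta_Ab=np.array([0.3]),
        # effect columns: [forward, backward, sp-self R1, sp-self R2]
        theta_B=np.array([
            [0.40, 0.30, -0.40, -0.30],   # DR
            [0.20, -0.20, 0.30, 0.20],    # SC
            [0.50, 0.10, -0.20, 0.40],    # DC
        ]),
        theta_C=np.array([0.0, -0.3]),
    )
    gain_model = GainModel.synthetic(n_sensors, arch.n_regions, seed=seed,
                                     psi=np.array([0.1, 1.0, 0.05, 0.3]))
    if nvc_spec is None:
        nvc_spec = nvc.NVCModelSpec("pre", "exclude", False, "direct")
    if beta is None:
        beta = _default_beta(nvc_spec, arch.n_regions)
    nvc_params = nvc.NVCParameters(beta=np.asarray(beta, float),
                                   theta_tau_nc=0.0)
    haemo = HaemoParameters(
        theta_eta=np.array([0.05, -0.05]),
        theta_tau_h=np.array([0.05, -0.05]),
        theta_epsilon=np.array([0.0, 0.0]),
    )
    return GroundTruth(arch, design, modulation, neuronal, gain_model,
                       nvc_spec, nvc_params, haemo, seed=seed)


def _default_beta(spec: nvc.NVCModelSpec, n_regions: int) -> np.ndarray:
    # signs follow the polarity of the drive channels (net positive BOLD):
    # presynaptic ss/dp inflows are net negative over a trial, sp/ii positive
    base = {
        4: np.array([-0.35, 0.25, 0.20, -0.15]),
        8: np.array([-0.35, 0.25, 0.20, -0.15, 0.10, -0.10, 0.05, 0.10]),
        3: np.array([0.30, -0.25, 0.15]),
        2: np.array([0.30, -0.25]),
    }[spec.n_channels]
    if spec.region_specific:
        scale = 1.0 + 0.3 * np.arange(n_regions)
        return np.outer(base, scale)
    return base


# ---------------------------------------------------------------------------
# event schedule
# ---------------------------------------------------------------------------

def generate_schedule(n_blocks: int = 40, tones_per_block: int = 15,
                      deviant_fraction: float = 0.25,
                      tone_interval: float = 0.6, block_gap: float = 3.0,
                      block_types: tuple[str, ...] = ("R", "C"),
                      tr: float = 2.0, dt: float = 0.05,
                      seed: int = 0) -> EventSchedule:
    """Roving-oddball-like block schedule with SR/DR/SC/DC labels.

    Blocks alternate between computer-controlled ("R"espond) and
    subject-controlled ("C"ontrol) types in seeded random order; each tone
    is independently a deviant with probability ``deviant_fraction``.  The
    ``block_gap`` seconds at the start of each block hold the cue and
    inter-block interval.  Deterministic given the seed.
    """
    if not 0 <= deviant_fraction < 1:
        raise ValidationError("deviant fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    reps = int(np.ceil(n_blocks / len(block_types)))
    types = rng.permutation(np.tile(np.asarray(block_types), reps)[:n_blocks])
    block_len = block_gap + tones_per_block * tone_interval
    duration = float(np.ceil(n_blocks * block_len / tr) * tr)
    onsets: dict[str, list[float]] = {c: [] for c in ("SR", "DR", "SC", "DC")}
    for b, btype in enumerate(types):
        start = b * block_len + block_gap
        deviants = rng.random(tones_per_block) < deviant_fraction
        for i in range(tones_per_block):
            label = ("D" if deviants[i] else "S") + str(btype)
            onsets[label].append(start + i * tone_interval)
    return EventSchedule(("SR", "DR", "SC", "DC"),
                         {k: np.array(v) for k, v in onsets.items()},
                         duration=duration, tr=tr, dt=dt)


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------

def simulate_erp_dataset(truth: GroundTruth, snr: float | None = None,
                         seed: int | None = None, dt: float = 1e-3,
                         t_max: float = 0.4) -> ERPDataset:
    """Noisy per-condition sensor data from the ground-truth microcircuit.

    I.i.d. Gaussian sensor noise with standard deviation sd(signal)/snr,
    where sd(signal) pools all conditions, times and sensors (amplitude
    signal-to-noise convention).  ``snr=inf`` returns the noiseless data.
    """
    snr = truth.erp_snr if snr is None else snr
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    signals = {}
    for c, cname in enumerate(truth.design.condition_names):
        traj = cmc.integrate_erp(truth.neuronal, truth.arch, truth.design, c,
                                 truth.modulation, t_max=t_max, dt=dt)
        signals[cname] = predict_sensors(traj.V, truth.gain_model)
    pooled_sd = float(np.std(np.concatenate(list(signals.values()))))
    noise_sd = 0.0 if np.isinf(snr) else pooled_sd / snr
    data = {c: signals[c] + noise_sd * rng.standard_normal(signals[c].shape)
            for c in signals}
    return ERPDataset(data=data, sample_interval=dt,
                      condition_names=tuple(truth.design.condition_names),
                      noise_sd=noise_sd)


def drive_templates(truth: GroundTruth, signal_type: str | None = None,
                    dt_out: float = 0.05) -> DriveSignal:
    """Condition drive templates implied by the ground-truth parameters."""
    st = truth.nvc_spec.parameterisation if signal_type is None else signal_type
    return compute_condition_drives(
        truth.neuronal, truth.arch, truth.design, signal_type=st,
        exclusion_mask=np.asarray(truth.nvc_spec.exclusion_mask),
        modulation=truth.modulation, dt_out=dt_out,
    )


def simulate_bold_dataset(truth: GroundTruth, schedule: EventSchedule,
                          snr: float | None = None, seed: int | None = None):
    """Region BOLD series at TR from the full ground-truth forward chain.

    Returns (bold, noiseless, template): the noisy (n_scans, n_regions)
    data, the noiseless prediction and the drive template used.  Per-region
    Gaussian noise with sd = sd(region signal)/snr.
    """
    snr = truth.bold_snr if snr is None else snr
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    template = drive_templates(truth, dt_out=schedule.dt)
    z = shift_and_sum(template, schedule)
    zj = nvc.combine_drives(z, template.channel_names, truth.nvc_params,
                            truth.nvc_spec, dt=schedule.dt)
    noiseless = predict_bold(zj, truth.haemo, dt=schedule.dt, tr=schedule.tr)
    if np.isinf(snr):
        noise_sd = np.zeros(noiseless.shape[1])
    else:
        noise_sd = noiseless.std(axis=0) / snr
    bold = noiseless + noise_sd * rng.standard_normal(noiseless.shape)
    return bold, noiseless, template
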