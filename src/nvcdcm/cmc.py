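"""Canonical microcircuit (CMC) neural mass model.

Each cortical region contains four neuronal populations — spiny stellate
cells (ss), superficial pyramidal cells (sp), inhibitory interneurons (ii)
and deep pyramidal cells (dp).  Mean depolarisation V of every population
obeys a second-order synaptic equation

    (1 + (1/kappa) d/dt)^2 V = f(V, u)
    <=>  V'' = kappa^2 (f - V) - 2 kappa V'

where f mixes sigmoid-transformed firing of the local populations (intrinsic
gains a), firing of distal regions routed through forward/backward extrinsic
matrices (Af, Ab), and an exogenous Gaussian input bump entering the spiny
stellate cells with gain C.  Gains are log-normal: effective = exp(theta) *
prior scale, so additive condition effects (B) in log space act
multiplicatively on the gains.

Experimental conditions share one parameter set plus condition-specific
additive effects declared in a between-trial-effects (BTF) design matrix;
the baseline condition has an all-zero BTF row.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._integrators import (
    INTRINSIC_TABLE,
    N_INTRINSIC,
    SELF_INDICES,
    cmc_rk4,
)
from .errors import IntegrationError, ParameterError, ShapeError, ValidationError

POPULATIONS = ("ss", "sp", "ii", "dp")

#: postsynaptic rate constants (1/s), mapped onto (ss, sp, ii, dp)
KAPPA_SCALE = np.array([256.0, 128.0, 16.0, 32.0])

#: Intrinsic gain prior scales.  The four printed scale values [2,1,1,1]*512
#: are mapped onto four connection classes: (1) recurrent self-inhibition
#: (2*512), (2) excitatory connections from spiny stellates (512),
#: (3) excitatory connections from pyramidal cells (512), (4) inhibitory
#: connections from interneurons (512).  Doubling the self-inhibition class
#: renders the linearised circuit non-singular at rest (any mapping that
#: leaves all classes at equal weight has an exactly neutral mode, so
#: responses would not return to baseline); overridable via
#: CMCParameters.intrinsic_scale.
INTRINSIC_SCALE = np.array(
    [2.0 * 512.0 if k in SELF_INDICES else 512.0 for k in range(N_INTRINSIC)]
)

INTRINSIC_NAMES = tuple(
    f"{POPULATIONS[src]}->{POPULATIONS[dst]}" for src, dst, _ in INTRINSIC_TABLE
)

#: Extrinsic rate scales (forward->ss, forward->dp, backward->sp,
#: backward->ii) multiplying the exp(theta)-scaled adjacency.  The adjacency
#: itself is 0/1, so a physical rate constant is needed for distal firing to
#: compete with intrinsic gains of order 512; forward input to the granular
#: layer and backward input to superficial pyramidals carry half the base
#: intrinsic rate scale (the largest value keeping the two-region loop well
#: inside its stability margin over the prior range of condition effects),
#: and the infragranular/interneuron copies carry a quarter.
EXTRINSIC_SCALE = np.array([256.0, 128.0, 256.0, 128.0])


# ---------------------------------------------------------------------------
# elementary functions
# ---------------------------------------------------------------------------

def synaptic_kernel(t, kappa: float):
    """Synaptic impulse response t * kappa * exp(-t * kappa), zero for t < 0."""
    if kappa <= 0:
        raise ParameterError(f"synaptic rate constant must be positive, got {kappa}")
    t = np.asarray(t, dtype=float)
    out = np.where(t >= 0, t * kappa * np.exp(-np.clip(t, 0, None) * kappa), 0.0)
    return out if out.ndim else float(out)


def firing_sigmoid(v, slope: float = 1.0, threshold: float = 0.0):
    """Firing-rate deviation from baseline.

    sigma(V) = 1/(1+exp(-slope (V - Vth))) - 1/(1+exp(slope Vth)); zero at
    V = 0 with the default threshold, and deliberately allowed to go negative
    (firing is a deviation from baseline).
    """
    v = np.asarray(v, dtype=float)
    out = 1.0 / (1.0 + np.exp(-slope * (v - threshold))) - 1.0 / (
        1.0 + np.exp(slope * threshold)
    )
    return out if out.ndim else float(out)


def gaussian_input(t, onset: float, dispersion: float):
    """Unit-amplitude Gaussian input bump centred at ``onset`` seconds."""
    if dispersion <= 0:
        raise ParameterError(f"input dispersion must be positive, got {dispersion}")
    t = np.asarray(t, dtype=float)
    out = np.exp(-0.5 * ((t - onset) / dispersion) ** 2)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# model structure
# ---------------------------------------------------------------------------

@dataclass
class CMCArchitecture:
    """Region count, allowed extrinsic edges and input targets.

    ``forward_mask[i, j]`` is nonzero when region j sends a forward
    (superficial-pyramidal) projection to region i; backward likewise from
    deep pyramidal cells.  Masks have zero diagonals.
    """

    n_regions: int
    forward_mask: np.ndarray
    backward_mask: np.ndarray
    input_regions: np.ndarray
    region_names: tuple[str, ...] | None = None
    population_labels: tuple[str, ...] = POPULATIONS

    def __post_init__(self):
        self.forward_mask = np.asarray(self.forward_mask, dtype=bool)
        self.backward_mask = np.asarray(self.backward_mask, dtype=bool)
        self.input_regions = np.asarray(self.input_regions, dtype=bool)
        R = self.n_regions
        for name, m in (("forward", self.forward_mask), ("backward", self.backward_mask)):
            if m.shape != (R, R):
                raise ShapeError(f"{name} mask must be {R}x{R}")
            if np.any(np.diag(m)):
                raise ValidationError(f"{name} mask has nonzero diagonal")
        if self.input_regions.shape != (R,):
            raise ShapeError("input_regions must be length n_regions")
        if not self.input_regions.any():
            raise ValidationError("at least one region must receive input")
        if self.region_names is None:
            self.region_names = tuple(f"R{i + 1}" for i in range(R))

    @property
    def forward_edges(self) -> list[tuple[int, int]]:
        """(target, source) pairs of allowed forward connections."""
        return [tuple(ij) for ij in np.argwhere(self.forward_mask)]

    @property
    def backward_edges(self) -> list[tuple[int, int]]:
        return [tuple(ij) for ij in np.argwhere(self.backward_mask)]

    @property
    def n_inputs(self) -> int:
        return int(self.input_regions.sum())


@dataclass
class ConditionDesign:
    """Condition names and the between-trial-effects (BTF) matrix.

    ``btf`` is conditions x effects; the baseline row is all-zero and each
    non-baseline condition switches on its declared effect columns.
    """

    condition_names: tuple[str, ...]
    btf: np.ndarray
    baseline_index: int = 0

    def __post_init__(self):
        self.btf = np.asarray(self.btf, dtype=float)
        if self.btf.shape[0] != len(self.condition_names):
            raise ShapeError("btf must have one row per condition")
        if np.any(self.btf[self.baseline_index] != 0):
            raise ValidationError("baseline BTF row must be all-zero")

    @property
    def n_conditions(self) -> int:
        return len(self.condition_names)

    @property
    def n_effects(self) -> int:
        return self.btf.shape[1]

    @classmethod
    def roving_oddball(cls) -> "ConditionDesign":
        """Four-condition design (SR baseline; DR, SC, DC each one effect)."""
        btf = np.array(
            [
                [0, 0, 0],  # SR: baseline
                [1, 0, 0],  # DR
                [0, 1, 0],  # SC
                [0, 0, 1],  # DC
            ],
            dtype=float,
        )
        return cls(("SR", "DR", "SC", "DC"), btf, baseline_index=0)


@dataclass
class ModulationSpec:
    """Which log-gains the condition effects (B) are allowed to change.

    Condition effects act on extrinsic forward/backward gains and on
    population self-inhibition gains; other intrinsic gains are
    condition-invariant.
    """

    forward: np.ndarray  # bool, one per forward edge
    backward: np.ndarray  # bool, one per backward edge
    self_inhibition: np.ndarray  # bool, (n_regions, 4)

    def __post_init__(self):
        self.forward = np.asarray(self.forward, dtype=bool)
        self.backward = np.asarray(self.backward, dtype=bool)
        self.self_inhibition = np.asarray(self.self_inhibition, dtype=bool)

    @property
    def n_modulated(self) -> int:
        return int(self.forward.sum() + self.backward.sum() + self.self_inhibition.sum())

    @classmethod
    def all_extrinsic_and_self(cls, arch: CMCArchitecture) -> "ModulationSpec":
        """Every extrinsic gain and every self-inhibition is modulable."""
        return cls(
            np.ones(len(arch.forward_edges), bool),
            np.ones(len(arch.backward_edges), bool),
            np.ones((arch.n_regions, 4), bool),
        )

    @classmethod
    def extrinsic_and_sp_self(cls, arch: CMCArchitecture) -> "ModulationSpec":
        """Extrinsic gains plus the sp self-inhibition in every region."""
        self_inh = np.zeros((arch.n_regions, 4), bool)
        self_inh[:, POPULATIONS.index("sp")] = True
        return cls(
            np.ones(len(arch.forward_edges), bool),
            np.ones(len(arch.backward_edges), bool),
            self_inh,
        )


@dataclass
class CMCParameters:
    """Log-scaling parameters of the microcircuit.

    All gain parameters are dimensionless log-scalings applied as
    exp(theta) * prior scale; ``theta_B`` has one row per BTF effect, laid out
    as [modulated forward edges, modulated backward edges, modulated
    self-inhibitions (region-major)].
    """

    theta_kappa: np.ndarray = field(default_factory=lambda: np.zeros(4))
    theta_a: np.ndarray = field(default_factory=lambda: np.zeros(N_INTRINSIC))
    theta_Af: np.ndarray = field(default_factory=lambda: np.zeros(0))
    theta_Ab: np.ndarray = field(default_factory=lambda: np.zeros(0))
    theta_B: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    theta_C: np.ndarray = field(default_factory=lambda: np.zeros(1))
    input_onset: float = 0.070
    input_dispersion: float = 0.016
    slope: float = 1.0
    threshold: float = 0.0
    kappa_scale: np.ndarray = field(default_factory=lambda: KAPPA_SCALE.copy())
    intrinsic_scale: np.ndarray = field(default_factory=lambda: INTRINSIC_SCALE.copy())
    extrinsic_scale: np.ndarray = field(default_factory=lambda: EXTRINSIC_SCALE.copy())
    #: additive per-region log shift of self-inhibition gains, (R, 4); used to
    #: carry already-applied condition effects (see apply_condition_effects)
    self_shift: np.ndarray | None = None

    def __post_init__(self):
        for name in ("theta_kappa", "theta_a", "theta_Af", "theta_Ab", "theta_C",
                     "kappa_scale", "intrinsic_scale", "extrinsic_scale"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), float)))
        self.theta_B = np.atleast_2d(np.asarray(self.theta_B, float))
        for name in ("theta_kappa", "theta_a", "theta_Af", "theta_Ab", "theta_B",
                     "theta_C"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ParameterError(f"non-finite entries in {name}")

    @classmethod
    def zeros(cls, arch: CMCArchitecture, design: ConditionDesign,
              modulation: ModulationSpec) -> "CMCParameters":
        return cls(
            theta_Af=np.zeros(len(arch.forward_edges)),
            theta_Ab=np.zeros(len(arch.backward_edges)),
            theta_B=np.zeros((design.n_effects, modulation.n_modulated)),
            theta_C=np.zeros(arch.n_inputs),
        )


def _b_contribution(params: CMCParameters, modulation: ModulationSpec,
                    design: ConditionDesign, condition: int):
    """Additive log-space effect of condition ``condition`` on each gain set."""
    n_f = modulation.forward.size
    n_b = modulation.backward.size
    weights = design.btf[condition]  # (n_effects,)
    if params.theta_B.size == 0 or weights.size == 0:
        total = np.zeros(modulation.n_modulated)
    else:
        if params.theta_B.shape != (design.n_effects, modulation.n_modulated):
            raise ShapeError(
                f"theta_B shape {params.theta_B.shape} does not match "
                f"({design.n_effects}, {modulation.n_modulated})"
            )
        total = weights @ params.theta_B
    d_f = np.zeros(n_f)
    d_b = np.zeros(n_b)
    d_self = np.zeros(modulation.self_inhibition.shape)
    i = 0
    nf_mod = int(modulation.forward.sum())
    nb_mod = int(modulation.backward.sum())
    d_f[modulation.forward] = total[:nf_mod]
    i += nf_mod
    d_b[modulation.backward] = total[i:i + nb_mod]
    i += nb_mod
    d_self[modulation.self_inhibition] = total[i:]
    return d_f, d_b, d_self


def apply_condition_effects(params: CMCParameters, condition: int,
                            design: ConditionDesign,
                            modulation: ModulationSpec) -> CMCParameters:
    """Fold the condition-specific B effects into the base log-gains.

    Returns parameters whose theta_Af / theta_Ab / self-inhibition theta_a
    include the additive B effect for ``condition``; the baseline condition
    returns an identical copy.
    """
    if not 0 <= condition < design.n_conditions:
        raise ValidationError(f"condition index {condition} out of range")
    d_f, d_b, d_self = _b_contribution(params, modulation, design, condition)
    base_shift = params.self_shift if params.self_shift is not None else 0.0
    return replace(
        params,
        theta_Af=params.theta_Af + d_f,
        theta_Ab=params.theta_Ab + d_b,
        theta_B=np.zeros_like(params.theta_B),
        self_shift=base_shift + d_self,
    )


def effective_gain_arrays(params: CMCParameters, arch: CMCArchitecture,
                          design: ConditionDesign, condition: int,
                          modulation: ModulationSpec):
    """Positive effective gain arrays for one condition.

    Returns (kappa (4,), a_eff (R, 13), Af (R, R), Ab (R, R), C (R,)).
    Intrinsic gains are returned per region because condition effects on
    self-inhibition may be region-specific.
    """
    d_f, d_b, d_self = _b_contribution(params, modulation, design, condition)
    if params.self_shift is not None:
        d_self = d_self + params.self_shift
    R = arch.n_regions
    kappa = params.kappa_scale * np.exp(params.theta_kappa)
    a_base = params.intrinsic_scale * np.exp(params.theta_a)  # (13,)
    a_eff = np.tile(a_base, (R, 1))
    for p, k in enumerate(SELF_INDICES):
        a_eff[:, k] = params.intrinsic_scale[k] * np.exp(
            params.theta_a[k] + d_self[:, p]
        )
    Af = np.zeros((R, R))
    for e, (i, j) in enumerate(arch.forward_edges):
        Af[i, j] = np.exp(params.theta_Af[e] + d_f[e])
    Ab = np.zeros((R, R))
    for e, (i, j) in enumerate(arch.backward_edges):
        Ab[i, j] = np.exp(params.theta_Ab[e] + d_b[e])
    C = np.zeros(R)
    if params.theta_C.size != arch.n_inputs:
        raise ShapeError("theta_C length does not match number of input regions")
    C[arch.input_regions] = np.exp(params.theta_C)
    return kappa, a_eff, Af, Ab, C


def cmc_derivatives(state: np.ndarray, params: CMCParameters,
                    arch: CMCArchitecture, u: float, t: float = 0.0,
                    design: ConditionDesign | None = None,
                    condition: int = 0,
                    modulation: ModulationSpec | None = None):
    """Reference (numpy) evaluation of the state derivative.

    ``state`` is (R, 4, 2) holding (V, dV/dt) per region and population.
    Returns an array of the same shape.  Used for testing and as readable
    documentation of the jitted integrator's right-hand side.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (arch.n_regions, 4, 2):
        raise ShapeError(f"state must be (n_regions, 4, 2), got {state.shape}")
    if design is None:
        design = ConditionDesign(("baseline",), np.zeros((1, 0)))
    if modulation is None:
        modulation = ModulationSpec(
            np.zeros(len(arch.forward_edges), bool),
            np.zeros(len(arch.backward_edges), bool),
            np.zeros((arch.n_regions, 4), bool),
        )
    kappa, a_eff, Af, Ab, C = effective_gain_arrays(
        params, arch, design, condition, modulation
    )
    V = state[:, :, 0]
    W = state[:, :, 1]
    f = _forcing(V, params, a_eff, Af, Ab, C, float(u))
    dV = W
    dW = kappa**2 * (f - V) - 2.0 * kappa * W
    return np.stack([dV, dW], axis=-1)


def _forcing(V, params: CMCParameters, a_eff, Af, Ab, C, u):
    """Population forcing f per region; numpy mirror of the jitted kernel."""
    sig = firing_sigmoid(V, params.slope, params.threshold)
    R = V.shape[0]
    f = np.zeros((R, 4))
    for k, (src, dst, sign) in enumerate(INTRINSIC_TABLE):
        f[:, dst] += sign * a_eff[:, k] * sig[:, src]
    fwd = Af @ sig[:, 1]
    bwd = Ab @ sig[:, 3]
    es = params.extrinsic_scale
    f[:, 0] += es[0] * fwd + C * u
    f[:, 3] += es[1] * fwd
    f[:, 1] += es[2] * bwd
    f[:, 2] += es[3] * bwd
    return f


# ---------------------------------------------------------------------------
# ERP integration with afferent-component bookkeeping
# ---------------------------------------------------------------------------

#: component group labels used by the decomposed neuronal drives
GROUP_EXC = "excitatory"
GROUP_INH = "inhibitory"
GROUP_EXT = "extrinsic"
GROUP_INPUT = "input"


@dataclass
class ERPTrajectory:
    """Depolarisation time courses plus the signed afferent components.

    ``components`` maps (population index, component name) -> (T, R) series;
    ``component_groups`` maps the same keys to one of the group labels.
    The sum of a population's components equals the forcing term f used in
    the integration, evaluated on the output grid.
    """

    times: np.ndarray
    V: np.ndarray  # (T, R, 4)
    components: dict[tuple[int, str], np.ndarray]
    component_groups: dict[tuple[int, str], str]

    def forcing(self, population: int) -> np.ndarray:
        """Sum of stored afferent components for one population, (T, R)."""
        out = None
        for (p, _name), series in self.components.items():
            if p == population:
                out = series.copy() if out is None else out + series
        if out is None:
            out = np.zeros((len(self.times), self.V.shape[1]))
        return out


def integrate_erp(params: CMCParameters, arch: CMCArchitecture,
                  design: ConditionDesign, condition: int,
                  modulation: ModulationSpec,
                  t_max: float = 0.4, dt: float = 1e-3,
                  n_sub: int = 5) -> ERPTrajectory:
    """Integrate the microcircuit from rest over the peristimulus window.

    Fixed-step RK4 with ``n_sub`` substeps per output sample (the coupled
    oscillatory modes run at kappa*sqrt(a/4), i.e. several kHz at the prior
    gains, so the stability limit requires steps of ~0.1 ms even though the
    output grid is 1 ms).  Afferent components are evaluated on the output
    grid after integration so downstream presynaptic drives can be
    assembled without re-integrating.
    """
    if dt > 1e-3 + 1e-12:
        raise ValidationError("ERP output grid requires a step of at most 1 ms")
    kappa, a_eff, Af, Ab, C = effective_gain_arrays(
        params, arch, design, condition, modulation
    )
    n_steps = int(round(t_max / dt))
    times = np.arange(n_steps + 1) * dt
    t_half = np.arange(2 * n_steps * n_sub + 1) * (dt / (2.0 * n_sub))
    u_half = gaussian_input(t_half, params.input_onset, params.input_dispersion)
    R = arch.n_regions
    V = cmc_rk4(
        np.zeros((R, 4)), np.zeros((R, 4)), kappa, a_eff, Af, Ab, C,
        u_half, dt, n_steps, params.slope, params.threshold,
        params.extrinsic_scale, n_sub,
    )
    if not np.all(np.isfinite(V)):
        raise IntegrationError(
            "neuronal trajectory became non-finite; check the extrinsic and "
            "intrinsic gain parameters", block="neuronal",
        )
    components, groups = _afferent_components(V, params, a_eff, Af, Ab, C,
                                              gaussian_input(times, params.input_onset,
                                                             params.input_dispersion))
    return ERPTrajectory(times=times, V=V, components=components,
                         component_groups=groups)


def _afferent_components(V, params: CMCParameters, a_eff, Af, Ab, C, u):
    """Signed afferent terms per population, each stored separately.

    Intrinsic terms are grouped by their source population (excitatory from
    ss/sp/dp, inhibitory from ii) with self-inhibition always inhibitory;
    extrinsic terms are the A-weighted distal firing; the exogenous input is
    its own group.
    """
    sig = firing_sigmoid(V, params.slope, params.threshold)  # (T, R, 4)
    components: dict[tuple[int, str], np.ndarray] = {}
    groups: dict[tuple[int, str], str] = {}
    for k, (src, dst, sign) in enumerate(INTRINSIC_TABLE):
        name = INTRINSIC_NAMES[k]
        series = sign * a_eff[None, :, k] * sig[:, :, src]
        if src == dst:
            group = GROUP_INH
        elif src == POPULATIONS.index("ii"):
            group = GROUP_INH
        else:
            group = GROUP_EXC
        components[(dst, name)] = series
        groups[(dst, name)] = group
    fwd = sig[:, :, 1] @ Af.T  # (T, R)
    bwd = sig[:, :, 3] @ Ab.T
    es = params.extrinsic_scale
    for dst, series in ((0, es[0] * fwd), (3, es[1] * fwd),
                        (1, es[2] * bwd), (2, es[3] * bwd)):
        key = (dst, f"extrinsic->{POPULATIONS[dst]}")
        components[key] = series.copy()
        groups[key] = GROUP_EXT
    key = (0, "input")
    components[key] = C[None, :] * u[:, None]
    groups[key] = GROUP_INPUT
    return components, groups
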