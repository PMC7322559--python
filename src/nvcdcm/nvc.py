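"""Neurovascular coupling: drive mixtures and the factorial model space.

The regional neurovascular signal is a weighted sum of the neuronal drive
channels, either passed to the haemodynamics instantaneously (*direct*
form) or convolved with a second-order delay kernel

    f_nc(t) = (t / tau_nc) * exp(-t / tau_nc),   t >= 0

that models the kinetics of vasoactive-agent release (e.g. astrocytic
calcium); the prior expectation of the time constant tau_nc is 0.7 s.

Hypotheses about the coupling are encoded as a factorial model space over
four questions: presynaptic / postsynaptic / decomposed-presynaptic
parameterisation (Q1), inclusion of distal afferents (Q2), region-specific
versus shared weights (Q3), and direct versus delayed form (Q4) — sixteen
candidate models in all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .drives import DECOMPOSED_CHANNELS, POST_CHANNELS, PRE_CHANNELS, DriveSignal
from .errors import ParameterError, ShapeError, ValidationError

TAU_NC_SCALE = 0.7  # seconds; prior expectation of the delay time constant

PARAMETERISATIONS = ("pre", "post", "decomposed")
FORMS = ("direct", "delay")


@dataclass(frozen=True)
class NVCModelSpec:
    """One cell of the factorial neurovascular model space."""

    parameterisation: str  # pre | post | decomposed
    distal: str  # include | exclude | na
    region_specific: bool
    form: str  # direct | delay
    exclusion_mask: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)

    def __post_init__(self):
        if self.parameterisation not in PARAMETERISATIONS:
            raise ValidationError(f"unknown parameterisation {self.parameterisation!r}")
        if self.form not in FORMS:
            raise ValidationError(f"unknown form {self.form!r}")
        if self.parameterisation == "post":
            if self.distal != "na":
                raise ValidationError("postsynaptic models must set distal='na'")
        elif self.distal not in ("include", "exclude"):
            raise ValidationError("distal must be include/exclude for presynaptic models")
        if self.parameterisation == "decomposed" and self.region_specific:
            raise ValidationError("decomposed models share weights across regions")

    @property
    def channel_names(self) -> tuple[str, ...]:
        if self.parameterisation == "post":
            return POST_CHANNELS
        if self.parameterisation == "pre":
            if self.distal == "include":
                return PRE_CHANNELS
            return PRE_CHANNELS[:4]
        if self.distal == "include":
            return DECOMPOSED_CHANNELS
        return DECOMPOSED_CHANNELS[:2]

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    @property
    def option_string(self) -> tuple[str, str, str]:
        """Canonical option triple {pre|post|de, s|d, exc|int|na}."""
        first = {"pre": "pre", "post": "post", "decomposed": "de"}[self.parameterisation]
        second = "d" if self.region_specific else "s"
        third = {"include": "exc", "exclude": "int", "na": "na"}[self.distal]
        return (first, second, third)

    def beta_shape(self, n_regions: int) -> tuple[int, ...]:
        if self.region_specific:
            return (self.n_channels, n_regions)
        return (self.n_channels,)


@dataclass
class NVCParameters:
    """Coupling weights and (for delayed models) the delay log-scaling."""

    beta: np.ndarray
    theta_tau_nc: float = 0.0

    def __post_init__(self):
        self.beta = np.asarray(self.beta, float)

    @property
    def tau_nc(self) -> float:
        return TAU_NC_SCALE * float(np.exp(self.theta_tau_nc))


def delay_kernel(t, tau_nc: float):
    """Second-order delay impulse response (t/tau) exp(-t/tau), 0 for t < 0."""
    if tau_nc <= 0:
        raise ParameterError(f"tau_nc must be positive, got {tau_nc}")
    t = np.asarray(t, dtype=float)
    out = np.where(t >= 0, (t / tau_nc) * np.exp(-np.clip(t, 0, None) / tau_nc), 0.0)
    return out if out.ndim else float(out)


def _select_channels(z: np.ndarray, drive_channels, spec: NVCModelSpec) -> np.ndarray:
    wanted = spec.channel_names
    names = tuple(drive_channels)
    try:
        idx = [names.index(w) for w in wanted]
    except ValueError as exc:
        raise ValidationError(
            f"drive channels {names} do not provide the channels {wanted} "
            f"required by the model spec"
        ) from exc
    return z[:, idx, :]


def combine_drives(z: np.ndarray, drive_channels, params: NVCParameters,
                   spec: NVCModelSpec, dt: float,
                   truncation: float = 8.0) -> np.ndarray:
    """Mix drive channels into the per-region neurovascular signal.

    ``z`` is (regions, channels, microtime).  Direct form: weighted sum per
    region.  Delay form: the weighted sum convolved causally with the delay
    kernel (discrete convolution scaled by dt, kernel support truncated at
    ``truncation`` * tau_nc).  Shared-weight specs broadcast one weight
    vector over regions.
    """
    z = np.asarray(z, float)
    if z.ndim != 3:
        raise ShapeError("drive series must be (regions, channels, time)")
    zsel = _select_channels(z, drive_channels, spec)
    R = z.shape[0]
    beta = params.beta
    if beta.shape != spec.beta_shape(R):
        raise ShapeError(
            f"beta shape {beta.shape} does not match spec shape {spec.beta_shape(R)}"
        )
    if spec.region_specific:
        zj = np.einsum("rct,cr->rt", zsel, beta)
    else:
        zj = np.einsum("rct,c->rt", zsel, beta)
    if spec.form == "delay":
        tau = params.tau_nc
        kernel = _discrete_delay_kernel(tau, dt, truncation)
        out = np.empty_like(zj)
        for r in range(R):
            out[r] = np.convolve(zj[r], kernel)[: zj.shape[1]]
        zj = out
    return zj


def _discrete_delay_kernel(tau: float, dt: float, truncation: float) -> np.ndarray:
    """Kernel weights for the causal discrete convolution.

    For a well-resolved kernel (tau >= 2 dt) the weights are point samples
    scaled by dt; when the kernel is narrower than the grid, point samples
    lose its mass, so the exact integral over each bin is used instead
    (cumulative integral of (t/tau) e^(-t/tau) is tau (1 - e^(-t/tau)
    (1 + t/tau))).  Either way the total mass approaches tau, the literal
    (unnormalised) kernel area.
    """
    n_k = max(int(np.ceil(truncation * tau / dt)), 2)
    if tau >= 2.0 * dt:
        return delay_kernel(np.arange(n_k) * dt, tau) * dt
    edges = np.arange(n_k + 1) * dt
    cumulative = tau * (1.0 - np.exp(-edges / tau) * (1.0 + edges / tau))
    return np.diff(cumulative)


def combine_drive_signal(signal_z: np.ndarray, template: DriveSignal,
                         params: NVCParameters, spec: NVCModelSpec) -> np.ndarray:
    """Convenience wrapper taking channel names and dt from a DriveSignal."""
    return combine_drives(signal_z, template.channel_names, params, spec,
                          dt=template.dt)


# ---------------------------------------------------------------------------
# model space
# ---------------------------------------------------------------------------

def enumerate_model_space(exclusion_mask=(1.0, 1.0, 1.0, 1.0)) -> list[NVCModelSpec]:
    """The sixteen-model factorial space, in canonical row order.

    Rows 1-8 are direct, 9-16 delayed; within each half: presynaptic with
    distal included/excluded x region-specific yes/no (rows 1-4), post-
    synaptic region-specific yes/no (5-6), decomposed with distal
    included/excluded (7-8).
    """
    mask = tuple(float(x) for x in exclusion_mask)
    half = [
        ("pre", "include", True),
        ("pre", "exclude", True),
        ("pre", "include", False),
        ("pre", "exclude", False),
        ("post", "na", True),
        ("post", "na", False),
        ("decomposed", "include", False),
        ("decomposed", "exclude", False),
    ]
    specs = []
    for form in FORMS:
        for parameterisation, distal, region_specific in half:
            specs.append(NVCModelSpec(parameterisation, distal, region_specific,
                                      form, mask))
    return specs


FAMILY_FACTORS = ("Q1", "Q2", "Q3", "Q4")


def family_partition(specs: list[NVCModelSpec], factor: str) -> dict[str, list[int]]:
    """Disjoint model families for one factor of the design.

    Q1 partitions all models by parameterisation; Q2 partitions the
    presynaptic/decomposed models by distal inclusion (postsynaptic models
    are not applicable); Q3 by region-specificity; Q4 by direct/delay.
    """
    if factor not in FAMILY_FACTORS:
        raise ValidationError(f"unknown family factor {factor!r}")
    part: dict[str, list[int]] = {}
    for i, s in enumerate(specs):
        if factor == "Q1":
            key = s.parameterisation
        elif factor == "Q2":
            if s.distal == "na":
                continue
            key = "distal" if s.distal == "include" else "local"
        elif factor == "Q3":
            key = "region-specific" if s.region_specific else "shared"
        else:
            key = s.form
        part.setdefault(key, []).append(i)
    return part
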