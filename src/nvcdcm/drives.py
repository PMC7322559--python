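"""Neuronal drive functions: condition templates and event-train expansion.

After the electrophysiological model has been fitted, the microcircuit is
integrated at the posterior parameter means for every experimental
condition, yielding stereotyped per-trial response templates over the
peristimulus window.  Templates come in three parameterisations:

``post``
    the population depolarisations V_i(t) themselves;
``pre``
    the signed presynaptic afferent components of each population, with the
    local (intrinsic + exogenous-input) terms summed per population and the
    extrinsic (distal, A-weighted) terms kept as separate channels;
``decomposed``
    presynaptic components pooled into excitatory / inhibitory / extrinsic
    group channels.

Templates are resampled from the millisecond integration grid to the fMRI
microtime grid by integral-preserving bin averaging, then shifted to each
event onset and summed (linear superposition) to produce the region x
channel drive series that enters neurovascular coupling.  An exclusion mask
O over the four populations zeroes the corresponding channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import cmc
from .errors import ShapeError, ValidationError

SIGNAL_TYPES = ("pre", "post", "decomposed")

#: channel names per signal type; "_ext" channels carry the distal
#: (extrinsic) afferents and are dropped by local-only coupling models
PRE_CHANNELS = ("ss", "sp", "ii", "dp", "ss_ext", "sp_ext", "ii_ext", "dp_ext")
POST_CHANNELS = ("ss", "sp", "ii", "dp")
DECOMPOSED_CHANNELS = ("excitatory", "inhibitory", "extrinsic")

#: conventional order of the exclusion vector at the command line:
#: (sp, ii, excitatory interneurons ~ ss, dp)
O_VECTOR_ORDER = ("sp", "ii", "ss", "dp")


def exclusion_from_o_vector(o_vector) -> np.ndarray:
    """Convert an O-vector in the conventional (sp, ii, ss, dp) order to
    the canonical (ss, sp, ii, dp) population mask."""
    o = np.asarray(o_vector, float).ravel()
    if o.shape != (4,) or not np.all(np.isin(o, (0.0, 1.0))):
        raise ValidationError("O vector must be four entries of 0/1")
    mask = np.empty(4)
    for printed_idx, pop in enumerate(O_VECTOR_ORDER):
        mask[cmc.POPULATIONS.index(pop)] = o[printed_idx]
    return mask


@dataclass
class EventSchedule:
    """Event onsets per condition plus the fMRI timing grid."""

    condition_names: tuple[str, ...]
    onsets: dict[str, np.ndarray]
    duration: float
    tr: float
    dt: float = 0.05

    def __post_init__(self):
        self.onsets = {c: np.sort(np.asarray(self.onsets.get(c, []), float))
                       for c in self.condition_names}
        for c, t in self.onsets.items():
            if t.size and (t.min() < 0 or t.max() >= self.duration):
                raise ValidationError(f"onsets for {c} fall outside [0, duration)")
        ratio = self.tr / self.dt
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValidationError("microtime dt must divide the TR")

    @property
    def n_microtime(self) -> int:
        return int(round(self.duration / self.dt))

    @property
    def n_scans(self) -> int:
        return int(round(self.duration / self.tr))

    def counts(self) -> dict[str, int]:
        return {c: int(self.onsets[c].size) for c in self.condition_names}


@dataclass
class DriveSignal:
    """Condition-specific drive templates on a shared grid.

    ``values`` is (n_conditions, n_regions, n_channels, n_samples); ``scale``
    records the single normalisation constant divided out of all templates
    (relative amplitudes across regions, channels and conditions are
    untouched).
    """

    signal_type: str
    condition_names: tuple[str, ...]
    channel_names: tuple[str, ...]
    values: np.ndarray
    dt: float
    exclusion_mask: np.ndarray = field(default_factory=lambda: np.ones(4))
    scale: float = 1.0

    def __post_init__(self):
        if self.signal_type not in SIGNAL_TYPES:
            raise ValidationError(f"unknown signal type {self.signal_type!r}")
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 4:
            raise ShapeError("drive values must be (cond, region, channel, time)")
        if self.values.shape[2] != len(self.channel_names):
            raise ShapeError("channel axis does not match channel names")

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


def _bin_average(series: np.ndarray, n_fine_per_coarse: int) -> np.ndarray:
    """Integral-preserving resampling along the last axis."""
    n = series.shape[-1]
    n_bins = n // n_fine_per_coarse
    trimmed = series[..., : n_bins * n_fine_per_coarse]
    shape = trimmed.shape[:-1] + (n_bins, n_fine_per_coarse)
    return trimmed.reshape(shape).mean(axis=-1)


def compute_condition_drives(posterior_params: cmc.CMCParameters,
                             arch: cmc.CMCArchitecture,
                             design: cmc.ConditionDesign,
                             signal_type: str = "pre",
                             exclusion_mask=None,
                             modulation: cmc.ModulationSpec | None = None,
                             dt_out: float = 0.05,
                             t_max: float = 0.4,
                             dt_fine: float = 1e-3,
                             normalise: bool = True) -> DriveSignal:
    """Per-trial drive templates from the fitted neuronal model.

    Integrates the microcircuit at the (posterior mean) parameters for each
    condition; assembles channels according to ``signal_type``; zeroes
    excluded populations; resamples to the microtime grid; and divides all
    templates by one shared constant (the global peak magnitude) so that the
    coupling weights act on order-one inputs.
    """
    if signal_type not in SIGNAL_TYPES:
        raise ValidationError(f"unknown signal type {signal_type!r}")
    if modulation is None:
        modulation = cmc.ModulationSpec.all_extrinsic_and_self(arch)
    mask = np.ones(4) if exclusion_mask is None else np.asarray(exclusion_mask, float)
    if mask.shape != (4,):
        raise ShapeError("exclusion mask must have four entries")

    if signal_type == "pre":
        channels = PRE_CHANNELS
    elif signal_type == "post":
        channels = POST_CHANNELS
    else:
        channels = DECOMPOSED_CHANNELS

    per_cond = []
    for c in range(design.n_conditions):
        traj = cmc.integrate_erp(posterior_params, arch, design, c, modulation,
                                 t_max=t_max, dt=dt_fine)
        T = len(traj.times)
        R = arch.n_regions
        out = np.zeros((R, len(channels), T))
        if signal_type == "post":
            for p in range(4):
                out[:, p, :] = mask[p] * traj.V[:, :, p].T
        else:
            local = np.zeros((T, R, 4))
            extrinsic = np.zeros((T, R, 4))
            groups = np.zeros((T, R, 3))  # exc, inh, ext
            for (p, name), series in traj.components.items():
                group = traj.component_groups[(p, name)]
                if group == cmc.GROUP_EXT:
                    extrinsic[:, :, p] += series
                    groups[:, :, 2] += mask[p] * series
                else:
                    local[:, :, p] += series
                    gi = 0 if group in (cmc.GROUP_EXC, cmc.GROUP_INPUT) else 1
                    groups[:, :, gi] += mask[p] * series
            if signal_type == "pre":
                for p in range(4):
                    out[:, p, :] = mask[p] * local[:, :, p].T
                    out[:, 4 + p, :] = mask[p] * extrinsic[:, :, p].T
            else:
                for g in range(3):
                    out[:, g, :] = groups[:, :, g].T
        per_cond.append(out)

    values = np.stack(per_cond, axis=0)  # (cond, R, ch, T_fine)
    scale = 1.0
    if normalise:
        # the constant comes from the fine-grid templates so it does not
        # depend on the microtime resolution chosen downstream
        peak = float(np.max(np.abs(values)))
        if peak > 0:
            scale = peak
            values = values / peak
    n_per = int(round(dt_out / dt_fine))
    values = _bin_average(values, n_per)
    return DriveSignal(signal_type=signal_type,
                       condition_names=tuple(design.condition_names),
                       channel_names=channels, values=values, dt=dt_out,
                       exclusion_mask=mask, scale=scale)


def shift_and_sum(template: DriveSignal, schedule: EventSchedule) -> np.ndarray:
    """Superpose condition templates at their event onsets.

    Returns the region x channel x microtime drive series; overlapping
    events add linearly.
    """
    if abs(template.dt - schedule.dt) > 1e-12:
        raise ValidationError("template and schedule must share the microtime step")
    n_cond, R, C, Tt = template.values.shape
    T = schedule.n_microtime
    z = np.zeros((R, C, T))
    for ci, cname in enumerate(template.condition_names):
        if cname not in schedule.onsets:
            continue
        for t0 in schedule.onsets[cname]:
            if t0 >= schedule.duration:
                raise ValidationError(f"onset {t0} beyond run duration")
            i0 = int(round(t0 / schedule.dt))
            i1 = min(i0 + Tt, T)
            if i1 > i0:
                z[:, :, i0:i1] += template.values[ci, :, :, : i1 - i0]
    return z
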