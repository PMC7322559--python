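"""Region-wise fMRI model inversion over the neurovascular model space.

Given neuronal drive templates (from the fitted electrophysiological model),
an event schedule and region BOLD time series, each candidate neurovascular
model defines a generator

    theta -> combine drives (beta, optional delay) -> Balloon -> BOLD at TR

whose parameters are estimated by variational Laplace with one noise
log-precision per region.  Free blocks: coupling weights beta (prior
N(0, 1/16)), the delay log-scaling theta_tau_nc for delayed models (prior
N(0, 1/16)) and per-region haemodynamic log-scalings theta_eta, theta_tau_h,
theta_epsilon (priors N(0, 1/256)); chi, alpha and E0 stay fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dct

from . import nvc
from .drives import DriveSignal, EventSchedule, shift_and_sum
from .errors import ShapeError, ValidationError
from .haemo import HaemoParameters, predict_bold
from .inference import InversionResult, variational_laplace
from .parameters import BlockLayout, PriorSpec


def default_fmri_priors(spec: nvc.NVCModelSpec, n_regions: int,
                        n_confounds: int = 0) -> PriorSpec:
    prior = PriorSpec()
    prior.add("beta", np.zeros(spec.beta_shape(n_regions)), 1.0 / 16)
    prior.add("theta_tau_nc", 0.0, 1.0 / 16 if spec.form == "delay" else 0.0)
    prior.add("theta_eta", np.zeros(n_regions), 1.0 / 256)
    prior.add("theta_tau_h", np.zeros(n_regions), 1.0 / 256)
    prior.add("theta_epsilon", np.zeros(n_regions), 1.0 / 256)
    prior.add("theta_chi", np.zeros(1), 0.0)
    prior.add("theta_alpha", np.zeros(1), 0.0)
    prior.add("theta_e0", np.zeros(1), 0.0)
    if n_confounds:
        prior.add("confounds", np.zeros((n_confounds, n_regions)), 1.0)
    return prior


def haemo_params_from_blocks(blocks: dict[str, np.ndarray]) -> HaemoParameters:
    return HaemoParameters(
        theta_eta=blocks["theta_eta"],
        theta_chi=blocks["theta_chi"],
        theta_tau_h=blocks["theta_tau_h"],
        theta_alpha=blocks["theta_alpha"],
        theta_epsilon=blocks["theta_epsilon"],
        theta_e0=blocks["theta_e0"],
    )


def dct_confounds(n_scans: int, n_confounds: int) -> np.ndarray:
    """Discrete-cosine drift regressors, (n_scans, n_confounds), unit norm."""
    if n_confounds == 0:
        return np.zeros((n_scans, 0))
    basis = dct(np.eye(n_scans), axis=0, norm="ortho")[:, 1:n_confounds + 1]
    return basis


def make_bold_generator(template: DriveSignal, schedule: EventSchedule,
                        spec: nvc.NVCModelSpec, layout: BlockLayout,
                        n_regions: int, n_confounds: int = 0):
    """Forward map: free vector -> flattened (scan-major per region) BOLD."""
    z_channels = shift_and_sum(template, schedule)  # (R, C, T)
    confounds = dct_confounds(schedule.n_scans, n_confounds)

    def generator(free_vector: np.ndarray) -> np.ndarray:
        blocks = layout.to_blocks(free_vector)
        params = nvc.NVCParameters(beta=blocks["beta"],
                                   theta_tau_nc=float(blocks["theta_tau_nc"].ravel()[0]))
        zj = nvc.combine_drives(z_channels, template.channel_names, params,
                                spec, dt=schedule.dt)
        hp = haemo_params_from_blocks(blocks)
        y = predict_bold(zj, hp, dt=schedule.dt, tr=schedule.tr)  # (scans, R)
        if n_confounds:
            y = y + confounds @ blocks["confounds"]
        return y.T.ravel()  # region-major

    return generator


@dataclass
class FMRIInversion:
    """Posterior over one neurovascular model plus fit diagnostics."""

    spec: nvc.NVCModelSpec
    result: InversionResult
    layout: BlockLayout
    n_regions: int

    @property
    def free_energy(self) -> float:
        return self.result.free_energy

    def posterior_blocks(self) -> dict[str, np.ndarray]:
        return self.layout.to_blocks(self.result.posterior.mean)

    def beta_posterior(self):
        """Posterior mean and covariance of the coupling weights."""
        idx = self.layout.free_indices("beta")
        mean = self.result.posterior.mean[idx]
        cov = self.result.posterior.cov[np.ix_(idx, idx)]
        return mean, cov

    def predicted_bold(self, template: DriveSignal,
                       schedule: EventSchedule, n_confounds: int = 0) -> np.ndarray:
        gen = make_bold_generator(template, schedule, self.spec, self.layout,
                                  self.n_regions, n_confounds)
        flat = gen(self.result.posterior.mean)
        return flat.reshape(self.n_regions, -1).T

    def explained_variance(self, bold: np.ndarray, template: DriveSignal,
                           schedule: EventSchedule) -> np.ndarray:
        """Per-region explained variance (percent) of the posterior fit."""
        pred = self.predicted_bold(template, schedule)
        resid = bold - pred
        total = np.sum((bold - bold.mean(axis=0)) ** 2, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            ev = 100.0 * (1.0 - np.sum(resid**2, axis=0) / total)
        return ev


def invert_fmri(bold: np.ndarray, template: DriveSignal,
                schedule: EventSchedule, spec: nvc.NVCModelSpec,
                priors: PriorSpec | None = None, n_confounds: int = 0,
                max_iter: int = 64, tol: float = 0.01,
                noise_hyperprior: tuple[float, float] = (0.0, 64.0),
                n_starts: int = 8, verbose: bool = False) -> FMRIInversion:
    """Fit one neurovascular/haemodynamic model to region BOLD series.

    ``bold`` is (n_scans, n_regions), in the same fractional units as the
    observation equation.  Each region forms its own noise stream.
    """
    bold = np.asarray(bold, float)
    if bold.ndim != 2:
        raise ShapeError("BOLD data must be (n_scans, n_regions)")
    n_scans, R = bold.shape
    if n_scans != schedule.n_scans:
        raise ValidationError(
            f"BOLD has {n_scans} scans but the schedule implies {schedule.n_scans}"
        )
    if R != template.n_regions:
        raise ShapeError("BOLD regions do not match drive template regions")
    if priors is None:
        priors = default_fmri_priors(spec, R, n_confounds)
    layout = BlockLayout(priors)
    generator = make_bold_generator(template, schedule, spec, layout, R,
                                    n_confounds)
    data = bold.T.ravel()
    streams = [np.arange(r * n_scans, (r + 1) * n_scans) for r in range(R)]
    result = variational_laplace(
        generator, data,
        prior_mean=layout.free_means(), prior_variance=layout.free_variances(),
        noise_hyperpriors=[noise_hyperprior] * R, streams=streams,
        max_iter=max_iter, tol=tol, labels=layout.labels, n_starts=n_starts,
        verbose=verbose,
    )
    return FMRIInversion(spec=spec, result=result, layout=layout, n_regions=R)


def fit_model_space(bold: np.ndarray, templates: dict[str, DriveSignal],
                    schedule: EventSchedule,
                    specs: list[nvc.NVCModelSpec] | None = None,
                    **kwargs) -> list[FMRIInversion]:
    """Invert every candidate model; returns fits in model-space order.

    ``templates`` maps each parameterisation ('pre', 'post', 'decomposed')
    to its drive template; only the parameterisations used by ``specs`` are
    required.
    """
    if specs is None:
        specs = nvc.enumerate_model_space()
    fits = []
    for spec in specs:
        if spec.parameterisation not in templates:
            raise ValidationError(
                f"no drive template supplied for {spec.parameterisation!r}"
            )
        fits.append(invert_fmri(bold, templates[spec.parameterisation],
                                schedule, spec, **kwargs))
    return fits
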