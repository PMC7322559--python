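"""Electromagnetic observation model and ERP model inversion.

Sensor data are modelled as a linear mixture of the per-region population
depolarisations: each region's populations are combined by a contribution
vector Psi, scaled by a spatial-basis expansion with coefficients Theta, and
projected to the sensors through a gain (lead-field) matrix.  Real head-model
lead fields are out of scope: gain matrices are user-supplied or synthesised
with seeded random orthonormal columns.

Inversion fits the composed generator (microcircuit integration -> sensor
projection -> principal-mode feature reduction) to observed event-related
responses with variational Laplace.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import cmc
from .errors import ShapeError, ValidationError
from .inference import InversionResult, variational_laplace
from .parameters import BlockLayout, PriorSpec


@dataclass
class GainModel:
    """Gain matrix, spatial basis and population contribution vector.

    ``gain`` is sensors x regions (one column per source); ``spatial_basis``
    is regions x n basis patterns with coefficients ``theta`` of the same
    shape; ``psi`` weights the four populations.  The per-region scalar
    applied to neuronal activity is sum_n basis[r, n] * theta[r, n].
    """

    gain: np.ndarray
    spatial_basis: np.ndarray | None = None
    theta: np.ndarray | None = None
    psi: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0, 0.0]))

    def __post_init__(self):
        self.gain = np.asarray(self.gain, dtype=float)
        if self.gain.ndim != 2:
            raise ShapeError("gain must be a sensors x regions matrix")
        R = self.gain.shape[1]
        if self.spatial_basis is None:
            self.spatial_basis = np.ones((R, 1))
        self.spatial_basis = np.asarray(self.spatial_basis, dtype=float)
        if self.theta is None:
            self.theta = np.ones_like(self.spatial_basis)
        self.theta = np.asarray(self.theta, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        if self.spatial_basis.shape[0] != R or self.theta.shape != self.spatial_basis.shape:
            raise ShapeError("spatial basis/theta must be regions x n_basis")
        if self.spatial_basis.shape[1] < 1:
            raise ValidationError("need at least one spatial basis function")
        if self.psi.shape != (4,):
            raise ShapeError("psi must have one entry per population")

    @property
    def n_sensors(self) -> int:
        return self.gain.shape[0]

    @property
    def n_regions(self) -> int:
        return self.gain.shape[1]

    @classmethod
    def synthetic(cls, n_sensors: int, n_regions: int, seed: int = 0,
                  psi=None) -> "GainModel":
        """Random lead field with near-orthonormal columns (seeded)."""
        rng = np.random.default_rng(seed)
        raw = rng.standard_normal((n_sensors, n_regions))
        q, _ = np.linalg.qr(raw)
        kwargs = {} if psi is None else {"psi": np.asarray(psi, float)}
        return cls(gain=q[:, :n_regions], **kwargs)


@dataclass
class ERPDataset:
    """Per-condition time x sensor matrices on a shared grid."""

    data: dict[str, np.ndarray]
    sample_interval: float
    condition_names: tuple[str, ...]
    noise_sd: float | None = None  # nominal simulation noise, when known

    def __post_init__(self):
        shapes = {self.data[c].shape for c in self.condition_names}
        if len(shapes) != 1:
            raise ShapeError("all conditions must share the time/sensor grid")

    @property
    def n_samples(self) -> int:
        return self.data[self.condition_names[0]].shape[0]

    @property
    def n_sensors(self) -> int:
        return self.data[self.condition_names[0]].shape[1]

    def stacked(self) -> np.ndarray:
        """Conditions stacked along time, (n_cond * T, sensors)."""
        return np.vstack([self.data[c] for c in self.condition_names])


def predict_sensors(trajectory: np.ndarray, gain_model: GainModel) -> np.ndarray:
    """Project population depolarisations (T, R, 4) to sensors (T, S).

    Linear in the contribution vector, the basis coefficients and the
    trajectory: y(t) = sum_K gain[:, K] * (basis_K . theta_K) * (psi . V_K(t)).
    """
    trajectory = np.asarray(trajectory, dtype=float)
    if trajectory.ndim != 3 or trajectory.shape[1] != gain_model.n_regions:
        raise ShapeError(
            f"trajectory shape {trajectory.shape} does not match "
            f"{gain_model.n_regions} gain columns"
        )
    mixed = trajectory @ gain_model.psi  # (T, R)
    region_scale = np.sum(gain_model.spatial_basis * gain_model.theta, axis=1)
    return (mixed * region_scale) @ gain_model.gain.T


@dataclass
class FeatureProjection:
    """Principal-mode projection shared by data and model predictions."""

    components: np.ndarray  # sensors x n_modes, orthonormal columns
    singular_values: np.ndarray

    @property
    def n_modes(self) -> int:
        return self.components.shape[1]

    def project(self, y: np.ndarray) -> np.ndarray:
        """Map time x sensor data into the mode space (time x n_modes)."""
        return np.asarray(y, float) @ self.components

    def sensor_projector(self) -> np.ndarray:
        """Idempotent sensors x sensors projector onto the retained modes."""
        return self.components @ self.components.T

    def captured_variance(self) -> float:
        s2 = self.singular_values**2
        return float(s2[: self.n_modes].sum() / s2.sum())


def project_features(observed: np.ndarray, n_modes: int) -> FeatureProjection:
    """Singular-value feature reduction computed from the observed data.

    The projection is computed once from the data (never refreshed from model
    predictions) and applied identically to both, so predictions and data
    share one feature space.
    """
    observed = np.asarray(observed, dtype=float)
    if n_modes > min(observed.shape):
        raise ValidationError(
            f"n_modes={n_modes} exceeds the rank bound {min(observed.shape)}"
        )
    _, s, vt = np.linalg.svd(observed, full_matrices=False)
    return FeatureProjection(components=vt[:n_modes].T, singular_values=s)


# ---------------------------------------------------------------------------
# ERP inversion
# ---------------------------------------------------------------------------

def default_erp_priors(arch: cmc.CMCArchitecture, design: cmc.ConditionDesign,
                       modulation: cmc.ModulationSpec,
                       gain_model: GainModel,
                       free_gain: bool = False) -> PriorSpec:
    """Standard shrinkage priors for the neuronal and observation blocks.

    Log-scalings of extrinsic gains and condition effects have variance 1/8,
    the input gain 1/32; rate constants and intrinsic gains are fixed (zero
    variance).  The input bump onset has prior 0.070 +/- 0.016 s and its
    dispersion is fixed at 0.016 s by default.
    """
    prior = PriorSpec()
    prior.add("theta_kappa", np.zeros(4), 0.0)
    prior.add("theta_a", np.zeros(cmc.N_INTRINSIC), 0.0)
    prior.add("theta_Af", np.zeros(len(arch.forward_edges)), 1.0 / 8)
    prior.add("theta_Ab", np.zeros(len(arch.backward_edges)), 1.0 / 8)
    prior.add("theta_B", np.zeros((design.n_effects, modulation.n_modulated)), 1.0 / 8)
    prior.add("theta_C", np.zeros(arch.n_inputs), 1.0 / 32)
    prior.add("input_onset", 0.070, 0.016**2)
    prior.add("input_dispersion", 0.016, 0.0)
    prior.add("psi", gain_model.psi, 1.0 / 16)
    prior.add("theta_gain", gain_model.theta.ravel(),
              1.0 / 16 if free_gain else 0.0)
    return prior


def params_from_blocks(blocks: dict[str, np.ndarray]) -> cmc.CMCParameters:
    """Rebuild CMC parameters from a block dictionary (inverse of packing)."""
    return cmc.CMCParameters(
        theta_kappa=blocks["theta_kappa"],
        theta_a=blocks["theta_a"],
        theta_Af=blocks["theta_Af"],
        theta_Ab=blocks["theta_Ab"],
        theta_B=blocks["theta_B"],
        theta_C=blocks["theta_C"],
        input_onset=float(np.ravel(blocks["input_onset"])[0]),
        input_dispersion=float(np.ravel(blocks["input_dispersion"])[0]),
    )


@dataclass
class ERPInversion:
    """Posterior over neuronal + observation parameters with free energy."""

    result: InversionResult
    layout: BlockLayout
    projection: FeatureProjection
    arch: cmc.CMCArchitecture
    design: cmc.ConditionDesign
    modulation: cmc.ModulationSpec
    gain_model: GainModel

    @property
    def free_energy(self) -> float:
        return self.result.free_energy

    def posterior_blocks(self) -> dict[str, np.ndarray]:
        return self.layout.to_blocks(self.result.posterior.mean)

    def posterior_params(self) -> cmc.CMCParameters:
        return params_from_blocks(self.posterior_blocks())

    def posterior_gain_model(self) -> GainModel:
        blocks = self.posterior_blocks()
        return replace(
            self.gain_model,
            psi=blocks["psi"],
            theta=blocks["theta_gain"].reshape(self.gain_model.theta.shape),
        )


def make_erp_generator(arch, design, modulation, gain_model, layout,
                       projection, n_samples: int, dt: float = 1e-3):
    """Forward map: free parameter vector -> flattened feature prediction."""

    t_max = (n_samples - 1) * dt

    def generator(free_vector: np.ndarray) -> np.ndarray:
        blocks = layout.to_blocks(free_vector)
        params = params_from_blocks(blocks)
        gm = replace(
            gain_model,
            psi=blocks["psi"],
            theta=blocks["theta_gain"].reshape(gain_model.theta.shape),
        )
        feats = []
        for c in range(design.n_conditions):
            traj = cmc.integrate_erp(params, arch, design, c, modulation,
                                     t_max=t_max, dt=dt)
            y = predict_sensors(traj.V, gm)
            feats.append(projection.project(y).ravel())
        return np.concatenate(feats)

    return generator


def invert_erp(dataset: ERPDataset, arch: cmc.CMCArchitecture,
               design: cmc.ConditionDesign, gain_model: GainModel,
               modulation: cmc.ModulationSpec | None = None,
               priors: PriorSpec | None = None, n_modes: int = 8,
               max_iter: int = 64, tol: float = 0.01,
               noise_hyperprior: tuple[float, float] = (0.0, 64.0),
               n_starts: int = 16, verbose: bool = False) -> ERPInversion:
    """Fit the microcircuit + observation model to event-related data.

    The observed per-condition responses are reduced to their principal
    sensor modes; the same projection is applied to model predictions, and
    the posterior over all free parameter blocks is obtained by variational
    Laplace with a single i.i.d. noise precision hyperparameter.
    """
    if tuple(dataset.condition_names) != tuple(design.condition_names):
        raise ValidationError("dataset and design condition names differ")
    if modulation is None:
        modulation = cmc.ModulationSpec.all_extrinsic_and_self(arch)
    if priors is None:
        priors = default_erp_priors(arch, design, modulation, gain_model)
    layout = BlockLayout(priors)
    n_modes = min(n_modes, dataset.n_sensors, dataset.n_samples)
    projection = project_features(dataset.stacked(), n_modes)
    generator = make_erp_generator(
        arch, design, modulation, gain_model, layout, projection,
        dataset.n_samples, dt=dataset.sample_interval,
    )
    data = np.concatenate(
        [projection.project(dataset.data[c]).ravel() for c in design.condition_names]
    )
    result = variational_laplace(
        generator, data,
        prior_mean=layout.free_means(), prior_variance=layout.free_variances(),
        noise_hyperpriors=[noise_hyperprior], max_iter=max_iter, tol=tol,
        labels=layout.labels, n_starts=n_starts, verbose=verbose,
    )
    return ERPInversion(result=result, layout=layout, projection=projection,
                        arch=arch, design=design, modulation=modulation,
                        gain_model=gain_model)
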