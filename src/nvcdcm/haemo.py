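"""Balloon haemodynamics and the BOLD observation equation.

A regional neurovascular signal z(t) drives a vasodilatory signal h_s via a
damped second-order filter, which induces blood inflow h_in; inflow feeds a
venous balloon whose volume h_v and deoxyhaemoglobin content h_q evolve as

    dh_s  = z - eta h_s - chi (h_in - 1)
    dh_in = h_s
    dh_v  = (h_in - h_v^(1/alpha)) / tau_h
    dh_q  = (h_in (1 - (1 - E0)^(1/h_in)) / E0 - h_v^(1/alpha) h_q / h_v) / tau_h

with all states dimensionless relative to rest (0, 1, 1, 1).  The measured
BOLD signal mixes volume and deoxyhaemoglobin:

    y = V0 (k1 (1 - h_q) + k2 (1 - h_q / h_v) + k3 (1 - h_v)),

with k1 = 6.9 E0, k2 = eps E0, k3 = 1 - eps.  Rate-type parameters are
log-normal around their canonical prior scales (eta 0.64/s, chi 0.32/s,
tau_h 2.0 s, alpha 0.32, eps 1.0, E0 0.40, V0 0.08); chi, alpha and E0 are
conventionally fixed.

Integration uses fixed-step RK4 on log-states for (h_in, h_v, h_q) so the
positive states remain positive by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._integrators import balloon_rk4
from .errors import IntegrationError, ParameterError, ShapeError

#: prior scales of the haemodynamic parameters
ETA_SCALE = 0.64
CHI_SCALE = 0.32
TAU_H_SCALE = 2.00
ALPHA_SCALE = 0.32
EPSILON_SCALE = 1.00
E0_SCALE = 0.40
V0_DEFAULT = 0.08


@dataclass
class HaemoParameters:
    """Log-scalings of the haemodynamic constants, possibly per region."""

    theta_eta: np.ndarray = field(default_factory=lambda: np.zeros(1))
    theta_chi: np.ndarray = field(default_factory=lambda: np.zeros(1))
    theta_tau_h: np.ndarray = field(default_factory=lambda: np.zeros(1))
    theta_alpha: np.ndarray = field(default_factory=lambda: np.zeros(1))
    theta_epsilon: np.ndarray = field(default_factory=lambda: np.zeros(1))
    theta_e0: np.ndarray = field(default_factory=lambda: np.zeros(1))
    v0: float = V0_DEFAULT

    def __post_init__(self):
        for name in ("theta_eta", "theta_chi", "theta_tau_h", "theta_alpha",
                     "theta_epsilon", "theta_e0"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), float)))
        if not (0 < self.e0().min() and self.e0().max() < 1):
            raise ParameterError("resting O2 extraction must lie in (0, 1)")
        if not (0 < self.alpha().min() and self.alpha().max() < 1):
            raise ParameterError("Grubb exponent must lie in (0, 1)")

    def _broadcast(self, theta: np.ndarray, n_regions: int) -> np.ndarray:
        if theta.size == 1:
            return np.repeat(theta, n_regions)
        if theta.size != n_regions:
            raise ShapeError("haemodynamic parameter length mismatch")
        return theta

    def eta(self, n_regions: int | None = None) -> np.ndarray:
        t = self.theta_eta if n_regions is None else self._broadcast(self.theta_eta, n_regions)
        return ETA_SCALE * np.exp(t)

    def chi(self, n_regions: int | None = None) -> np.ndarray:
        t = self.theta_chi if n_regions is None else self._broadcast(self.theta_chi, n_regions)
        return CHI_SCALE * np.exp(t)

    def tau_h(self, n_regions: int | None = None) -> np.ndarray:
        t = self.theta_tau_h if n_regions is None else self._broadcast(self.theta_tau_h, n_regions)
        return TAU_H_SCALE * np.exp(t)

    def alpha(self, n_regions: int | None = None) -> np.ndarray:
        t = self.theta_alpha if n_regions is None else self._broadcast(self.theta_alpha, n_regions)
        return ALPHA_SCALE * np.exp(t)

    def epsilon(self, n_regions: int | None = None) -> np.ndarray:
        t = self.theta_epsilon if n_regions is None else self._broadcast(self.theta_epsilon, n_regions)
        return EPSILON_SCALE * np.exp(t)

    def e0(self, n_regions: int | None = None) -> np.ndarray:
        t = self.theta_e0 if n_regions is None else self._broadcast(self.theta_e0, n_regions)
        return E0_SCALE * np.exp(t)

    def bold_coefficients(self, n_regions: int | None = None):
        """(k1, k2, k3) recomputed from the current parameters."""
        e0 = self.e0(n_regions)
        eps = self.epsilon(n_regions)
        return 6.9 * e0, eps * e0, 1.0 - eps


REST_STATE = np.array([0.0, 1.0, 1.0, 1.0])  # (h_s, h_in, h_v, h_q)


def haemo_derivatives(state, z: float, params: HaemoParameters,
                      region: int = 0) -> np.ndarray:
    """State derivative at one region (reference numpy implementation)."""
    state = np.asarray(state, float)
    if state.shape != (4,):
        raise ShapeError("haemodynamic state must be (h_s, h_in, h_v, h_q)")
    hs, hin, hv, hq = state
    if hin <= 0 or hv <= 0:
        raise ParameterError("inflow and volume must remain positive")
    eta = params.eta()[min(region, params.theta_eta.size - 1)]
    chi = params.chi()[min(region, params.theta_chi.size - 1)]
    tau = params.tau_h()[min(region, params.theta_tau_h.size - 1)]
    alpha = params.alpha()[min(region, params.theta_alpha.size - 1)]
    e0 = params.e0()[min(region, params.theta_e0.size - 1)]
    fout = hv ** (1.0 / alpha)
    extraction = hin * (1.0 - (1.0 - e0) ** (1.0 / hin)) / e0
    return np.array([
        z - eta * hs - chi * (hin - 1.0),
        hs,
        (hin - fout) / tau,
        (extraction - fout * hq / hv) / tau,
    ])


def bold_observation(hv, hq, params: HaemoParameters, region: int | None = None):
    """BOLD signal from volume and deoxyhaemoglobin (zero at rest)."""
    hv = np.asarray(hv, float)
    hq = np.asarray(hq, float)
    if np.any(hv <= 0):
        raise ParameterError("blood volume must be positive")
    k1, k2, k3 = params.bold_coefficients()
    if region is not None:
        k1 = k1[min(region, k1.size - 1)]
        k2 = k2[min(region, k2.size - 1)]
        k3 = k3[min(region, k3.size - 1)]
    elif k1.size == 1:
        k1, k2, k3 = k1.item(), k2.item(), k3.item()
    y = params.v0 * (k1 * (1.0 - hq) + k2 * (1.0 - hq / hv) + k3 * (1.0 - hv))
    return y if np.ndim(y) else float(y)


def integrate_haemodynamics(z: np.ndarray, params: HaemoParameters,
                            dt: float, n_sub: int = 1) -> np.ndarray:
    """Integrate the Balloon states for all regions from exact rest.

    ``z`` is (regions, microtime) held piecewise-constant over each step of
    width ``dt``.  Returns states (microtime + 1, regions, 4).
    """
    z = np.atleast_2d(np.asarray(z, float))
    R = z.shape[0]
    states = balloon_rk4(
        np.ascontiguousarray(z),
        np.ascontiguousarray(params.eta(R)),
        np.ascontiguousarray(params.chi(R)),
        np.ascontiguousarray(params.tau_h(R)),
        np.ascontiguousarray(params.alpha(R)),
        np.ascontiguousarray(params.e0(R)),
        dt, n_sub,
    )
    if not np.all(np.isfinite(states)):
        raise IntegrationError(
            "haemodynamic states became non-finite "
            f"(eta={params.eta(R)}, tau_h={params.tau_h(R)})",
            block="haemodynamic",
        )
    return states


def predict_bold(z: np.ndarray, params: HaemoParameters, dt: float,
                 tr: float, n_sub: int = 1) -> np.ndarray:
    """Forward BOLD prediction sampled at the repetition time.

    ``z`` is the (regions, microtime) neurovascular signal.  Returns
    (n_scans, regions) with scans at t = 0, TR, 2 TR, ...
    """
    z = np.atleast_2d(np.asarray(z, float))
    states = integrate_haemodynamics(z, params, dt, n_sub=n_sub)
    step = int(round(tr / dt))
    n_scans = z.shape[1] // step
    sampled = states[: n_scans * step + 1 : step]  # includes t = 0
    sampled = sampled[:n_scans]
    hv = sampled[:, :, 2]
    hq = sampled[:, :, 3]
    R = z.shape[0]
    k1, k2, k3 = params.bold_coefficients(R)
    return params.v0 * (k1 * (1.0 - hq) + k2 * (1.0 - hq / hv) + k3 * (1.0 - hv))
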