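"""Fixed-step RK4 inner loops for the neuronal and haemodynamic ODEs.

Both loops are jitted with numba: model inversion evaluates the forward model
thousands of times (finite-difference Jacobians inside Gauss-Newton ascent),
so the per-call cost of these integrators dominates the whole pipeline.

The neuronal loop integrates the coupled second-order depolarisation
equations of the four-population microcircuit; the haemodynamic loop
integrates the vasodilatory-signal/Balloon equations in log-states for the
positive quantities (inflow, volume, deoxyhaemoglobin) so trajectories can
never leave the positive orthant.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Canonical intrinsic connection table: (source population, target population,
# sign as printed in the microcircuit equations).  Population order is
# (ss, sp, ii, dp) = (0, 1, 2, 3).
INTRINSIC_TABLE = (
    (0, 0, -1.0),  # ss -> ss  (self-inhibition)
    (1, 0, -1.0),  # sp -> ss
    (2, 0, -1.0),  # ii -> ss
    (0, 1, +1.0),  # ss -> sp
    (1, 1, -1.0),  # sp -> sp  (self)
    (2, 1, -1.0),  # ii -> sp
    (0, 2, +1.0),  # ss -> ii
    (1, 2, +1.0),  # sp -> ii
    (2, 2, -1.0),  # ii -> ii  (self)
    (3, 2, -1.0),  # dp -> ii
    (1, 3, +1.0),  # sp -> dp
    (2, 3, -1.0),  # ii -> dp
    (3, 3, -1.0),  # dp -> dp  (self)
)

N_INTRINSIC = len(INTRINSIC_TABLE)
SELF_INDICES = (0, 4, 8, 12)  # positions of the four self-inhibition gains

_SRC = np.array([row[0] for row in INTRINSIC_TABLE], dtype=np.int64)
_DST = np.array([row[1] for row in INTRINSIC_TABLE], dtype=np.int64)
_SGN = np.array([row[2] for row in INTRINSIC_TABLE], dtype=np.float64)


@njit(cache=True)
def _sigmoid(v, slope, vth):
    return 1.0 / (1.0 + np.exp(-slope * (v - vth))) - 1.0 / (1.0 + np.exp(slope * vth))


@njit(cache=True)
def _cmc_f(V, a_eff, Af, Ab, C, u, slope, vth, ext_scale, src, dst, sgn):
    """Population forcing terms f_i for every region; V is (R, 4).

    ``a_eff`` is (R, 13): intrinsic gains per region (condition effects on
    self-inhibition may differ across regions).  ``ext_scale`` holds the
    four extrinsic rate scales (forward->ss, forward->dp, backward->sp,
    backward->ii) applied on top of the exp(theta)-scaled adjacency.
    """
    R = V.shape[0]
    sig = np.empty((R, 4))
    for r in range(R):
        for p in range(4):
            sig[r, p] = _sigmoid(V[r, p], slope, vth)
    f = np.zeros((R, 4))
    # intrinsic terms
    for k in range(a_eff.shape[1]):
        s, d, g = src[k], dst[k], sgn[k]
        for r in range(R):
            f[r, d] += g * a_eff[r, k] * sig[r, s]
    # extrinsic terms: forward from distal sp to ss and dp; backward from
    # distal dp to sp and ii
    for r in range(R):
        acc_f = 0.0
        acc_b = 0.0
        for j in range(R):
            acc_f += Af[r, j] * sig[j, 1]
            acc_b += Ab[r, j] * sig[j, 3]
        f[r, 0] += ext_scale[0] * acc_f + C[r] * u
        f[r, 3] += ext_scale[1] * acc_f
        f[r, 1] += ext_scale[2] * acc_b
        f[r, 2] += ext_scale[3] * acc_b
    return f


@njit(cache=True)
def cmc_rk4(V0, W0, kappa, a_eff, Af, Ab, C, u_half, dt, n_steps, slope, vth,
            ext_scale, n_sub):
    """Integrate V-double-dot = kappa^2 (f - V) - 2 kappa V-dot with RK4.

    ``n_sub`` RK4 substeps of width dt/n_sub are taken per output step of
    width ``dt`` (the coupled system's fastest modes run at kappa*sqrt(gain),
    well above the rate constants themselves, so the stability limit binds
    far below dt = 1/kappa).  ``u_half`` holds the exogenous input at
    half-substep resolution (length 2*n_steps*n_sub + 1).  Returns the
    depolarisation trajectory with shape (n_steps + 1, R, 4).
    """
    R = V0.shape[0]
    traj = np.empty((n_steps + 1, R, 4))
    V = V0.copy()
    W = W0.copy()
    traj[0] = V
    k2v = kappa * kappa
    h = dt / n_sub
    for n in range(n_steps):
        for s in range(n_sub):
            base = 2 * (n * n_sub + s)
            u0 = u_half[base]
            um = u_half[base + 1]
            u1 = u_half[base + 2]

            f = _cmc_f(V, a_eff, Af, Ab, C, u0, slope, vth, ext_scale, _SRC, _DST, _SGN)
            k1v = W
            k1w = k2v * (f - V) - 2.0 * kappa * W

            V2 = V + 0.5 * h * k1v
            W2 = W + 0.5 * h * k1w
            f = _cmc_f(V2, a_eff, Af, Ab, C, um, slope, vth, ext_scale, _SRC, _DST, _SGN)
            k2v_ = W2
            k2w = k2v * (f - V2) - 2.0 * kappa * W2

            V3 = V + 0.5 * h * k2v_
            W3 = W + 0.5 * h * k2w
            f = _cmc_f(V3, a_eff, Af, Ab, C, um, slope, vth, ext_scale, _SRC, _DST, _SGN)
            k3v = W3
            k3w = k2v * (f - V3) - 2.0 * kappa * W3

            V4 = V + h * k3v
            W4 = W + h * k3w
            f = _cmc_f(V4, a_eff, Af, Ab, C, u1, slope, vth, ext_scale, _SRC, _DST, _SGN)
            k4v = W4
            k4w = k2v * (f - V4) - 2.0 * kappa * W4

            V = V + h / 6.0 * (k1v + 2.0 * k2v_ + 2.0 * k3v + k4v)
            W = W + h / 6.0 * (k1w + 2.0 * k2w + 2.0 * k3w + k4w)
        traj[n + 1] = V
    return traj


@njit(cache=True)
def _balloon_deriv(x, z, eta, chi, tauh, alpha, e0):
    """Derivative of (hs, log hin, log hv, log hq) at one region."""
    hs = x[0]
    hin = np.exp(x[1])
    hv = np.exp(x[2])
    hq = np.exp(x[3])
    dhs = z - eta * hs - chi * (hin - 1.0)
    dhin = hs
    fout = hv ** (1.0 / alpha)
    extraction = hin * (1.0 - (1.0 - e0) ** (1.0 / hin)) / e0
    dhv = (hin - fout) / tauh
    dhq = (extraction - fout * hq / hv) / tauh
    out = np.empty(4)
    out[0] = dhs
    out[1] = dhin / hin
    out[2] = dhv / hv
    out[3] = dhq / hq
    return out


@njit(cache=True)
def balloon_rk4(z, eta, chi, tauh, alpha, e0, dt, n_sub):
    """Integrate the vasodilatory/Balloon equations for all regions.

    ``z`` is (R, T): the neurovascular drive held piecewise-constant over each
    microtime interval of width ``dt``; ``n_sub`` RK4 substeps are taken per
    interval.  Returns states (T + 1, R, 4) as (hs, hin, hv, hq) with the
    positive states mapped back from log space.
    """
    R, T = z.shape
    traj = np.empty((T + 1, R, 4))
    x = np.zeros((R, 4))  # rest: hs=0, log hin = log hv = log hq = 0
    for r in range(R):
        traj[0, r, 0] = 0.0
        traj[0, r, 1] = 1.0
        traj[0, r, 2] = 1.0
        traj[0, r, 3] = 1.0
    h = dt / n_sub
    for t in range(T):
        for r in range(R):
            zr = z[r, t]
            xr = x[r].copy()
            for _ in range(n_sub):
                k1 = _balloon_deriv(xr, zr, eta[r], chi[r], tauh[r], alpha[r], e0[r])
                k2 = _balloon_deriv(xr + 0.5 * h * k1, zr, eta[r], chi[r], tauh[r], alpha[r], e0[r])
                k3 = _balloon_deriv(xr + 0.5 * h * k2, zr, eta[r], chi[r], tauh[r], alpha[r], e0[r])
                k4 = _balloon_deriv(xr + h * k3, zr, eta[r], chi[r], tauh[r], alpha[r], e0[r])
                xr = xr + h / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            x[r] = xr
            traj[t + 1, r, 0] = xr[0]
            traj[t + 1, r, 1] = np.exp(xr[1])
            traj[t + 1, r, 2] = np.exp(xr[2])
            traj[t + 1, r, 3] = np.exp(xr[3])
    return traj
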