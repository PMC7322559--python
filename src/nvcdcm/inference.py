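"""Variational Laplace inversion, Bayesian model reduction and comparison.

The inversion scheme maximises the Laplace free energy

    F = E_q[ln p(y | theta, lambda)] - KL(q(theta) || p(theta))
        - KL(q(lambda) || p(lambda))

under a fixed-form Gaussian posterior q(theta) = N(m, S), by Gauss-Newton
ascent with Levenberg-Marquardt damping.  Observation noise is i.i.d. within
each declared data stream with a log-precision hyperparameter lambda_s,
updated by Newton steps under a Gaussian hyperprior.  F lower-bounds the log
model evidence and is exact for linear-Gaussian models, which the test suite
exploits as an oracle.

Bayesian model reduction evaluates the evidence and posterior of a model
whose priors have been changed (typically: parameters switched off by
shrinking their prior variance) analytically from the full model's posterior,
without refitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .errors import NumericalError, ValidationError

LOG2PI = np.log(2.0 * np.pi)


@dataclass
class GaussianDensity:
    """Gaussian over a named parameter vector."""

    mean: np.ndarray
    cov: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self):
        self.mean = np.atleast_1d(np.asarray(self.mean, float))
        self.cov = np.atleast_2d(np.asarray(self.cov, float))
        if self.cov.shape != (self.mean.size, self.mean.size):
            raise ValidationError("covariance shape does not match mean")
        if self.mean.size and np.max(np.abs(self.cov - self.cov.T)) > 1e-10:
            raise ValidationError("covariance is not symmetric")

    def sd(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    def credible_interval(self, level: float = 0.90):
        """Central credible interval per parameter (lo, hi arrays)."""
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2.0)
        sd = self.sd()
        return self.mean - z * sd, self.mean + z * sd


@dataclass
class InversionResult:
    posterior: GaussianDensity
    free_energy: float
    trace: list[float] = field(default_factory=list)
    noise_log_precision: np.ndarray | None = None
    noise_log_precision_cov: np.ndarray | None = None
    converged: bool = True
    n_data: int = 0


def _finite_difference_jacobian(generator, m, step: float):
    """Central finite differences, column per parameter."""
    y0 = np.asarray(generator(m), float)
    J = np.empty((y0.size, m.size))
    for i in range(m.size):
        dm = np.zeros_like(m)
        dm[i] = step
        yp = np.asarray(generator(m + dm), float)
        ym = np.asarray(generator(m - dm), float)
        J[:, i] = (yp - ym) / (2.0 * step)
    return y0, J


def _stream_slices(n_data: int, streams):
    if streams is None:
        return [np.arange(n_data)]
    out = []
    for s in streams:
        idx = np.arange(n_data)[s] if isinstance(s, slice) else np.asarray(s, int)
        out.append(idx)
    cover = np.concatenate(out)
    if sorted(cover.tolist()) != list(range(n_data)):
        raise ValidationError("streams must partition the data vector")
    return out


def variational_laplace(generator, data, prior_mean, prior_variance,
                        noise_hyperpriors=None, streams=None,
                        fixed_noise_precision=None,
                        max_iter: int = 64, tol: float = 0.01,
                        fd_step: float = 1e-3, labels=None,
                        init=None, n_starts: int = 1, start_seed: int = 0,
                        verbose: bool = False) -> InversionResult:
    """Invert ``data = generator(theta) + noise`` by free-energy ascent.

    Parameters
    ----------
    generator : callable mapping the free parameter vector to a prediction.
    data : 1-d observation vector.
    prior_mean, prior_variance : diagonal Gaussian prior over free parameters.
    noise_hyperpriors : per-stream (mean, variance) of the log-precision
        hyperprior; default (0, 64).
    streams : per-stream index arrays partitioning the data (default: one).
    fixed_noise_precision : per-stream precisions; when given the noise is
        not estimated and F contains no hyperparameter terms (the exact
        linear-Gaussian evidence is then recovered on linear problems).
    tol : convergence threshold on the free-energy increase, required for
        three consecutive accepted steps.
    init : optional starting point for the ascent (default: the prior mean).
    n_starts : when > 1, the ascent starts from the best of the prior mean
        and ``n_starts - 1`` seeded prior draws, scored by prior-penalised
        sum of squares; a cheap, deterministic guard against the local
        optima of strongly nonlinear generators.
    """
    data = np.asarray(data, float).ravel()
    m0 = np.atleast_1d(np.asarray(prior_mean, float))
    v0 = np.atleast_1d(np.asarray(prior_variance, float))
    if np.any(v0 <= 0):
        raise ValidationError(
            "zero-variance parameters must be excluded before inversion"
        )
    n, p = data.size, m0.size
    idx_s = _stream_slices(n, streams)
    ns = len(idx_s)
    n_per = np.array([len(ix) for ix in idx_s], float)

    estimate_noise = fixed_noise_precision is None
    if estimate_noise:
        if noise_hyperpriors is None:
            noise_hyperpriors = [(0.0, 64.0)] * ns
        if len(noise_hyperpriors) == 1 and ns > 1:
            noise_hyperpriors = list(noise_hyperpriors) * ns
        eta0 = np.array([h[0] for h in noise_hyperpriors], float)
        hvar = np.array([h[1] for h in noise_hyperpriors], float)
        lam = eta0.copy()
    else:
        lam = np.log(np.asarray(fixed_noise_precision, float))
        if lam.size == 1 and ns > 1:
            lam = np.repeat(lam, ns)
        eta0 = hvar = None

    P0 = np.diag(1.0 / v0) if p else np.zeros((0, 0))
    ld_P0 = float(np.sum(np.log(1.0 / v0))) if p else 0.0
    m = m0.copy() if init is None else np.atleast_1d(np.asarray(init, float)).copy()
    if init is None and n_starts > 1 and p:
        rng = np.random.default_rng(start_seed)
        data_var = max(float(np.var(data)), 1e-300)
        best_score = np.inf
        for k in range(n_starts):
            cand = m0 if k == 0 else m0 + np.sqrt(v0) * rng.standard_normal(p)
            try:
                resid = data - np.asarray(generator(cand), float)
            except (NumericalError, FloatingPointError, OverflowError):
                continue
            if not np.all(np.isfinite(resid)):
                continue
            score = float(resid @ resid) / data_var + float(
                ((cand - m0) ** 2 / v0).sum()
            )
            if score < best_score:
                best_score, m = score, cand.copy()

    def sq_per_stream(r):
        return np.array([float(r[ix] @ r[ix]) for ix in idx_s])

    def tr_per_stream(J, S):
        out = np.empty(ns)
        for s, ix in enumerate(idx_s):
            Js = J[ix]
            out[s] = float(np.sum((Js @ S) * Js))
        return out

    def update_lambda(lam, rr, tr):
        """Newton ascent on F in lambda (per stream, independent)."""
        lam = lam.copy()
        for _ in range(16):
            w = np.exp(lam)
            grad = 0.5 * (n_per - w * (rr + tr)) - (lam - eta0) / hvar
            curv = 0.5 * w * (rr + tr) + 1.0 / hvar
            dl = np.clip(grad / curv, -2.0, 2.0)
            lam = lam + dl
            if np.max(np.abs(dl)) < 1e-8:
                break
        slam = 1.0 / (0.5 * np.exp(lam) * (rr + tr) + 1.0 / hvar)
        return lam, slam

    def free_energy(r, J, lam, m_cur, slam):
        w = np.exp(lam)
        Pi_diag = np.empty(n)
        for s, ix in enumerate(idx_s):
            Pi_diag[ix] = w[s]
        JPJ = (J * Pi_diag[:, None]).T @ J if p else np.zeros((0, 0))
        P = JPJ + P0
        if p:
            sign, ld_P = np.linalg.slogdet(P)
            if sign <= 0:
                raise NumericalError("posterior precision lost positive-definiteness")
            S = np.linalg.inv(P)
        else:
            ld_P, S = 0.0, np.zeros((0, 0))
        rr = sq_per_stream(r)
        tr = tr_per_stream(J, S) if p else np.zeros(ns)
        acc = -0.5 * float(w @ (rr + tr)) + 0.5 * float(n_per @ lam) - 0.5 * n * LOG2PI
        e = m_cur - m0
        kl_theta = 0.5 * (float(e @ P0 @ e) + float(np.trace(S @ P0))
                          - p + ld_P - ld_P0)
        F = acc - kl_theta
        if estimate_noise:
            dl = lam - eta0
            kl_lam = 0.5 * float(np.sum(dl * dl / hvar))
            kl_lam += 0.5 * float(np.sum(slam / hvar))
            kl_lam += 0.5 * float(np.sum(np.log(hvar) - np.log(slam))) - 0.5 * ns
            F -= kl_lam
        return F, S, P, rr, tr

    trace: list[float] = []
    converged = False
    slam = np.zeros(ns)
    n_small = 0
    nu = 1e-6  # Levenberg-Marquardt damping
    y0, J = _finite_difference_jacobian(generator, m, fd_step) if p else (
        np.asarray(generator(m), float), np.zeros((n, 0)))
    r = data - y0
    if estimate_noise:
        # initial noise update needs S; bootstrap with prior covariance
        S_boot = np.diag(v0) if p else np.zeros((0, 0))
        rr = sq_per_stream(r)
        tr = tr_per_stream(J, S_boot) if p else np.zeros(ns)
        lam, slam = update_lambda(lam, rr, tr)
    F, S, P, rr, tr = free_energy(r, J, lam, m, slam)
    trace.append(F)

    for _ in range(max_iter):
        accepted = False
        if p:
            w = np.exp(lam)
            Pi_diag = np.empty(n)
            for s, ix in enumerate(idx_s):
                Pi_diag[ix] = w[s]
            grad = J.T @ (Pi_diag * r) - P0 @ (m - m0)
            for _try in range(8):
                try:
                    dm = np.linalg.solve(P + nu * np.diag(np.diag(P)), grad)
                except np.linalg.LinAlgError:
                    nu = max(nu, 1e-6) * 8.0
                    continue
                m_try = m + dm
                try:
                    y_try, J_try = _finite_difference_jacobian(generator, m_try, fd_step)
                except (NumericalError, FloatingPointError, OverflowError):
                    nu = max(nu, 1e-6) * 8.0
                    continue
                r_try = data - y_try
                if not np.all(np.isfinite(r_try)):
                    nu = max(nu, 1e-6) * 8.0
                    continue
                lam_try, slam_try = (lam, slam)
                if estimate_noise:
                    S_cur = S
                    rr_t = sq_per_stream(r_try)
                    tr_t = tr_per_stream(J_try, S_cur)
                    lam_try, slam_try = update_lambda(lam, rr_t, tr_t)
                try:
                    F_try, S_try, P_try, rr_t, tr_t = free_energy(
                        r_try, J_try, lam_try, m_try, slam_try)
                except NumericalError:
                    nu = max(nu, 1e-6) * 8.0
                    continue
                if np.isfinite(F_try) and F_try > F - 1e-12:
                    dF = F_try - F
                    m, r, J = m_try, r_try, J_try
                    lam, slam = lam_try, slam_try
                    F, S, P = F_try, S_try, P_try
                    trace.append(F)
                    nu = max(nu / 2.0, 1e-8)
                    accepted = True
                    n_small = n_small + 1 if dF < tol else 0
                    break
                nu = max(nu, 1e-6) * 8.0
        else:
            # no free parameters: only the noise hyperparameters move
            if estimate_noise:
                lam_new, slam_new = update_lambda(lam, rr, tr)
                F_new, S, P, rr, tr = free_energy(r, J, lam_new, m, slam_new)
                if F_new > F + 1e-12:
                    lam, slam, F = lam_new, slam_new, F_new
                    trace.append(F)
                    accepted = True
        if verbose:
            print(f"VL iter: F={F:.4f} accepted={accepted} nu={nu:.1e}")
        if accepted and n_small >= 3:
            converged = True
            break
        if not accepted:
            # no direction improves F: treat the current point as a maximum
            converged = True
            break

    posterior = GaussianDensity(m, 0.5 * (S + S.T) if p else np.zeros((0, 0)),
                                labels=list(labels) if labels else None)
    return InversionResult(
        posterior=posterior, free_energy=float(F), trace=trace,
        noise_log_precision=lam.copy(),
        noise_log_precision_cov=np.diag(slam) if estimate_noise else None,
        converged=converged, n_data=n,
    )


# ---------------------------------------------------------------------------
# Bayesian model reduction
# ---------------------------------------------------------------------------

def bayesian_model_reduction(full_prior: GaussianDensity,
                             full_posterior: GaussianDensity,
                             reduced_prior: GaussianDensity):
    """Evidence change and posterior under modified (reduced) priors.

    Returns (delta_F, reduced_posterior) where delta_F = ln p_reduced(y) -
    ln p_full(y), computed analytically under the Laplace assumption without
    refitting the model.
    """
    mu0, S0 = full_prior.mean, full_prior.cov
    m, Sp = full_posterior.mean, full_posterior.cov
    mur, Sr = reduced_prior.mean, reduced_prior.cov
    if not (mu0.shape == m.shape == mur.shape):
        raise ValidationError("BMR requires identical parameter vectors")
    try:
        P0 = np.linalg.inv(S0)
        Pp = np.linalg.inv(Sp)
        Pr = np.linalg.inv(Sr)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(f"singular covariance in BMR inputs: {exc}") from exc
    Pq = Pp + Pr - P0
    sign_q, ld_Pq = np.linalg.slogdet(Pq)
    if sign_q <= 0:
        raise NumericalError(
            "reduced-model precision is not positive definite; the reduced "
            "prior is incompatible with the full posterior"
        )
    hq = Pp @ m + Pr @ mur - P0 @ mu0
    mq = np.linalg.solve(Pq, hq)
    ld = (np.linalg.slogdet(Pp)[1] + np.linalg.slogdet(Pr)[1]
          - np.linalg.slogdet(P0)[1] - ld_Pq)
    quad = (mq @ Pq @ mq - m @ Pp @ m - mur @ Pr @ mur + mu0 @ P0 @ mu0)
    dF = 0.5 * float(ld + quad)
    Sq = np.linalg.inv(Pq)
    reduced_posterior = GaussianDensity(mq, 0.5 * (Sq + Sq.T),
                                        labels=full_posterior.labels)
    return dF, reduced_posterior


def reduce_prior(prior: GaussianDensity, off_indices,
                 pinned_variance: float = 1e-8) -> GaussianDensity:
    """Prior with the given parameters switched off (pinned near zero)."""
    cov = prior.cov.copy()
    mean = prior.mean.copy()
    off = np.asarray(off_indices, int)
    cov[off, :] = 0.0
    cov[:, off] = 0.0
    cov[off, off] = pinned_variance
    mean[off] = 0.0
    return GaussianDensity(mean, cov, labels=prior.labels)


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    free_energies: np.ndarray
    probabilities: np.ndarray
    family_probabilities: dict[str, float] | None = None

    def __post_init__(self):
        self.free_energies = np.asarray(self.free_energies, float)
        self.probabilities = np.asarray(self.probabilities, float)
        if abs(self.probabilities.sum() - 1.0) > 1e-12:
            raise ValidationError("model probabilities must sum to one")


def compare_models(free_energies) -> ComparisonResult:
    """Fixed-effects posterior model probabilities under uniform priors."""
    F = np.asarray(free_energies, float)
    logp = F - logsumexp(F)
    return ComparisonResult(F, np.exp(logp))


def family_posterior(free_energies, partition: dict[str, list[int]]):
    """Family probabilities under a prior uniform over families.

    The model prior is uniform across families and uniform within each
    family, which corrects for unequal family sizes; only models covered by
    the partition contribute.
    """
    F = np.asarray(free_energies, float)
    names = list(partition)
    members = {k: np.asarray(v, int) for k, v in partition.items()}
    all_idx = np.concatenate(list(members.values())) if names else np.array([], int)
    if len(set(all_idx.tolist())) != all_idx.size:
        raise ValidationError("family partition has overlapping members")
    K = len(names)
    log_joint = {}
    for k in names:
        idx = members[k]
        log_prior = -np.log(K) - np.log(len(idx))
        log_joint[k] = logsumexp(F[idx] + log_prior)
    norm = logsumexp(np.array(list(log_joint.values())))
    return {k: float(np.exp(log_joint[k] - norm)) for k in names}


# ---------------------------------------------------------------------------
# greedy parameter pruning
# ---------------------------------------------------------------------------

@dataclass
class PruneResult:
    posterior: GaussianDensity
    free_energy: float
    removed: list[str]
    presence_log_odds: dict[str, float]


def prune_parameters(result: InversionResult, full_prior: GaussianDensity,
                     candidates: dict[str, np.ndarray]) -> PruneResult:
    """Greedy Bayesian-model-reduction search over switch-off candidates.

    Each candidate names a set of parameter indices; candidates whose removal
    does not decrease the free energy are switched off (prior pinned at zero)
    one at a time, best-first.  Presence log-odds per candidate compare the
    final model with that candidate present versus absent.
    """
    removed: list[str] = []
    best_dF = 0.0

    def dF_for(off_names):
        off_idx = (np.concatenate([candidates[n] for n in off_names])
                   if off_names else np.array([], int))
        rp = reduce_prior(full_prior, off_idx)
        return bayesian_model_reduction(full_prior, result.posterior, rp)

    while True:
        best = None
        for name in candidates:
            if name in removed:
                continue
            try:
                dF, _ = dF_for(removed + [name])
            except NumericalError:
                continue
            if best is None or dF > best[1]:
                best = (name, dF)
        if best is None or best[1] < best_dF:
            break
        removed.append(best[0])
        best_dF = best[1]

    dF_final, post = dF_for(removed) if removed else (0.0, result.posterior)
    odds = {}
    for name in candidates:
        with_it = [n for n in removed if n != name]
        without_it = sorted(set(removed) | {name})
        try:
            dF_present, _ = dF_for(with_it)
            dF_absent, _ = dF_for(without_it)
            odds[name] = float(dF_present - dF_absent)
        except NumericalError:
            odds[name] = np.nan
    return PruneResult(posterior=post, free_energy=result.free_energy + dF_final,
                       removed=removed, presence_log_odds=odds)
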