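"""Length-weighted bivariate Gaussian mixture fit by EM, M-step first.

The scaffold features x_i = (logit GC, FPKM) are modeled as a mixture
P(x_i) = sum_k tau_k phi_k(x_i | mu_k, Sigma_k) of G bivariate normals with
unconstrained covariances. Every scaffold carries a length weight
w_i = l_i / sum_j l_j, so the fitted objective is the weighted observed-data
log-likelihood sum_i w_i log P(x_i) (the quantity EM increases monotonically);
the weighted complete-data log-likelihood
l_c = sum_ik z_ik w_i log[tau_k phi_k(x_i)] is exposed for reporting.

G is the number of contour-derived initial groups plus one: the extra
component absorbs scaffolds scattered between clusters (the "noise"
component). Responsibilities start one-hot from the initial binning —
label-0 scaffolds (including coverage outliers masked from the KDE) start
in the noise component — and the first step is an M-step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .density import InitialBinning
from .features import FeatureTable
from .io import NOISE

logger = logging.getLogger("contourbin")

_LOG_2PI = float(np.log(2.0 * np.pi))

#: relative eigenvalue floor for component covariances: below roughly 1e-5
#: of the mean variance, float64 round-off in the M-step gets amplified by
#: the ~1/eigenvalue curvature of the log-likelihood and EM monotonicity is
#: lost, so collapsing components are held at this scale
RIDGE_REL_FLOOR = 1e-5
#: absolute fallback scale when a component collapses onto identical points
RIDGE_ABS_SCALE = 1e-4


@dataclass
class MixtureParams:
    """Mixing proportions, means and covariances of a G-component mixture."""

    tau: np.ndarray  # (G,)
    mu: np.ndarray  # (G, 2)
    sigma: np.ndarray  # (G, 2, 2)

    @property
    def G(self) -> int:
        return len(self.tau)

    def validate(self) -> None:
        if (self.tau < 0).any() or abs(self.tau.sum() - 1.0) > 1e-12:
            raise ValueError("mixing proportions must be a probability vector")
        for k in range(self.G):
            if np.linalg.eigvalsh(self.sigma[k])[0] <= 0:
                raise ValueError(f"component {k} covariance is not positive definite")


@dataclass
class FittedMixture:
    """EM result: parameters, responsibilities, likelihood trace."""

    params: MixtureParams
    z: np.ndarray  # (N, G) responsibilities
    loglik_trace: list[float]
    converged: bool
    noise_component: int | None
    complete_data_loglik: float = float("nan")
    dropped_components: int = 0


def bivariate_normal_logpdf(x: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Log density of N(mu, sigma) in 2-D via Cholesky (no explicit inverse).

    ``x`` may be a single 2-vector or an (N, 2) array.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    try:
        chol = linalg.cholesky(sigma, lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError("covariance matrix is not positive definite") from exc
    dev = x - np.asarray(mu, dtype=float)
    sol = linalg.solve_triangular(chol, dev.T, lower=True)
    maha = np.sum(sol * sol, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    out = -0.5 * (2.0 * _LOG_2PI + logdet + maha)
    return out if out.size > 1 else float(out[0])


def _component_logpdfs(points: np.ndarray, params: MixtureParams) -> np.ndarray:
    """(N, G) matrix of per-component log densities."""
    return np.column_stack(
        [np.atleast_1d(bivariate_normal_logpdf(points, params.mu[k], params.sigma[k]))
         for k in range(params.G)]
    )


def m_step(
    points: np.ndarray,
    weights: np.ndarray,
    z: np.ndarray,
    prev: MixtureParams | None = None,
) -> MixtureParams:
    """Closed-form maximizers of the weighted complete-data log-likelihood.

    tau_k = sum_i w_i z_ik / sum_i w_i, mu_k and Sigma_k the responsibility-
    and length-weighted mean and covariance. Near-singular covariances are
    held at an eigenvalue floor so they stay positive definite; when ``prev``
    is given, a floored component whose Q-term would drop below its previous
    value keeps the previous (mu, Sigma) — a generalized-EM safeguard that
    preserves likelihood monotonicity while a component collapses. A
    component with zero total responsibility yields tau_k = 0 (the caller
    drops it).
    """
    points = np.asarray(points, dtype=float)
    weights = np.asarray(weights, dtype=float)
    G = z.shape[1]
    wz = weights[:, None] * z  # (N, G)
    totals = wz.sum(axis=0)  # sum_i w_i z_ik
    tau = totals / weights.sum()
    mu = np.zeros((G, 2))
    sigma = np.zeros((G, 2, 2))
    for k in range(G):
        if totals[k] <= 0:
            sigma[k] = np.eye(2)
            continue
        mu[k] = wz[:, k] @ points / totals[k]
        dev = points - mu[k]
        sigma[k] = (wz[:, k, None] * dev).T @ dev / totals[k]
        sigma[k] = 0.5 * (sigma[k] + sigma[k].T)
        floor = RIDGE_REL_FLOOR * max(np.trace(sigma[k]) / 2.0, RIDGE_ABS_SCALE)
        min_eig = np.linalg.eigvalsh(sigma[k])[0]
        if min_eig < floor:
            sigma[k] += (floor - min_eig) * np.eye(2)
            if prev is not None and prev.G == G:
                q_new = wz[:, k] @ np.atleast_1d(
                    bivariate_normal_logpdf(points, mu[k], sigma[k]))
                q_old = wz[:, k] @ np.atleast_1d(
                    bivariate_normal_logpdf(points, prev.mu[k], prev.sigma[k]))
                if q_new < q_old:
                    mu[k] = prev.mu[k]
                    sigma[k] = prev.sigma[k]
    return MixtureParams(tau=tau, mu=mu, sigma=sigma)


def e_step(points: np.ndarray, params: MixtureParams) -> np.ndarray:
    """Responsibilities z_ik = tau_k phi_k(x_i) / sum_j tau_j phi_j(x_i).

    Computed in log space with max-subtraction; a point whose density
    underflows in every component gets a uniform row (with a warning).
    """
    with np.errstate(divide="ignore"):
        logp = _component_logpdfs(points, params) + np.log(params.tau)
    m = logp.max(axis=1, keepdims=True)
    bad = ~np.isfinite(m[:, 0])
    if bad.any():
        logger.warning("%d points underflow in every component; uniform rows", bad.sum())
        logp[bad] = 0.0
        m[bad] = 0.0
    p = np.exp(logp - m)
    return p / p.sum(axis=1, keepdims=True)


def weighted_observed_loglik(
    points: np.ndarray, weights: np.ndarray, params: MixtureParams
) -> float:
    """sum_i w_i log sum_k tau_k phi_k(x_i) — EM's monotone objective."""
    with np.errstate(divide="ignore"):
        logp = _component_logpdfs(points, params) + np.log(params.tau)
    m = logp.max(axis=1)
    lse = m + np.log(np.exp(logp - m[:, None]).sum(axis=1))
    return float(np.asarray(weights) @ lse)


def complete_data_loglik(
    points: np.ndarray, weights: np.ndarray, z: np.ndarray, params: MixtureParams
) -> float:
    """l_c = sum_ik z_ik w_i log[tau_k phi_k(x_i)], reported alongside the fit."""
    with np.errstate(divide="ignore"):
        logp = _component_logpdfs(points, params) + np.log(params.tau)
    term = np.where(z > 0, z * logp, 0.0)
    return float(np.asarray(weights) @ term.sum(axis=1))


def fit_em(
    table: FeatureTable,
    init: InitialBinning,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> FittedMixture:
    """Fit the G = n_groups + 1 component mixture from the KDE initialization.

    Responsibilities start one-hot on the initial group; label-0 scaffolds
    start in the extra noise component. Iterates M-step then E-step until
    the relative change of the weighted observed-data log-likelihood drops
    below ``tol`` or ``max_iter`` is reached. Components that lose all
    responsibility are dropped (G shrinks, tau renormalizes, logged).
    """
    if init.n_groups < 1:
        raise ValueError(
            "initial binning has 0 groups; lower the contour level to obtain "
            "at least one group"
        )
    points = table.points
    weights = table.weights
    G = init.n_groups + 1
    noise: int | None = G - 1
    z = np.zeros((len(table), G))
    for i, sid in enumerate(table.ids):
        lab = init.labels.get(sid, 0)
        z[i, lab - 1 if lab >= 1 else noise] = 1.0

    trace: list[float] = []
    converged = False
    dropped = 0
    params = None
    for _ in range(max_iter):
        params = m_step(points, weights, z, prev=params)
        empty = np.flatnonzero(params.tau <= 0)
        if empty.size:
            keep = np.setdiff1d(np.arange(params.G), empty)
            logger.info("dropping %d empty component(s)", empty.size)
            dropped += int(empty.size)
            if noise is not None:
                noise = None if noise in empty else int(np.searchsorted(keep, noise))
            z = z[:, keep]
            z = z / z.sum(axis=1, keepdims=True)
            params = m_step(points, weights, z)
            params.tau = params.tau / params.tau.sum()
        z = e_step(points, params)
        ll = weighted_observed_loglik(points, weights, params)
        if trace and abs(ll - trace[-1]) <= tol * max(abs(trace[-1]), 1.0):
            trace.append(ll)
            converged = True
            break
        trace.append(ll)
    assert params is not None
    lc = complete_data_loglik(points, weights, z, params)
    return FittedMixture(
        params=params, z=z, loglik_trace=trace, converged=converged,
        noise_component=noise, complete_data_loglik=lc, dropped_components=dropped,
    )


def hard_assign(
    fitted: FittedMixture,
    ids: list[str],
    min_posterior: float = 0.5,
) -> dict[str, object]:
    """Map each scaffold to its best non-noise bin, or to noise.

    A scaffold goes to bin argmax_k z_ik (non-noise k, 1-based labels) if
    that posterior reaches ``min_posterior`` and exceeds the noise
    component's posterior; otherwise it is left as noise. Ties break toward
    the lower component index.
    """
    z = fitted.z
    noise = fitted.noise_component
    out: dict[str, object] = {}
    cols = [k for k in range(z.shape[1]) if k != noise]
    for i, sid in enumerate(ids):
        best = max(cols, key=lambda k: (z[i, k], -k)) if cols else None
        if best is None:
            out[sid] = NOISE
            continue
        p = z[i, best]
        p_noise = z[i, noise] if noise is not None else 0.0
        if p >= min_posterior and p > p_noise:
            out[sid] = cols.index(best) + 1
        else:
            out[sid] = NOISE
    return out
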