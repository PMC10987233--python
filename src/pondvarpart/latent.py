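"""Binomial latent-variable ordination of presence–absence communities.

The multivariate response used by the partitioning models is not the raw
site-by-species matrix but the site scores of a generalized linear latent
variable model (GLLVM) with no covariates:

    P(y_ij = 1) = logit⁻¹( β0_j + z_iᵀ γ_j ),   z_i ~ N(0, I_d)

The latent axes capture the covariation shared among species while shedding
species-specific noise.  The number of axes d is chosen by the lowest AIC
over d = 1..d_max, and each selected axis is then modelled by its own GAM.

Fitting uses a variational Gaussian approximation: q(z_i) = N(m_i,
diag(s_i²)), maximizing the evidence lower bound (ELBO) by L-BFGS with
analytic gradients; the intractable E_q[log(1 + e^η)] is evaluated by
Gauss–Hermite quadrature.  Identifiability follows the standard constraint:
loadings are lower-triangular (γ_jk = 0 for k > j) with positive diagonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

__all__ = ["LatentModelFit", "LatentAxes", "fit_latent_model", "select_latent_dimension"]

_GH_POINTS = 12


def _gh_nodes(num: int = _GH_POINTS) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.hermite.hermgauss(num)
    return np.sqrt(2.0) * x, w / np.sqrt(np.pi)


@dataclass
class LatentModelFit:
    d: int
    site_scores: np.ndarray  # n × d variational means
    site_sds: np.ndarray  # n × d variational standard deviations
    loadings: np.ndarray  # m × d, lower-triangular constraint
    intercepts: np.ndarray  # m
    log_likelihood: float  # ELBO at the optimum (lower bound surrogate)
    aic: float
    n_parameters: int
    converged: bool
    elbo_trace: np.ndarray = field(default_factory=lambda: np.array([]))
    species_kept: list = field(default_factory=list)


@dataclass
class LatentAxes:
    """AIC-selected latent site scores used as the multivariate response."""

    scores: pd.DataFrame  # samples × axis1..axisd
    taxon: str | None
    d: int
    aic_by_d: dict = field(default_factory=dict)
    fit: LatentModelFit | None = None


def _free_gamma_indices(m: int, d: int) -> tuple[np.ndarray, np.ndarray]:
    rows, cols = [], []
    for j in range(m):
        for k in range(d):
            if k <= j:
                rows.append(j)
                cols.append(k)
    return np.array(rows), np.array(cols)


def _unpack(theta, n, m, d, rows, cols):
    q = len(rows)
    beta0 = theta[:m]
    G = np.zeros((m, d))
    G[rows, cols] = theta[m : m + q]
    M = theta[m + q : m + q + n * d].reshape(n, d)
    logs = theta[m + q + n * d :].reshape(n, d)
    return beta0, G, M, logs


def _neg_elbo_and_grad(theta, Y, rows, cols, t_q, w_q):
    n, m = Y.shape
    d = int(cols.max()) + 1 if len(cols) else 1
    beta0, G, M, logs = _unpack(theta, n, m, d, rows, cols)
    s2 = np.exp(2.0 * logs)  # n × d variational variances

    mu = beta0[None, :] + M @ G.T  # n × m
    sig2 = s2 @ (G**2).T  # n × m
    sig = np.sqrt(np.maximum(sig2, 1e-300))

    # E_q softplus(eta) and its derivatives by Gauss–Hermite quadrature
    eta = mu[:, :, None] + sig[:, :, None] * t_q[None, None, :]
    sp = np.logaddexp(0.0, eta)
    sg = expit(eta)
    Phi = sp @ w_q  # n × m
    P = sg @ w_q  # dPhi/dmu
    Q = sg @ (w_q * t_q)  # dPhi/dsigma

    elbo = float(np.sum(Y * mu - Phi)) + 0.5 * float(
        np.sum(1.0 + 2.0 * logs - M**2 - s2)
    )

    R = Y - P  # n × m
    g_beta0 = R.sum(axis=0)
    g_M = R @ G - M
    Qs = np.where(sig > 0, Q / sig, 0.0)  # n × m
    g_G = R.T @ M - (Qs.T @ s2) * G  # m × d
    g_logs = -(Qs @ G**2) * s2 + (1.0 - s2)
    grad = np.concatenate(
        [g_beta0, g_G[rows, cols], g_M.ravel(), g_logs.ravel()]
    )
    return -elbo, -grad


def fit_latent_model(
    Y,
    d: int,
    seed: int = 0,
    *,
    n_starts: int = 3,
    max_iter: int = 2000,
) -> LatentModelFit:
    """Fit the d-axis binomial GLLVM by variational approximation.

    Multiple starts (one informed by a singular-value decomposition of the
    centred data, the rest random) guard against local optima; the best
    bound wins.  Species present or absent everywhere carry no information
    about the latent axes and are dropped with a warning.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    Y = pd.DataFrame(Y)
    keep = [c for c in Y.columns if 0 < Y[c].sum() < len(Y)]
    dropped = [c for c in Y.columns if c not in keep]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-variance species")
    if not keep:
        raise ValueError("no informative species")
    Yk = Y[keep].to_numpy(dtype=float)
    if not np.isin(Yk, (0.0, 1.0)).all():
        raise ValueError("community matrix must be binary")
    n, m = Yk.shape
    rows, cols = _free_gamma_indices(m, d)
    q = len(rows)
    t_q, w_q = _gh_nodes()
    rng = np.random.default_rng(seed)

    # informed start: SVD of the centred matrix on a crude logit scale
    Z0 = (Yk - Yk.mean(axis=0)) * 4.0
    U, sv, Vt = np.linalg.svd(Z0, full_matrices=False)
    M0 = U[:, :d] * np.sqrt(n)
    M0 = M0[:, : d] if M0.shape[1] >= d else np.pad(M0, ((0, 0), (0, d - M0.shape[1])))
    G0 = (Vt[:d, :].T * sv[:d] / np.sqrt(n) / max(np.sqrt(n), 1.0))
    pbar = np.clip(Yk.mean(axis=0), 1e-3, 1 - 1e-3)
    b0 = np.log(pbar / (1 - pbar))

    best = None
    best_trace = None
    any_converged = False
    for start in range(n_starts):
        if start == 0:
            theta0 = np.concatenate(
                [b0, G0[rows, cols], M0.ravel(), np.full(n * d, np.log(0.5))]
            )
        else:
            theta0 = np.concatenate(
                [
                    b0 + 0.1 * rng.standard_normal(m),
                    0.3 * rng.standard_normal(q),
                    0.5 * rng.standard_normal(n * d),
                    np.full(n * d, np.log(0.5)),
                ]
            )
        trace: list[float] = []

        def cb(xk):
            trace.append(-_neg_elbo_and_grad(xk, Yk, rows, cols, t_q, w_q)[0])

        res = minimize(
            _neg_elbo_and_grad,
            theta0,
            args=(Yk, rows, cols, t_q, w_q),
            jac=True,
            method="L-BFGS-B",
            callback=cb,
            options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-7},
        )
        any_converged = any_converged or bool(res.success)
        if best is None or -res.fun > -best.fun:
            best = res
            best_trace = np.array(trace)

    if not any_converged:
        warnings.warn("latent model: no start converged; best iterate returned")
    beta0, G, M, logs = _unpack(best.x, n, m, d, rows, cols)
    # resolve reflection indeterminacy: positive loading diagonal
    for k in range(min(d, m)):
        if G[k, k] < 0:
            G[:, k] = -G[:, k]
            M[:, k] = -M[:, k]
    elbo = -float(best.fun)
    n_parameters = m + m * d - d * (d - 1) // 2
    return LatentModelFit(
        d=d,
        site_scores=M,
        site_sds=np.exp(logs),
        loadings=G,
        intercepts=beta0,
        log_likelihood=elbo,
        aic=-2.0 * elbo + 2.0 * n_parameters,
        n_parameters=n_parameters,
        converged=any_converged,
        elbo_trace=best_trace if best_trace is not None else np.array([]),
        species_kept=list(keep),
    )


def select_latent_dimension(
    Y,
    d_max: int = 5,
    seed: int = 0,
    taxon: str | None = None,
    *,
    n_starts: int = 3,
    max_iter: int = 2000,
) -> LatentAxes:
    """Fit d = 1..d_max and keep the scores of the lowest-AIC model."""
    if d_max < 1:
        raise ValueError("d_max must be >= 1")
    Y = pd.DataFrame(Y)
    fits: dict[int, LatentModelFit] = {}
    for d in range(1, d_max + 1):
        fits[d] = fit_latent_model(Y, d, seed=seed + d, n_starts=n_starts, max_iter=max_iter)
    if not any(f.converged for f in fits.values()):
        raise RuntimeError("no latent model converged for any candidate dimension")
    aic_by_d = {d: f.aic for d, f in fits.items()}
    d_best = min(aic_by_d, key=aic_by_d.get)
    fit = fits[d_best]
    scores = pd.DataFrame(
        fit.site_scores,
        index=Y.index,
        columns=[f"axis{k + 1}" for k in range(d_best)],
    )
    return LatentAxes(scores=scores, taxon=taxon, d=d_best, aic_by_d=aic_by_d, fit=fit)
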