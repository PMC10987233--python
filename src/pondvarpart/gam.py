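"""Penalized-regression-spline GAMs for a single Gaussian response.

The partitioning models regress each latent ordination axis (a continuous
score) on smooth terms: 1-D cubic regression splines of the environmental
principal components or of time, and a 2-D thin-plate-style smooth of the
planar coordinates.  Smoothness is chosen per term by GCV; model quality is
summarized by the adjusted R² with complexity measured in effective degrees
of freedom (trace of the hat matrix), and terms carry Wald-type approximate
p-values used by the forward-selection procedure with the double-stopping
criterion.

Implementation notes
--------------------
* 1-D basis: natural cubic spline through k knots at covariate quantiles,
  parameterized by its knot values; the curvature penalty is the exact
  integrated squared second derivative (Green–Silverman form
  ``D' B⁻¹ D``).  The sum-to-zero constraint is absorbed, leaving k−1
  columns whose penalty null space is the centred linear function.
* 2-D basis: radial basis r²·log r on k space-filling knots with polynomial
  null space {1, x, y}; the side condition T'δ = 0 is absorbed so the
  bending-energy penalty is positive semi-definite, then the centring
  constraint is absorbed as for 1-D terms.
* λ per term minimizes the global GCV score n·RSS/(n − edf)² by cyclic
  coordinate descent on a log-spaced grid with one local refinement pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats as sps

__all__ = ["SmoothSpec", "TermBasis", "GamFit", "build_basis", "fit_gam", "forward_select"]

_LOG10_LAMBDA_GRID = np.linspace(-6.0, 7.0, 14)


@dataclass(frozen=True)
class SmoothSpec:
    """A smooth term: one covariate (spline) or two (thin-plate surface)."""

    variables: tuple[str, ...]
    k: int = 9

    def __post_init__(self) -> None:
        if isinstance(self.variables, str):
            object.__setattr__(self, "variables", (self.variables,))
        else:
            object.__setattr__(self, "variables", tuple(self.variables))
        if len(self.variables) not in (1, 2):
            raise ValueError("a smooth takes 1 or 2 covariates")
        if self.k < 3:
            raise ValueError("basis dimension k must be >= 3")

    @property
    def label(self) -> str:
        return f"s({','.join(self.variables)})"


@dataclass
class TermBasis:
    """Centred design block and penalty for one smooth term."""

    spec: SmoothSpec
    X: np.ndarray  # n × p, centring constraint absorbed
    S: np.ndarray  # p × p penalty, PSD
    null_X: np.ndarray  # n × q, centred penalty-null-space columns (linear part)
    knots: np.ndarray


def _absorb_centering(X: np.ndarray, S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    c = X.sum(axis=0)
    Z = sla.null_space(c[None, :])
    Xc = X @ Z
    Sc = Z.T @ S @ Z
    Sc = 0.5 * (Sc + Sc.T)
    # unit spectral norm: puts every term's λ on a comparable scale
    if Sc.size:
        s_max = float(np.linalg.eigvalsh(Sc)[-1])
        if s_max > 0:
            Sc = Sc / s_max
    return Xc, Sc


def _natural_cubic(x: np.ndarray, knots: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Design mapping knot values to spline evaluations, and curvature penalty."""
    k = len(knots)
    h = np.diff(knots)
    # D (k-2 × k), B (k-2 × k-2): gamma = B^{-1} D f are knot second derivatives
    D = np.zeros((k - 2, k))
    B = np.zeros((k - 2, k - 2))
    for i in range(k - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
        B[i, i] = (h[i] + h[i + 1]) / 3.0
        if i + 1 < k - 2:
            B[i, i + 1] = B[i + 1, i] = h[i + 1] / 6.0
    F = np.linalg.solve(B, D)  # (k-2) × k
    K = D.T @ F  # curvature penalty on knot values
    xc = np.clip(x, knots[0], knots[-1])
    idx = np.clip(np.searchsorted(knots, xc, side="right") - 1, 0, k - 2)
    hl = h[idx]
    a = (knots[idx + 1] - xc) / hl
    b = (xc - knots[idx]) / hl
    cpos = hl**2 * (a**3 - a) / 6.0
    dpos = hl**2 * (b**3 - b) / 6.0
    n = len(x)
    A = np.zeros((n, k))
    A[np.arange(n), idx] = a
    A[np.arange(n), idx + 1] = b
    C = np.zeros((n, k))
    C[np.arange(n), idx] = cpos
    C[np.arange(n), idx + 1] = dpos
    # gamma vector padded with zeros at the two boundary knots (natural spline)
    G = np.zeros((k, k))
    G[1:-1, :] = F
    X = A + C @ G
    return X, 0.5 * (K + K.T)


def _farthest_point_knots(pts: np.ndarray, k: int) -> np.ndarray:
    """Greedy maximin subset — space-filling knot locations for the 2-D smooth."""
    n = len(pts)
    if k >= n:
        return pts
    start = int(np.argmin(np.linalg.norm(pts - pts.mean(axis=0), axis=1)))
    chosen = [start]
    d = np.linalg.norm(pts - pts[start], axis=1)
    for _ in range(k - 1):
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(pts - pts[nxt], axis=1))
    return pts[np.sort(chosen)]


def _tps_eta(r: np.ndarray) -> np.ndarray:
    out = np.zeros_like(r)
    pos = r > 0
    out[pos] = r[pos] ** 2 * np.log(r[pos])
    return out


def build_basis(predictors: pd.DataFrame, spec: SmoothSpec) -> TermBasis:
    """Construct the centred basis and penalty for one term.

    1-D: cubic regression spline, knots at quantiles of the covariate;
    duplicate quantiles reduce k with a warning.  2-D: thin-plate-style
    radial basis on a space-filling subset of site locations.
    """
    if any(v not in predictors.columns for v in spec.variables):
        missing = [v for v in spec.variables if v not in predictors.columns]
        raise KeyError(f"covariate(s) {missing} not in predictor table")
    if len(spec.variables) == 1:
        x = predictors[spec.variables[0]].to_numpy(dtype=float)
        uniq = np.unique(x)
        if uniq.size < 2:
            raise ValueError(f"constant covariate {spec.variables[0]!r}")
        k = spec.k
        if uniq.size < k:
            k = uniq.size
            warnings.warn(
                f"{spec.label}: only {uniq.size} distinct values; k reduced to {k}"
            )
        if k < 3:
            # two distinct values support only a linear trend
            xc = x - x.mean()
            Xc = xc[:, None] / max(np.abs(xc).max(), 1e-300)
            return TermBasis(spec, Xc, np.zeros((1, 1)), Xc.copy(), uniq)
        knots = np.unique(np.quantile(x, np.linspace(0.0, 1.0, k)))
        while knots.size < k:
            k = knots.size
            knots = np.unique(np.quantile(x, np.linspace(0.0, 1.0, k)))
        X, S = _natural_cubic(x, knots)
        Xc, Sc = _absorb_centering(X, S)
        null_X = (x - x.mean())[:, None]
        return TermBasis(spec, Xc, Sc, null_X, knots)

    # 2-D thin-plate-style smooth
    P = predictors[list(spec.variables)].to_numpy(dtype=float)
    if np.allclose(P.std(axis=0), 0.0):
        raise ValueError(f"constant covariates in {spec.label}")
    scale = max(P.max(axis=0).max() - P.min(axis=0).min(), 1e-12)
    Pu = (P - P.mean(axis=0)) / scale
    sites = np.unique(Pu, axis=0)
    k = min(spec.k, len(sites))
    if k < 4:
        raise ValueError(f"{spec.label}: need >= 4 distinct sites, got {len(sites)}")
    knots = _farthest_point_knots(sites, k)
    r_nk = np.linalg.norm(Pu[:, None, :] - knots[None, :, :], axis=-1)
    r_kk = np.linalg.norm(knots[:, None, :] - knots[None, :, :], axis=-1)
    E_nk = _tps_eta(r_nk)
    E_kk = _tps_eta(r_kk)
    T = np.column_stack([np.ones(k), knots])
    Zt = sla.null_space(T.T)  # k × (k-3)
    Sz = Zt.T @ E_kk @ Zt
    Sz = 0.5 * (Sz + Sz.T)
    w, V = np.linalg.eigh(Sz)
    Sz = (V * np.clip(w, 0.0, None)) @ V.T  # floor round-off negatives
    X = np.column_stack([E_nk @ Zt, Pu])
    p_pen = Zt.shape[1]
    S = np.zeros((p_pen + 2, p_pen + 2))
    S[:p_pen, :p_pen] = Sz
    Xc, Sc = _absorb_centering(X, S)
    null_X = Pu - Pu.mean(axis=0)
    return TermBasis(spec, Xc, Sc, null_X, knots)


@dataclass
class GamFit:
    """A fitted penalized-spline model for one response."""

    terms: list[SmoothSpec]
    coefficients: np.ndarray  # intercept first, then term blocks
    blocks: list[slice]
    lambdas: np.ndarray
    edf: np.ndarray  # per term
    edf_total: float
    fitted: np.ndarray
    rss: float
    tss: float
    r2: float
    r2_adj: float
    residual_variance: float
    term_pvalues: np.ndarray
    n: int
    gcv: float
    r2_adj_unbiased: float = 0.0
    X: np.ndarray = field(repr=False, default=None)
    bases: list[TermBasis] = field(repr=False, default=None)


def _assemble(y: np.ndarray, bases: list[TermBasis], linear_flags: list[bool]):
    n = len(y)
    cols = [np.ones((n, 1))]
    S_blocks, blocks = [], []
    start = 1
    for tb, lin in zip(bases, linear_flags):
        B = tb.null_X if lin else tb.X
        cols.append(B)
        p = B.shape[1]
        blocks.append(slice(start, start + p))
        S_blocks.append(None if lin else tb.S)
        start += p
    X = np.hstack(cols)
    return X, S_blocks, blocks


def _penalized_solve(XtX, Xty, S_blocks, blocks, lambdas, n, yty):
    A = XtX.copy()
    for lam, S, sl in zip(lambdas, S_blocks, blocks):
        if S is not None:
            A[sl, sl] += lam * S
    try:
        cf = sla.cho_factor(A, lower=True)

        def solver(B, cf=cf):
            return sla.cho_solve(cf, B)
    except sla.LinAlgError:
        # collinear predictors (e.g. a component duplicated across sets):
        # the minimum-norm solution reproduces the union-model fit
        Ainv = np.linalg.pinv(A, hermitian=True, rcond=1e-10)

        def solver(B, Ainv=Ainv):
            return Ainv @ B
    beta = solver(Xty)
    F = solver(XtX)  # (X'X + S)^{-1} X'X ; trace = edf
    rss = float(yty - 2 * beta @ Xty + beta @ XtX @ beta)
    rss = max(rss, 0.0)
    edf_total = float(np.trace(F))
    return beta, F, rss, edf_total, solver


def fit_gam(
    y,
    terms: list[SmoothSpec],
    predictors: pd.DataFrame,
    *,
    lambdas=None,
    linear: bool = False,
    bases: list[TermBasis] | None = None,
    max_cycles: int = 10,
    tol: float = 1e-8,
) -> GamFit:
    """Fit a Gaussian GAM ``y ~ 1 + Σ s_j(x_j)`` by penalized least squares.

    Per-term smoothing parameters minimize the GCV score
    ``n·RSS/(n − edf_total)²`` by cyclic coordinate descent on a log-λ grid
    (coarse pass then local refinement), iterated until the fitted values
    change by less than ``tol``.  ``linear=True`` restricts every term to
    its penalty null space (the classical linear-model limit, used as a
    bridge to traditional variation partitioning).  ``lambdas`` fixes the
    smoothing parameters and skips the search.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if not terms:
        fitted = np.full(n, y.mean())
        rss = float(((y - fitted) ** 2).sum())
        return GamFit(
            terms=[], coefficients=np.array([y.mean()]), blocks=[],
            lambdas=np.array([]), edf=np.array([]), edf_total=1.0,
            fitted=fitted, rss=rss, tss=rss, r2=0.0, r2_adj=0.0,
            residual_variance=rss / max(n - 1, 1), term_pvalues=np.array([]),
            n=n, gcv=n * rss / (n - 1.0) ** 2, X=np.ones((n, 1)), bases=[],
        )
    if bases is None:
        bases = [build_basis(predictors, t) for t in terms]
    # a mapping fixes λ per term regardless of which model the term sits in
    from collections.abc import Mapping

    if isinstance(lambdas, Mapping):
        lambdas = [lambdas[t] for t in terms]
    # drop terms whose design block duplicates an earlier one (a predictor
    # shared between components): the union model is fit exactly once
    kept: list[int] = []
    for i, tb in enumerate(bases):
        if not any(
            tb.X.shape == bases[j].X.shape
            and np.allclose(tb.X, bases[j].X, atol=1e-12, rtol=0.0)
            for j in kept
        ):
            kept.append(i)
    if len(kept) < len(bases):
        terms = [terms[i] for i in kept]
        bases = [bases[i] for i in kept]
        if lambdas is not None and len(lambdas) > len(kept):
            lambdas = [lambdas[i] for i in kept]
    n_terms = len(terms)
    # λ = inf is the exact null-space (linear) limit for that term
    linear_flags = [linear] * n_terms
    if lambdas is not None:
        lam_in = np.asarray(lambdas, dtype=float)
        linear_flags = [linear or np.isinf(l) for l in lam_in]
    X, S_blocks, blocks = _assemble(y, bases, linear_flags)
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    tss = float(((y - y.mean()) ** 2).sum())

    if all(S is None or S.size == 0 for S in S_blocks):
        lam = np.zeros(n_terms)
        beta, F, rss, edf_total, solver = _penalized_solve(
            XtX, Xty, [None] * n_terms, blocks, lam, n, yty
        )
    elif lambdas is not None:
        lam = np.where(np.isinf(lam_in), 0.0, lam_in)
        beta, F, rss, edf_total, solver = _penalized_solve(XtX, Xty, S_blocks, blocks, lam, n, yty)
    else:
        lam = np.full(n_terms, 1.0)
        prev_fit = None
        for _cycle in range(max_cycles):
            for j in range(n_terms):
                if S_blocks[j] is None or S_blocks[j].size == 0:
                    continue
                best = (np.inf, lam[j])
                # descending scan: GCV ties (flat curves) resolve to the
                # smoothest candidate
                grid = 10.0 ** _LOG10_LAMBDA_GRID[::-1]
                for lam_j in grid:
                    trial = lam.copy()
                    trial[j] = lam_j
                    _, _, rss_t, edf_t, _ = _penalized_solve(
                        XtX, Xty, S_blocks, blocks, trial, n, yty
                    )
                    gcv = n * rss_t / (n - edf_t) ** 2
                    if gcv < best[0]:
                        best = (gcv, lam_j)
                # local refinement around the best grid point
                centre = np.log10(best[1])
                for lg in np.linspace(centre + 0.6, centre - 0.6, 9):
                    trial = lam.copy()
                    trial[j] = 10.0 ** lg
                    _, _, rss_t, edf_t, _ = _penalized_solve(
                        XtX, Xty, S_blocks, blocks, trial, n, yty
                    )
                    gcv = n * rss_t / (n - edf_t) ** 2
                    if gcv < best[0]:
                        best = (gcv, 10.0 ** lg)
                lam[j] = best[1]
                if np.isclose(np.log10(lam[j]), _LOG10_LAMBDA_GRID[0]) or np.isclose(
                    np.log10(lam[j]), _LOG10_LAMBDA_GRID[-1]
                ):
                    warnings.warn(
                        f"{terms[j].label}: smoothing parameter search hit a bound"
                    )
            beta, F, rss, edf_total, solver = _penalized_solve(
                XtX, Xty, S_blocks, blocks, lam, n, yty
            )
            fitted = X @ beta
            if prev_fit is not None and np.max(np.abs(fitted - prev_fit)) < tol:
                break
            prev_fit = fitted

    fitted = X @ beta
    edf_term = np.array([float(np.trace(F[sl, sl])) for sl in blocks])
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    denom = max(n - edf_total, 1e-8)
    r2_adj = 1.0 - (rss / denom) / (tss / (n - 1)) if tss > 0 else 0.0
    sigma2 = rss / denom
    # unbiased-risk variant: with edf* = 2·tr(H) − tr(H'H) the null
    # expectation of the adjusted R² is exactly zero for a fixed smoother —
    # the scale the MSR null correction works on
    edf_star = 2.0 * edf_total - float(np.sum(F * F.T))
    denom_star = max(n - edf_star, 1e-8)
    r2_adj_unbiased = 1.0 - (rss / denom_star) / (tss / (n - 1)) if tss > 0 else 0.0

    # Wald-type term p-values on the penalized coefficients.  The Bayesian
    # posterior covariance (X'X + S)⁻¹σ² with rank = ceil(edf) calibrates
    # markedly better under the null than the frequentist sandwich after
    # GCV smoothing selection.
    Ainv = solver(np.eye(XtX.shape[0]))
    Vb = Ainv * sigma2
    pvals = np.empty(n_terms)
    for j, sl in enumerate(blocks):
        bj = beta[sl]
        Vj = Vb[sl, sl]
        rank = max(int(np.ceil(edf_term[j])), 1)
        wv, Wv = np.linalg.eigh(0.5 * (Vj + Vj.T))
        order = np.argsort(wv)[::-1][:rank]
        wr = np.clip(wv[order], 1e-300, None)
        proj = Wv[:, order].T @ bj
        stat = float(np.sum(proj**2 / wr))
        pvals[j] = float(sps.f.sf(stat / rank, rank, max(n - edf_total, 1.0)))

    return GamFit(
        terms=list(terms), coefficients=beta, blocks=blocks, lambdas=lam,
        edf=edf_term, edf_total=edf_total, fitted=fitted, rss=rss, tss=tss,
        r2=r2, r2_adj=r2_adj, residual_variance=sigma2, term_pvalues=pvals,
        n=n, gcv=n * rss / denom**2, r2_adj_unbiased=r2_adj_unbiased,
        X=X, bases=bases,
    )


@dataclass
class SelectionResult:
    selected: list[SmoothSpec]
    r2_adj: float
    r2_global: float
    log: list[dict]
    fallback_used: bool = False


def forward_select(
    y,
    candidates: list[SmoothSpec],
    predictors: pd.DataFrame,
    *,
    alpha: float = 0.05,
    max_terms: int | None = None,
    linear: bool = False,
) -> SelectionResult:
    """Forward selection with the double-stopping criterion.

    A global model with all candidates sets the adjusted-R² ceiling.  At
    each step the candidate whose addition maximizes adjusted R² is
    examined; selection stops when that candidate's Wald p-value is not
    below ``alpha``, when the selected model's adjusted R² reaches the
    global model's, or when ``max_terms`` is reached.  If nothing is
    selected but some candidate is significant on its own, the single most
    significant candidate is kept (the at-least-one fallback).
    """
    if not candidates:
        raise ValueError("no candidate terms")
    log: list[dict] = []
    global_fit = fit_gam(y, candidates, predictors, linear=linear)
    r2_global = global_fit.r2_adj
    selected: list[SmoothSpec] = []
    remaining = list(candidates)
    current_r2 = 0.0
    while remaining:
        if max_terms is not None and len(selected) >= max_terms:
            log.append({"event": "stop", "reason": "max_terms"})
            break
        trials = []
        for cand in remaining:
            fit = fit_gam(y, selected + [cand], predictors, linear=linear)
            trials.append((fit.r2_adj, cand, fit.term_pvalues[-1]))
        best_r2, best_cand, best_p = max(trials, key=lambda t: t[0])
        log.append(
            {"event": "step", "candidate": best_cand.label,
             "r2_adj": best_r2, "p": best_p}
        )
        if best_p >= alpha:
            log.append({"event": "stop", "reason": "p_not_significant"})
            break
        selected.append(best_cand)
        remaining.remove(best_cand)
        current_r2 = best_r2
        if current_r2 >= r2_global:
            log.append({"event": "stop", "reason": "reached_global_r2"})
            break
    fallback = False
    if not selected:
        singles = []
        for cand in candidates:
            fit = fit_gam(y, [cand], predictors, linear=linear)
            singles.append((fit.term_pvalues[0], cand, fit.r2_adj))
        p_min, cand_min, r2_min = min(singles, key=lambda t: t[0])
        if p_min < alpha:
            selected = [cand_min]
            current_r2 = r2_min
            fallback = True
            log.append({"event": "fallback", "candidate": cand_min.label, "p": p_min})
    return SelectionResult(selected, current_r2, r2_global, log, fallback)
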