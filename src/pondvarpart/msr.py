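"""Moran eigenvector bases and Moran spectral randomization (MSR).

The environmental fraction of a variation partition is inflated whenever
the environment itself is spatially (or spatio-temporally) structured.  The
correction used here nulls that inflation with surrogate environmental
variables that keep each variable's variance and autocorrelation (Moran's
I) but scramble everything else.

Surrogates are built by expressing a centred variable in the orthonormal
eigenbasis of the doubly centred spatial weight matrix (the Moran
eigenvector basis) and flipping the signs of its coefficients at random —
an orthogonal remix that preserves the coefficient magnitudes and therefore
both the variance and the Moran quadratic form exactly.  One sign vector
per draw is shared across variables, so their cross-covariances are
preserved too.

For pooled pond × occasion data the basis is the Kronecker combination of
the spatial eigenbasis with a temporal eigenbasis derived from the chain
graph over ordered occasions; sign flips then preserve the spatio-temporal
autocorrelation quadratic form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay

__all__ = [
    "gabriel_graph",
    "MoranBasis",
    "moran_basis",
    "spatiotemporal_basis",
    "moran_i",
    "msr_surrogates",
]


def gabriel_graph(coords: np.ndarray) -> np.ndarray:
    """Binary adjacency of the Gabriel graph over planar points.

    Edge (i, j) is kept iff no third point lies inside the circle with
    diameter ij.  Candidate edges come from the Delaunay triangulation
    (the Gabriel graph is one of its subgraphs).
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n < 3:
        W = np.ones((n, n)) - np.eye(n)
        return W
    tri = Delaunay(coords)
    edges = set()
    for simplex in tri.simplices:
        for a in range(len(simplex)):
            for b in range(a + 1, len(simplex)):
                i, j = int(simplex[a]), int(simplex[b])
                edges.add((min(i, j), max(i, j)))
    W = np.zeros((n, n))
    for i, j in edges:
        mid = 0.5 * (coords[i] + coords[j])
        r2 = np.sum((coords[i] - coords[j]) ** 2) / 4.0
        d2 = np.sum((coords - mid) ** 2, axis=1)
        d2[[i, j]] = np.inf
        if np.all(d2 > r2 - 1e-12):
            W[i, j] = W[j, i] = 1.0
    return W


def _chain_graph(n: int) -> np.ndarray:
    W = np.zeros((n, n))
    for i in range(n - 1):
        W[i, i + 1] = W[i + 1, i] = 1.0
    return W


@dataclass
class MoranBasis:
    """Orthonormal eigenbasis of a doubly centred connectivity matrix."""

    vectors: np.ndarray  # n × n orthonormal
    eigenvalues: np.ndarray  # n, aligned with vectors
    quad: np.ndarray  # the centred quadratic-form matrix the basis diagonalizes
    W: np.ndarray  # raw connectivity


def _centered_eigh(C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of a doubly centred matrix with the constant
    vector carried as an exact trailing eigenvector (eigenvalue 0).

    Decomposing on the orthogonal complement of 1 prevents numerical mixing
    of the constant direction into near-zero eigenvectors, which would
    break the mean-preservation of coefficient sign flips.
    """
    from scipy.linalg import null_space

    n = C.shape[0]
    Q = null_space(np.ones((1, n)))  # n × (n-1), orthonormal, ⊥ 1
    lam, E = np.linalg.eigh(Q.T @ C @ Q)
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    V = Q @ E[:, order]
    pos = int(np.searchsorted(-lam, 0.0, side="left"))  # keep descending order
    V = np.insert(V, pos, 1.0 / np.sqrt(n), axis=1)
    lam = np.insert(lam, pos, 0.0)
    return V, lam


def moran_basis(coords: np.ndarray, W: np.ndarray | None = None) -> MoranBasis:
    """Moran eigenvector basis from pond coordinates (Gabriel connectivity)."""
    if W is None:
        W = gabriel_graph(np.asarray(coords, dtype=float))
    n = W.shape[0]
    H = np.eye(n) - np.ones((n, n)) / n
    C = H @ (0.5 * (W + W.T)) @ H
    C = 0.5 * (C + C.T)
    eigvecs, eigvals = _centered_eigh(C)
    return MoranBasis(eigvecs, eigvals, C, W)


def spatiotemporal_basis(coords: np.ndarray, n_occasions: int) -> MoranBasis:
    """Kronecker (time ⊗ space) basis for pooled pond × occasion samples.

    Sample order must be occasion-major: all ponds at occasion 1, then all
    at occasion 2, ...  The quadratic form is the sum of the temporal and
    spatial centred forms acting on their own margins; the Kronecker basis
    diagonalizes it, so coefficient sign flips preserve it.
    """
    sb = moran_basis(coords)
    Wt = _chain_graph(n_occasions)
    nt = n_occasions
    Ht = np.eye(nt) - np.ones((nt, nt)) / nt
    Ct = Ht @ Wt @ Ht
    Vt, et = _centered_eigh(0.5 * (Ct + Ct.T))
    ns = sb.vectors.shape[0]
    V = np.kron(Vt, sb.vectors)
    quad = np.kron(Ct, np.eye(ns)) + np.kron(np.eye(nt), sb.quad)
    lam = (np.kron(et, np.ones(ns)) + np.kron(np.ones(nt), sb.eigenvalues))
    W = np.kron(Wt, np.eye(ns)) + np.kron(np.eye(nt), sb.W)
    return MoranBasis(V, lam, quad, W)


def moran_i(x: np.ndarray, basis: MoranBasis) -> float:
    """Moran's I of ``x`` under the basis' connectivity.

    I = (n / Σw) · (x_cᵀ C x_c) / (x_cᵀ x_c) with C the doubly centred
    weight matrix — identical to the classical definition for binary W.
    """
    x = np.asarray(x, dtype=float)
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0:
        raise ValueError("constant variable has undefined Moran's I")
    w_sum = float(basis.W.sum())
    return len(x) / w_sum * float(xc @ basis.quad @ xc) / denom


def msr_surrogates(
    X: np.ndarray,
    basis: MoranBasis,
    n_null: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Spatially constrained randomizations of the columns of ``X``.

    Returns an array of shape (n_null, n, p).  Each draw flips the signs of
    the eigenbasis coefficients (one sign vector shared by all columns);
    every surrogate column keeps its mean, variance, Moran's I and the
    cross-covariances with the other columns.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    n, p = X.shape
    V = basis.vectors
    mu = X.mean(axis=0)
    coeff = V.T @ (X - mu)  # n × p
    out = np.empty((n_null, n, p))
    for l in range(n_null):
        signs = rng.choice([-1.0, 1.0], size=n)
        out[l] = V @ (signs[:, None] * coeff) + mu
    return out
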