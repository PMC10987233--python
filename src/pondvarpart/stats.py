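"""Auxiliary inference: multivariate dispersion and paired signed-rank tests.

PERMDISP compares environmental heterogeneity between groups (regions, or
sampling periods) as the spread of samples around their group's multivariate
centre, with significance by permutation.  The exact paired Wilcoxon test
compares the relative fractions obtained by the spatial and spatio-temporal
partitioning approaches across taxa; with only seven taxa per region the
exact (enumerative) null is the appropriate reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .env import EnvMatrix, standardized_values

__all__ = [
    "DispersionResult",
    "WilcoxonResult",
    "permdisp",
    "wilcoxon_paired_exact",
    "compare_approaches",
]


@dataclass
class DispersionResult:
    groups: np.ndarray
    distances: np.ndarray  # per-sample distance to own group's centre
    F: float
    p: float
    n_perm: int
    center: str


@dataclass
class WilcoxonResult:
    V: float
    p: float
    n: int  # pairs used after dropping zero differences


def _geometric_median(X: np.ndarray, tol: float = 1e-10, max_iter: int = 500) -> np.ndarray:
    """Weiszfeld iteration with the standard fix when an iterate hits a point."""
    y = X.mean(axis=0)
    for _ in range(max_iter):
        d = np.linalg.norm(X - y, axis=1)
        at_point = d < 1e-12
        if at_point.any():
            d = np.where(at_point, np.inf, d)
        w = 1.0 / d
        y_new = (w[:, None] * X).sum(axis=0) / w.sum()
        if np.linalg.norm(y_new - y) < tol:
            return y_new
        y = y_new
    return y


def _anova_f(distances: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = len(distances)
    grand = distances.mean()
    ss_between = 0.0
    ss_within = 0.0
    for g in range(n_groups):
        d_g = distances[codes == g]
        ss_between += len(d_g) * (d_g.mean() - grand) ** 2
        ss_within += ((d_g - d_g.mean()) ** 2).sum()
    df_b = n_groups - 1
    df_w = n - n_groups
    if ss_within == 0.0:
        return 0.0 if ss_between == 0.0 else np.inf
    return (ss_between / df_b) / (ss_within / df_w)


def permdisp(
    env,
    groups,
    n_perm: int = 999,
    seed: int = 0,
    center: str = "median",
) -> DispersionResult:
    """Homogeneity of multivariate dispersions, Euclidean distances.

    Variables are standardized; each sample's distance to its own group's
    spatial median (or centroid) is the dispersion measure.  The observed
    one-way ANOVA F on these distances is compared with its distribution
    under ``n_perm`` random permutations of the group labels:
    p = (#{F* >= F} + 1) / (n_perm + 1).
    """
    if isinstance(env, EnvMatrix):
        X = standardized_values(env).to_numpy(dtype=float)
    else:
        X = np.asarray(env, dtype=float)
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("zero-variance variable in dispersion input")
        X = (X - X.mean(axis=0)) / sd
    groups = np.asarray(groups)
    if len(groups) != len(X):
        raise ValueError("groups length does not match sample count")
    labels, codes = np.unique(groups, return_inverse=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(codes)
    if counts.min() < 2:
        small = labels[counts < 2].tolist()
        raise ValueError(f"groups with fewer than 2 samples: {small}")
    if center not in ("median", "centroid"):
        raise ValueError("center must be 'median' or 'centroid'")

    distances = np.empty(len(X))
    for g in range(len(labels)):
        Xg = X[codes == g]
        c = _geometric_median(Xg) if center == "median" else Xg.mean(axis=0)
        distances[codes == g] = np.linalg.norm(Xg - c, axis=1)

    F_obs = _anova_f(distances, codes, len(labels))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _anova_f(distances, perm, len(labels)) >= F_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return DispersionResult(
        groups=groups, distances=distances, F=F_obs, p=p, n_perm=n_perm, center=center
    )


def wilcoxon_paired_exact(x, y) -> WilcoxonResult:
    """Exact two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped (with a warning); |differences| receive
    midranks; V sums the ranks of the positive differences.  The exact
    two-sided p-value enumerates all 2ⁿ equally likely sign assignments of
    the observed ranks: p = 2·min(P(V* ≤ V), P(V* ≥ V)), capped at 1.
    With seven direction-consistent pairs this gives V ∈ {0, 28} and
    p = 2/2⁷ ≈ 0.016.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    d = x - y
    nonzero = d != 0.0
    if not nonzero.any():
        raise ValueError("no informative pairs: all differences are zero")
    if nonzero.sum() < len(d):
        warnings.warn(f"dropping {int((~nonzero).sum())} zero difference(s)")
    d = d[nonzero]
    n = len(d)
    if n > 25:
        raise ValueError("exact enumeration limited to 25 nonzero pairs")
    ranks = rankdata(np.abs(d))
    V = float(ranks[d > 0].sum())

    # distribution of V* over all 2^n sign patterns via a generating-function
    # convolution on doubled (integer) midranks
    r2 = np.round(2.0 * ranks).astype(int)
    dist = np.zeros(r2.sum() + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: len(dist) - r]
        dist = 0.5 * (dist + shifted)
    V2 = int(round(2.0 * V))
    p_le = dist[: V2 + 1].sum()
    p_ge = dist[V2:].sum()
    p = min(1.0, 2.0 * min(p_le, p_ge))
    return WilcoxonResult(V=V, p=p, n=n)


def st_relative_excluding_time(partition3, corrected: bool | None = None) -> dict:
    """Spatio-temporal fractions renormalized over the E+S mass only.

    Maps the pooled three-way fractions onto the two-way vocabulary —
    pure_E ← E|(S+T), pure_S ← S|(E+T), common ← (E∩S)|T — and divides by
    their (truncated) sum, which is how the two approaches are compared
    head-to-head per taxon.
    """
    use_corr = partition3.corrected is not None if corrected is None else corrected
    src = partition3.corrected if use_corr else partition3.fractions
    vals = {
        "pure_E": max(src["pure_E"], 0.0),
        "pure_S": max(src["pure_S"], 0.0),
        "common": max(src["ES_given_T"], 0.0),
    }
    denom = sum(vals.values())
    if denom <= 0:
        return {k: np.nan for k in vals}
    return {k: v / denom for k, v in vals.items()}


def compare_approaches(
    spatial_results: dict,
    spatiotemporal_results: dict,
) -> pd.DataFrame:
    """Paired Wilcoxon contrasts of relative fractions between approaches.

    ``spatial_results``: taxon → list of two-way partition results (one per
    period); ``spatiotemporal_results``: taxon → three-way result.  Per
    taxon the spatial value of each fraction is the mean over periods of
    its relative share, and the spatio-temporal value is the share after
    excluding the temporal fractions.  Returns one row per fraction with
    V, p and n (NA when all paired differences are zero).
    """
    taxa_s = set(spatial_results)
    taxa_t = set(spatiotemporal_results)
    if taxa_s != taxa_t:
        raise ValueError(
            f"taxon mismatch between approaches: only-spatial={sorted(taxa_s - taxa_t)}, "
            f"only-spatiotemporal={sorted(taxa_t - taxa_s)}"
        )
    taxa = sorted(taxa_s)
    rows = []
    for frac in ("pure_E", "pure_S", "common"):
        xs, ys = [], []
        for taxon in taxa:
            per_period = [
                r.relative[frac]
                for r in spatial_results[taxon]
                if r.relative is not None
            ]
            st = st_relative_excluding_time(spatiotemporal_results[taxon])
            if not per_period or not np.isfinite(st[frac]):
                continue
            xs.append(float(np.mean(per_period)))
            ys.append(st[frac])
        row = {"fraction": frac, "n_taxa": len(xs)}
        try:
            res = wilcoxon_paired_exact(np.array(xs), np.array(ys))
            row.update({"V": res.V, "p": res.p, "n": res.n})
        except ValueError:
            row.update({"V": np.nan, "p": np.nan, "n": 0})
        rows.append(row)
    return pd.DataFrame(rows)
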