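"""Adjusted-R² variation partitioning over GAM fits.

Every latent axis is regressed on each combination of the predictor
components — environment E (smooths of the first three environmental PCs),
space S (a smooth surface of the planar coordinates) and, in the pooled
analysis, time T (a smooth of days since first sampling).  Component R²
values are the unweighted average of the adjusted R² across axes; the
unique and shared fractions then follow by inclusion–exclusion:

two components      pure_E = R²(ES) − R²(S)
                    pure_S = R²(ES) − R²(E)
                    common = R²(E) + R²(S) − R²(ES)

three components    the seven Möbius fractions of {E, S, T}, with the
                    triple overlap taken as the residual that makes the
                    seven sum exactly to R²(EST).

Because adjusted R² is not monotone in predictor sets, individual fractions
can be negative; they are reported raw and truncated at zero for the
relative view (fraction / total explained), which is how results are
compared across taxa and regions.

The environmental fractions can be corrected for spurious spatial (or
spatio-temporal) structure via Moran spectral randomization: see
:func:`correct_env`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gam import SmoothSpec, fit_gam
from .latent import LatentAxes
from . import msr

__all__ = [
    "PartitionResult2",
    "PartitionResult3",
    "partition_two",
    "partition_three",
    "correct_env",
    "relative_fractions",
]

_FRACTIONS2 = ("pure_E", "pure_S", "common")
_FRACTIONS3 = (
    "pure_E",
    "pure_S",
    "pure_T",
    "ES_given_T",
    "ET_given_S",
    "ST_given_E",
    "EST",
)


def _axis_matrix(axes) -> np.ndarray:
    if isinstance(axes, LatentAxes):
        return axes.scores.to_numpy(dtype=float)
    arr = np.asarray(axes, dtype=float)
    return arr[:, None] if arr.ndim == 1 else arr


def _mean_adj_r2(
    A: np.ndarray, terms: list[SmoothSpec], predictors: pd.DataFrame, **kw
) -> float:
    """Average adjusted R² of per-axis GAMs for one predictor set."""
    if not terms:
        return 0.0
    vals = [fit_gam(A[:, j], terms, predictors, **kw).r2_adj for j in range(A.shape[1])]
    return float(np.mean(vals))


@dataclass
class PartitionResult2:
    """Two-component (E, S) partition of one taxon/period."""

    total: float
    fractions: dict  # raw values, keys pure_E / pure_S / common
    model_r2: dict  # keys E, S, ES
    corrected: dict | None = None
    corrected_total: float | None = None
    relative: dict | None = None
    flags: list = field(default_factory=list)
    n_axes: int = 1
    # context needed to recompute models under MSR nulls
    _axes: np.ndarray | None = field(default=None, repr=False)
    _predictors: pd.DataFrame | None = field(default=None, repr=False)
    _E_terms: list | None = field(default=None, repr=False)
    _S_terms: list | None = field(default=None, repr=False)
    _gam_kw: dict = field(default_factory=dict, repr=False)

    @property
    def fraction_names(self):
        return _FRACTIONS2

    def truncated(self, corrected: bool = False) -> dict:
        src = self.corrected if (corrected and self.corrected is not None) else self.fractions
        return {k: max(v, 0.0) for k, v in src.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        rel = self.relative or {}
        for name in self.fraction_names:
            rows.append(
                {
                    "fraction": name,
                    "raw": self.fractions[name],
                    "corrected": (self.corrected or {}).get(name, np.nan),
                    "truncated": self.truncated(corrected=self.corrected is not None)[name],
                    "relative": rel.get(name, np.nan),
                }
            )
        rows.append(
            {
                "fraction": "total",
                "raw": self.total,
                "corrected": self.corrected_total if self.corrected_total is not None else np.nan,
                "truncated": max(self.total, 0.0),
                "relative": 1.0 if rel else np.nan,
            }
        )
        return pd.DataFrame(rows)


@dataclass
class PartitionResult3(PartitionResult2):
    """Three-component (E, S, T) partition of one taxon (pooled occasions)."""

    _T_terms: list | None = field(default=None, repr=False)

    @property
    def fraction_names(self):
        return _FRACTIONS3


def _fractions_two(r_e: float, r_s: float, r_es: float) -> dict:
    return {
        "pure_E": r_es - r_s,
        "pure_S": r_es - r_e,
        "common": r_e + r_s - r_es,
    }


def _fractions_three(u: dict) -> dict:
    """Möbius masses from union R² values keyed 'E','S','T','ES','ET','ST','EST'."""
    out = {
        "pure_E": u["EST"] - u["ST"],
        "pure_S": u["EST"] - u["ET"],
        "pure_T": u["EST"] - u["ES"],
        "ES_given_T": u["ET"] + u["ST"] - u["T"] - u["EST"],
        "ET_given_S": u["ES"] + u["ST"] - u["S"] - u["EST"],
        "ST_given_E": u["ES"] + u["ET"] - u["E"] - u["EST"],
    }
    out["EST"] = u["EST"] - sum(out.values())
    return out


def partition_two(
    axes,
    predictors: pd.DataFrame,
    E_terms: list[SmoothSpec],
    S_terms: list[SmoothSpec],
    **gam_kw,
) -> PartitionResult2:
    """Partition the latent axes' variation into (E | S), (S | E), (E ∩ S).

    ``E_terms`` and ``S_terms`` are the forward-selected smooths for each
    component; either may be empty (that component then explains nothing
    and the result is flagged degenerate if both are).
    """
    A = _axis_matrix(axes)
    flags = []
    if not E_terms and not S_terms:
        flags.append("degenerate: no predictors in either component")
    r_e = _mean_adj_r2(A, E_terms, predictors, **gam_kw)
    r_s = _mean_adj_r2(A, S_terms, predictors, **gam_kw)
    r_es = (
        _mean_adj_r2(A, list(E_terms) + list(S_terms), predictors, **gam_kw)
        if (E_terms or S_terms)
        else 0.0
    )
    fr = _fractions_two(r_e, r_s, r_es)
    res = PartitionResult2(
        total=r_es,
        fractions=fr,
        model_r2={"E": r_e, "S": r_s, "ES": r_es},
        flags=flags,
        n_axes=A.shape[1],
        _axes=A,
        _predictors=predictors,
        _E_terms=list(E_terms),
        _S_terms=list(S_terms),
        _gam_kw=dict(gam_kw),
    )
    relative_fractions(res)
    return res


def partition_three(
    axes,
    predictors: pd.DataFrame,
    E_terms: list[SmoothSpec],
    S_terms: list[SmoothSpec],
    T_terms: list[SmoothSpec],
    **gam_kw,
) -> PartitionResult3:
    """Partition pooled variation into the seven (E, S, T) fractions."""
    A = _axis_matrix(axes)
    flags = []
    if not (E_terms or S_terms or T_terms):
        flags.append("degenerate: no predictors in any component")
    sets = {
        "E": list(E_terms),
        "S": list(S_terms),
        "T": list(T_terms),
    }
    u = {}
    for key in ("E", "S", "T", "ES", "ET", "ST", "EST"):
        terms = [t for c in key for t in sets[c]]
        u[key] = _mean_adj_r2(A, terms, predictors, **gam_kw) if terms else 0.0
    fr = _fractions_three(u)
    res = PartitionResult3(
        total=u["EST"],
        fractions=fr,
        model_r2=u,
        flags=flags,
        n_axes=A.shape[1],
        _axes=A,
        _predictors=predictors,
        _E_terms=sets["E"],
        _S_terms=sets["S"],
        _gam_kw=dict(gam_kw),
        _T_terms=sets["T"],
    )
    relative_fractions(res)
    return res


def relative_fractions(partition: PartitionResult2) -> dict | None:
    """Relative view: truncated fractions divided by their sum.

    Undefined (and flagged) when nothing is explained.  Stored on the
    result and returned.
    """
    tr = partition.truncated(corrected=partition.corrected is not None)
    denom = sum(tr.values())
    total_used = (
        partition.corrected_total
        if partition.corrected is not None and partition.corrected_total is not None
        else partition.total
    )
    if total_used <= 0 or denom <= 0:
        partition.relative = None
        if "relative view undefined (total <= 0)" not in partition.flags:
            partition.flags.append("relative view undefined (total <= 0)")
        return None
    partition.relative = {k: v / denom for k, v in tr.items()}
    return partition.relative


def _env_variables(E_terms: list[SmoothSpec]) -> list[str]:
    seen: list[str] = []
    for t in E_terms:
        for v in t.variables:
            if v not in seen:
                seen.append(v)
    return seen


def correct_env(
    partition: PartitionResult2,
    coordinates: np.ndarray,
    *,
    n_occasions: int = 1,
    n_null: int = 199,
    seed: int = 0,
) -> PartitionResult2:
    """MSR null correction of the environmental fractions (in place).

    For every fitted model that contains E, the spurious increment that a
    spatially (or spatio-temporally) structured but ecologically unlinked
    environment would contribute is estimated as the null mean over
    ``n_null`` Moran-spectral-randomization surrogates of the environmental
    predictors, and subtracted from that model's R².  All fractions are
    then recomputed from the corrected model R²s, so the corrected
    fractions sum to a corrected total.

    ``coordinates`` are the pond planar coordinates (one row per pond).
    For pooled data pass ``n_occasions > 1``; samples must then be ordered
    occasion-major (all ponds of occasion 1 first), the layout produced by
    the simulator and the pipeline.
    """
    if partition._axes is None:
        raise ValueError("partition lacks refit context")
    coords = np.asarray(coordinates, dtype=float)
    if len(coords) < 4:
        partition.flags.append("correction unavailable: fewer than 4 ponds")
        return partition
    if not partition._E_terms:
        partition.corrected = dict(partition.fractions)
        partition.corrected_total = partition.total
        partition.flags.append("no environmental terms: correction is identity")
        relative_fractions(partition)
        return partition

    basis = (
        msr.spatiotemporal_basis(coords, n_occasions)
        if n_occasions > 1
        else msr.moran_basis(coords)
    )
    env_vars = _env_variables(partition._E_terms)
    P = partition._predictors
    X_env = P[env_vars].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    surrogates = msr.msr_surrogates(X_env, basis, n_null, rng)

    A = partition._axes
    kw = partition._gam_kw
    is3 = isinstance(partition, PartitionResult3)
    S_terms = partition._S_terms or []
    T_terms = getattr(partition, "_T_terms", None) or []
    u = partition.model_r2

    # models containing E, and the corresponding E-free submodels
    if is3:
        model_pairs = [("E", ""), ("ES", "S"), ("ET", "T"), ("EST", "ST")]
    else:
        model_pairs = [("E", ""), ("ES", "S")]
    # Null refits hold each model's smoothing parameters at their observed
    # (GCV-chosen) values: the null then measures autocorrelation leakage at
    # fixed model complexity, not the smoother's own adaptive-fitting bias.
    # The spurious increment is a difference on the unbiased-risk R² scale
    # (null mean of the E-containing model minus the observed E-free base
    # model), which is exactly zero in expectation when the surrogates are
    # unrelated to the response.
    def _terms_for(key: str) -> list:
        terms = list(partition._E_terms) if "E" in key else []
        if "S" in key:
            terms += S_terms
        if "T" in key:
            terms += T_terms
        return terms

    obs_fits: dict[str, list] = {}
    base_unbiased: dict[str, float] = {"": 0.0}
    for key, base in model_pairs:
        obs_fits[key] = [
            fit_gam(A[:, j], _terms_for(key), P, **kw) for j in range(A.shape[1])
        ]
        if base and base not in base_unbiased:
            base_unbiased[base] = float(
                np.mean(
                    [
                        fit_gam(A[:, j], _terms_for(base), P, **kw).r2_adj_unbiased
                        for j in range(A.shape[1])
                    ]
                )
            )
    null_means = {k: 0.0 for k, _ in model_pairs}
    for l in range(n_null):
        Pl = P.copy()
        Pl[env_vars] = surrogates[l]
        for key, _base in model_pairs:
            vals = [
                fit_gam(
                    A[:, j], f.terms, Pl, lambdas=f.lambdas, **kw
                ).r2_adj_unbiased
                for j, f in enumerate(obs_fits[key])
            ]
            null_means[key] += float(np.mean(vals))
    for k in null_means:
        null_means[k] /= n_null

    u_corr = dict(u)
    for key, base in model_pairs:
        spurious = null_means[key] - base_unbiased[base]
        u_corr[key] = u[key] - spurious
    if is3:
        fr = _fractions_three(u_corr)
    else:
        fr = _fractions_two(u_corr["E"], u_corr["S"], u_corr["ES"])
    partition.corrected = fr
    partition.corrected_total = u_corr["EST"] if is3 else u_corr["ES"]
    partition.flags.append(
        f"environmental fractions MSR-corrected (n_null={n_null}, "
        f"{'spatio-temporal' if n_occasions > 1 else 'spatial'} basis)"
    )
    relative_fractions(partition)
    return partition
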