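"""Environmental-variable preprocessing.

Raw pond descriptors mix units (conductivity in µS/cm, depth in m, land-use
fractions, precipitation in mm).  Before they enter any model they are
(1) transformed variable-by-variable to tame skew — log for right-skewed
positive variables, arcsine-square-root for proportions — and (2) condensed
to their first three principal components, which are the environmental
predictors used throughout the partitioning models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_CLASSES = ("climatic", "limnological")
VALID_TRANSFORMS = ("log", "asin_sqrt", "none")


@dataclass
class EnvMatrix:
    """Samples × variables environmental table with per-variable metadata.

    Parameters
    ----------
    values :
        DataFrame indexed by sample id, one column per variable.
    meta :
        DataFrame indexed by variable name with columns ``var_class``
        (``climatic`` or ``limnological``) and ``transform`` (``log``,
        ``asin_sqrt`` or ``none``).  An ``applied`` boolean column records
        whether the transform has already been applied to ``values``.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if "applied" not in self.meta.columns:
            self.meta = self.meta.assign(applied=False)
        missing = [v for v in self.values.columns if v not in self.meta.index]
        if missing:
            raise ValueError(f"variables missing from meta: {missing}")
        bad_class = self.meta.loc[
            ~self.meta["var_class"].isin(VALID_CLASSES)
        ].index.tolist()
        if bad_class:
            raise ValueError(f"invalid var_class for variables: {bad_class}")
        bad_tr = self.meta.loc[
            ~self.meta["transform"].isin(VALID_TRANSFORMS)
        ].index.tolist()
        if bad_tr:
            raise ValueError(f"invalid transform tag for variables: {bad_tr}")

    @property
    def variable_names(self) -> list[str]:
        return list(self.values.columns)

    def subset_class(self, var_class: str) -> "EnvMatrix":
        """Return the climatic-only or limnological-only sub-table."""
        if var_class not in VALID_CLASSES:
            raise ValueError(f"unknown variable class {var_class!r}")
        cols = [v for v in self.values.columns if self.meta.loc[v, "var_class"] == var_class]
        return EnvMatrix(self.values[cols].copy(), self.meta.loc[cols].copy())

    def loc_samples(self, index) -> "EnvMatrix":
        return EnvMatrix(self.values.loc[index].copy(), self.meta.copy())

    def copy(self) -> "EnvMatrix":
        return EnvMatrix(self.values.copy(), self.meta.copy())


@dataclass
class PCScores:
    """First principal components of the transformed environment."""

    scores: pd.DataFrame  # samples × n_components, columns PC1..PCk
    loadings: pd.DataFrame  # variables × n_components
    explained_variance_fractions: np.ndarray = field(default_factory=lambda: np.array([]))


def auto_tag_transforms(raw: EnvMatrix) -> EnvMatrix:
    """Assign a transform tag to each variable from its marginal distribution.

    Proportions (all values in [0, 1]) get ``asin_sqrt``; strictly positive
    variables with sample skewness > 1 get ``log``; everything else passes
    through untransformed.
    """
    from scipy.stats import skew

    out = raw.copy()
    for v in out.values.columns:
        x = out.values[v].to_numpy(dtype=float)
        if np.all((x >= 0.0) & (x <= 1.0)):
            tag = "asin_sqrt"
        elif np.all(x > 0.0) and skew(x) > 1.0:
            tag = "log"
        else:
            tag = "none"
        out.meta.loc[v, "transform"] = tag
    out.meta["applied"] = False
    return out


def transform_env(raw: EnvMatrix) -> EnvMatrix:
    """Apply each variable's tagged transform.

    ``asin_sqrt`` → arcsin(√x) for x in [0, 1]; ``log`` → log(x + c) with
    c = half the minimum positive value if zeros occur, else c = 0.
    Already-applied tables pass through unchanged (idempotence).
    """
    out = raw.copy()
    for v in out.values.columns:
        if bool(out.meta.loc[v, "applied"]):
            continue
        tag = out.meta.loc[v, "transform"]
        x = out.values[v].to_numpy(dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError(f"variable {v!r} has non-finite values")
        if tag == "asin_sqrt":
            if np.any(x < 0.0) or np.any(x > 1.0):
                raise ValueError(
                    f"variable {v!r} tagged asin_sqrt has values outside [0, 1]"
                )
            out.values[v] = np.arcsin(np.sqrt(x))
        elif tag == "log":
            if np.any(x < 0.0):
                raise ValueError(f"variable {v!r} tagged log has negative values")
            c = 0.0
            if np.any(x == 0.0):
                positive = x[x > 0.0]
                if positive.size == 0:
                    raise ValueError(f"variable {v!r} tagged log is identically zero")
                c = 0.5 * float(positive.min())
            out.values[v] = np.log(x + c)
        out.meta.loc[v, "applied"] = True
    return out


def pca_reduce(env: EnvMatrix, n_components: int = 3) -> PCScores:
    """Correlation-matrix PCA of the (transformed) environment.

    Variables are centred and scaled to unit variance; the eigenvectors of
    their correlation matrix define the loadings.  Sign convention: the
    largest-magnitude entry of each loading vector is positive.

    Returns the first ``n_components`` score columns (default 3 — the
    environmental predictors used by the partitioning models).
    """
    X = env.values.to_numpy(dtype=float)
    n, p = X.shape
    if p < n_components:
        raise ValueError(f"need at least {n_components} variables, got {p}")
    if n < 4:
        raise ValueError(f"need at least 4 samples, got {n}")
    sd = X.std(axis=0, ddof=1)
    zero_var = [env.values.columns[j] for j in range(p) if sd[j] == 0.0]
    if zero_var:
        raise ValueError(f"zero-variance variable(s): {zero_var}")
    Z = (X - X.mean(axis=0)) / sd
    R = np.corrcoef(Z, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(R)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # sign convention: dominant loading entry positive
    for j in range(eigvecs.shape[1]):
        i_max = int(np.argmax(np.abs(eigvecs[:, j])))
        if eigvecs[i_max, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    frac = eigvals / eigvals.sum()
    k = n_components
    scores = Z @ eigvecs[:, :k]
    cols = [f"PC{i + 1}" for i in range(k)]
    return PCScores(
        scores=pd.DataFrame(scores, index=env.values.index, columns=cols),
        loadings=pd.DataFrame(eigvecs[:, :k], index=env.values.columns, columns=cols),
        explained_variance_fractions=frac[:k],
    )


def standardized_values(env: EnvMatrix) -> pd.DataFrame:
    """Column-standardized transformed values (used by PERMDISP)."""
    X = env.values.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0.0):
        warnings.warn("zero-variance variable(s) dropped before standardization")
        keep = sd > 0.0
        X = X[:, keep]
        cols = [c for c, k in zip(env.values.columns, keep) if k]
    else:
        cols = list(env.values.columns)
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    return pd.DataFrame(Z, index=env.values.index, columns=cols)
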