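"""End-to-end orchestration of the spatial and spatio-temporal approaches.

The *spatial approach* treats each sampling occasion as an independent
snapshot: per taxon × occasion it transforms the environment, computes a
per-period PCA, fits a per-period latent ordination, forward-selects
environmental and spatial smooths, and partitions variation into
(E | S), (S | E) and (E ∩ S) with MSR correction.

The *spatio-temporal approach* pools all occasions into one model, adds a
smooth of days-since-first-sampling as the temporal component, and
partitions into the seven (E, S, T) fractions.

Defaults follow the emulated study design: 3 environmental PCs, nine basis
functions per smooth, forward selection at α = 0.05, at most three
predictors per model in the per-period analysis.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .env import EnvMatrix, auto_tag_transforms, pca_reduce, transform_env
from .gam import SmoothSpec, forward_select
from .geo import to_planar_km
from .latent import select_latent_dimension
from .partition import PartitionResult2, PartitionResult3, correct_env, partition_three, partition_two
from .simulate import SimulationConfig, read_dataset, simulate_taxa
from .stats import compare_approaches, permdisp

logger = logging.getLogger("pondvarpart")

__all__ = ["RunConfig", "PipelineResult", "load_data", "run",
           "run_spatial_approach", "run_spatiotemporal_approach"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    simulate: SimulationConfig | None = None
    n_taxa: int = 7
    data_dir: str | None = None
    approach: str = "both"  # spatial | spatiotemporal | both
    taxa: list[str] | None = None
    alpha: float = 0.05
    k: int = 9
    n_pcs: int = 3
    max_terms_spatial: int = 3
    max_total_spatial: int = 3
    d_max: int = 5
    n_null: int = 199
    n_perm: int = 999
    seed: int = 0
    out_dir: str | None = None
    correct: bool = True
    n_starts: int = 3
    min_samples: int = 10

    def __post_init__(self) -> None:
        if self.approach not in ("spatial", "spatiotemporal", "both"):
            raise ValueError("approach must be spatial, spatiotemporal or both")
        if self.simulate is None and self.data_dir is None:
            raise ValueError("either simulate config or data_dir is required")


@dataclass
class PipelineResult:
    spatial: dict = field(default_factory=dict)  # taxon -> [PartitionResult2 per occasion]
    spatiotemporal: dict = field(default_factory=dict)  # taxon -> PartitionResult3
    comparison: pd.DataFrame | None = None
    permdisp: pd.DataFrame | None = None
    skipped: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


def load_data(cfg: RunConfig) -> dict:
    """Simulate or read the input bundle: sample frame, env, communities."""
    if cfg.simulate is not None:
        datasets = simulate_taxa(cfg.simulate, n_taxa=cfg.n_taxa)
        return {
            "sample_frame": datasets[0].sample_frame,
            "env": datasets[0].env,
            "communities": {ds.taxon: ds.community for ds in datasets},
        }
    return read_dataset(cfg.data_dir)


def _prepared_env(env: EnvMatrix) -> EnvMatrix:
    # curated transform tags are respected; untagged tables are auto-tagged
    if (env.meta["transform"] == "none").all() and not env.meta["applied"].any():
        env = auto_tag_transforms(env)
    return transform_env(env)


def _predictor_table(frame: pd.DataFrame, pcs, cfg: RunConfig) -> pd.DataFrame:
    x, y = to_planar_km(
        frame["longitude"].to_numpy(float), frame["latitude"].to_numpy(float)
    )
    P = pcs.scores.copy()
    P["x_km"] = x
    P["y_km"] = y
    P["days"] = frame["days_since_first"].to_numpy(float)
    return P


def _pond_coords(frame: pd.DataFrame) -> np.ndarray:
    ponds = frame.drop_duplicates("pond_id").sort_values("pond_id")
    x, y = to_planar_km(
        ponds["longitude"].to_numpy(float), ponds["latitude"].to_numpy(float)
    )
    return np.column_stack([x, y])


def _select_union(
    A: np.ndarray,
    candidates: list[SmoothSpec],
    predictors: pd.DataFrame,
    alpha: float,
    max_terms: int | None,
) -> list[SmoothSpec]:
    """Forward-select per latent axis and combine by selection frequency.

    Each axis runs its own double-stopping selection; terms are ranked by
    how many axes kept them (candidate order breaks ties) and capped at
    ``max_terms``.
    """
    counts: dict[SmoothSpec, int] = {}
    for j in range(A.shape[1]):
        sel = forward_select(
            A[:, j], candidates, predictors, alpha=alpha, max_terms=max_terms
        )
        for t in sel.selected:
            counts[t] = counts.get(t, 0) + 1
        for entry in sel.log:
            logger.debug("axis %d selection: %s", j + 1, entry)
    ranked = sorted(
        counts, key=lambda t: (-counts[t], candidates.index(t))
    )
    if max_terms is not None:
        ranked = ranked[:max_terms]
    return ranked


def _latent_axes(community: pd.DataFrame, cfg: RunConfig, seed: int, taxon: str):
    informative = [
        c for c in community.columns if 0 < community[c].sum() < len(community)
    ]
    if len(informative) < 2:
        raise ValueError("fewer than 2 informative species")
    return select_latent_dimension(
        community, d_max=cfg.d_max, seed=seed, taxon=taxon, n_starts=cfg.n_starts
    )


def run_spatial_approach(data: dict, cfg: RunConfig) -> tuple[dict, list]:
    """Per-period two-component partitions for every taxon."""
    frame = data["sample_frame"]
    env_all = _prepared_env(data["env"])
    coords = _pond_coords(frame)
    occasions = sorted(frame["occasion"].unique())
    taxa = cfg.taxa or sorted(data["communities"])
    results: dict[str, list] = {}
    skipped = []
    seed_iter = iter(np.random.SeedSequence(cfg.seed).generate_state(10000) % (2**31))
    for taxon in taxa:
        community = data["communities"][taxon]
        per_period = []
        for occ in occasions:
            mask = frame["occasion"] == occ
            if int(mask.sum()) < cfg.min_samples:
                reason = f"{taxon}/period{occ}: only {int(mask.sum())} samples"
                logger.warning("skipping %s", reason)
                skipped.append(reason)
                continue
            idx = frame.index[mask]
            try:
                env_p = EnvMatrix(env_all.values.loc[idx].copy(), env_all.meta.copy())
                pcs = pca_reduce(env_p, n_components=cfg.n_pcs)
                P = _predictor_table(frame.loc[idx], pcs, cfg)
                axes = _latent_axes(community.loc[idx], cfg, int(next(seed_iter)), taxon)
            except (ValueError, RuntimeError) as exc:
                reason = f"{taxon}/period{occ}: {exc}"
                logger.warning("skipping %s", reason)
                skipped.append(reason)
                continue
            A = axes.scores.to_numpy(float)
            E_cands = [SmoothSpec((f"PC{i+1}",), k=cfg.k) for i in range(cfg.n_pcs)]
            S_cands = [SmoothSpec(("x_km", "y_km"), k=cfg.k)]
            E_sel = _select_union(A, E_cands, P, cfg.alpha, cfg.max_terms_spatial)
            S_sel = _select_union(A, S_cands, P, cfg.alpha, None)
            if len(E_sel) + len(S_sel) > cfg.max_total_spatial:
                # the per-period sample size supports at most three predictors
                E_sel = _select_union(
                    A, E_cands, P, cfg.alpha, cfg.max_total_spatial - len(S_sel)
                )
            res = partition_two(axes, P, E_sel, S_sel)
            if cfg.correct:
                correct_env(
                    res, coords, n_occasions=1, n_null=cfg.n_null,
                    seed=int(next(seed_iter)),
                )
            res.taxon = taxon
            res.period = occ
            res.latent_d = axes.d
            per_period.append(res)
        results[taxon] = per_period
    return results, skipped


def run_spatiotemporal_approach(data: dict, cfg: RunConfig) -> tuple[dict, list]:
    """Pooled three-component partitions for every taxon."""
    frame = data["sample_frame"]
    env_all = _prepared_env(data["env"])
    coords = _pond_coords(frame)
    n_occ = int(frame["occasion"].nunique())
    taxa = cfg.taxa or sorted(data["communities"])
    # occasion-major sample order so the Kronecker MSR basis lines up
    order = frame.sort_values(["occasion", "pond_id"]).index
    frame = frame.loc[order]
    results: dict = {}
    skipped = []
    seed_iter = iter(
        (np.random.SeedSequence(cfg.seed).generate_state(10000) % (2**31))[5000:]
    )
    pcs = pca_reduce(
        EnvMatrix(env_all.values.loc[order].copy(), env_all.meta.copy()),
        n_components=cfg.n_pcs,
    )
    P = _predictor_table(frame, pcs, cfg)
    balanced = frame.groupby("pond_id")["occasion"].count().nunique() == 1
    for taxon in taxa:
        community = data["communities"][taxon].loc[order]
        if len(community) < cfg.min_samples:
            skipped.append(f"{taxon}: only {len(community)} samples")
            continue
        try:
            axes = _latent_axes(community, cfg, int(next(seed_iter)), taxon)
        except (ValueError, RuntimeError) as exc:
            reason = f"{taxon}: {exc}"
            logger.warning("skipping %s", reason)
            skipped.append(reason)
            continue
        A = axes.scores.to_numpy(float)
        E_cands = [SmoothSpec((f"PC{i+1}",), k=cfg.k) for i in range(cfg.n_pcs)]
        S_cands = [SmoothSpec(("x_km", "y_km"), k=cfg.k)]
        T_cands = (
            [SmoothSpec(("days",), k=max(3, min(cfg.k, n_occ)))] if n_occ > 1 else []
        )
        E_sel = _select_union(A, E_cands, P, cfg.alpha, None)
        S_sel = _select_union(A, S_cands, P, cfg.alpha, None)
        T_sel = _select_union(A, T_cands, P, cfg.alpha, None) if T_cands else []
        res = partition_three(axes, P, E_sel, S_sel, T_sel)
        if cfg.correct and n_occ > 1 and balanced:
            correct_env(
                res, coords, n_occasions=n_occ, n_null=cfg.n_null,
                seed=int(next(seed_iter)),
            )
        elif cfg.correct:
            correct_env(res, coords, n_occasions=1, n_null=cfg.n_null,
                        seed=int(next(seed_iter)))
        res.taxon = taxon
        res.latent_d = axes.d
        results[taxon] = res
    return results, skipped


def _permdisp_table(data: dict, cfg: RunConfig) -> pd.DataFrame:
    """Environmental-heterogeneity contrasts by variable class.

    With two or more regions, regions are contrasted (per period and
    pooled); with one region, sampling periods are contrasted instead.
    """
    frame = data["sample_frame"]
    env_all = _prepared_env(data["env"])
    regions = frame["region"].unique() if "region" in frame.columns else ["all"]
    rows = []
    rng_seed = int(np.random.SeedSequence(cfg.seed + 1).generate_state(1)[0] % (2**31))
    contrast_col = "region" if len(regions) > 1 else "occasion"
    scopes: list[tuple[str, pd.Index]] = [("pooled", frame.index)]
    if contrast_col == "region":
        for occ in sorted(frame["occasion"].unique()):
            scopes.append((f"period{occ}", frame.index[frame["occasion"] == occ]))
    for var_class in ("all", "climatic", "limnological"):
        env_c = env_all if var_class == "all" else env_all.subset_class(var_class)
        if env_c.values.shape[1] == 0:
            continue
        for scope, idx in scopes:
            groups = frame.loc[idx, contrast_col].to_numpy()
            if len(np.unique(groups)) < 2:
                continue
            try:
                res = permdisp(
                    env_c.loc_samples(idx), groups, n_perm=cfg.n_perm, seed=rng_seed
                )
            except ValueError as exc:
                logger.warning("permdisp %s/%s skipped: %s", var_class, scope, exc)
                continue
            rows.append(
                {
                    "variable_class": var_class,
                    "scope": scope,
                    "contrast": contrast_col,
                    "F": res.F,
                    "p": res.p,
                    "n_perm": res.n_perm,
                }
            )
    return pd.DataFrame(rows)


def _write_outputs(result: PipelineResult, cfg: RunConfig) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for taxon, per_period in result.spatial.items():
        for res in per_period:
            df = res.to_frame()
            df.insert(0, "taxon", taxon)
            df.insert(1, "period", res.period)
            df.to_csv(out / f"partition_{taxon}_period{res.period}.csv", index=False)
    for taxon, res in result.spatiotemporal.items():
        df = res.to_frame()
        df.insert(0, "taxon", taxon)
        df.to_csv(out / f"partition3_{taxon}.csv", index=False)
    if result.comparison is not None and len(result.comparison):
        result.comparison.to_csv(out / "wilcoxon_results.csv", index=False)
    if result.permdisp is not None and len(result.permdisp):
        result.permdisp.to_csv(out / "permdisp_results.csv", index=False)
    (out / "provenance.json").write_text(json.dumps(result.provenance, indent=2))


def run(cfg: RunConfig) -> PipelineResult:
    """Run the configured approach(es) and optionally write result tables."""
    data = load_data(cfg)
    result = PipelineResult()
    if cfg.approach in ("spatial", "both"):
        result.spatial, sk = run_spatial_approach(data, cfg)
        result.skipped.extend(sk)
    if cfg.approach in ("spatiotemporal", "both"):
        result.spatiotemporal, sk = run_spatiotemporal_approach(data, cfg)
        result.skipped.extend(sk)
    if result.spatial and result.spatiotemporal:
        shared = {
            t: v for t, v in result.spatial.items()
            if v and t in result.spatiotemporal
        }
        if shared:
            result.comparison = compare_approaches(
                shared, {t: result.spatiotemporal[t] for t in shared}
            )
    result.permdisp = _permdisp_table(data, cfg)
    prov = asdict(cfg)
    if prov.get("simulate") is not None:
        prov["simulate"]["occasion_days"] = list(prov["simulate"]["occasion_days"])
    prov["package_version"] = __version__
    result.provenance = prov
    if cfg.out_dir is not None:
        _write_outputs(result, cfg)
    return result
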