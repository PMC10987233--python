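"""Synthetic temporary-pond metacommunities with known structure.

The generator emulates the study design the pipeline targets: ~30 ponds
surveyed three times over one hydroperiod, presence–absence of tens of
species per taxon, environmental variables that are partly spatially
structured, and occupancy driven by configurable environmental, residual
spatial and temporal effects.  Because every generating component is kept in
``truth``, parameter-recovery experiments can verify each pipeline stage
without any field data.

Model
-----
Ponds are placed uniformly in a planar square of side ``region_extent_km``.
Each environmental variable is a Gaussian random field over pond locations
(exponential covariance, range ``env_spatial_range_km``) plus independent
noise; limnological variables additionally receive an occasion-specific
shift, while climatic variables are constant over the hydroperiod.  Species
``s`` is present at sample ``i`` with probability

    logit⁻¹( a_s + β_E·f_s(env_i) + β_S·u_s(x_i, y_i) + β_T·g_s(t_i) )

where ``f_s`` is a linear or unimodal response to a species-specific
environmental gradient, ``u_s`` is a smooth residual spatial field and
``g_s`` a half-sine seasonal trend in days since first sampling.  Each of
the three components is standardized to unit variance across samples so the
β's are directly comparable effect sizes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .env import EnvMatrix
from .geo import from_planar_km

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_metacommunity",
    "simulate_taxa",
    "write_dataset",
    "read_dataset",
]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic metacommunity.

    Defaults mirror the emulated study design: 30 ponds × 3 occasions at
    0/150/250 days since first sampling, a ~120 km planar extent, and ten
    environmental variables split 4 climatic + 6 limnological.
    """

    n_ponds: int = 30
    n_occasions: int = 3
    n_species: int = 60
    occasion_days: tuple[int, ...] = (0, 150, 250)
    region_extent_km: float = 120.0
    n_climatic: int = 4
    n_limnological: int = 6
    beta_E: float = 1.0
    beta_S: float = 1.0
    beta_T: float = 1.0
    env_spatial_range_km: float = 30.0
    env_noise_sd: float = 0.4
    limno_occasion_sd: float = 0.5
    spatial_range_km: float = 30.0
    intercept_sd: float = 0.5
    unimodal_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_ponds", "n_occasions", "n_species", "n_climatic", "n_limnological"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        days = tuple(self.occasion_days)[: self.n_occasions]
        if len(days) != self.n_occasions:
            raise ValueError("occasion_days shorter than n_occasions")
        if days[0] != 0:
            raise ValueError("occasion_days must start at 0")
        if any(d2 <= d1 for d1, d2 in zip(days, days[1:])):
            raise ValueError("occasion_days must be strictly increasing")
        self.occasion_days = days
        for name in ("beta_E", "beta_S", "beta_T"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.region_extent_km <= 0 or self.env_spatial_range_km <= 0:
            raise ValueError("extent and correlation range must be positive")

    @property
    def n_env_vars(self) -> int:
        return self.n_climatic + self.n_limnological

    @property
    def n_samples(self) -> int:
        return self.n_ponds * self.n_occasions


@dataclass
class SyntheticDataset:
    """A simulated taxon's dataset plus the generating truth."""

    sample_frame: pd.DataFrame  # sample_id, pond_id, occasion, longitude, latitude, days_since_first
    env: EnvMatrix  # raw (untransformed) scale
    community: pd.DataFrame  # samples × species, 0/1
    truth: dict = field(default_factory=dict)
    config: SimulationConfig | None = None
    taxon: str = "taxon1"


def _exp_gauss_field(coords_km: np.ndarray, range_km: float, rng: np.random.Generator,
                     n_draws: int = 1) -> np.ndarray:
    """Gaussian random field(s) over fixed locations, exponential covariance.

    Exact Cholesky realization — trivially cheap at <= a few dozen ponds.
    Returns (n_locations, n_draws).
    """
    d = np.linalg.norm(coords_km[:, None, :] - coords_km[None, :, :], axis=-1)
    cov = np.exp(-d / range_km) + 1e-9 * np.eye(len(coords_km))
    L = np.linalg.cholesky(cov)
    return L @ rng.standard_normal((len(coords_km), n_draws))


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (x - x.mean(axis=0)) / sd


def _sample_frame(cfg: SimulationConfig, rng: np.random.Generator,
                  region: str = "simulated") -> tuple[pd.DataFrame, np.ndarray]:
    coords = rng.uniform(0.0, cfg.region_extent_km, size=(cfg.n_ponds, 2))
    lon, lat = from_planar_km(coords[:, 0] - coords[:, 0].mean(),
                              coords[:, 1] - coords[:, 1].mean())
    rows = []
    for occ in range(cfg.n_occasions):
        for p in range(cfg.n_ponds):
            rows.append(
                {
                    "sample_id": f"p{p + 1:02d}_o{occ + 1}",
                    "pond_id": f"p{p + 1:02d}",
                    "occasion": occ + 1,
                    "longitude": lon[p],
                    "latitude": lat[p],
                    "days_since_first": cfg.occasion_days[occ],
                    "region": region,
                }
            )
    frame = pd.DataFrame(rows).set_index("sample_id")
    return frame, coords


def _environment(cfg: SimulationConfig, coords: np.ndarray,
                 rng: np.random.Generator) -> tuple[EnvMatrix, np.ndarray]:
    """Raw-scale environment; returns the EnvMatrix and the latent fields.

    The latent (Gaussian) per-sample fields drive species responses; the raw
    table warps them through shapes (plain / lognormal / proportion) so the
    transform-tagging stage has something real to do.
    """
    n, n_occ = cfg.n_ponds, cfg.n_occasions
    names, classes, shapes = [], [], []
    for j in range(cfg.n_climatic):
        names.append(f"clim{j + 1}")
        classes.append("climatic")
        shapes.append(["none", "lognormal", "proportion"][j % 3])
    for j in range(cfg.n_limnological):
        names.append(f"limno{j + 1}")
        classes.append("limnological")
        shapes.append(["lognormal", "none", "proportion"][j % 3])

    structured = _exp_gauss_field(coords, cfg.env_spatial_range_km, rng, cfg.n_env_vars)
    latent = np.empty((n * n_occ, cfg.n_env_vars))
    for v in range(cfg.n_env_vars):
        pond_level = structured[:, v] + cfg.env_noise_sd * rng.standard_normal(n)
        if classes[v] == "climatic":
            per_occ = np.tile(pond_level, n_occ)
        else:
            shifts = cfg.limno_occasion_sd * rng.standard_normal(n_occ)
            noise = 0.5 * cfg.env_noise_sd * rng.standard_normal((n_occ, n))
            per_occ = np.concatenate([pond_level + shifts[o] + noise[o] for o in range(n_occ)])
        latent[:, v] = per_occ

    raw = np.empty_like(latent)
    for v, shape in enumerate(shapes):
        z = latent[:, v]
        if shape == "lognormal":
            raw[:, v] = np.exp(z)
        elif shape == "proportion":
            raw[:, v] = expit(z)
        else:
            raw[:, v] = z
    sample_ids = [f"p{p + 1:02d}_o{o + 1}" for o in range(n_occ) for p in range(n)]
    values = pd.DataFrame(raw, index=pd.Index(sample_ids, name="sample_id"), columns=names)
    meta = pd.DataFrame(
        {"var_class": classes, "transform": "none", "applied": False},
        index=pd.Index(names, name="variable"),
    )
    return EnvMatrix(values, meta), latent


def _community(cfg: SimulationConfig, coords: np.ndarray, latent_env: np.ndarray,
               days: np.ndarray, rng: np.random.Generator) -> tuple[pd.DataFrame, dict]:
    n_samp, S = cfg.n_samples, cfg.n_species

    # per-species environmental gradient and response shape
    w = rng.standard_normal((cfg.n_env_vars, S))
    w /= np.linalg.norm(w, axis=0, keepdims=True)
    grad = _standardize(latent_env @ w)  # n_samp × S
    unimodal = rng.random(S) < cfg.unimodal_fraction
    optima = rng.uniform(-1.0, 1.0, S)
    f = np.where(
        unimodal[None, :],
        np.exp(-0.5 * ((grad - optima[None, :]) / 0.75) ** 2),
        grad,
    )
    f = _standardize(f)

    # residual spatial fields, constant over occasions
    u_pond = _exp_gauss_field(coords, cfg.spatial_range_km, rng, S)
    u = np.tile(u_pond, (cfg.n_occasions, 1))
    u = _standardize(u)

    # temporal trend: half-sine over the hydroperiod with random sign/phase
    if cfg.n_occasions > 1:
        span = float(max(cfg.occasion_days))
        amp = rng.choice([-1.0, 1.0], S)
        phase = rng.uniform(0.0, 0.5, S)
        g = amp[None, :] * np.sin(np.pi * (days[:, None] / span + phase[None, :]) / (1.0 + phase[None, :]))
        g = _standardize(g)
    else:
        g = np.zeros((n_samp, S))

    a = cfg.intercept_sd * rng.standard_normal(S)
    eta = a[None, :] + cfg.beta_E * f + cfg.beta_S * u + cfg.beta_T * g
    if not np.all(np.isfinite(eta)):
        bad = np.argwhere(~np.isfinite(eta))[0]
        raise FloatingPointError(
            f"non-finite linear predictor at sample {bad[0]}, species {bad[1]}"
        )
    y = (rng.random((n_samp, S)) < expit(eta)).astype(np.int64)
    truth = {
        "env_response": f,
        "env_gradient": grad,
        "spatial_field": u,
        "temporal_trend": g,
        "intercepts": a,
        "linear_predictor": eta,
        "unimodal": unimodal,
    }
    return y, truth


def simulate_metacommunity(config: SimulationConfig, taxon: str = "taxon1") -> SyntheticDataset:
    """Draw one taxon's synthetic dataset under ``config`` (deterministic in seed)."""
    rng = np.random.default_rng(config.seed)
    frame, coords = _sample_frame(config, rng)
    envmat, latent_env = _environment(config, coords, rng)
    days = frame["days_since_first"].to_numpy(dtype=float)
    y, truth = _community(config, coords, latent_env, days, rng)
    truth["pond_coords_km"] = coords
    community = pd.DataFrame(
        y,
        index=frame.index.copy(),
        columns=[f"sp{j + 1:03d}" for j in range(config.n_species)],
    )
    return SyntheticDataset(frame, envmat, community, truth, config, taxon)


def simulate_taxa(config: SimulationConfig, n_taxa: int = 7) -> list[SyntheticDataset]:
    """Draw ``n_taxa`` taxa sharing ponds and environment, independent communities.

    Mirrors the study layout of seven organism groups surveyed at the same
    ponds.  The shared pond/environment draw uses ``config.seed``; each
    taxon's species responses and Bernoulli draws use an independent
    sub-seed.
    """
    rng = np.random.default_rng(config.seed)
    frame, coords = _sample_frame(config, rng)
    envmat, latent_env = _environment(config, coords, rng)
    days = frame["days_since_first"].to_numpy(dtype=float)
    seeds = np.random.SeedSequence(config.seed).spawn(n_taxa)
    datasets = []
    for t, ss in enumerate(seeds):
        taxon_rng = np.random.default_rng(ss)
        y, truth = _community(config, coords, latent_env, days, taxon_rng)
        truth["pond_coords_km"] = coords
        community = pd.DataFrame(
            y,
            index=frame.index.copy(),
            columns=[f"sp{j + 1:03d}" for j in range(config.n_species)],
        )
        datasets.append(
            SyntheticDataset(frame.copy(), envmat.copy(), community, truth, config, f"taxon{t + 1}")
        )
    return datasets


# ---------------------------------------------------------------------------
# CSV round trip


def write_dataset(datasets: SyntheticDataset | list[SyntheticDataset], directory) -> list[Path]:
    """Write the CSV layout the pipeline reads.

    samples.csv, env.csv, env_meta.csv and one community_<taxon>.csv per
    taxon; UTF-8, comma separators, '.' decimal.
    """
    if isinstance(datasets, SyntheticDataset):
        datasets = [datasets]
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    first = datasets[0]
    written = []
    p = directory / "samples.csv"
    first.sample_frame.to_csv(p)
    written.append(p)
    p = directory / "env.csv"
    first.env.values.to_csv(p)
    written.append(p)
    p = directory / "env_meta.csv"
    first.env.meta[["var_class", "transform"]].to_csv(p)
    written.append(p)
    for ds in datasets:
        p = directory / f"community_{ds.taxon}.csv"
        ds.community.to_csv(p)
        written.append(p)
    if first.config is not None:
        cfg = asdict(first.config)
        cfg["occasion_days"] = list(cfg["occasion_days"])
        (directory / "simulation_config.json").write_text(json.dumps(cfg, indent=2))
    return written


def read_dataset(directory) -> dict:
    """Read the CSV layout back into in-memory containers.

    Returns a dict with ``sample_frame``, ``env`` (EnvMatrix) and
    ``communities`` (taxon → DataFrame).
    """
    directory = Path(directory)
    frame = pd.read_csv(directory / "samples.csv", index_col="sample_id")
    values = pd.read_csv(directory / "env.csv", index_col="sample_id")
    meta = pd.read_csv(directory / "env_meta.csv", index_col="variable")
    communities = {}
    for p in sorted(directory.glob("community_*.csv")):
        taxon = p.stem.replace("community_", "")
        communities[taxon] = pd.read_csv(p, index_col="sample_id")
    return {
        "sample_frame": frame,
        "env": EnvMatrix(values, meta),
        "communities": communities,
    }
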