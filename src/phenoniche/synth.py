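"""Synthetic landscapes with known niche structure.

Generates (a) spatially autocorrelated, cross-correlated continuous
environmental layers, (b) a categorical biome map, (c) a vegetation-change
layer for the filtering rule, and (d) phenotype-labelled presence records
sampled from configurable per-phenotype suitability surfaces, so that every
downstream stage of the pipeline can be exercised against ground truth.

Autocorrelation is produced by Gaussian smoothing of white noise; the target
cross-correlation is imposed exactly by empirically whitening the smoothed
fields and re-mixing them with the Cholesky factor of the target matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .raster import EnvStack, GridSpec, Raster, write_ascii_grid
from .records import LocationRecord, write_records

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate_env_stack", "generate_records",
           "generate_truth", "true_suitability", "write_truth"]


@dataclass
class SyntheticConfig:
    grid_shape: tuple[int, int] = (80, 80)
    cell_size: float = 0.05
    origin: tuple[float, float] = (0.0, 0.0)
    n_layers: int = 3
    target_corr: np.ndarray | None = None
    autocorr_range: float = 4.0
    n_biomes: int = 4
    n_records: int = 600
    melanism_freq_by_biome: Sequence[float] = (0.30, 0.10, 0.02, 0.0)
    #: per-phenotype {layer_name: (linear, quadratic)} coefficients of the
    #: log-suitability surface over standardized layer values
    niche_coeffs: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)
    year: int = 2015
    #: grid row splitting the landscape for the barrier-contrast experiment
    barrier_row: int | None = None
    #: additive step applied to the first layer south of the barrier row
    barrier_step: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records < 2:
            raise ValueError("n_records must be >= 2")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if len(self.melanism_freq_by_biome) != self.n_biomes:
            raise ValueError("melanism_freq_by_biome must have one entry per biome")
        if any(not 0.0 <= f <= 1.0 for f in self.melanism_freq_by_biome):
            raise ValueError("melanism frequencies must lie in [0, 1]")
        if self.target_corr is None:
            self.target_corr = np.eye(self.n_layers)
        self.target_corr = np.asarray(self.target_corr, dtype=float)
        if self.target_corr.shape != (self.n_layers, self.n_layers):
            raise ValueError("target_corr must be n_layers x n_layers")
        if not np.allclose(self.target_corr, self.target_corr.T):
            raise ValueError("target_corr must be symmetric")
        eig = np.linalg.eigvalsh(self.target_corr)
        if eig.min() < -1e-10:
            raise ValueError(
                f"target_corr is not positive semi-definite (min eigenvalue {eig.min():.3g})"
            )

    @property
    def grid(self) -> GridSpec:
        return GridSpec(
            nrows=self.grid_shape[0],
            ncols=self.grid_shape[1],
            xll=self.origin[0],
            yll=self.origin[1],
            cellsize=self.cell_size,
        )

    def layer_names(self) -> list[str]:
        return [f"env_{i}" for i in range(self.n_layers)]


@dataclass
class SyntheticTruth:
    records: list[LocationRecord]
    env: EnvStack
    biomes: Raster
    true_suitability: dict[str, Raster]
    ndvi_change: Raster
    config: SyntheticConfig


def _smoothed_fields(rng: np.random.Generator, n: int, shape: tuple[int, int],
                     sigma: float) -> np.ndarray:
    fields = rng.standard_normal((n, *shape))
    if sigma > 0:
        fields = np.stack([gaussian_filter(f, sigma=sigma, mode="wrap") for f in fields])
    return fields


def generate_env_stack(cfg: SyntheticConfig) -> EnvStack:
    """Correlated, autocorrelated continuous layers on the configured grid.

    The empirical pairwise correlation over cells matches ``target_corr``
    exactly (the smoothed fields are whitened before Cholesky mixing), which is
    stricter than the +/-0.05 contract.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    k = cfg.n_layers
    fields = _smoothed_fields(rng, k, cfg.grid_shape, cfg.autocorr_range)
    flat = fields.reshape(k, -1)
    flat = flat - flat.mean(axis=1, keepdims=True)
    # exact empirical whitening, then re-mix to the target correlation
    cov = flat @ flat.T / flat.shape[1]
    white = np.linalg.inv(np.linalg.cholesky(cov)) @ flat
    # eigen square root handles semi-definite targets (e.g. duplicated layers)
    w, v = np.linalg.eigh(cfg.target_corr)
    mix = v @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ v.T
    mixed = mix @ white
    layers = {}
    for i, name in enumerate(cfg.layer_names()):
        layer = mixed[i].reshape(cfg.grid_shape)
        if i == 0 and cfg.barrier_row is not None and cfg.barrier_step:
            layer = layer.copy()
            layer[cfg.barrier_row:, :] += cfg.barrier_step
        layers[name] = layer
    return EnvStack(cfg.grid, layers)


def generate_biomes(cfg: SyntheticConfig) -> Raster:
    """Categorical biome raster: quantile bins of an independent smooth field."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    f = _smoothed_fields(rng, 1, cfg.grid_shape, max(cfg.autocorr_range, 2.0))[0]
    qs = np.quantile(f, np.linspace(0, 1, cfg.n_biomes + 1)[1:-1])
    codes = np.digitize(f, qs).astype(float)
    return Raster(cfg.grid, codes)


def generate_ndvi_change(cfg: SyntheticConfig, scale: float = 0.25) -> Raster:
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    f = _smoothed_fields(rng, 1, cfg.grid_shape, cfg.autocorr_range)[0]
    sd = f.std()
    if sd > 0:
        f = f / sd * scale
    return Raster(cfg.grid, np.clip(f, -1.0, 1.0))


def true_suitability(cfg: SyntheticConfig, env: EnvStack, phenotype: str) -> Raster:
    """Generating suitability surface exp(sum a*z + b*z^2), max-normalized."""
    coeffs = cfg.niche_coeffs.get(phenotype, {})
    log_s = np.zeros(cfg.grid_shape)
    for name, (a, b) in coeffs.items():
        z = env.layers[name]
        z = (z - z.mean()) / (z.std() or 1.0)
        log_s = log_s + a * z + b * z * z
    s = np.exp(log_s - log_s.max())
    s[~env.mask] = np.nan
    return Raster(cfg.grid, s)


def generate_records(cfg: SyntheticConfig, env: EnvStack,
                     biomes: Raster | None = None) -> SyntheticTruth:
    """Sample phenotype-labelled presence records from the generating surfaces.

    Locations and labels are drawn jointly from
    ``P(cell, phenotype) ∝ S_phenotype(cell) * f(biome(cell), phenotype)``
    where ``f`` is the configured per-biome melanism frequency, so that when
    the two suitability surfaces coincide the per-biome melanism fraction
    equals the configured probability exactly.
    """
    if biomes is None:
        biomes = generate_biomes(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 4]))
    suit = {p: true_suitability(cfg, env, p) for p in ("melanistic", "non_melanistic")}
    freqs = np.asarray(cfg.melanism_freq_by_biome, dtype=float)
    biome_codes = biomes.values.astype(int)
    f_cell = freqs[biome_codes]

    # surfaces enter with unit total mass so the per-biome frequencies set the
    # phenotype split regardless of how peaked either suitability surface is
    s_mel = np.where(env.mask, suit["melanistic"].values, 0.0)
    s_non = np.where(env.mask, suit["non_melanistic"].values, 0.0)
    if s_mel.sum() <= 0 or s_non.sum() <= 0:
        raise ValueError("all-zero joint suitability surface; cannot sample records")
    w_mel = s_mel / s_mel.sum() * f_cell
    w_non = s_non / s_non.sum() * (1.0 - f_cell)
    weights = np.concatenate([w_mel.ravel(), w_non.ravel()])
    total = weights.sum()
    if total <= 0:
        raise ValueError("all-zero joint suitability surface; cannot sample records")
    draws = rng.choice(weights.size, size=cfg.n_records, p=weights / total)

    ncell = w_mel.size
    is_mel = draws < ncell
    cells = np.where(is_mel, draws, draws - ncell)
    rows, cols = np.unravel_index(cells, cfg.grid_shape)
    lon, lat = cfg.grid.cell_center(rows, cols)
    jitter = rng.uniform(-0.3, 0.3, size=(2, cfg.n_records)) * cfg.cell_size
    lon = lon + jitter[0]
    lat = lat + jitter[1]

    sources = rng.choice(
        ["camera_trap", "museum", "field_capture", "communication"],
        p=[0.75, 0.10, 0.08, 0.07],
        size=cfg.n_records,
    )
    records = []
    for i in range(cfg.n_records):
        records.append(
            LocationRecord(
                id=f"rec_{i:05d}",
                lon=float(lon[i]),
                lat=float(lat[i]),
                phenotype="melanistic" if is_mel[i] else "non_melanistic",
                source=str(sources[i]),
                year=cfg.year,
                biome=f"biome_{biome_codes[rows[i], cols[i]]}",
            )
        )
    return SyntheticTruth(
        records=records,
        env=env,
        biomes=biomes,
        true_suitability=suit,
        ndvi_change=generate_ndvi_change(cfg),
        config=cfg,
    )


def generate_truth(cfg: SyntheticConfig) -> SyntheticTruth:
    """Full synthetic bundle: layers, biomes, vegetation change and records."""
    env = generate_env_stack(cfg)
    return generate_records(cfg, env)


def write_truth(truth: SyntheticTruth, directory: str | Path) -> dict[str, str]:
    """Write the bundle as plain-text artifacts (CSV + ESRI ASCII grids)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    p = write_records(truth.records, directory / "records.csv")
    manifest["records"] = str(p)
    for path in truth.env.write(directory / "env"):
        manifest[f"env:{path.stem}"] = str(path)
    manifest["biomes"] = str(write_ascii_grid(directory / "biomes.asc", truth.biomes))
    manifest["ndvi_change"] = str(
        write_ascii_grid(directory / "ndvi_change.asc", truth.ndvi_change)
    )
    for phen, r in truth.true_suitability.items():
        manifest[f"true_suitability:{phen}"] = str(
            write_ascii_grid(directory / f"true_suitability_{phen}.asc", r)
        )
    return manifest
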