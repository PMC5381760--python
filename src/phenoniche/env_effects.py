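"""Environmental-driver contrasts between phenotype models.

Three analyses: (1) per-scale, per-variable contrasts of suitability-weighted
variable values between the two phenotype models, with Bonferroni-corrected
paired t-tests and suitability~variable regressions on a shared record set;
(2) a barrier contrast sampling equal point counts on both sides of a split
within one biome class and t-testing a target variable; (3) leave-region-out
refits to check the spatial robustness of a fitted model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import shapely
from scipy import stats

from .maxent import _extract, _points_array
from .raster import EnvStack, Raster

__all__ = ["ScaleDefinition", "VariableContrast", "DriverContrast", "BarrierResult",
           "driver_contrast", "barrier_contrast", "leave_region_out"]


@dataclass
class ScaleDefinition:
    """Named spatial subset; ``polygon`` is a shapely geometry in lon/lat
    (None = full extent)."""

    name: str
    polygon: shapely.Geometry | None = None

    def select(self, pts: np.ndarray) -> np.ndarray:
        if self.polygon is None:
            return np.ones(len(pts), dtype=bool)
        return shapely.contains_xy(self.polygon, pts[:, 0], pts[:, 1])


@dataclass
class VariableContrast:
    scale: str
    variable: str
    mean_abs_a: float
    mean_abs_b: float
    t_statistic: float
    p_value: float
    significant: bool
    slope_a: float
    slope_b: float
    r_a: float
    r_b: float
    n: int


@dataclass
class DriverContrast:
    contrasts: list[VariableContrast]
    alpha: float
    adjusted_alpha: float
    n_comparisons: int

    def frame(self):
        import pandas as pd

        return pd.DataFrame([vars(c) for c in self.contrasts])


def driver_contrast(
    records: Sequence,
    env: EnvStack,
    suitability_by_phenotype: dict[str, Raster],
    scales: Sequence[ScaleDefinition] | None = None,
    alpha: float = 0.05,
) -> DriverContrast:
    """Contrast environmental drivers between two phenotype models.

    For every scale and layer: the suitability-weighted mean absolute variable
    value under each model (weights = the model's suitability at the shared
    record locations), a paired t-test across records of the weighted values,
    Bonferroni-adjusted over (variables x scales), plus per-phenotype
    least-squares slope and Pearson R of suitability against the variable.
    """
    if len(suitability_by_phenotype) != 2:
        raise ValueError("need exactly two phenotype suitability maps")
    (name_a, map_a), (name_b, map_b) = sorted(suitability_by_phenotype.items())
    if scales is None:
        scales = [ScaleDefinition("full")]
    pts = _points_array(records)
    X = _extract(env, pts)
    sa = map_a.sample(pts[:, 0], pts[:, 1])
    sb = map_b.sample(pts[:, 0], pts[:, 1])
    ok = np.isfinite(X).all(axis=1) & np.isfinite(sa) & np.isfinite(sb)
    pts, X, sa, sb = pts[ok], X[ok], sa[ok], sb[ok]

    n_comparisons = len(scales) * len(env.layer_names)
    adj_alpha = alpha / n_comparisons
    contrasts: list[VariableContrast] = []
    for scale in scales:
        sel = scale.select(pts)
        if sel.sum() < 3:
            warnings.warn(f"scale {scale.name!r} has <3 records; skipped")
            continue
        Xs, sas, sbs = X[sel], sa[sel], sb[sel]
        for j, var in enumerate(env.layer_names):
            v = Xs[:, j]
            wa = sas * np.abs(v)
            wb = sbs * np.abs(v)
            d = wa - wb
            sd = d.std(ddof=1)
            if sd == 0:
                t_stat, p = 0.0, 1.0
            else:
                t_stat = float(d.mean() / (sd / np.sqrt(len(d))))
                p = float(2.0 * stats.t.sf(abs(t_stat), df=len(d) - 1))
            reg_a = stats.linregress(v, sas) if v.std() > 0 else None
            reg_b = stats.linregress(v, sbs) if v.std() > 0 else None
            contrasts.append(
                VariableContrast(
                    scale=scale.name,
                    variable=var,
                    mean_abs_a=float(wa.mean()),
                    mean_abs_b=float(wb.mean()),
                    t_statistic=t_stat,
                    p_value=p,
                    significant=p < adj_alpha,
                    slope_a=float(reg_a.slope) if reg_a else 0.0,
                    slope_b=float(reg_b.slope) if reg_b else 0.0,
                    r_a=float(reg_a.rvalue) if reg_a else 0.0,
                    r_b=float(reg_b.rvalue) if reg_b else 0.0,
                    n=int(sel.sum()),
                )
            )
    return DriverContrast(
        contrasts=contrasts,
        alpha=alpha,
        adjusted_alpha=adj_alpha,
        n_comparisons=n_comparisons,
    )


@dataclass
class BarrierResult:
    variable: str
    mean_north: float
    mean_south: float
    t_statistic: float
    p_value: float
    n_per_side: int
    seed: int


def barrier_contrast(
    env: EnvStack,
    barrier_lat: float,
    biome_layer: Raster,
    biome_class: int,
    variable: str | None = None,
    n_points: int = 600,
    seed: int = 0,
) -> BarrierResult:
    """Two-sample contrast of a variable across a latitudinal barrier.

    Samples exactly ``n_points/2`` random cells on each side of
    ``barrier_lat`` restricted to ``biome_class``, extracts ``variable``
    (default: first layer) and runs a two-sample t-test.
    """
    if n_points % 2 != 0:
        raise ValueError("n_points must be even (exact 50/50 split required)")
    if variable is None:
        variable = env.layer_names[0]
    if variable not in env.layers:
        raise ValueError(f"variable {variable!r} not in environment stack")
    half = n_points // 2
    rows, cols = env.valid_indices()
    lon, lat = env.grid.cell_center(rows, cols)
    in_class = biome_layer.values[rows, cols] == biome_class
    north = in_class & (lat > barrier_lat)
    south = in_class & (lat <= barrier_lat)
    for side, m in (("north", north), ("south", south)):
        if m.sum() < half:
            raise ValueError(
                f"insufficient eligible cells on the {side} side: "
                f"need {half}, have {int(m.sum())}"
            )
    rng = np.random.default_rng(seed)
    pick_n = rng.choice(np.nonzero(north)[0], size=half, replace=False)
    pick_s = rng.choice(np.nonzero(south)[0], size=half, replace=False)
    vals = env.layers[variable][rows, cols]
    v_n, v_s = vals[pick_n], vals[pick_s]
    t_stat, p = stats.ttest_ind(v_n, v_s)
    return BarrierResult(
        variable=variable,
        mean_north=float(v_n.mean()),
        mean_south=float(v_s.mean()),
        t_statistic=float(t_stat),
        p_value=float(p),
        n_per_side=half,
        seed=seed,
    )


def leave_region_out(
    records: Sequence,
    env: EnvStack,
    region: shapely.Geometry,
    model_protocol: Callable[[Sequence], Raster],
) -> dict:
    """Refit a phenotype model excluding records inside ``region``.

    ``model_protocol`` maps a record sequence to a suitability raster (it must
    consume its own fixed seed so that identical inputs give identical
    outputs).  Reports the mean suitability inside the region before and after
    exclusion.
    """
    pts = _points_array(records)
    inside = shapely.contains_xy(region, pts[:, 0], pts[:, 1])
    if not inside.any():
        warnings.warn("region contains no records; model is unchanged")
    retained = [r for r, drop in zip(records, inside) if not drop]
    if not retained:
        raise ValueError("excluding the region leaves no training records")

    map_full = model_protocol(list(records))
    map_excl = model_protocol(retained)

    rows, cols = env.valid_indices()
    lon, lat = env.grid.cell_center(rows, cols)
    in_region = shapely.contains_xy(region, lon, lat)
    if not in_region.any():
        raise ValueError("region does not intersect the environment grid")
    before = float(np.nanmean(map_full.values[rows[in_region], cols[in_region]]))
    after = float(np.nanmean(map_excl.values[rows[in_region], cols[in_region]]))
    return {
        "n_excluded": int(inside.sum()),
        "n_retained": len(retained),
        "mean_suitability_before": before,
        "mean_suitability_after": after,
        "ratio_after_before": after / before if before > 0 else np.nan,
        "map_full": map_full,
        "map_excluded": map_excl,
    }
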