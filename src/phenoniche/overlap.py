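"""Niche-overlap statistics and the reciprocal-resampling equivalency test.

Overlap between two suitability maps normalized to probability surfaces:

* ``D``  = 1 - 0.5 * sum |p - q|            (Schoener overlap)
* ``I``  = 1 - 0.5 * sum (sqrt(p)-sqrt(q))^2  (Hellinger-based overlap)
* ``RR`` = probability that two independently drawn cells are ranked the same
  way by both maps (ties, including the same cell twice, count as agreement)

``RR`` is computed exactly in O(n log n) through the discordant-pair identity
RR = 1 - 2*Q/n^2 with Q the number of discordant unordered cell pairs; a
brute-force enumerator and a seeded pair-sampling estimator are provided for
audit.

The equivalency null refits the model protocol on resampled pseudo-phenotype
groups (by default random re-partitions of the pooled records at the observed
group sizes) and compares every cross pair of pseudo maps against the
observed overlap.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .maxent import (
    FeatureSpec,
    fit_maxent_design,
    predict,
    sample_background,
    _extract,
    _points_array,
)
from .raster import EnvStack, Raster

__all__ = ["OverlapResult", "SuitabilityComparison", "ModelProtocol",
           "overlap_statistics", "schoener_d", "hellinger_i", "relative_rank",
           "equivalency_null", "paired_suitability_test"]


def _normalized_pair(map1: Raster, map2: Raster) -> tuple[np.ndarray, np.ndarray]:
    if map1.grid != map2.grid:
        raise ValueError("suitability maps are on different grids")
    shared = map1.mask & map2.mask
    if not shared.any():
        raise ValueError("maps share no valid cells")
    a = map1.values[shared]
    b = map2.values[shared]
    if a.sum() <= 0 or b.sum() <= 0:
        raise ValueError("all-zero suitability map")
    return a / a.sum(), b / b.sum()


def schoener_d(p: np.ndarray, q: np.ndarray) -> float:
    return float(1.0 - 0.5 * np.abs(p - q).sum())


def hellinger_i(p: np.ndarray, q: np.ndarray) -> float:
    return float(1.0 - 0.5 * ((np.sqrt(p) - np.sqrt(q)) ** 2).sum())


def _tie_pairs(x: np.ndarray) -> float:
    _, counts = np.unique(x, return_counts=True)
    return float((counts * (counts - 1) // 2).sum())


def relative_rank(
    p: np.ndarray,
    q: np.ndarray,
    method: str = "exact",
    max_exhaustive_pairs: int = 2_000_000,
    n_sample_pairs: int = 1_000_000,
    seed: int = 0,
) -> float:
    """Rank-agreement probability over independently drawn cell pairs.

    ``exact`` uses the discordant-pair identity (always exact, any size);
    ``brute`` enumerates ordered pairs when ``n^2 <= max_exhaustive_pairs`` and
    otherwise falls back to seeded sampling of ``n_sample_pairs`` pairs.
    """
    p = np.asarray(p, dtype=float).ravel()
    q = np.asarray(q, dtype=float).ravel()
    n = p.size
    if n != q.size:
        raise ValueError("maps must have equal cell counts")
    if method == "exact":
        res = stats.kendalltau(p, q)
        n0 = n * (n - 1) / 2.0
        n1 = _tie_pairs(p)
        n2 = _tie_pairs(q)
        denom = np.sqrt((n0 - n1) * (n0 - n2))
        c_minus_d = res.statistic * denom if denom > 0 else 0.0
        joint = np.unique(np.column_stack([p, q]), axis=0, return_counts=True)[1]
        n3 = float((joint * (joint - 1) // 2).sum())
        c_plus_d = n0 - n1 - n2 + n3
        discordant = max((c_plus_d - c_minus_d) / 2.0, 0.0)
        return float(1.0 - 2.0 * discordant / (n * n))
    if method == "brute":
        if n * n <= max_exhaustive_pairs:
            dp = np.sign(p[:, None] - p[None, :])
            dq = np.sign(q[:, None] - q[None, :])
            return float(np.mean(dp * dq >= 0))
        rng = np.random.default_rng(seed)
        i = rng.integers(0, n, size=n_sample_pairs)
        j = rng.integers(0, n, size=n_sample_pairs)
        return float(np.mean(np.sign(p[i] - p[j]) * np.sign(q[i] - q[j]) >= 0))
    raise ValueError(f"unknown RR method {method!r}")


def overlap_statistics(map1: Raster, map2: Raster,
                       rr_method: str = "exact") -> tuple[float, float, float]:
    """(D, I, RR) between two aligned suitability maps."""
    p, q = _normalized_pair(map1, map2)
    return schoener_d(p, q), hellinger_i(p, q), relative_rank(p, q, method=rr_method)


@dataclass
class OverlapResult:
    D: float
    I: float
    RR: float
    null_D: np.ndarray
    null_I: np.ndarray
    null_RR: np.ndarray
    p_D: float
    p_I: float
    p_RR: float
    n_null: int
    seed: int | None = None
    two_sided: bool = False

    def to_json(self, path: str | Path | None = None, include_null: bool = True) -> str:
        payload = {
            "D": self.D, "I": self.I, "RR": self.RR,
            "p_D": self.p_D, "p_I": self.p_I, "p_RR": self.p_RR,
            "n_null": self.n_null, "seed": self.seed, "two_sided": self.two_sided,
        }
        if include_null:
            payload["null_D"] = list(map(float, self.null_D))
            payload["null_I"] = list(map(float, self.null_I))
            payload["null_RR"] = list(map(float, self.null_RR))
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass
class ModelProtocol:
    """How each (pseudo-)phenotype model is fitted during equivalency runs."""

    features: FeatureSpec = field(default_factory=lambda: FeatureSpec(classes=("linear", "quadratic")))
    n_background: int = 2000
    reg_multiplier: float = 1.0
    max_iter: int = 200
    tol: float = 1e-5
    #: subsample fits averaged into each (observed or pseudo) phenotype map
    n_map_replicates: int = 1
    train_fraction: float = 0.7


def _fit_map(X: np.ndarray, Xbg: np.ndarray, layer_names, env: EnvStack,
             protocol: ModelProtocol) -> Raster:
    model = fit_maxent_design(X, Xbg, layer_names, features=protocol.features,
                              reg_multiplier=protocol.reg_multiplier,
                              max_iter=protocol.max_iter, tol=protocol.tol)
    return predict(model, env)


def _mean_map(X: np.ndarray, Xbg: np.ndarray, layer_names, env: EnvStack,
              protocol: ModelProtocol, rng: np.random.Generator) -> Raster:
    """Mean of ``n_map_replicates`` train-fraction subsample fits.

    Observed and null maps go through this same routine so that, under label
    exchangeability, the observed overlap is a draw from the null ensemble.
    """
    n = X.shape[0]
    n_train = min(max(int(round(protocol.train_fraction * n)), 2), n)
    acc = None
    for _ in range(protocol.n_map_replicates):
        pick = rng.choice(n, size=n_train, replace=False)
        r = _fit_map(X[pick], Xbg, layer_names, env, protocol)
        vals = np.where(np.isfinite(r.values), r.values, 0.0)
        acc = vals if acc is None else acc + vals
    acc = acc / protocol.n_map_replicates
    acc[~env.mask] = np.nan
    return Raster(env.grid, acc)


def _mc_p(null: np.ndarray, observed: float, two_sided: bool) -> float:
    n = len(null)
    lo = (1.0 + np.sum(null <= observed)) / (n + 1.0)
    if not two_sided:
        return float(lo)
    hi = (1.0 + np.sum(null >= observed)) / (n + 1.0)
    return float(min(1.0, 2.0 * min(lo, hi)))


def equivalency_null(
    records: Sequence,
    env: EnvStack,
    frac_minor: float = 0.1,
    n_replicates: int = 100,
    protocol: ModelProtocol | None = None,
    seed: int = 0,
    two_sided: bool = False,
    rr_method: str = "exact",
    null_mode: str = "pooled",
) -> OverlapResult:
    """Resampling niche-equivalency test between the two phenotypes.

    Observed D/I/RR come from the per-phenotype mean suitability maps over the
    protocol's replicate runs.  Two null constructions are available, both
    producing ``n_replicates**2`` cross-pair null values and sized by the
    observed phenotype proportion (``frac_minor`` / ``1 - frac_minor``):

    * ``pooled`` (default): per replicate the combined record set is randomly
      partitioned into a minor-fraction pseudo-melanistic training sample and
      a major-fraction pseudo-non-melanistic one — the standard
      identity-test null, calibrated under label exchangeability and powerful
      against distinct niches.
    * ``reciprocal``: pseudo minor-phenotype samples are drawn from the major
      group and pseudo major-phenotype samples from the minor group.  Because
      the overlap statistics are symmetric, this label-swapped null has
      essentially no power against distinct niches; it is retained for
      comparability only.

    One-sided p: proportion of null values at or below the observed overlap
    (low observed overlap => niches not equivalent).
    """
    if null_mode not in ("pooled", "reciprocal"):
        raise ValueError(f"unknown null_mode {null_mode!r}")
    if protocol is None:
        protocol = ModelProtocol()
    mel = [r for r in records if r.phenotype == "melanistic"]
    non = [r for r in records if r.phenotype == "non_melanistic"]
    n_pseudo_minor = int(round(frac_minor * len(non)))
    n_pseudo_major = int(round((1.0 - frac_minor) * len(mel)))
    if len(mel) < 4 or n_pseudo_major < 2 or n_pseudo_minor < 2:
        raise ValueError(
            "minor group too small to resample: need >=4 melanistic records and "
            "pseudo-sample sizes >=2 "
            f"(got {len(mel)} melanistic, pseudo sizes {n_pseudo_minor}/{n_pseudo_major})"
        )

    rng = np.random.default_rng(seed)
    layer_names = env.layer_names
    Xbg = _extract(env, sample_background(env, protocol.n_background,
                                          seed=int(rng.integers(2**31))))

    X_non = _extract(env, _points_array(non))
    X_mel = _extract(env, _points_array(mel))
    X_non = X_non[np.isfinite(X_non).all(axis=1)]
    X_mel = X_mel[np.isfinite(X_mel).all(axis=1)]

    map_mel = _mean_map(X_mel, Xbg, layer_names, env, protocol, rng)
    map_non = _mean_map(X_non, Xbg, layer_names, env, protocol, rng)
    D_obs, I_obs, RR_obs = overlap_statistics(map_mel, map_non, rr_method=rr_method)

    pseudo_minor_maps, pseudo_major_maps = [], []
    if null_mode == "pooled":
        # exchangeable null: re-partition the pool at the observed group sizes
        X_pool = np.vstack([X_mel, X_non])
        k_minor = len(X_mel)
        for _ in range(n_replicates):
            perm = rng.permutation(len(X_pool))
            pseudo_minor_maps.append(
                _mean_map(X_pool[perm[:k_minor]], Xbg, layer_names, env, protocol, rng)
            )
            pseudo_major_maps.append(
                _mean_map(X_pool[perm[k_minor:]], Xbg, layer_names, env, protocol, rng)
            )
    else:
        for _ in range(n_replicates):
            pick = rng.choice(len(X_non), size=n_pseudo_minor, replace=False)
            pseudo_minor_maps.append(
                _mean_map(X_non[pick], Xbg, layer_names, env, protocol, rng)
            )
            pick = rng.choice(len(X_mel), size=min(n_pseudo_major, len(X_mel) - 1),
                              replace=False)
            pseudo_major_maps.append(
                _mean_map(X_mel[pick], Xbg, layer_names, env, protocol, rng)
            )

    null_D = np.empty(n_replicates * n_replicates)
    null_I = np.empty_like(null_D)
    null_RR = np.empty_like(null_D)
    k = 0
    for a in pseudo_minor_maps:
        for b in pseudo_major_maps:
            d, i, rr = overlap_statistics(a, b, rr_method=rr_method)
            null_D[k], null_I[k], null_RR[k] = d, i, rr
            k += 1

    return OverlapResult(
        D=D_obs, I=I_obs, RR=RR_obs,
        null_D=null_D, null_I=null_I, null_RR=null_RR,
        p_D=_mc_p(null_D, D_obs, two_sided),
        p_I=_mc_p(null_I, I_obs, two_sided),
        p_RR=_mc_p(null_RR, RR_obs, two_sided),
        n_null=len(null_D), seed=seed, two_sided=two_sided,
    )


@dataclass
class SuitabilityComparison:
    suitability_a: np.ndarray
    suitability_b: np.ndarray
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t_statistic: float
    dof: int
    p_value: float
    n_used: int
    n_dropped: int


def paired_suitability_test(records: Sequence, map_a: Raster,
                            map_b: Raster) -> SuitabilityComparison:
    """Paired t-test on per-record suitabilities under two models.

    Records on nodata in either map are dropped pairwise.  Zero-variance
    differences yield t = 0, p = 1 by convention.
    """
    pts = _points_array(records)
    sa = map_a.sample(pts[:, 0], pts[:, 1])
    sb = map_b.sample(pts[:, 0], pts[:, 1])
    ok = np.isfinite(sa) & np.isfinite(sb)
    n_dropped = int((~ok).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} records on nodata cells of either map")
    sa, sb = sa[ok], sb[ok]
    n = len(sa)
    if n < 2:
        raise ValueError("paired test requires at least 2 records on valid cells")
    diff = sa - sb
    sd = diff.std(ddof=1)
    if sd == 0.0:
        t_stat, p = 0.0, 1.0
    else:
        t_stat = float(diff.mean() / (sd / np.sqrt(n)))
        p = float(2.0 * stats.t.sf(abs(t_stat), df=n - 1))
    return SuitabilityComparison(
        suitability_a=sa, suitability_b=sb,
        mean_a=float(sa.mean()), sd_a=float(sa.std(ddof=1)),
        mean_b=float(sb.mean()), sd_b=float(sb.std(ddof=1)),
        t_statistic=t_stat, dof=n - 1, p_value=p,
        n_used=n, n_dropped=n_dropped,
    )
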