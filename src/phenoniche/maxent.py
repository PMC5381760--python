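"""From-scratch maximum-entropy presence-background niche model.

The model is the Gibbs distribution over background cells that maximizes the
L1-penalized log-likelihood of the presence sample:

    maximize_lambda  mean_presence(lambda . f) - log Z(lambda) - sum_j beta_j |lambda_j|

with features standardized to [0, 1] over the training extent and per-feature
regularization following the published default schedules by feature class and
presence sample size.  Optimization is proximal gradient descent (ISTA with
backtracking line search), which is monotone in the penalized objective; the
convergence threshold applies to the relative objective change.

Output is the conventional logistic transform raw * e^H / (1 + raw * e^H)
where H is the entropy of the fitted raw distribution (implied prevalence
0.5), with features clamped to their training bounds at prediction time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import rankdata

from .raster import EnvStack, Raster

__all__ = [
    "FeatureSpec",
    "FeatureMapper",
    "MaxentModel",
    "ModelEvaluation",
    "auto_feature_classes",
    "select_predictors",
    "sample_background",
    "fit_maxent",
    "fit_maxent_design",
    "predict",
    "predict_values",
    "run_replicates",
    "auc_score",
]

DEFAULT_N_BACKGROUND = 10_000
DEFAULT_MAX_ITER = 500
DEFAULT_TOL = 1e-5
DEFAULT_TRAIN_FRACTION = 0.7

# default L1 schedule: (sample sizes, base beta) interpolation per feature class
_BETA_TABLE = {
    "linear": ([0, 10, 30, 100], [1.0, 1.0, 0.2, 0.05]),
    "quadratic": ([0, 10, 30, 100], [1.0, 1.0, 0.2, 0.05]),
    "product": ([0, 10, 30, 100], [1.0, 1.0, 0.2, 0.05]),
    "hinge": ([0, 1], [0.5, 0.5]),
}


def auto_feature_classes(n_presence: int) -> tuple[str, ...]:
    """Default feature classes by presence sample size (3.3.x auto-features)."""
    if n_presence < 10:
        return ("linear",)
    if n_presence < 15:
        return ("linear", "quadratic")
    if n_presence < 80:
        return ("linear", "quadratic", "hinge")
    return ("linear", "quadratic", "product", "hinge")


@dataclass(frozen=True)
class FeatureSpec:
    classes: tuple[str, ...] | str = "auto"
    n_hinge: int = 50

    def resolve(self, n_presence: int) -> tuple[str, ...]:
        if self.classes == "auto":
            return auto_feature_classes(n_presence)
        classes = (self.classes,) if isinstance(self.classes, str) else tuple(self.classes)
        unknown = set(classes) - set(_BETA_TABLE)
        if unknown:
            raise ValueError(f"unknown feature classes: {sorted(unknown)}")
        return classes


class FeatureMapper:
    """Expands raw layer values into standardized model features.

    Fitting records per-layer min/max over the training extent; these double
    as the clamp bounds applied at prediction time.
    """

    def __init__(self, layer_names: Sequence[str], classes: tuple[str, ...],
                 n_hinge: int = 50):
        self.layer_names = list(layer_names)
        self.classes = classes
        self.n_hinge = n_hinge
        self.mins: np.ndarray | None = None
        self.maxs: np.ndarray | None = None
        self.feature_names: list[str] = []
        self.feature_class: list[str] = []

    def fit(self, X: np.ndarray) -> "FeatureMapper":
        X = np.asarray(X, dtype=float)
        bad = ~np.isfinite(X)
        if bad.any():
            j = int(np.nonzero(bad.any(axis=0))[0][0])
            raise ValueError(f"non-finite values in layer {self.layer_names[j]!r}")
        self.mins = X.min(axis=0)
        self.maxs = X.max(axis=0)
        names, kinds = [], []
        L = self.layer_names
        if "linear" in self.classes:
            names += [f"lin({l})" for l in L]
            kinds += ["linear"] * len(L)
        if "quadratic" in self.classes:
            names += [f"quad({l})" for l in L]
            kinds += ["quadratic"] * len(L)
        if "product" in self.classes:
            for a in range(len(L)):
                for b in range(a + 1, len(L)):
                    names.append(f"prod({L[a]},{L[b]})")
                    kinds.append("product")
        if "hinge" in self.classes:
            for l in L:
                for direction, knot in self._hinge_knots():
                    names.append(f"hinge_{direction}({l},{knot:.3f})")
                    kinds.append("hinge")
        self.feature_names = names
        self.feature_class = kinds
        return self

    def _hinge_knots(self) -> list[tuple[str, float]]:
        n_fwd = self.n_hinge // 2
        n_rev = self.n_hinge - n_fwd
        fwd = np.linspace(0.0, 1.0, n_fwd + 1)[:-1]
        rev = np.linspace(0.0, 1.0, n_rev + 1)[1:]
        return [("fwd", t) for t in fwd] + [("rev", t) for t in rev]

    def _scale(self, X: np.ndarray, clamp: bool) -> np.ndarray:
        span = np.where(self.maxs > self.mins, self.maxs - self.mins, 1.0)
        Z = (np.asarray(X, dtype=float) - self.mins) / span
        if clamp:
            Z = np.clip(Z, 0.0, 1.0)
        return Z

    def transform(self, X: np.ndarray, clamp: bool = False) -> np.ndarray:
        if self.mins is None:
            raise RuntimeError("FeatureMapper.transform called before fit")
        Z = self._scale(X, clamp)
        cols = []
        if "linear" in self.classes:
            cols.append(Z)
        if "quadratic" in self.classes:
            cols.append(Z * Z)
        if "product" in self.classes:
            k = Z.shape[1]
            cols.extend(Z[:, [a]] * Z[:, [b]] for a in range(k) for b in range(a + 1, k))
        if "hinge" in self.classes:
            for j in range(Z.shape[1]):
                z = Z[:, [j]]
                for direction, t in self._hinge_knots():
                    if direction == "fwd":
                        cols.append(np.clip((z - t) / (1.0 - t), 0.0, 1.0))
                    else:
                        cols.append(np.clip((t - z) / t, 0.0, 1.0))
        return np.hstack([np.atleast_2d(c) for c in cols])


def _feature_betas(mapper: FeatureMapper, F_pres: np.ndarray,
                   reg_multiplier: float) -> np.ndarray:
    """Per-feature L1 weights: class schedule x presence spread / sqrt(m)."""
    m = F_pres.shape[0]
    std = F_pres.std(axis=0)
    betas = np.empty(F_pres.shape[1])
    for kind in set(mapper.feature_class):
        xs, ys = _BETA_TABLE[kind]
        base = float(np.interp(m, xs, ys))
        sel = np.array([c == kind for c in mapper.feature_class])
        betas[sel] = base * np.maximum(std[sel], 1e-3) / np.sqrt(m)
    return reg_multiplier * betas


@dataclass
class MaxentModel:
    mapper: FeatureMapper
    weights: np.ndarray
    log_z: float                 # log sum over training background of exp(lambda.f)
    entropy: float               # entropy of the fitted raw distribution
    betas: np.ndarray
    objective_path: np.ndarray
    n_presence: int
    n_background: int
    iterations_run: int
    converged: bool
    seed: int | None = None

    @property
    def layer_names(self) -> list[str]:
        return self.mapper.layer_names


def fit_maxent_design(
    X_presence: np.ndarray,
    X_background: np.ndarray,
    layer_names: Sequence[str],
    features: FeatureSpec = FeatureSpec(),
    reg_multiplier: float = 1.0,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    seed: int | None = None,
) -> MaxentModel:
    """Fit on raw (n, n_layers) value matrices for presences and background."""
    X_presence = np.asarray(X_presence, dtype=float)
    X_background = np.asarray(X_background, dtype=float)
    if X_presence.ndim != 2 or X_presence.shape[0] < 2:
        raise ValueError("need at least 2 presence points")
    classes = features.resolve(X_presence.shape[0])
    mapper = FeatureMapper(layer_names, classes, n_hinge=features.n_hinge)
    mapper.fit(np.vstack([X_presence, X_background]))
    F_pres = mapper.transform(X_presence)
    B = mapper.transform(X_background)
    betas = _feature_betas(mapper, F_pres, reg_multiplier)
    p_bar = F_pres.mean(axis=0)

    k = B.shape[1]
    lam = np.zeros(k)

    def loss_and_grad(l):
        s = B @ l
        ls = logsumexp(s)
        q = np.exp(s - ls)
        return ls - p_bar @ l, B.T @ q - p_bar

    def loss_only(l):
        return logsumexp(B @ l) - p_bar @ l

    step = 1.0
    loss, grad = loss_and_grad(lam)
    obj = loss + betas @ np.abs(lam)
    path = [obj]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        while True:
            cand = np.sign(lam - step * grad) * np.maximum(
                np.abs(lam - step * grad) - step * betas, 0.0
            )
            diff = cand - lam
            cand_loss = loss_only(cand)
            if cand_loss <= loss + grad @ diff + (diff @ diff) / (2.0 * step) + 1e-12:
                break
            step *= 0.5
            if step < 1e-12:
                cand, cand_loss = lam, loss
                break
        lam = cand
        loss, grad = loss_and_grad(lam)
        new_obj = loss + betas @ np.abs(lam)
        path.append(new_obj)
        rel = abs(obj - new_obj) / (abs(obj) + 1e-12)
        obj = new_obj
        step *= 1.5
        if rel < tol:
            converged = True
            break

    s_bg = B @ lam
    log_z = float(logsumexp(s_bg))
    q = np.exp(s_bg - log_z)
    entropy = float(-(q * np.log(np.maximum(q, 1e-300))).sum())
    return MaxentModel(
        mapper=mapper,
        weights=lam,
        log_z=log_z,
        entropy=entropy,
        betas=betas,
        objective_path=np.asarray(path),
        n_presence=X_presence.shape[0],
        n_background=X_background.shape[0],
        iterations_run=it,
        converged=converged,
        seed=seed,
    )


def fit_maxent(
    presences: np.ndarray,
    background: np.ndarray,
    env: EnvStack,
    features: FeatureSpec = FeatureSpec(),
    reg_multiplier: float = 1.0,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    seed: int | None = None,
) -> MaxentModel:
    """Fit from (n, 2) lon/lat point sets, extracting layer values from env."""
    Xp = _extract(env, presences)
    Xb = _extract(env, background)
    ok = np.isfinite(Xp).all(axis=1)
    if not ok.all():
        warnings.warn(f"dropping {int((~ok).sum())} presences on nodata cells")
        Xp = Xp[ok]
    if Xp.shape[0] == 0:
        raise ValueError("no presence points remain after masking")
    return fit_maxent_design(Xp, Xb, env.layer_names, features=features,
                             reg_multiplier=reg_multiplier, max_iter=max_iter,
                             tol=tol, seed=seed)


def _extract(env: EnvStack, points: np.ndarray) -> np.ndarray:
    points = np.asarray(points, dtype=float)
    sampled = env.sample(points[:, 0], points[:, 1])
    return np.column_stack([sampled[n] for n in env.layer_names])


def raw_values(model: MaxentModel, X: np.ndarray) -> np.ndarray:
    """Raw (normalized over training background) output for value rows."""
    F = model.mapper.transform(X, clamp=True)
    return np.exp(F @ model.weights - model.log_z)


def predict_values(model: MaxentModel, X: np.ndarray) -> np.ndarray:
    """Logistic output for raw layer-value rows (clamped to training bounds)."""
    r = raw_values(model, X) * np.exp(model.entropy)
    return r / (1.0 + r)


def predict(model: MaxentModel, env: EnvStack) -> Raster:
    """Logistic suitability raster; nodata propagated."""
    missing = [n for n in model.layer_names if n not in env.layers]
    if missing:
        raise ValueError(f"environment stack is missing model layers {missing}")
    rows, cols = env.valid_indices()
    X = np.column_stack([env.layers[n][rows, cols] for n in model.layer_names])
    out = np.full(env.grid.shape, np.nan)
    out[rows, cols] = predict_values(model, X)
    return Raster(env.grid, out)


def sample_background(env: EnvStack, n_background: int = DEFAULT_N_BACKGROUND,
                      seed: int = 0) -> np.ndarray:
    """Uniform random non-nodata cell centers, without replacement."""
    rows, cols = env.valid_indices()
    n_avail = len(rows)
    if n_background > n_avail:
        warnings.warn(
            f"requested {n_background} background points but only {n_avail} "
            "valid cells are available; using all of them"
        )
        n_background = n_avail
    rng = np.random.default_rng(seed)
    pick = rng.choice(n_avail, size=n_background, replace=False)
    lon, lat = env.grid.cell_center(rows[pick], cols[pick])
    return np.column_stack([lon, lat])


def select_predictors(
    env: EnvStack,
    range_polygon=None,
    n_points: int = DEFAULT_N_BACKGROUND,
    r_cutoff: float = 0.7,
    seed: int = 0,
) -> list[str]:
    """Correlation-based predictor pre-selection.

    Samples unique random cells (within ``range_polygon`` if given, a shapely
    geometry in lon/lat), computes pairwise Pearson r among layers, and
    iteratively drops the layer with the most over-threshold partners (ties by
    larger mean |r|, then name order) until no retained pair exceeds the
    cutoff.
    """
    if len(env.layer_names) < 2:
        raise ValueError("predictor selection needs at least 2 layers")
    rows, cols = env.valid_indices()
    if range_polygon is not None:
        import shapely

        lon, lat = env.grid.cell_center(rows, cols)
        inside = shapely.contains_xy(range_polygon, lon, lat)
        rows, cols = rows[inside], cols[inside]
    n_avail = len(rows)
    if n_points > n_avail:
        warnings.warn(
            f"requested {n_points} sample points but only {n_avail} cells available"
        )
        n_points = n_avail
    rng = np.random.default_rng(seed)
    pick = rng.choice(n_avail, size=n_points, replace=False)
    X = env.table(rows[pick], cols[pick])
    names = list(env.layer_names)
    R = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(R, 0.0)
    absR = np.abs(R)
    keep = list(range(len(names)))
    while True:
        sub = absR[np.ix_(keep, keep)]
        over = sub > r_cutoff
        n_over = over.sum(axis=1)
        if n_over.max() == 0:
            break
        worst = n_over.max()
        tied = [i for i in range(len(keep)) if n_over[i] == worst]
        if len(tied) > 1:
            mean_abs = sub.mean(axis=1)
            best = max(mean_abs[i] for i in tied)
            tied = [i for i in tied if mean_abs[i] == best]
        drop = min(tied, key=lambda i: names[keep[i]])
        keep.pop(drop)
    return [names[i] for i in keep]


def auc_score(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """Mann-Whitney AUC with tie correction (midranks)."""
    pos_scores = np.asarray(pos_scores, dtype=float)
    neg_scores = np.asarray(neg_scores, dtype=float)
    n1, n2 = len(pos_scores), len(neg_scores)
    if n1 == 0 or n2 == 0:
        raise ValueError("AUC requires nonempty score sets")
    ranks = rankdata(np.concatenate([pos_scores, neg_scores]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n2))


@dataclass
class ModelEvaluation:
    auc_train: float
    auc_test: float
    auc_test_se: float
    per_replicate_auc: np.ndarray
    variable_importance: dict[str, float]
    response_curves: dict[str, tuple[np.ndarray, np.ndarray]]
    n_presence: int
    n_background: int
    n_replicates: int
    seed: int

    def importance_sum(self) -> float:
        return float(sum(self.variable_importance.values()))


def run_replicates(
    records,
    env: EnvStack,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    n_replicates: int = 10,
    seed: int = 0,
    n_background: int = DEFAULT_N_BACKGROUND,
    features: FeatureSpec = FeatureSpec(),
    reg_multiplier: float = 1.0,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
) -> tuple[Raster, ModelEvaluation]:
    """Replicated 70/30 fit-evaluate runs; mean suitability map + evaluation.

    Per replicate: random presence split at ``train_fraction``, model fit on
    the training split, AUC of test presences against the background sample,
    and permutation variable importance (mean AUC drop when one layer's values
    are shuffled across evaluation points, normalized to percentages).
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    pts = _points_array(records)
    Xall = _extract(env, pts)
    ok = np.isfinite(Xall).all(axis=1)
    if not ok.all():
        warnings.warn(f"dropping {int((~ok).sum())} records on nodata cells")
        Xall = Xall[ok]
    n = Xall.shape[0]
    if n < 4:
        raise ValueError("need at least 4 usable presence records")
    bg_pts = sample_background(env, n_background, seed=seed)
    Xbg = _extract(env, bg_pts)
    rng = np.random.default_rng(seed)
    layer_names = env.layer_names

    mean_map = np.zeros(env.grid.shape)
    aucs_test, aucs_train = [], []
    drops = np.zeros((n_replicates, len(layer_names)))
    curves_acc: dict[str, np.ndarray] = {}
    curve_grids: dict[str, np.ndarray] = {}

    for rep in range(n_replicates):
        for _attempt in range(20):
            perm = rng.permutation(n)
            n_train = int(round(train_fraction * n))
            n_train = min(max(n_train, 2), n - 2)
            train, test = perm[:n_train], perm[n_train:]
            if len(test) >= 2:
                break
            warnings.warn("replicate split produced <2 test presences; resampling")
        model = fit_maxent_design(Xall[train], Xbg, layer_names, features=features,
                                  reg_multiplier=reg_multiplier, max_iter=max_iter,
                                  tol=tol)
        s_test = predict_values(model, Xall[test])
        s_train = predict_values(model, Xall[train])
        s_bg = predict_values(model, Xbg)
        auc = auc_score(s_test, s_bg)
        aucs_test.append(auc)
        aucs_train.append(auc_score(s_train, s_bg))

        X_eval = np.vstack([Xall[test], Xbg])
        n_test = len(test)
        for j in range(len(layer_names)):
            Xp = X_eval.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            sp = predict_values(model, Xp)
            drops[rep, j] = auc - auc_score(sp[:n_test], sp[n_test:])

        rast = predict(model, env)
        mean_map += np.where(np.isfinite(rast.values), rast.values, 0.0)

        X_train_mean = Xall[train].mean(axis=0)
        for j, name in enumerate(layer_names):
            lo, hi = Xall[:, j].min(), Xall[:, j].max()
            grid = np.linspace(lo, hi, 50)
            Xc = np.tile(X_train_mean, (50, 1))
            Xc[:, j] = grid
            resp = predict_values(model, Xc)
            curve_grids[name] = grid
            curves_acc[name] = curves_acc.get(name, 0.0) + resp

    mean_map /= n_replicates
    mean_map[~env.mask] = np.nan
    mean_drop = np.clip(drops.mean(axis=0), 0.0, None)
    total = mean_drop.sum()
    if total > 0:
        importance = {nm: 100.0 * d / total for nm, d in zip(layer_names, mean_drop)}
    else:
        importance = {nm: 100.0 / len(layer_names) for nm in layer_names}
    aucs_test = np.asarray(aucs_test)
    evaluation = ModelEvaluation(
        auc_train=float(np.mean(aucs_train)),
        auc_test=float(aucs_test.mean()),
        auc_test_se=float(aucs_test.std(ddof=1) / np.sqrt(len(aucs_test)))
        if len(aucs_test) > 1
        else 0.0,
        per_replicate_auc=aucs_test,
        variable_importance=importance,
        response_curves={
            nm: (curve_grids[nm], curves_acc[nm] / n_replicates) for nm in layer_names
        },
        n_presence=n,
        n_background=Xbg.shape[0],
        n_replicates=n_replicates,
        seed=seed,
    )
    return Raster(env.grid, mean_map), evaluation


def _points_array(records) -> np.ndarray:
    if isinstance(records, np.ndarray):
        return np.asarray(records, dtype=float)
    return np.array([[r.lon, r.lat] for r in records], dtype=float)
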