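"""Penalized presence-background climate suitability model.

The model is a lasso-penalized logistic regression on use/availability labels
(a maxnet-equivalent parameterization) over linear / quadratic / hinge
feature expansions of min-max scaled covariates. A regularization-multiplier
sweep is scored by AIC with k = number of nonzero coefficients. Projection
clamps covariates to the training range; the MOP surface flags extrapolation.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .evaluation import auc
from .grids import Grid, Raster, RasterStack
from .occurrences import SampleTable

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureSpec",
    "MaxentModel",
    "SweepResult",
    "MopSurface",
    "build_features",
    "fit_maxent",
    "sweep_regularization",
    "checkerboard_partition",
    "cv_evaluate",
    "predict_surface",
    "project_gcms",
    "mop",
    "DEFAULT_REG_GRID",
]

DEFAULT_REG_GRID = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0)
# base per-sample lasso weight multiplied by the regularization multiplier
BASE_PENALTY = 0.005
COEF_TOL = 1e-6


@dataclass
class FeatureSpec:
    classes: tuple[str, ...] = ("linear", "quadratic")
    hinge_knots: int = 3
    normalization: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        allowed = {"linear", "quadratic", "hinge"}
        if not self.classes or not set(self.classes) <= allowed:
            raise ValueError(f"feature classes must be a nonempty subset of {allowed}")


def _scale(x: np.ndarray, lo: float, hi: float, clamp: bool) -> np.ndarray:
    z = (x - lo) / (hi - lo)
    return np.clip(z, 0.0, 1.0) if clamp else z


def build_features(
    X: np.ndarray,
    names: list[str],
    spec: FeatureSpec,
    fit_normalization: bool = False,
    clamp: bool = False,
) -> tuple[np.ndarray, list[str]]:
    """Design matrix of scaled covariates expanded per feature class.

    With ``fit_normalization`` the per-covariate (min, max) is learned from
    ``X`` and stored on the spec; otherwise the stored ranges are used
    (optionally clamping out-of-range values, for projection).
    """
    X = np.asarray(X, dtype=float)
    cols: list[np.ndarray] = []
    out_names: list[str] = []
    for j, name in enumerate(names):
        x = X[:, j]
        if fit_normalization:
            lo, hi = float(np.min(x)), float(np.max(x))
            if hi <= lo:
                warnings.warn(f"constant covariate {name!r}: features dropped")
                continue
            spec.normalization[name] = (lo, hi)
        if name not in spec.normalization:
            continue  # dropped as constant at fit time
        lo, hi = spec.normalization[name]
        z = _scale(x, lo, hi, clamp)
        if "linear" in spec.classes:
            cols.append(z)
            out_names.append(f"{name}")
        if "quadratic" in spec.classes:
            cols.append(z**2)
            out_names.append(f"{name}^2")
        if "hinge" in spec.classes:
            knots = np.linspace(0, 1, spec.hinge_knots + 2)[1:-1]
            for t in knots:
                cols.append(np.maximum(z - t, 0.0) / (1 - t))
                out_names.append(f"hinge({name}>{t:.3g})")
                cols.append(np.maximum(t - z, 0.0) / t)
                out_names.append(f"hinge({name}<{t:.3g})")
    if not cols:
        raise ValueError("no usable covariates (all constant?)")
    return np.column_stack(cols), out_names


@dataclass
class MaxentModel:
    spec: FeatureSpec
    covariate_names: list[str]
    feature_names: list[str]
    coefficients: np.ndarray
    intercept: float
    reg_multiplier: float
    log_likelihood: float = np.nan
    n_clamped: int = 0  # updated by predict_surface

    @property
    def n_nonzero(self) -> int:
        return int(np.sum(np.abs(self.coefficients) > COEF_TOL))

    def predict(self, X: np.ndarray, clamp: bool = True) -> np.ndarray:
        F, _ = build_features(X, self.covariate_names, self.spec, clamp=clamp)
        eta = F @ self.coefficients + self.intercept
        return 1.0 / (1.0 + np.exp(-eta))

    def to_json(self) -> str:
        return json.dumps(
            {
                "format": "habscape-maxent-v1",
                "classes": list(self.spec.classes),
                "hinge_knots": self.spec.hinge_knots,
                "normalization": {k: list(v) for k, v in self.spec.normalization.items()},
                "covariates": self.covariate_names,
                "features": self.feature_names,
                "coefficients": self.coefficients.tolist(),
                "intercept": self.intercept,
                "reg_multiplier": self.reg_multiplier,
                "log_likelihood": self.log_likelihood,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "MaxentModel":
        d = json.loads(text)
        spec = FeatureSpec(
            tuple(d["classes"]),
            d["hinge_knots"],
            {k: tuple(v) for k, v in d["normalization"].items()},
        )
        return cls(
            spec,
            d["covariates"],
            d["features"],
            np.asarray(d["coefficients"], dtype=float),
            float(d["intercept"]),
            float(d["reg_multiplier"]),
            float(d["log_likelihood"]),
        )


def _log_likelihood(F: np.ndarray, y: np.ndarray, coef: np.ndarray, icpt: float) -> float:
    eta = F @ coef + icpt
    # stable log(1 + exp(-|eta|)) formulation
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_maxent(
    table: SampleTable,
    reg_multiplier: float = 1.0,
    spec: FeatureSpec | None = None,
    max_iter: int = 5000,
) -> MaxentModel:
    """Lasso-penalized presence-background logistic fit."""
    if reg_multiplier <= 0:
        raise ValueError("reg_multiplier must be positive")
    y = table.labels
    if y.sum() < 10 or (1 - y).sum() < 10:
        raise ValueError("need at least 10 presences and 10 background points")
    spec = spec or FeatureSpec()
    spec = FeatureSpec(spec.classes, spec.hinge_knots, {})
    F, feat_names = build_features(table.X, table.covariate_names, spec, fit_normalization=True)
    n = len(y)
    lam = BASE_PENALTY * reg_multiplier  # per-sample l1 weight
    C = 1.0 / (lam * n)
    clf = LogisticRegression(
        l1_ratio=1, C=C, solver="liblinear", max_iter=max_iter, tol=1e-8, random_state=0
    )
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            clf.fit(F, y)
        except ConvergenceWarning as exc:  # pragma: no cover - iteration cap
            raise RuntimeError("maxent fit failed to converge") from exc
    coef = clf.coef_.ravel().copy()
    coef[np.abs(coef) <= COEF_TOL] = 0.0
    icpt = float(clf.intercept_[0])
    model = MaxentModel(spec, list(table.covariate_names), feat_names, coef, icpt, reg_multiplier)
    model.log_likelihood = _log_likelihood(F, y, coef, icpt)
    return model


@dataclass
class SweepResult:
    candidates: list[dict]  # reg_multiplier, model, log_likelihood, k, aic
    selected: int

    @property
    def model(self) -> MaxentModel:
        return self.candidates[self.selected]["model"]


def sweep_regularization(
    table: SampleTable,
    multipliers=DEFAULT_REG_GRID,
    spec: FeatureSpec | None = None,
) -> SweepResult:
    """One candidate per multiplier; argmin AIC selected (tie -> larger reg)."""
    multipliers = list(multipliers)
    if not multipliers:
        raise ValueError("multipliers must be nonempty")
    candidates = []
    for m in multipliers:
        try:
            model = fit_maxent(table, reg_multiplier=m, spec=spec)
        except RuntimeError:
            logger.warning("sweep: fit failed at multiplier %g", m)
            continue
        k = model.n_nonzero
        aic = 2 * k - 2 * model.log_likelihood
        candidates.append(
            {
                "reg_multiplier": m,
                "model": model,
                "log_likelihood": model.log_likelihood,
                "k": k,
                "aic": aic,
            }
        )
    if not candidates:
        raise RuntimeError("all sweep fits failed")
    aics = np.array([c["aic"] for c in candidates])
    regs = np.array([c["reg_multiplier"] for c in candidates])
    best = np.flatnonzero(np.isclose(aics, aics.min()))
    selected = int(best[np.argmax(regs[best])])
    return SweepResult(candidates, selected)


def checkerboard_partition(points, template: Grid, aggregation_factor: int = 1) -> np.ndarray:
    """Two spatial folds by parity of coarse checkerboard blocks."""
    if aggregation_factor < 1:
        raise ValueError("aggregation_factor must be >= 1")
    lon = np.asarray(points["lon"], dtype=float)
    lat = np.asarray(points["lat"], dtype=float)
    row, col = template.index_of(lon, lat)
    folds = ((row // aggregation_factor + col // aggregation_factor) % 2).astype(int)
    if len(np.unique(folds)) < 2:
        warnings.warn("all points fall in a single checkerboard fold")
    return folds


def cv_evaluate(
    table: SampleTable,
    folds: np.ndarray,
    reg_multiplier: float = 1.0,
    spec: FeatureSpec | None = None,
) -> list[float]:
    """Held-out AUC per occupied fold (fit on the rest)."""
    folds = np.asarray(folds)
    uniq = np.unique(folds)
    if len(uniq) < 2:
        raise ValueError("need at least 2 occupied folds")
    y = table.labels
    aucs = []
    for f in uniq:
        test = folds == f
        train = ~test
        if y[test].sum() == 0 or y[train].sum() < 10:
            logger.warning("cv_evaluate: fold %s skipped (no presences)", f)
            continue
        sub = SampleTable(
            table.data[train].reset_index(drop=True),
            table.covariate_names,
            source_tag=table.source_tag,
        )
        model = fit_maxent(sub, reg_multiplier=reg_multiplier, spec=spec)
        scores = model.predict(table.X[test])
        aucs.append(auc(scores[y[test] == 1], scores[y[test] == 0]))
    return aucs


def predict_surface(model: MaxentModel, stack: RasterStack) -> Raster:
    """Per-cell prediction in [0,1]; out-of-range covariates are clamped."""
    missing = [n for n in model.covariate_names if n not in stack]
    if missing:
        raise KeyError(f"stack missing covariate layers: {missing}")
    arr = stack.as_array(model.covariate_names)  # (p, r, c)
    p, nr, nc = arr.shape
    flat = arr.reshape(p, -1).T
    valid = ~np.isnan(flat).any(axis=1)
    out = np.full(nr * nc, np.nan)
    if valid.any():
        Xv = flat[valid]
        n_clamped = 0
        for j, name in enumerate(model.covariate_names):
            if name in model.spec.normalization:
                lo, hi = model.spec.normalization[name]
                n_clamped += int(np.sum((Xv[:, j] < lo) | (Xv[:, j] > hi)))
        model.n_clamped = n_clamped
        out[valid] = model.predict(Xv, clamp=True)
    return Raster(stack.grid, out.reshape(nr, nc))


def project_gcms(
    model: MaxentModel, future_stacks: list[RasterStack], threshold: float
) -> tuple[Raster, Raster]:
    """Mean suitability over pseudo-GCMs and count of stacks >= threshold."""
    if not future_stacks:
        raise ValueError("need at least one future stack")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    grid = future_stacks[0].grid
    total = np.zeros(grid.shape)
    count = np.zeros(grid.shape)
    valid = np.ones(grid.shape, dtype=bool)
    for stack in future_stacks:
        if not stack.grid.aligned_with(grid):
            raise ValueError("future stacks are on inconsistent grids")
        pred = predict_surface(model, stack).values
        valid &= ~np.isnan(pred)
        total += np.nan_to_num(pred)
        count += (np.nan_to_num(pred) >= threshold) & ~np.isnan(pred)
    mean = np.where(valid, total / len(future_stacks), np.nan)
    bsum = np.where(valid, count, np.nan)
    return Raster(grid, mean), Raster(grid, bsum)


@dataclass
class MopSurface:
    similarity: Raster  # in [0, 1]
    extrapolation_mask: Raster  # 1 where any covariate outside calibration range


def mop(
    calibration: SampleTable | np.ndarray,
    projection_stack: RasterStack,
    covariate_names: list[str] | None = None,
    fraction: float = 0.10,
    sample_rows: int = 2000,
    seed=0,
) -> MopSurface:
    """Similarity of each projection cell to the nearest ``fraction`` of the
    calibration cloud (standardized Euclidean distance), rescaled to [0,1]."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if isinstance(calibration, SampleTable):
        names = covariate_names or calibration.covariate_names
        calib = calibration.data[names].to_numpy(dtype=float)
    else:
        calib = np.asarray(calibration, dtype=float)
        if calib.ndim == 1:
            calib = calib[:, None]
        names = covariate_names or projection_stack.names
    if calib.shape[0] < 10:
        raise ValueError("need at least 10 calibration rows")
    if not projection_stack.layers:
        raise ValueError("projection stack is empty")
    rng = np.random.default_rng(seed)
    if calib.shape[0] > sample_rows:
        calib = calib[rng.choice(calib.shape[0], sample_rows, replace=False)]
    mu = calib.mean(axis=0)
    sd = calib.std(axis=0)
    sd[sd == 0] = 1.0
    cal_lo = calib.min(axis=0)
    cal_hi = calib.max(axis=0)
    calz = (calib - mu) / sd

    arr = projection_stack.as_array(names)
    p, nr, nc = arr.shape
    flat = arr.reshape(p, -1).T
    valid = ~np.isnan(flat).any(axis=1)
    m = int(np.ceil(fraction * calz.shape[0]))
    dist = np.full(nr * nc, np.nan)
    extrap = np.full(nr * nc, np.nan)
    if valid.any():
        Xv = flat[valid]
        extrap[valid] = ((Xv < cal_lo) | (Xv > cal_hi)).any(axis=1).astype(float)
        Xz = (Xv - mu) / sd
        means = np.empty(Xz.shape[0])
        chunk = max(1, 2_000_000 // max(calz.shape[0], 1))
        for i in range(0, Xz.shape[0], chunk):
            d = np.sqrt(
                np.maximum(
                    ((Xz[i : i + chunk] ** 2).sum(1)[:, None])
                    - 2 * Xz[i : i + chunk] @ calz.T
                    + (calz**2).sum(1)[None, :],
                    0.0,
                )
            )
            if m < d.shape[1]:
                d = np.partition(d, m - 1, axis=1)[:, :m]
            means[i : i + chunk] = d.mean(axis=1)
        dist[valid] = means
    d_max = np.nanmax(dist)
    sim = 1.0 - dist / d_max if d_max > 0 else np.where(np.isnan(dist), np.nan, 1.0)
    return MopSurface(
        Raster(projection_stack.grid, sim.reshape(nr, nc)),
        Raster(projection_stack.grid, extrap.reshape(nr, nc)),
    )
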