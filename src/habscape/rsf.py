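"""Four-learner ensemble habitat model on presence/background tables.

Members: the penalized presence-background model, a random forest, a single
classification tree (class-probability output), and an unpenalized logistic
GLM. The ensemble prediction is the equal-weight mean of member predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.tree import DecisionTreeClassifier

from .climate import fit_maxent
from .grids import Raster, RasterStack
from .occurrences import SampleTable

__all__ = ["EnsembleModel", "fit_ensemble", "predict_ensemble", "REDUCED_PREDICTORS"]

# reduced predictor set used by default (full set available by config)
REDUCED_PREDICTORS = (
    "dist_major_road",
    "road_density",
    "frac_agriculture",
    "frac_barren",
    "frac_grass",
    "frac_shrub",
    "frac_urban",
)

MEMBER_NAMES = ("maxent", "random_forest", "cart", "glm_logistic")


@dataclass
class EnsembleModel:
    members: dict
    training_covariates: list[str]
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one fitted member")

    def member_predict(self, name: str, X: np.ndarray) -> np.ndarray:
        member = self.members[name]
        if name == "maxent":
            return member.predict(X)
        return member.predict_proba(X)[:, 1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        preds = [self.member_predict(name, X) for name in self.members]
        return np.mean(preds, axis=0)


def fit_ensemble(
    table: SampleTable,
    covariates=None,
    seed: int = 0,
    n_trees: int = 500,
    reg_multiplier: float = 1.0,
) -> EnsembleModel:
    """Fit all four members on identical rows; any member failure raises."""
    names = list(covariates) if covariates is not None else list(table.covariate_names)
    sub = SampleTable(table.data, names, source_tag=table.source_tag)
    y = sub.labels
    if len(y) < 30:
        raise ValueError("need at least 30 rows to fit the ensemble")
    if y.min() == y.max():
        raise ValueError("both presence and background labels are required")
    X = sub.X
    members: dict = {}
    members["maxent"] = fit_maxent(sub, reg_multiplier=reg_multiplier)
    # trees get mild leaf-size regularization: fully-grown trees memorize the
    # presence/background noise and destabilize the consensus on desk-scale data
    members["random_forest"] = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, min_samples_leaf=10, n_jobs=1
    ).fit(X, y)
    members["cart"] = DecisionTreeClassifier(random_state=seed, min_samples_leaf=25).fit(X, y)
    members["glm_logistic"] = LogisticRegression(C=np.inf, max_iter=2000).fit(X, y)
    return EnsembleModel(members, names, seed)


def predict_ensemble(model: EnsembleModel, stack: RasterStack) -> Raster:
    """Per-cell mean of member predictions; nodata propagated."""
    missing = [n for n in model.training_covariates if n not in stack]
    if missing:
        raise KeyError(f"stack missing covariate layers: {missing}")
    arr = stack.as_array(model.training_covariates)
    p, nr, nc = arr.shape
    flat = arr.reshape(p, -1).T
    valid = ~np.isnan(flat).any(axis=1)
    out = np.full(nr * nc, np.nan)
    if valid.any():
        out[valid] = model.predict(flat[valid])
    return Raster(stack.grid, out.reshape(nr, nc))
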