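"""Boosted-regression-tree machinery shared by both analyses.

Thin, contract-checked layer over scikit-learn's gradient-boosting
estimators providing the pieces both analysis stages need:

* stagewise fits with shrinkage, per-tree row subsampling (bag
  fraction), depth-limited trees and observation weights, deterministic
  under a fixed seed;
* tree-count selection by minimizing mean out-of-fold deviance along
  the staged ensemble, scanning a tree grid (default 50-10,000 in steps
  of ten) — the cross-validated analogue of stagewise early stopping
  used for ecological boosted-tree models;
* relative influence (improvement-based importance normalized to sum
  to 100%);
* partial dependence: mean prediction over the training rows with one
  variable clamped to each grid value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, GradientBoostingRegressor
from sklearn.model_selection import KFold, StratifiedKFold

_EPS = 1e-12


@dataclass
class BRTConfig:
    learning_rate: float = 0.001
    bag_fraction: float = 0.5
    tree_complexity: int = 3          # max interaction depth
    n_trees_range: tuple[int, int] = (50, 10000)
    n_trees_step: int = 10
    loss: str = "bernoulli"           # "bernoulli" or "squared"
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not (0 < self.bag_fraction <= 1):
            raise ValueError("bag_fraction must be in (0, 1]")
        if self.tree_complexity < 1:
            raise ValueError("tree_complexity must be >= 1")
        if self.loss not in ("bernoulli", "squared"):
            raise ValueError("loss must be 'bernoulli' or 'squared'")
        lo, hi = self.n_trees_range
        if lo < 1 or hi < lo or self.n_trees_step < 1:
            raise ValueError("inconsistent tree range/step")

    def tree_grid(self) -> np.ndarray:
        lo, hi = self.n_trees_range
        return np.arange(lo, hi + 1, self.n_trees_step)


@dataclass
class BRTModel:
    estimator: object
    config: BRTConfig
    n_trees: int
    feature_names: list[str]
    deviance_trace: pd.DataFrame | None = None
    train_X: pd.DataFrame | None = None

    @property
    def is_classifier(self) -> bool:
        return self.config.loss == "bernoulli"

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Probability of the positive class (bernoulli) or the fitted value."""
        X = X[self.feature_names]
        if self.is_classifier:
            return self.estimator.predict_proba(X)[:, 1]
        return self.estimator.predict(X)


def _make_estimator(config: BRTConfig, n_trees: int, seed: int):
    kw = dict(learning_rate=config.learning_rate, n_estimators=int(n_trees),
              subsample=config.bag_fraction, max_depth=config.tree_complexity,
              random_state=int(seed))
    if config.loss == "bernoulli":
        return GradientBoostingClassifier(**kw)
    return GradientBoostingRegressor(loss="squared_error", **kw)


def bernoulli_deviance(y, p, weights=None) -> float:
    """-2 sum w [y log p + (1-y) log(1-p)], probabilities clipped for safety."""
    p = np.clip(np.asarray(p, dtype=float), _EPS, 1.0 - _EPS)
    y = np.asarray(y, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    return float(-2.0 * np.sum(w * (y * np.log(p) + (1 - y) * np.log1p(-p))))


def squared_error(y, yhat, weights=None) -> float:
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    return float(np.sum(w * (y - yhat) ** 2))


def _staged_deviances(est, X, y, w, grid, loss) -> np.ndarray:
    """Holdout deviance at every grid tree count along the staged ensemble."""
    out = np.empty(len(grid))
    pos = 0
    stages = (est.staged_predict_proba(X) if loss == "bernoulli"
              else est.staged_predict(X))
    for i, stage in enumerate(stages, start=1):
        if pos < len(grid) and i == grid[pos]:
            if loss == "bernoulli":
                out[pos] = bernoulli_deviance(y, stage[:, 1], w)
            else:
                out[pos] = squared_error(y, stage, w)
            pos += 1
        if pos == len(grid):
            break
    return out


def select_n_trees(X: pd.DataFrame, y, config: BRTConfig,
                   sample_weight=None) -> tuple[int, pd.DataFrame]:
    """Choose the tree count minimizing mean out-of-fold deviance.

    Each fold fits the maximal ensemble once and evaluates its staged
    predictions on the held-out fold at every grid count; ties go to
    the smallest count.  Returns ``(n_trees, trace)`` where ``trace``
    has columns ``n_trees`` and ``deviance``.
    """
    y = np.asarray(y)
    w = None if sample_weight is None else np.asarray(sample_weight, dtype=float)
    grid = config.tree_grid()
    if config.loss == "bernoulli":
        splitter = StratifiedKFold(n_splits=config.n_folds, shuffle=True,
                                   random_state=config.seed)
    else:
        splitter = KFold(n_splits=config.n_folds, shuffle=True,
                         random_state=config.seed)
    dev = np.zeros(len(grid))
    for k, (tr, te) in enumerate(splitter.split(X, y)):
        est = _make_estimator(config, grid[-1], config.seed + 1000 * (k + 1))
        est.fit(X.iloc[tr], y[tr], sample_weight=None if w is None else w[tr])
        dev += _staged_deviances(est, X.iloc[te], y[te],
                                 None if w is None else w[te], grid, config.loss)
    dev /= config.n_folds
    best = int(grid[int(np.argmin(dev))])  # argmin returns the first (smallest) tie
    trace = pd.DataFrame({"n_trees": grid, "deviance": dev})
    return best, trace


def fit_brt(X: pd.DataFrame, y, config: BRTConfig,
            sample_weight=None, n_trees: int | None = None) -> BRTModel:
    """Fit a boosted-tree ensemble; selects the tree count by CV when not given."""
    if X.isna().any().any():
        raise ValueError("missing feature values; drop incomplete rows upstream")
    y = np.asarray(y)
    if len(y) < 10:
        raise ValueError("need at least 10 rows")
    if config.loss == "bernoulli" and len(np.unique(y)) < 2:
        raise ValueError("bernoulli loss requires both classes in the response")
    trace = None
    if n_trees is None:
        n_trees, trace = select_n_trees(X, y, config, sample_weight)
    est = _make_estimator(config, n_trees, config.seed)
    est.fit(X, y, sample_weight=sample_weight)
    return BRTModel(estimator=est, config=config, n_trees=int(n_trees),
                    feature_names=list(X.columns), deviance_trace=trace,
                    train_X=X.reset_index(drop=True))


def relative_influence(model: BRTModel) -> pd.Series:
    """Per-variable relative influence in percent (sums to 100)."""
    if not hasattr(model.estimator, "feature_importances_"):
        raise ValueError("model is not fitted")
    imp = np.asarray(model.estimator.feature_importances_, dtype=float)
    total = imp.sum()
    pct = imp * 100.0 / total if total > 0 else np.full_like(imp, 100.0 / len(imp))
    return pd.Series(pct, index=model.feature_names).sort_values(ascending=False)


def partial_dependence(model: BRTModel, variable: str,
                       grid_size: int = 50,
                       X: pd.DataFrame | None = None,
                       grid: str = "quantile") -> pd.DataFrame:
    """Marginal effect of one variable: mean prediction with it clamped.

    For each grid value v spanning the observed range, every training
    row has ``variable`` set to v and the predictions are averaged.
    The default grid places points at empirical quantiles (including
    the observed min and max) so skewed covariates are resolved where
    the data live; ``grid="linear"`` gives an equally spaced grid.
    """
    if variable not in model.feature_names:
        raise KeyError(f"unknown model variable: {variable!r}")
    data = model.train_X if X is None else X
    if data is None:
        raise ValueError("no training data stored; pass X explicitly")
    vals = data[variable].to_numpy(dtype=float)
    if grid == "quantile":
        grid = np.unique(np.quantile(vals, np.linspace(0.0, 1.0, grid_size)))
    else:
        grid = np.linspace(vals.min(), vals.max(), grid_size)
    grid_size = len(grid)
    work = data.copy()
    yhat = np.empty(grid_size)
    for i, v in enumerate(grid):
        work[variable] = v
        yhat[i] = float(np.mean(model.predict(work)))
    return pd.DataFrame({"value": grid, "yhat": yhat})
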