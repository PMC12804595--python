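"""Cascade-forest regressor (deep forest without multi-grained scanning).

Each layer is an ensemble of forest units — by default 2 random forests and
2 extremely-randomized-trees regressors of 100 trees each.  A layer predicts
its input and the per-unit prediction vector (the *augmentation vector*) is
concatenated to the original features as the next layer's input, so every
layer after the first sees d + U columns.  Depth is adaptive: a candidate
layer is retained only if its internal cross-validation score improves on the
best retained layer by more than a tolerance; otherwise it is discarded and
growth stops.  The final output is the arithmetic mean of the last layer's
unit predictions.

During training the augmentation passed forward is built from out-of-fold
(OOF) predictions of a k-fold cross-fit, which prevents the cascade from
trivially overfitting its own in-sample outputs; at prediction time each
stored unit (refit on the full layer input) produces the augmentation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import ExtraTreesRegressor, RandomForestRegressor
from sklearn.model_selection import KFold

from .seeds import derive_seed

log = logging.getLogger("toxcascade.cascade")

UNIT_KINDS = ("rf", "et")


@dataclass(frozen=True)
class CascadeConfig:
    """Hyperparameters of the cascade.

    Defaults follow the standard deep-forest configuration: four units per
    layer (2 RF + 2 extra-trees), 100 trees per unit, 3-fold internal CV.
    ``growth_tolerance`` and ``max_layers`` are explicit convergence guards.
    """

    units_per_layer: tuple[str, ...] = ("rf", "rf", "et", "et")
    trees_per_unit: int = 100
    cv_folds: int = 3
    max_layers: int = 20
    growth_tolerance: float = 1e-4
    growth_metric: str = "r2"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.units_per_layer:
            raise ValueError("need at least one unit per layer")
        bad = set(self.units_per_layer) - set(UNIT_KINDS)
        if bad:
            raise ValueError(f"unknown unit kinds {sorted(bad)}; use {UNIT_KINDS}")
        if self.trees_per_unit < 1:
            raise ValueError("trees_per_unit must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.max_layers < 1:
            raise ValueError("max_layers must be >= 1")
        if self.growth_tolerance < 0:
            raise ValueError("growth_tolerance must be nonnegative")
        if self.growth_metric not in ("r2", "neg_mse"):
            raise ValueError("growth_metric must be 'r2' or 'neg_mse'")

    @property
    def n_units(self) -> int:
        return len(self.units_per_layer)


def make_forest_unit(kind: str, trees: int, seed: int):
    """Construct one forest unit (sklearn estimator) with a fixed seed."""
    if kind == "rf":
        return RandomForestRegressor(n_estimators=trees, random_state=seed, n_jobs=1)
    if kind == "et":
        return ExtraTreesRegressor(n_estimators=trees, random_state=seed, n_jobs=1)
    raise ValueError(f"unknown unit kind {kind!r}")


def _layer_score(y: np.ndarray, oof_mean: np.ndarray, metric: str) -> float:
    """Internal-CV score of a layer from the unit-averaged OOF prediction.

    For a degenerate (constant) target the R² ratio is undefined; a perfect
    OOF fit scores 1 and anything else -inf, so growth halts after layer 1.
    """
    resid = float(np.mean((y - oof_mean) ** 2))
    if metric == "neg_mse":
        return -resid
    ss_tot = float(np.mean((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if resid < 1e-12 else -np.inf
    return 1.0 - resid / ss_tot


@dataclass
class _Layer:
    units: list
    input_width: int


@dataclass
class CascadeForestModel:
    """A fitted cascade: ordered layers of forest units plus a growth trace."""

    config: CascadeConfig
    input_width: int
    layers: list[_Layer] = field(default_factory=list)
    growth_trace: list[float] = field(default_factory=list)

    @property
    def depth(self) -> int:
        return len(self.layers)

    @property
    def n_units(self) -> int:
        return self.config.n_units

    # -- inference ---------------------------------------------------------

    def _check_width(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.input_width:
            raise ValueError(
                f"expected {self.input_width} feature columns, got "
                f"{X.shape[1] if X.ndim == 2 else 'non-2D input'}"
            )
        return X

    def _unit_matrix(self, layer: _Layer, X_in: np.ndarray) -> np.ndarray:
        return np.column_stack([u.predict(X_in) for u in layer.units])

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Propagate X through all layers; mean of final-layer unit outputs."""
        X = self._check_width(X)
        cur = X
        for k, layer in enumerate(self.layers):
            preds = self._unit_matrix(layer, cur)
            if k + 1 == self.depth:
                return preds.mean(axis=1)
            cur = np.hstack([X, preds])
        raise RuntimeError("unfitted model")

    def layer_predict(self, layer_index: int, X: np.ndarray) -> np.ndarray:
        """Per-unit predictions (m×U) of one layer, 1-based index.

        ``X`` must match that layer's input width: d for layer 1, d+U after.
        """
        if not 1 <= layer_index <= self.depth:
            raise IndexError(
                f"layer_index {layer_index} outside 1..{self.depth}"
            )
        layer = self.layers[layer_index - 1]
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != layer.input_width:
            raise ValueError(
                f"layer {layer_index} expects {layer.input_width} columns, "
                f"got {X.shape[1] if X.ndim == 2 else 'non-2D input'}"
            )
        return self._unit_matrix(layer, X)

    def feature_importance(self, n_features: int | None = None) -> np.ndarray:
        """Mean impurity importance of the final layer's units, truncated to
        the first ``n_features`` columns (default: the original input width,
        dropping augmentation columns) and renormalized to sum 1."""
        if not self.layers:
            raise RuntimeError("unfitted model")
        n_features = self.input_width if n_features is None else int(n_features)
        if not 1 <= n_features <= self.layers[-1].input_width:
            raise ValueError("n_features outside the final layer's width")
        imps = np.mean(
            [u.feature_importances_ for u in self.layers[-1].units], axis=0
        )
        head = imps[:n_features]
        total = head.sum()
        if total <= 0:  # all signal in augmentation columns — uniform fallback
            return np.full(n_features, 1.0 / n_features)
        return head / total


def fit_cascade(
    X: np.ndarray, y: np.ndarray, config: CascadeConfig | None = None
) -> CascadeForestModel:
    """Fit a cascade forest with internal-CV-gated adaptive depth.

    Layer 1 trains on X; each later layer on [X | previous OOF augmentation].
    A candidate layer must beat the best retained internal-CV score by more
    than ``growth_tolerance`` or it is discarded and growth stops.
    """
    config = config or CascadeConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D with one row per y entry")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    n = X.shape[0]
    if n < config.cv_folds:
        raise ValueError(f"n={n} smaller than cv_folds={config.cv_folds}")

    model = CascadeForestModel(config=config, input_width=X.shape[1])
    best = -np.inf
    aug: np.ndarray | None = None

    for ell in range(1, config.max_layers + 1):
        X_in = X if ell == 1 else np.hstack([X, aug])
        kf = KFold(
            n_splits=config.cv_folds,
            shuffle=True,
            random_state=derive_seed(config.seed, "folds", ell),
        )
        fold_splits = list(kf.split(X_in))
        oof = np.empty((n, config.n_units))
        fitted = []
        for u, kind in enumerate(config.units_per_layer):
            for f, (tr, te) in enumerate(fold_splits):
                est = make_forest_unit(
                    kind,
                    config.trees_per_unit,
                    derive_seed(config.seed, "cv", ell, u, f),
                )
                est.fit(X_in[tr], y[tr])
                oof[te, u] = est.predict(X_in[te])
            full = make_forest_unit(
                kind, config.trees_per_unit, derive_seed(config.seed, "full", ell, u)
            )
            full.fit(X_in, y)
            fitted.append(full)

        score = _layer_score(y, oof.mean(axis=1), config.growth_metric)
        if ell > 1 and score <= best + config.growth_tolerance:
            log.debug("layer %d discarded (score %.5f <= best %.5f)", ell, score, best)
            break
        model.layers.append(_Layer(units=fitted, input_width=X_in.shape[1]))
        model.growth_trace.append(score)
        best = score
        aug = oof

    return model
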