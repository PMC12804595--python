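"""Regression metrics (RMSE, R²) and the repeated cross-validation harness."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import EndpointDataset, MultiTaskCollection
from .seeds import derive_seed

log = logging.getLogger("toxcascade.evaluation")


def _check_pair(y_true, y_pred) -> tuple[np.ndarray, np.ndarray]:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be 1-D of equal length")
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    if not (np.isfinite(y_true).all() and np.isfinite(y_pred).all()):
        raise ValueError("non-finite values in labels or predictions")
    return y_true, y_pred


def rmse(y_true, y_pred) -> float:
    """Root mean square error: sqrt(mean((ŷ − y)²))."""
    y_true, y_pred = _check_pair(y_true, y_pred)
    return float(np.sqrt(np.mean((y_pred - y_true) ** 2)))


def r_squared(y_true, y_pred, baseline_mean: float | None = None) -> float:
    """Coefficient of determination 1 − Σ(ŷ−y)² / Σ(y−ȳ)².

    ``baseline_mean`` is ȳ — by convention the mean label of the *training*
    samples; when omitted it defaults to mean(y_true) (the sklearn
    convention) and the choice is logged.  Can be negative for very poor
    predictions; raises on a degenerate (zero-variance) reference.
    """
    y_true, y_pred = _check_pair(y_true, y_pred)
    if baseline_mean is None:
        baseline_mean = float(y_true.mean())
        log.debug("r_squared: defaulting baseline_mean to mean(y_true)")
    ss_tot = float(np.sum((y_true - baseline_mean) ** 2))
    if ss_tot == 0.0:
        raise ValueError("degenerate target: zero total sum of squares")
    ss_res = float(np.sum((y_pred - y_true) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass
class MetricReport:
    """Scores of one endpoint on one evaluation slice."""

    endpoint_id: int
    n_test: int
    r2: float
    rmse: float
    run: int | None = None
    fold: int | None = None


def repeated_cv(
    collection: MultiTaskCollection,
    trainer,
    runs: int = 10,
    folds: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Repeated k-fold cross-validation over every endpoint.

    Per run, each endpoint's rows are partitioned into ``folds`` folds under
    a run-specific seed; each fold serves once as the test set while the
    remaining rows are re-split 3:1 into train:valid, reconstructing the
    60/20/20 geometry inside each fold.  ``trainer(collection, seed)`` must
    return a model exposing ``predict(endpoint_id, X) -> vector``.

    Returns ``(long, summary)``: a long-format table with one row per
    (run, fold, endpoint) and the per-endpoint means over runs×folds.
    Endpoints with fewer rows than ``folds`` are skipped with a warning.
    """
    if runs < 1 or folds < 2:
        raise ValueError("need runs >= 1 and folds >= 2")
    rows = []
    for run in range(runs):
        # per-endpoint fold assignment for this run
        assignment: dict[int, np.ndarray] = {}
        for ep in collection:
            if ep.n < folds:
                log.warning(
                    "endpoint %d has %d rows < %d folds; skipped",
                    ep.meta.endpoint_id, ep.n, folds,
                )
                continue
            rng = np.random.default_rng(
                derive_seed(seed, "cvfold", run, ep.meta.endpoint_id)
            )
            order = rng.permutation(ep.n)
            fold_of = np.empty(ep.n, dtype=int)
            for f in range(folds):
                fold_of[order[f::folds]] = f
            assignment[ep.meta.endpoint_id] = fold_of

        for f in range(folds):
            eps = []
            for ep in collection:
                if ep.meta.endpoint_id not in assignment:
                    continue
                fold_of = assignment[ep.meta.endpoint_id]
                split = np.empty(ep.n, dtype=object)
                split[fold_of == f] = "test"
                rest = np.flatnonzero(fold_of != f)
                rng = np.random.default_rng(
                    derive_seed(seed, "resplit", run, f, ep.meta.endpoint_id)
                )
                rest = rng.permutation(rest)
                n_valid = len(rest) // 4  # 3:1 train:valid
                split[rest[:n_valid]] = "valid"
                split[rest[n_valid:]] = "train"
                eps.append(EndpointDataset(ep.meta, ep.X.copy(), ep.y.copy(), split))
            if not eps:
                continue
            fold_coll = MultiTaskCollection(eps, collection.view_name)
            model = trainer(fold_coll, derive_seed(seed, "trainer", run, f))
            for ep in fold_coll:
                X_test, y_test = ep.subset("test")
                if len(y_test) == 0:
                    continue
                y_hat = model.predict(ep.meta.endpoint_id, X_test)
                y_train = ep.subset("train", "valid")[1]
                rows.append(
                    {
                        "run": run,
                        "fold": f,
                        "endpoint": ep.meta.endpoint_id,
                        "n_test": len(y_test),
                        "r2": r_squared(y_test, y_hat, float(y_train.mean())),
                        "rmse": rmse(y_test, y_hat),
                    }
                )
    long = pd.DataFrame(rows)
    if long.empty:
        raise ValueError("no endpoint was large enough to cross-validate")
    summary = long.groupby("endpoint")[["r2", "rmse"]].mean().reset_index()
    return long, summary
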