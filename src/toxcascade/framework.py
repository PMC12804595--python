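"""End-to-end multi-task cascade-forest framework.

Training runs four stages:

1. pool every endpoint's train+valid rows and fit the source cascade, whose
   first layer becomes the source model;
2. enhance every endpoint's features with the source model's U-dimensional
   prediction vector (d → d+U);
3. build the covariance-distance matrix between endpoints on raw features;
2b. (default) pooled training rows receive out-of-fold source predictions
   so the enhancement carries no memorized-label leakage;
4. per endpoint: fit a baseline cascade on its own enhanced training rows,
   then greedily pull in the nearest neighbor endpoints' train+valid rows —
   a candidate is kept only if the endpoint's own validation R² strictly
   improves — and finally retrain on the accepted pool plus the endpoint's
   validation rows.

Test rows never enter any training pool; every fit records row-level
bookkeeping so this can be audited.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cascade_forest import CascadeConfig, CascadeForestModel, fit_cascade
from .data_model import MultiTaskCollection
from .evaluation import r_squared, rmse
from .seeds import derive_seed
from .task_distance import DistanceMatrix, build_distance_matrix, rank_neighbors
from .transfer import (
    SourceModel,
    aggregate_training_data,
    enhance_collection,
    enhance_features,
    fit_source_model,
)

log = logging.getLogger("toxcascade.framework")


@dataclass(frozen=True)
class FrameworkConfig:
    """Framework options on top of the cascade hyperparameters.

    ``patience`` is the number of consecutive rejected candidates tolerated
    before the greedy search halts (0 = stop at the first failure).
    Endpoints with fewer than ``min_valid_rows`` validation rows skip the
    greedy stage — the validation score would be too noisy to gate on.
    """

    cascade: CascadeConfig = field(default_factory=CascadeConfig)
    patience: int = 0
    min_valid_rows: int = 5
    # enhance pooled training rows with out-of-fold source predictions;
    # in-sample enhancement (False) leaks memorized labels into training
    # rows and measurably degrades test generalization
    source_oof: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience < 0:
            raise ValueError("patience must be >= 0")
        if self.min_valid_rows < 1:
            raise ValueError("min_valid_rows must be >= 1")


@dataclass
class GreedySearchResult:
    """Trace of the greedy neighbor search for one endpoint."""

    endpoint_id: int
    baseline_valid_score: float
    candidate_order: list[int]
    accepted_ids: list[int] = field(default_factory=list)
    #: (candidate_id, valid_score, accepted)
    trajectory: list[tuple[int, float, bool]] = field(default_factory=list)
    #: endpoint_id -> number of training rows contributed to the best pool
    best_train_composition: dict[int, int] = field(default_factory=dict)
    skipped: bool = False


def _cascade_cfg(config: FrameworkConfig, *tokens) -> CascadeConfig:
    """Cascade config with a seed derived from the framework seed."""
    import dataclasses

    return dataclasses.replace(
        config.cascade, seed=derive_seed(config.seed, *tokens)
    )


def _pool_arrays(enhanced: MultiTaskCollection, pool: list[tuple[int, np.ndarray]]):
    Xs = [enhanced[eid].X[idx] for eid, idx in pool]
    ys = [enhanced[eid].y[idx] for eid, idx in pool]
    return np.vstack(Xs), np.concatenate(ys)


def fit_endpoint_greedy(
    endpoint_id: int,
    enhanced: MultiTaskCollection,
    distances: DistanceMatrix,
    config: FrameworkConfig,
) -> tuple[CascadeForestModel, GreedySearchResult]:
    """Baseline fit plus greedy incorporation of neighbor endpoints.

    The baseline cascade trains on the endpoint's own enhanced train rows and
    is scored by R² on its validation rows.  Candidates are visited in
    ascending covariance distance; each refit adds the candidate's train+valid
    rows to the pool and is accepted only if the validation R² strictly
    exceeds the previous best.  Rejections beyond ``patience`` in a row stop
    the search.  Returns the model fitted on the accepted pool.
    """
    ep = enhanced[endpoint_id]
    X_valid, y_valid = ep.subset("valid")
    if len(y_valid) == 0:
        raise ValueError(
            f"endpoint {endpoint_id}: cannot score greedy steps (empty valid set)"
        )
    own_train = ep.indices("train")
    pool: list[tuple[int, np.ndarray]] = [(endpoint_id, own_train)]

    X0, y0 = _pool_arrays(enhanced, pool)
    model = fit_cascade(X0, y0, _cascade_cfg(config, "ep", endpoint_id, 0))
    best = r_squared(y_valid, model.predict(X_valid))

    result = GreedySearchResult(
        endpoint_id=endpoint_id,
        baseline_valid_score=best,
        candidate_order=rank_neighbors(distances, endpoint_id),
    )
    if len(y_valid) < config.min_valid_rows:
        log.info(
            "endpoint %d: %d validation rows < min_valid_rows=%d; "
            "greedy stage skipped",
            endpoint_id, len(y_valid), config.min_valid_rows,
        )
        result.skipped = True
        result.best_train_composition = {endpoint_id: len(own_train)}
        return model, result

    rejections = 0
    for step, cand in enumerate(result.candidate_order, start=1):
        cand_idx = enhanced[cand].indices("train", "valid")
        trial_pool = pool + [(cand, cand_idx)]
        Xp, yp = _pool_arrays(enhanced, trial_pool)
        trial = fit_cascade(Xp, yp, _cascade_cfg(config, "ep", endpoint_id, step))
        score = r_squared(y_valid, trial.predict(X_valid))
        accepted = score > best
        result.trajectory.append((cand, score, accepted))
        if accepted:
            pool = trial_pool
            model = trial
            best = score
            result.accepted_ids.append(cand)
            rejections = 0
        else:
            rejections += 1
            if rejections > config.patience:
                break

    result.best_train_composition = {eid: len(idx) for eid, idx in pool}
    result._pool = pool  # row-level bookkeeping for finalize/audit
    return model, result


def finalize_endpoint_model(
    endpoint_id: int,
    result: GreedySearchResult,
    enhanced: MultiTaskCollection,
    config: FrameworkConfig,
) -> tuple[CascadeForestModel, list[tuple[int, np.ndarray]]]:
    """Retrain on the accepted pool plus the endpoint's own validation rows
    (re-included to minimize information loss).  Test rows never enter."""
    pool = list(getattr(result, "_pool", [(endpoint_id, enhanced[endpoint_id].indices("train"))]))
    pool.append((endpoint_id, enhanced[endpoint_id].indices("valid")))
    for eid, idx in pool:
        test_idx = set(enhanced[eid].indices("test").tolist())
        if test_idx & set(np.asarray(idx).tolist()):
            raise RuntimeError(
                f"bookkeeping violation: test rows of endpoint {eid} in pool"
            )
    Xf, yf = _pool_arrays(enhanced, pool)
    model = fit_cascade(Xf, yf, _cascade_cfg(config, "ep", endpoint_id, "final"))
    return model, pool


@dataclass
class MultiTaskCascadeForest:
    """Fitted framework: source model, distances, one cascade per endpoint."""

    config: FrameworkConfig
    source: SourceModel
    distances: DistanceMatrix
    models: dict[int, CascadeForestModel]
    results: dict[int, GreedySearchResult]
    #: endpoint_id -> final training pool [(endpoint_id, row indices), ...]
    training_pools: dict[int, list[tuple[int, np.ndarray]]]
    raw_width: int

    def predict(self, endpoint_id: int, X_raw: np.ndarray) -> np.ndarray:
        """Enhance raw-width features with the source model, then predict
        with the endpoint's cascade."""
        if endpoint_id not in self.models:
            raise KeyError(f"unknown endpoint {endpoint_id}")
        X_raw = np.asarray(X_raw, dtype=float)
        if X_raw.ndim != 2 or X_raw.shape[1] != self.raw_width:
            raise ValueError(
                f"expected raw width {self.raw_width}, got "
                f"{X_raw.shape[1] if X_raw.ndim == 2 else 'non-2D input'}"
            )
        return self.models[endpoint_id].predict(enhance_features(self.source, X_raw))

    def evaluate(
        self, collection: MultiTaskCollection
    ) -> tuple[list[dict], dict[str, float]]:
        """Per-endpoint test scores and their unweighted means.

        R² uses the endpoint's own train+valid label mean as the baseline
        (the training-mean convention).  Endpoints with an empty test set are
        skipped with a warning and excluded from the means.
        """
        reports = []
        for ep in collection:
            X_test, y_test = ep.subset("test")
            if len(y_test) == 0:
                log.warning(
                    "endpoint %d has no test rows; excluded from averages",
                    ep.meta.endpoint_id,
                )
                continue
            y_hat = self.predict(ep.meta.endpoint_id, X_test)
            y_train = ep.subset("train", "valid")[1]
            reports.append(
                {
                    "endpoint_id": ep.meta.endpoint_id,
                    "n_test": len(y_test),
                    "r2": r_squared(y_test, y_hat, float(y_train.mean())),
                    "rmse": rmse(y_test, y_hat),
                }
            )
        if not reports:
            raise ValueError("no endpoint had test rows")
        avg = {
            "r2": float(np.mean([r["r2"] for r in reports])),
            "rmse": float(np.mean([r["rmse"] for r in reports])),
        }
        return reports, avg

    def feature_importance(self, endpoint_id: int) -> np.ndarray:
        """Importance over the raw feature space (source-enhancement and
        cascade-augmentation columns dropped, renormalized to sum 1)."""
        return self.models[endpoint_id].feature_importance(n_features=self.raw_width)


def fit(collection: MultiTaskCollection, config: FrameworkConfig | None = None) -> MultiTaskCascadeForest:
    """Train the full framework on a split collection (see module docstring)."""
    config = config or FrameworkConfig()
    for ep in collection:
        if not ep.is_split:
            raise ValueError(f"endpoint {ep.meta.endpoint_id} is not split")

    log.info("aggregating %d endpoints for the source model", collection.T)
    X_pool, y_pool, row_ids = aggregate_training_data(collection)
    source = fit_source_model(
        X_pool,
        y_pool,
        _cascade_cfg(config, "source"),
        row_ids=row_ids,
        keep_oof=config.source_oof,
    )
    enhanced = enhance_collection(source, collection, use_oof=config.source_oof)
    distances = build_distance_matrix(collection, use_rows="trainvalid")

    models: dict[int, CascadeForestModel] = {}
    results: dict[int, GreedySearchResult] = {}
    pools: dict[int, list[tuple[int, np.ndarray]]] = {}
    for eid in collection.endpoint_ids:
        try:
            greedy_model, result = fit_endpoint_greedy(eid, enhanced, distances, config)
            final_model, pool = finalize_endpoint_model(eid, result, enhanced, config)
        except Exception as exc:
            raise RuntimeError(f"endpoint {eid}: {exc}") from exc
        # no-harm invariant: accepted steps never fall below the baseline
        scores = [s for _, s, acc in result.trajectory if acc]
        if any(
            b >= a
            for b, a in zip(
                [result.baseline_valid_score] + scores, scores
            )
        ):
            raise RuntimeError(
                f"endpoint {eid}: accepted validation scores are not increasing"
            )
        models[eid] = final_model
        results[eid] = result
        pools[eid] = pool
        log.info(
            "endpoint %d: baseline R2=%.3f, accepted neighbors %s",
            eid, result.baseline_valid_score, result.accepted_ids,
        )

    model = MultiTaskCascadeForest(
        config=config,
        source=source,
        distances=distances,
        models=models,
        results=results,
        training_pools=pools,
        raw_width=collection.d,
    )
    leakage_audit(model, collection)
    return model


def leakage_audit(
    model: MultiTaskCascadeForest, collection: MultiTaskCollection
) -> bool:
    """Verify that no endpoint's test rows appear in any training pool
    (including the source-model pool).  Raises on violation."""
    test_rows = {
        ep.meta.endpoint_id: set(ep.indices("test").tolist()) for ep in collection
    }
    # the source pool is train+valid by construction; re-derive and check
    _, _, src_ids = aggregate_training_data(collection)
    for eid, ridx in src_ids:
        if ridx in test_rows.get(eid, ()):
            raise RuntimeError(f"source pool contains a test row of endpoint {eid}")
    for owner, pool in model.training_pools.items():
        for eid, idx in pool:
            hit = set(np.asarray(idx).tolist()) & test_rows.get(eid, set())
            if hit:
                raise RuntimeError(
                    f"training pool of endpoint {owner} contains test rows "
                    f"{sorted(hit)} of endpoint {eid}"
                )
    return True
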