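"""Knowledge transfer: data aggregation, source model, feature enhancement.

The first transfer mechanism pools every endpoint's train+valid rows into one
source-domain training set; a cascade forest fitted on that pool carries the
shared knowledge, and its *first layer* (U forest units on the raw width-d
features) is extracted as the source model.  The second mechanism — feature
enhancement by layer transfer — appends the source model's U-dimensional
prediction vector to every sample, widening the feature space from d to d+U
(d+4 with the default configuration).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cascade_forest import CascadeConfig, fit_cascade
from .data_model import MultiTaskCollection

log = logging.getLogger("toxcascade.transfer")


@dataclass
class SourceModel:
    """First cascade layer trained on the aggregated multi-task pool."""

    units: list
    input_width: int
    provenance: dict[int, int]  # endpoint_id -> rows contributed
    seed: int
    # OOF predictions for the rows that trained the source, keyed by
    # (endpoint_id, local_row_index); empty unless requested at fit time
    oof_by_row: dict[tuple[int, int], np.ndarray] | None = None

    @property
    def n_units(self) -> int:
        return len(self.units)

    def predict_units(self, X: np.ndarray) -> np.ndarray:
        """n×U matrix of per-unit source predictions."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.input_width:
            raise ValueError(
                f"source model expects {self.input_width} columns, got "
                f"{X.shape[1] if X.ndim == 2 else 'non-2D input'}"
            )
        return np.column_stack([u.predict(X) for u in self.units])


def aggregate_training_data(
    collection: MultiTaskCollection,
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Row-wise union of every endpoint's train+valid rows (test excluded).

    Returns (X, y, row_ids) where row_ids[k] = (endpoint_id, local_row_index)
    for bookkeeping; endpoints appear in collection order, rows in input
    order.  Compounds measured in several endpoints stay as separate rows
    (the pool is a multiset over measurements).
    """
    Xs, ys, ids = [], [], []
    for ep in collection:
        if not ep.is_split:
            raise ValueError(f"endpoint {ep.meta.endpoint_id} is not split")
        idx = ep.indices("train", "valid")
        Xs.append(ep.X[idx])
        ys.append(ep.y[idx])
        ids.extend((ep.meta.endpoint_id, int(i)) for i in idx)
    return np.vstack(Xs), np.concatenate(ys), ids


def fit_source_model(
    X: np.ndarray,
    y: np.ndarray,
    config: CascadeConfig | None = None,
    row_ids: list[tuple[int, int]] | None = None,
    keep_oof: bool = False,
) -> SourceModel:
    """Fit a cascade on the aggregated pool and extract layer 1 as the source.

    The extracted units are the layer-1 units refit on the full pool, so
    ``SourceModel.predict_units`` equals the cascade's layer-1 prediction.
    With ``keep_oof`` the layer-1 out-of-fold predictions are retained per
    pooled row for leakage-sensitive enhancement.
    """
    config = config or CascadeConfig()
    provenance: dict[int, int] = {}
    if row_ids is not None:
        for eid, _ in row_ids:
            provenance[eid] = provenance.get(eid, 0) + 1

    cascade = fit_cascade(X, y, config)
    src = SourceModel(
        units=cascade.layers[0].units,
        input_width=cascade.input_width,
        provenance=provenance,
        seed=config.seed,
    )
    if keep_oof:
        if row_ids is None:
            raise ValueError("keep_oof requires row_ids")
        # recompute layer-1 OOF with the same folds/seeds used in fit_cascade
        from sklearn.model_selection import KFold

        from .cascade_forest import make_forest_unit
        from .seeds import derive_seed

        kf = KFold(
            n_splits=config.cv_folds,
            shuffle=True,
            random_state=derive_seed(config.seed, "folds", 1),
        )
        oof = np.empty((X.shape[0], config.n_units))
        for u, kind in enumerate(config.units_per_layer):
            for f, (tr, te) in enumerate(kf.split(X)):
                est = make_forest_unit(
                    kind, config.trees_per_unit, derive_seed(config.seed, "cv", 1, u, f)
                )
                est.fit(X[tr], y[tr])
                oof[te, u] = est.predict(X[te])
        src.oof_by_row = {rid: oof[k] for k, rid in enumerate(row_ids)}
    return src


def enhance_features(source: SourceModel, X: np.ndarray) -> np.ndarray:
    """[X | source unit predictions]: width grows from d to d+U, and the
    first d columns are bit-identical to X."""
    X = np.asarray(X, dtype=float)
    return np.hstack([X, source.predict_units(X)])


def enhance_collection(
    source: SourceModel,
    collection: MultiTaskCollection,
    use_oof: bool = False,
) -> MultiTaskCollection:
    """Enhance every endpoint's full feature matrix (train, valid and test
    rows alike — endpoint models consume d+U columns, so test rows must be
    enhanced with the same source model).

    With ``use_oof`` rows that trained the source receive their out-of-fold
    source predictions instead of in-sample ones; other rows (test) always
    get direct predictions.
    """
    if collection.d != source.input_width:
        raise ValueError(
            f"collection width {collection.d} != source width {source.input_width}"
        )
    if use_oof and source.oof_by_row is None:
        raise ValueError("source model was fitted without keep_oof")
    new_X = {}
    for ep in collection:
        enhanced = enhance_features(source, ep.X)
        if use_oof:
            for i in range(ep.n):
                key = (ep.meta.endpoint_id, i)
                if key in source.oof_by_row:
                    enhanced[i, source.input_width :] = source.oof_by_row[key]
        new_X[ep.meta.endpoint_id] = enhanced
    return collection.replace_features(new_X, collection.view_name + "+src")
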