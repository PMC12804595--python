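"""Multi-view modeling (concatenation, consensus) and importance analysis.

A *view* is one feature representation (Avalon, AtomPair, Morgan, ...) of
the same compounds; a ViewSet aligns several views row-for-row over the same
endpoints, labels and splits.  Two multi-view strategies are provided:
concatenating the per-view feature blocks into one wide collection, and the
consensus ensemble — averaging the predictions of independently trained
per-view framework models.

For interpretability, per-endpoint (or per-species) feature-importance
vectors are compared by pairwise Euclidean distance: endpoints whose models
attend to similar substructure bits end up close, which is how cross-species
toxicity associations are read off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .data_model import EndpointDataset, EndpointMeta, MultiTaskCollection


@dataclass
class ViewSet:
    """Named collections over the same compounds/endpoints/splits."""

    views: dict[str, MultiTaskCollection]

    def __post_init__(self) -> None:
        if not self.views:
            raise ValueError("empty view set")
        colls = list(self.views.values())
        ref = colls[0]
        for name, coll in self.views.items():
            if coll.endpoint_ids != ref.endpoint_ids:
                raise ValueError(f"view {name!r} disagrees on endpoint ids")
            for ep_ref, ep in zip(ref, coll):
                if ep.n != ep_ref.n:
                    raise ValueError(
                        f"view {name!r}, endpoint {ep.meta.endpoint_id}: "
                        f"row count {ep.n} != {ep_ref.n}"
                    )
                if not np.array_equal(ep.y, ep_ref.y):
                    raise ValueError(
                        f"view {name!r}, endpoint {ep.meta.endpoint_id}: "
                        "labels differ between views"
                    )
                if (ep.split is None) != (ep_ref.split is None) or (
                    ep.split is not None
                    and not np.array_equal(ep.split, ep_ref.split)
                ):
                    raise ValueError(
                        f"view {name!r}, endpoint {ep.meta.endpoint_id}: "
                        "split labels differ between views"
                    )

    @property
    def names(self) -> list[str]:
        return list(self.views)


def concat_views(viewset: ViewSet) -> MultiTaskCollection:
    """Horizontal per-row concatenation of all views, in declared order."""
    colls = list(viewset.views.values())
    eps = []
    for k, ep_ref in enumerate(colls[0]):
        X = np.hstack([coll.endpoints[k].X for coll in colls])
        split = None if ep_ref.split is None else ep_ref.split.copy()
        eps.append(EndpointDataset(ep_ref.meta, X, ep_ref.y.copy(), split))
    return MultiTaskCollection(eps, "+".join(viewset.names))


def consensus_predict(models: list, endpoint_id: int, inputs: list[np.ndarray]) -> np.ndarray:
    """Unweighted mean of per-view model predictions for one endpoint.

    ``models[v]`` must expose ``predict(endpoint_id, X)`` and ``inputs[v]``
    is that view's feature matrix, row-aligned across views.
    """
    if len(models) != len(inputs):
        raise ValueError(
            f"{len(models)} models but {len(inputs)} input matrices"
        )
    if not models:
        raise ValueError("no models")
    preds = [m.predict(endpoint_id, X) for m, X in zip(models, inputs)]
    lengths = {len(p) for p in preds}
    if len(lengths) != 1:
        raise ValueError("views disagree on row count")
    return np.mean(preds, axis=0)


def species_merge(collection: MultiTaskCollection) -> MultiTaskCollection:
    """Pool endpoints by species, treating each species as one endpoint.

    Rows are concatenated across routes and toxicity types in endpoint
    order; labels and split assignments are untouched.  The merged
    endpoint's route/toxtype codes are taken from its largest constituent
    and the names flagged as mixed when constituents disagree.
    """
    by_species: dict[int, list[EndpointDataset]] = {}
    for ep in collection:
        by_species.setdefault(ep.meta.species_code, []).append(ep)
    eps = []
    for new_id, (species, members) in enumerate(sorted(by_species.items()), start=1):
        largest = max(members, key=lambda e: e.n)
        mixed_route = len({e.meta.route_code for e in members}) > 1
        mixed_tox = len({e.meta.toxtype_code for e in members}) > 1
        meta = EndpointMeta(
            endpoint_id=new_id,
            species_code=species,
            route_code=largest.meta.route_code,
            toxtype_code=largest.meta.toxtype_code,
            species_name=largest.meta.species_name,
            route_name="mixed" if mixed_route else largest.meta.route_name,
            toxtype_name="mixed" if mixed_tox else largest.meta.toxtype_name,
        )
        X = np.vstack([e.X for e in members])
        y = np.concatenate([e.y for e in members])
        split = (
            np.concatenate([e.split for e in members])
            if all(e.split is not None for e in members)
            else None
        )
        eps.append(EndpointDataset(meta, X, y, split))
    return MultiTaskCollection(eps, collection.view_name + "+species")


@dataclass
class ImportanceAssociation:
    """Pairwise Euclidean distances between feature-importance vectors."""

    labels: list
    E: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.E, index=self.labels, columns=self.labels)


def importance_association(vectors: dict) -> ImportanceAssociation:
    """Build the label→label Euclidean distance matrix from importance
    vectors of equal length (symmetric, zero diagonal, nonnegative)."""
    labels = list(vectors)
    if not labels:
        raise ValueError("no importance vectors")
    arrs = [np.asarray(vectors[k], dtype=float) for k in labels]
    lengths = {a.shape for a in arrs}
    if len(lengths) != 1:
        raise ValueError(f"importance vectors disagree on length: {lengths}")
    M = np.vstack(arrs)
    E = squareform(pdist(M, metric="euclidean")) if len(labels) > 1 else np.zeros((1, 1))
    return ImportanceAssociation(labels, E)
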