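"""Covariance-distance task similarity between toxicity endpoints.

Each endpoint's feature block X (n×d) is summarized by its sample covariance
matrix CM(X) (d×d, denominator n−1, diagonal = column variances).  The
distance between two endpoints is the mean absolute element-wise difference
of their covariance matrices, taken over all d² entries.  Smaller distance
means more similar feature distributions — the signal used to rank candidate
neighbor endpoints for sample transfer.

Distances are computed on the raw (un-enhanced) features of train+valid
rows: similarity should reflect the chemistry, not source-model outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import MultiTaskCollection


@dataclass
class DistanceMatrix:
    """Symmetric T×T covariance-distance matrix with its endpoint-id order."""

    D: np.ndarray
    endpoint_ids: list[int]

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        T = len(self.endpoint_ids)
        if self.D.shape != (T, T):
            raise ValueError("distance matrix shape does not match id list")

    def row(self, endpoint_id: int) -> np.ndarray:
        return self.D[self.endpoint_ids.index(endpoint_id)]


def covariance_matrix(X: np.ndarray) -> np.ndarray:
    """Sample covariance of the columns of X: entry (i, j) is
    Σₙ (Xᵢₙ−X̄ᵢ)(Xⱼₙ−X̄ⱼ) / (n−1), including the diagonal (variances)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if X.shape[0] < 2:
        raise ValueError("covariance undefined for fewer than 2 rows")
    return np.atleast_2d(np.cov(X, rowvar=False, ddof=1))


def covariance_distance(Xa: np.ndarray, Xb: np.ndarray) -> float:
    """Mean over all d² elements of |CM(Xa) − CM(Xb)|."""
    Xa, Xb = np.asarray(Xa, dtype=float), np.asarray(Xb, dtype=float)
    if Xa.shape[1] != Xb.shape[1]:
        raise ValueError(
            f"feature width mismatch: {Xa.shape[1]} vs {Xb.shape[1]}"
        )
    return float(np.mean(np.abs(covariance_matrix(Xa) - covariance_matrix(Xb))))


def build_distance_matrix(
    collection: MultiTaskCollection, use_rows: str = "trainvalid"
) -> DistanceMatrix:
    """All-pairs covariance distances over each endpoint's selected rows.

    ``use_rows``: "trainvalid" (default), "train", or "all".  Each unordered
    pair is computed once; the result is symmetric, nonnegative, and zero on
    the diagonal.
    """
    if use_rows not in ("trainvalid", "train", "all"):
        raise ValueError("use_rows must be 'trainvalid', 'train', or 'all'")
    blocks = []
    for ep in collection:
        if use_rows == "all":
            X = ep.X
        elif use_rows == "train":
            X = ep.subset("train")[0]
        else:
            X = ep.subset("train", "valid")[0]
        if X.shape[0] < 2:
            raise ValueError(
                f"endpoint {ep.meta.endpoint_id} has fewer than 2 usable rows"
            )
        blocks.append(X)

    cms = [covariance_matrix(X) for X in blocks]
    T = len(cms)
    D = np.zeros((T, T))
    for a in range(T):
        for b in range(a + 1, T):
            D[a, b] = D[b, a] = float(np.mean(np.abs(cms[a] - cms[b])))
    return DistanceMatrix(D, collection.endpoint_ids)


def rank_neighbors(distances: DistanceMatrix, endpoint_id: int) -> list[int]:
    """Endpoint ids sorted by ascending covariance distance from endpoint i,
    self excluded; ties broken by ascending endpoint id.  Length T−1."""
    if endpoint_id not in distances.endpoint_ids:
        raise KeyError(f"unknown endpoint id {endpoint_id}")
    row = distances.row(endpoint_id)
    pairs = [
        (row[k], eid)
        for k, eid in enumerate(distances.endpoint_ids)
        if eid != endpoint_id
    ]
    pairs.sort(key=lambda t: (t[0], t[1]))
    return [eid for _, eid in pairs]


def write_distance_tsv(distances: DistanceMatrix, path) -> None:
    """Write a labeled T×T TSV (header + index column of endpoint ids)."""
    import pandas as pd

    pd.DataFrame(
        distances.D, index=distances.endpoint_ids, columns=distances.endpoint_ids
    ).to_csv(path, sep="\t", index_label="endpoint_id")
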