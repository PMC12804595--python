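"""Domain types for multi-task toxicity data, splitting, and model IO.

A *toxicity endpoint* is one (species, administration route, toxicity type)
triple — e.g. "mouse / oral / LD50" — and defines one regression task with
its own compounds, continuous toxicity labels, and train/valid/test split.
A collection bundles the T endpoints that share one feature space.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import joblib
import numpy as np
import pandas as pd

SPLIT_LABELS = ("train", "valid", "test")

#: on-disk model archive format; bumped on incompatible layout changes
MODEL_FORMAT_VERSION = 1

N_SPECIES = 15
N_ROUTES = 8
N_TOXTYPES = 3


@dataclass(frozen=True)
class EndpointMeta:
    """Identity of one toxicity endpoint.

    The three integer codes double as the endpoint's prior-knowledge
    vector (x, y, z): species in 1..15, administration route in 1..8,
    toxicity type (LD50 / LDLo / TDLo) in 1..3.
    """

    endpoint_id: int
    species_code: int
    route_code: int
    toxtype_code: int
    species_name: str = ""
    route_name: str = ""
    toxtype_name: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.species_code <= N_SPECIES:
            raise ValueError(
                f"species_code {self.species_code} outside 1..{N_SPECIES}"
            )
        if not 1 <= self.route_code <= N_ROUTES:
            raise ValueError(f"route_code {self.route_code} outside 1..{N_ROUTES}")
        if not 1 <= self.toxtype_code <= N_TOXTYPES:
            raise ValueError(
                f"toxtype_code {self.toxtype_code} outside 1..{N_TOXTYPES}"
            )


@dataclass
class EndpointDataset:
    """One endpoint's feature matrix, labels, and split assignment."""

    meta: EndpointMeta
    X: np.ndarray
    y: np.ndarray
    split: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError(
                f"endpoint {self.meta.endpoint_id}: X has {self.X.shape[0]} rows "
                f"but y has {self.y.shape[0]}"
            )
        if self.n == 0:
            raise ValueError(f"endpoint {self.meta.endpoint_id} is empty")
        if self.split is not None:
            self.split = np.asarray(self.split, dtype=object)
            if self.split.shape[0] != self.n:
                raise ValueError("split length must match number of rows")
            bad = set(self.split) - set(SPLIT_LABELS)
            if bad:
                raise ValueError(f"unknown split labels: {sorted(bad)}")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    @property
    def is_split(self) -> bool:
        return self.split is not None

    def mask(self, *labels: str) -> np.ndarray:
        if self.split is None:
            raise ValueError(
                f"endpoint {self.meta.endpoint_id} has no split assignment"
            )
        return np.isin(self.split, labels)

    def indices(self, *labels: str) -> np.ndarray:
        """Local row indices belonging to the given split labels."""
        return np.flatnonzero(self.mask(*labels))

    def subset(self, *labels: str) -> tuple[np.ndarray, np.ndarray]:
        m = self.mask(*labels)
        return self.X[m], self.y[m]


@dataclass
class MultiTaskCollection:
    """Ordered set of endpoints sharing one feature space of width d."""

    endpoints: list[EndpointDataset]
    view_name: str = "unnamed"

    def __post_init__(self) -> None:
        if not self.endpoints:
            raise ValueError("no endpoints")
        widths = {ep.d for ep in self.endpoints}
        if len(widths) > 1:
            raise ValueError(f"endpoints disagree on feature width: {sorted(widths)}")
        ids = [ep.meta.endpoint_id for ep in self.endpoints]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate endpoint ids")

    @property
    def T(self) -> int:
        return len(self.endpoints)

    @property
    def d(self) -> int:
        return self.endpoints[0].d

    @property
    def endpoint_ids(self) -> list[int]:
        return [ep.meta.endpoint_id for ep in self.endpoints]

    def __iter__(self):
        return iter(self.endpoints)

    def __getitem__(self, endpoint_id: int) -> EndpointDataset:
        for ep in self.endpoints:
            if ep.meta.endpoint_id == endpoint_id:
                return ep
        raise KeyError(f"unknown endpoint id {endpoint_id}")

    def replace_features(
        self, new_X: Mapping[int, np.ndarray], view_name: str | None = None
    ) -> "MultiTaskCollection":
        """Return a copy with each endpoint's X swapped (labels/splits kept)."""
        eps = []
        for ep in self.endpoints:
            X = np.asarray(new_X[ep.meta.endpoint_id], dtype=float)
            if X.shape[0] != ep.n:
                raise ValueError(
                    f"endpoint {ep.meta.endpoint_id}: replacement has "
                    f"{X.shape[0]} rows, expected {ep.n}"
                )
            split = None if ep.split is None else ep.split.copy()
            eps.append(EndpointDataset(ep.meta, X, ep.y.copy(), split))
        return MultiTaskCollection(eps, view_name or self.view_name)


# ---------------------------------------------------------------------------
# loading


def load_collection(
    records: pd.DataFrame,
    meta: pd.DataFrame,
    features: Mapping[str, np.ndarray],
    view_name: str = "unnamed",
) -> MultiTaskCollection:
    """Assemble a collection from a records table, a metadata table, and a
    compound→feature-vector map.

    ``records`` needs columns ``smiles`` (or any compound key), ``endpoint_id``
    and ``value``; ``meta`` needs ``endpoint_id,species,route,toxtype`` plus
    optional ``*_name`` columns.  Rows are grouped by endpoint in input order.
    Duplicate compound–endpoint measurements are kept as-is.
    """
    if len(records) == 0:
        raise ValueError("no endpoints: records table is empty")
    meta_by_id: dict[int, EndpointMeta] = {}
    for _, row in meta.iterrows():
        em = EndpointMeta(
            endpoint_id=int(row["endpoint_id"]),
            species_code=int(row["species"]),
            route_code=int(row["route"]),
            toxtype_code=int(row["toxtype"]),
            species_name=str(row.get("species_name", "")),
            route_name=str(row.get("route_name", "")),
            toxtype_name=str(row.get("toxtype_name", "")),
        )
        meta_by_id[em.endpoint_id] = em

    key_col = "smiles" if "smiles" in records.columns else records.columns[0]
    widths = {np.asarray(v).shape[-1] for v in features.values()}
    if len(widths) > 1:
        raise ValueError(f"feature vectors disagree on width: {sorted(widths)}")

    endpoints = []
    for eid, grp in records.groupby("endpoint_id", sort=True):
        eid = int(eid)
        if eid not in meta_by_id:
            raise KeyError(f"records reference unknown endpoint_id {eid}")
        rows = []
        for key in grp[key_col]:
            if key not in features:
                raise KeyError(f"no feature vector for compound {key!r}")
            rows.append(np.asarray(features[key], dtype=float))
        X = np.vstack(rows)
        y = grp["value"].to_numpy(dtype=float)
        endpoints.append(EndpointDataset(meta_by_id[eid], X, y))
    return MultiTaskCollection(endpoints, view_name)


# ---------------------------------------------------------------------------
# splitting


def split_endpoint(
    ds: EndpointDataset,
    proportions: Sequence[float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> EndpointDataset:
    """Assign train/valid/test labels by a seeded uniform permutation.

    Block sizes are floored; the remainder goes to train so tiny endpoints
    stay trainable.  Default proportions are 60/20/20.
    """
    if len(proportions) != 3 or not np.isclose(sum(proportions), 1.0):
        raise ValueError("proportions must be three values summing to 1")
    n = ds.n
    if n < 3:
        raise ValueError(
            f"endpoint {ds.meta.endpoint_id} too small to split (n={n} < 3)"
        )
    n_valid = int(np.floor(n * proportions[1]))
    n_test = int(np.floor(n * proportions[2]))
    n_train = n - n_valid - n_test
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    split = np.empty(n, dtype=object)
    split[order[:n_train]] = "train"
    split[order[n_train : n_train + n_valid]] = "valid"
    split[order[n_train + n_valid :]] = "test"
    return EndpointDataset(ds.meta, ds.X.copy(), ds.y.copy(), split)


def split_collection(
    collection: MultiTaskCollection,
    proportions: Sequence[float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> MultiTaskCollection:
    """Split every endpoint, deriving a per-endpoint seed from ``seed``."""
    from .seeds import derive_seed

    eps = [
        split_endpoint(ep, proportions, derive_seed(seed, "split", ep.meta.endpoint_id))
        for ep in collection
    ]
    return MultiTaskCollection(eps, collection.view_name)


# ---------------------------------------------------------------------------
# collection directory IO (plain TSV)


def write_collection_dir(collection: MultiTaskCollection, path) -> None:
    """Write a collection as a directory of TSV files: ``meta.tsv`` plus one
    ``endpoint_<id>.tsv`` per endpoint (columns: split, y, f0..f{d-1})."""
    import pathlib

    path = pathlib.Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta_rows = []
    for ep in collection.endpoints:
        m = ep.meta
        meta_rows.append(
            {
                "endpoint_id": m.endpoint_id,
                "species": m.species_code,
                "route": m.route_code,
                "toxtype": m.toxtype_code,
                "species_name": m.species_name,
                "route_name": m.route_name,
                "toxtype_name": m.toxtype_name,
            }
        )
        df = pd.DataFrame(ep.X, columns=[f"f{j}" for j in range(ep.d)])
        df.insert(0, "y", ep.y)
        df.insert(0, "split", ep.split if ep.split is not None else "")
        df.to_csv(path / f"endpoint_{m.endpoint_id}.tsv", sep="\t", index=False)
    pd.DataFrame(meta_rows).to_csv(path / "meta.tsv", sep="\t", index=False)
    (path / "view.txt").write_text(collection.view_name + "\n")


def read_collection_dir(path) -> MultiTaskCollection:
    """Read a collection written by :func:`write_collection_dir`."""
    import pathlib

    path = pathlib.Path(path)
    meta = pd.read_csv(path / "meta.tsv", sep="\t").fillna("")
    view_file = path / "view.txt"
    view_name = view_file.read_text().strip() if view_file.exists() else "unnamed"
    endpoints = []
    for _, row in meta.iterrows():
        em = EndpointMeta(
            endpoint_id=int(row["endpoint_id"]),
            species_code=int(row["species"]),
            route_code=int(row["route"]),
            toxtype_code=int(row["toxtype"]),
            species_name=str(row.get("species_name", "")),
            route_name=str(row.get("route_name", "")),
            toxtype_name=str(row.get("toxtype_name", "")),
        )
        df = pd.read_csv(path / f"endpoint_{em.endpoint_id}.tsv", sep="\t")
        feat_cols = [c for c in df.columns if c.startswith("f")]
        split = None
        if df["split"].notna().all() and (df["split"].astype(str) != "").all():
            split = df["split"].to_numpy(dtype=object)
        endpoints.append(
            EndpointDataset(
                em, df[feat_cols].to_numpy(float), df["y"].to_numpy(float), split
            )
        )
    return MultiTaskCollection(endpoints, view_name)


# ---------------------------------------------------------------------------
# persistence


def save_model(obj, path) -> None:
    """Persist any fitted framework object to a single versioned archive."""
    joblib.dump({"format_version": MODEL_FORMAT_VERSION, "payload": obj}, path)


def load_model(path):
    """Load an archive written by :func:`save_model`.

    Raises on a missing/corrupt file or a format-version mismatch.
    """
    try:
        blob = joblib.load(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # corrupt archive
        raise ValueError(f"cannot read model archive {path}: {exc}") from exc
    if not isinstance(blob, dict) or "format_version" not in blob:
        raise ValueError(f"{path} is not a toxcascade model archive")
    if blob["format_version"] != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"incompatible model archive version {blob['format_version']} "
            f"(this build reads version {MODEL_FORMAT_VERSION})"
        )
    return blob["payload"]
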