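"""SMILES → fixed-width fingerprint matrices, plus endpoint prior-knowledge.

Three fingerprint views are computed in-repo with RDKit: Avalon and Morgan
(1024-bit Boolean) and AtomPair (1024-bin counts).  Any other representation
(physicochemical descriptors, learned embeddings) enters the pipeline as a
precomputed matrix via :func:`toxcascade.data_model.load_collection`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Avalon import pyAvalonTools
from rdkit.Chem import rdFingerprintGenerator

from .data_model import EndpointMeta, MultiTaskCollection

log = logging.getLogger("toxcascade.featurization")

RDLogger.DisableLog("rdApp.error")  # parse failures are raised, not printed

VIEW_NAMES = ("avalon", "atompair", "morgan")

#: Morgan radius 2 is the conventional ECFP4-equivalent neighbourhood.
MORGAN_RADIUS = 2


@dataclass(frozen=True)
class ViewSpec:
    """One fingerprint view: name, bit width, and value kind."""

    name: str
    width: int = 1024

    def __post_init__(self) -> None:
        if self.name not in VIEW_NAMES:
            raise ValueError(f"unknown view {self.name!r}; choose from {VIEW_NAMES}")
        if self.width < 1:
            raise ValueError("width must be positive")

    @property
    def value_kind(self) -> str:
        """Avalon and Morgan are Boolean; AtomPair is count-valued."""
        return "count" if self.name == "atompair" else "boolean"


def _parse(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return mol


def featurize_smiles(smiles: str, view: ViewSpec) -> np.ndarray:
    """Fingerprint one SMILES string into a length-``view.width`` vector.

    Deterministic; Boolean views yield {0,1}, count views nonnegative ints.
    """
    mol = _parse(smiles)
    out = np.zeros(view.width, dtype=float)
    if view.name == "avalon":
        fp = pyAvalonTools.GetAvalonFP(mol, nBits=view.width)
        out[list(fp.GetOnBits())] = 1.0
    elif view.name == "morgan":
        gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=MORGAN_RADIUS, fpSize=view.width
        )
        out[list(gen.GetFingerprint(mol).GetOnBits())] = 1.0
    else:  # atompair counts, no clipping
        gen = rdFingerprintGenerator.GetAtomPairGenerator(fpSize=view.width)
        for bit, count in gen.GetCountFingerprint(mol).GetNonzeroElements().items():
            out[bit] = float(count)
    return out


def featurize_table(
    smiles_list: list[str], view: ViewSpec, strict: bool = True
) -> tuple[np.ndarray, list[int]]:
    """Fingerprint a list of SMILES into an n×width matrix.

    Returns ``(matrix, dropped_rows)``.  In strict mode any invalid SMILES
    aborts with an error listing the offending rows; in lenient mode bad rows
    are dropped, logged, and reported in ``dropped_rows``.
    """
    if not smiles_list:
        raise ValueError("empty SMILES list")
    rows, bad = [], []
    for k, smi in enumerate(smiles_list):
        try:
            rows.append(featurize_smiles(smi, view))
        except ValueError:
            bad.append(k)
    if bad:
        if strict:
            raise ValueError(
                f"invalid SMILES at rows {bad}: "
                f"{[smiles_list[k] for k in bad]}"
            )
        log.warning("dropped %d unparseable SMILES rows: %s", len(bad), bad)
    if not rows:
        raise ValueError("no valid SMILES remain after dropping bad rows")
    return np.vstack(rows), bad


def append_prior_knowledge(X: np.ndarray, meta: EndpointMeta) -> np.ndarray:
    """Concatenate the endpoint's (species, route, toxtype) code triple to
    every row, widening X from d to d+3.

    The codes are appended as raw integers — tree ensembles are invariant to
    feature scale, so no normalisation is applied.
    """
    X = np.asarray(X, dtype=float)
    pk = np.array(
        [meta.species_code, meta.route_code, meta.toxtype_code], dtype=float
    )
    return np.hstack([X, np.tile(pk, (X.shape[0], 1))])


def append_prior_knowledge_collection(
    collection: MultiTaskCollection,
) -> MultiTaskCollection:
    """Append each endpoint's own prior-knowledge triple to its features."""
    new_X = {
        ep.meta.endpoint_id: append_prior_knowledge(ep.X, ep.meta)
        for ep in collection
    }
    return collection.replace_features(new_X, collection.view_name + "+pk")
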