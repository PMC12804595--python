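"""Synthetic multi-task collections with fingerprint-like structure.

Real acute-toxicity endpoints are tabular regression tasks over sparse
binary fingerprints, with heterogeneous sample sizes and feature
distributions that cluster by chemistry.  The generator emulates exactly
those properties so the whole framework is testable offline:

* tasks are grouped into clusters; each cluster c has its own
  column-activation profile πc (per-feature Bernoulli rates concentrated on
  a cluster-specific block of columns, so covariance distance can separate
  clusters) and a sparse coefficient vector βc;
* task t in cluster c draws rows Xₜ ~ Bernoulli(πc) and labels
  yₜ = Xₜ·(ρ·βc + (1−ρ)·βₜ) + N(0, σ²) with a task-private βₜ, so the
  relatedness knob ρ ∈ [0,1] interpolates between fully shared and fully
  private response signal;
* coefficients are scaled so the noiseless signal has roughly unit standard
  deviation, making σ directly interpretable as a noise-to-signal level.

What it does not emulate: real chemistry (no SMILES), hashed-bit collision
structure, or heavy-tailed label distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import (
    EndpointDataset,
    EndpointMeta,
    MultiTaskCollection,
    N_ROUTES,
    N_SPECIES,
    N_TOXTYPES,
    split_endpoint,
)
from .seeds import derive_seed


@dataclass(frozen=True)
class SynthSpec:
    """Conditions for one synthetic multi-task collection."""

    T: int = 6
    sizes: tuple[int, ...] = (200, 200, 200, 200, 200, 200)
    d: int = 50
    n_clusters: int = 2
    relatedness: float = 0.9  # ρ: 1 = cluster members share coefficients exactly
    feature_sparsity: float = 0.2  # approximate overall fraction of 1-bits
    noise_sd: float = 0.3  # σ, relative to ~unit signal sd
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T < 1 or len(self.sizes) != self.T:
            raise ValueError("sizes must list one n per task")
        if any(n < 3 for n in self.sizes):
            raise ValueError("every task needs n >= 3")
        if self.d < 2:
            raise ValueError("d must be >= 2")
        if not 1 <= self.n_clusters <= self.T:
            raise ValueError("n_clusters must be in 1..T")
        if not 0.0 <= self.relatedness <= 1.0:
            raise ValueError("relatedness must lie in [0, 1]")
        if not 0.0 < self.feature_sparsity < 1.0:
            raise ValueError("feature_sparsity must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _sparse_beta(rng: np.random.Generator, d: int, active: np.ndarray) -> np.ndarray:
    """Sparse coefficients supported on ~8 of the cluster's active columns."""
    k = min(8, len(active))
    beta = np.zeros(d)
    support = rng.choice(active, size=k, replace=False)
    beta[support] = rng.normal(0.0, 1.0, size=k)
    return beta


def generate_collection(spec: SynthSpec, pre_split: bool = True) -> MultiTaskCollection:
    """Draw one collection under ``spec`` (pre-split 60/20/20 by default)."""
    rng = np.random.default_rng(derive_seed(spec.seed, "synth"))
    d, K = spec.d, spec.n_clusters
    # cluster-specific activation profiles on near-disjoint column blocks:
    # in-block rates average K * sparsity (so the overall density stays ~p),
    # out-of-block columns keep a small floor rate
    base_rate = 0.02
    block = np.array_split(np.arange(d), K)
    profiles, betas = [], []
    for c in range(K):
        pi = np.full(d, base_rate)
        in_rate = np.clip(
            rng.uniform(0.5, 1.5, size=len(block[c])) * spec.feature_sparsity * K,
            0.05,
            0.95,
        )
        pi[block[c]] = in_rate
        profiles.append(pi)
        betas.append(_sparse_beta(rng, d, block[c]))

    cluster_of = [t % K for t in range(spec.T)]
    endpoints = []
    for t in range(spec.T):
        c = cluster_of[t]
        task_rng = np.random.default_rng(derive_seed(spec.seed, "task", t))
        beta_private = _sparse_beta(task_rng, d, block[c])
        beta = spec.relatedness * betas[c] + (1 - spec.relatedness) * beta_private
        n = spec.sizes[t]
        X = (task_rng.random((n, d)) < profiles[c]).astype(float)
        signal = X @ beta
        sd = signal.std()
        if sd > 0:
            signal = signal / sd  # ~unit signal sd, so noise_sd is relative
        y = signal + task_rng.normal(0.0, spec.noise_sd, size=n)
        meta = EndpointMeta(
            endpoint_id=t + 1,
            species_code=(c % N_SPECIES) + 1,
            route_code=(t % N_ROUTES) + 1,
            toxtype_code=(t % N_TOXTYPES) + 1,
            species_name=f"synthetic-species-{c + 1}",
            route_name=f"route-{(t % N_ROUTES) + 1}",
            toxtype_name=("LD50", "LDLo", "TDLo")[t % N_TOXTYPES],
        )
        ds = EndpointDataset(meta, X, y)
        if pre_split:
            ds = split_endpoint(ds, seed=derive_seed(spec.seed, "split", t))
        endpoints.append(ds)
    return MultiTaskCollection(endpoints, view_name="synthetic")


def generate_viewset(
    spec: SynthSpec, n_views: int = 3, flip_prob: float = 0.05
) -> dict[str, MultiTaskCollection]:
    """Multiple noisy views of one underlying collection.

    All views share labels and splits; each view independently flips every
    bit of X with probability ``flip_prob``, emulating representations that
    carry the same signal behind independent measurement noise.
    """
    base = generate_collection(spec)
    views = {}
    for v in range(n_views):
        rng = np.random.default_rng(derive_seed(spec.seed, "view", v))
        new_X = {}
        for ep in base:
            flips = rng.random(ep.X.shape) < flip_prob
            new_X[ep.meta.endpoint_id] = np.where(flips, 1.0 - ep.X, ep.X)
        views[f"view{v + 1}"] = base.replace_features(new_X, f"view{v + 1}")
    return views


def worked_example() -> MultiTaskCollection:
    """Tiny fixed two-endpoint collection backing the hand-derived examples.

    Endpoint 1's feature block is X = [[1,2],[3,4],[5,6]] — its column
    covariance is [[4,4],[4,4]] — and endpoint 2's block is all zeros, so
    the covariance distance between them is exactly 4.  Content is identical
    on every call.
    """
    X1 = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
    X2 = np.zeros((3, 2))
    split = np.array(["train", "valid", "test"], dtype=object)
    meta1 = EndpointMeta(1, 1, 1, 1, "example-a", "oral", "LD50")
    meta2 = EndpointMeta(2, 2, 1, 1, "example-b", "oral", "LD50")
    eps = [
        EndpointDataset(meta1, X1, np.array([1.0, 2.0, 3.0]), split.copy()),
        EndpointDataset(meta2, X2, np.array([0.0, 1.0, 0.0]), split.copy()),
    ]
    return MultiTaskCollection(eps, view_name="worked-example")
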