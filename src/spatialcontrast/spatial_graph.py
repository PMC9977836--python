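"""Spot neighborhood graphs: k-NN construction, symmetric normalization,
the feature-shuffled corruption view, and joint graphs across slices.

The adjacency is the symmetric OR of the directed k-nearest-neighbor
relation (ties broken toward the smaller spot index), and the normalized
operator is D^(-1/2) (A + I) D^(-1/2) with self-loops on by default so each
spot keeps its own signal during aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import cdist

from .preprocess import FeatureMatrix, SpatialDataset


@dataclass
class NeighborGraph:
    """Binary symmetric spot adjacency with per-spot neighbor sets."""

    adjacency: sp.csr_matrix  # symmetric, zero diagonal
    neighbor_sets: list[np.ndarray]  # N_i, self excluded
    k: int
    coords: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class NormalizedAdjacency:
    """D^(-1/2) (A [+ I]) D^(-1/2), symmetric with spectrum in [-1, 1]."""

    matrix: sp.csr_matrix
    self_loops: bool


def build_knn_graph(coords: np.ndarray, k: int = 3) -> NeighborGraph:
    """Symmetric k-NN graph on Euclidean distance.

    Each spot points at its ``k`` nearest *other* spots; when several
    candidates are tied at the k-th smallest distance, *all* of them are
    included (tie-inclusive selection is deterministic, invariant to spot
    storage order, and keeps co-located spots — e.g. overlaid serial
    sections — exactly exchangeable). The undirected adjacency is the OR of
    the directed relation, so spots can end up with more than ``k``
    neighbors. Duplicate coordinates are allowed (distance 0 sorts first).
    """
    coords = np.asarray(coords, dtype=np.float64)
    n = coords.shape[0]
    if not np.all(np.isfinite(coords)):
        raise ValueError("coords must be finite")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError(f"k={k} must be < number of spots ({n})")

    dist = cdist(coords, coords)
    np.fill_diagonal(dist, np.inf)
    kth = np.partition(dist, k - 1, axis=1)[:, k - 1]
    directed = sp.csr_matrix(dist <= kth[:, None], dtype=np.float64)
    adj = directed.maximum(directed.T).tocsr()
    adj.setdiag(0)
    adj.eliminate_zeros()
    adj.data[:] = 1.0

    neighbor_sets = [adj.indices[adj.indptr[i] : adj.indptr[i + 1]].copy() for i in range(n)]
    return NeighborGraph(adjacency=adj, neighbor_sets=neighbor_sets, k=k, coords=coords)


def symmetric_normalize(g: NeighborGraph, add_self_loops: bool = True) -> NormalizedAdjacency:
    """Return D^(-1/2) (A + I) D^(-1/2) (self-loops optional)."""
    a = g.adjacency.tocsr().astype(np.float64)
    if (abs(a - a.T) > 0).nnz:
        raise ValueError("adjacency must be symmetric")
    if a.data.size and a.data.min() < 0:
        raise ValueError("adjacency must be non-negative")
    if add_self_loops:
        a = (a + sp.identity(a.shape[0], format="csr")).tocsr()
    deg = np.asarray(a.sum(axis=1)).ravel()
    with np.errstate(divide="ignore"):
        dinv = 1.0 / np.sqrt(deg)
    dinv[~np.isfinite(dinv)] = 0.0
    d = sp.diags(dinv)
    return NormalizedAdjacency(matrix=(d @ a @ d).tocsr(), self_loops=add_self_loops)


def permute_features(X: FeatureMatrix, seed: int) -> FeatureMatrix:
    """Corruption view: seeded uniform random permutation of the rows of X.

    The graph topology is untouched; callers reuse the original adjacency,
    so each spot is paired with another spot's expression vector.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(X.n_items)
    return FeatureMatrix(
        values=X.values[perm],
        feature_ids=list(X.feature_ids),
        item_ids=[X.item_ids[i] for i in perm],
        scaling_stats=dict(X.scaling_stats),
    )


def _apply_transform(coords: np.ndarray, transform: Optional[np.ndarray]) -> np.ndarray:
    if transform is None:
        return coords
    t = np.asarray(transform, dtype=np.float64)
    if t.shape != (2, 3):
        raise ValueError("rigid transform must be a 2x3 matrix [[c,-s,tx],[s,c,ty]]")
    return coords @ t[:, :2].T + t[:, 2]


def build_joint_graph(
    slices: Sequence[SpatialDataset],
    transforms: Optional[Sequence[Optional[np.ndarray]]] = None,
    k: int = 3,
) -> tuple[SpatialDataset, NeighborGraph]:
    """Concatenate pre-aligned slices and build one k-NN graph over pooled coordinates.

    Slices are restricted to their shared gene universe (ordered as in the
    first slice), per-slice rigid transforms (2x3, rotation + translation)
    place them in one frame, and batch labels record slice membership.
    Neighbor sets may then cross slice boundaries, which is what lets the
    encoder smooth features between slices.
    """
    if len(slices) < 2:
        raise ValueError("joint graph needs at least 2 slices")
    if transforms is not None and len(transforms) != len(slices):
        raise ValueError("one transform per slice required")

    shared = set(slices[0].gene_ids)
    for s in slices[1:]:
        shared &= set(s.gene_ids)
    if not shared:
        raise ValueError("slices share no genes")
    genes = [g for g in slices[0].gene_ids if g in shared]

    counts_blocks, coords_blocks, spot_ids, batch, truth = [], [], [], [], []
    any_truth = all(s.truth_labels is not None for s in slices)
    for i, s in enumerate(slices):
        pos = {g: j for j, g in enumerate(s.gene_ids)}
        idx = [pos[g] for g in genes]
        counts_blocks.append(s.counts[:, idx])
        t = None if transforms is None else transforms[i]
        coords_blocks.append(_apply_transform(s.coords, t))
        spot_ids.extend(f"s{i}:{sid}" for sid in s.spot_ids)
        batch.extend([f"slice{i}"] * s.n_spots)
        if any_truth:
            truth.extend(np.asarray(s.truth_labels).tolist())

    combined = SpatialDataset(
        counts=np.vstack(counts_blocks),
        gene_ids=genes,
        spot_ids=spot_ids,
        coords=np.vstack(coords_blocks),
        batch=np.asarray(batch),
        truth_labels=np.asarray(truth) if any_truth else None,
    )
    graph = build_knn_graph(combined.coords, k=k)
    return combined, graph
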