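"""Vertical / horizontal multi-slice integration and the iLISI mixing score.

Integration needs no explicit batch covariate: slices placed in one
coordinate frame share a single k-NN graph, so the encoder smooths features
across slice boundaries and the contrastive loss pulls cross-slice
neighbors together — batch effects are corrected implicitly.

iLISI (integration Local Inverse Simpson's Index) measures how many
distinct batches a spot's perplexity-weighted neighborhood effectively
contains: 1 means no mixing, B means perfect mixing of B batches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .preprocess import FeatureMatrix, SpatialDataset, normalize_select_scale
from .representation import RepresentationOutput, TrainConfig, train_representation
from .spatial_graph import NeighborGraph, build_joint_graph


@dataclass
class IntegratedDataset:
    combined: SpatialDataset
    joint_graph: NeighborGraph
    features: FeatureMatrix
    Z_joint: np.ndarray
    H_joint: np.ndarray
    representation: RepresentationOutput


def integrate_slices(
    slices: Sequence[SpatialDataset],
    transforms: Optional[Sequence[Optional[np.ndarray]]] = None,
    cfg: Optional[TrainConfig] = None,
    k: int = 3,
    n_hvg: int = 3000,
) -> IntegratedDataset:
    """Pool pre-aligned slices, build the joint graph, and train one representation.

    Preprocessing runs on the pooled counts (a single HVG set feeds one
    encoder); batch labels are recorded but never enter the model.
    """
    if len(slices) < 2:
        raise ValueError("integration needs at least 2 slices")
    cfg = cfg or TrainConfig()
    combined, graph = build_joint_graph(slices, transforms=transforms, k=k)
    features = normalize_select_scale(combined, n_hvg=n_hvg)
    rep = train_representation(features, graph, cfg)
    return IntegratedDataset(
        combined=combined,
        joint_graph=graph,
        features=features,
        Z_joint=rep.Z_s,
        H_joint=rep.H_s,
        representation=rep,
    )


def _perplexity_weights(dists: np.ndarray, perplexity: float, tol: float = 1e-5) -> np.ndarray:
    """Gaussian-kernel weights over one spot's neighbor distances, with the
    bandwidth found by binary search so the weight entropy matches
    log(perplexity)."""
    d2 = dists.astype(np.float64) ** 2
    target = np.log(perplexity)
    beta, beta_min, beta_max = 1.0, 0.0, np.inf
    if np.all(d2 == 0):
        return np.full(d2.shape, 1.0 / d2.size)
    for _ in range(100):
        w = np.exp(-beta * (d2 - d2.min()))
        sw = w.sum()
        p = w / sw
        nz = p > 0
        h = -np.sum(p[nz] * np.log(p[nz]))
        if abs(h - target) < tol:
            break
        if h > target:  # too flat -> narrow the kernel
            beta_min = beta
            beta = beta * 2 if not np.isfinite(beta_max) else (beta + beta_max) / 2
        else:
            beta_max = beta
            beta = beta / 2 if beta_min == 0 else (beta + beta_min) / 2
    return p


def ilisi_score(
    embeddings: np.ndarray,
    batch_labels: Sequence,
    perplexity: float = 30.0,
) -> float:
    """Mean inverse Simpson index of perplexity-weighted batch frequencies.

    For each item, Gaussian weights over its 3 x perplexity nearest
    neighbors (bandwidth calibrated to the perplexity) give a batch
    frequency vector p; the item's score is 1 / sum(p^2). Ranges from 1
    (neighborhoods are single-batch) to the number of batches.
    """
    emb = np.asarray(embeddings, dtype=np.float64)
    labels = np.asarray(batch_labels)
    n = emb.shape[0]
    if n < 2:
        raise ValueError("need at least 2 items")
    if labels.shape[0] != n:
        raise ValueError("batch_labels must align with embeddings")
    if perplexity >= n - 1:
        raise ValueError(f"perplexity ({perplexity}) must be < N-1 ({n - 1})")

    _, codes = np.unique(labels, return_inverse=True)
    n_batches = codes.max() + 1
    if n_batches == 1:
        return 1.0

    k = int(min(3 * perplexity, n - 1))
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    dists, idx = nn.kneighbors(emb)
    dists, idx = dists[:, 1:], idx[:, 1:]  # drop self

    scores = np.empty(n)
    for i in range(n):
        p = _perplexity_weights(dists[i], perplexity)
        freq = np.bincount(codes[idx[i]], weights=p, minlength=n_batches)
        scores[i] = 1.0 / np.sum(freq**2)
    return float(scores.mean())
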