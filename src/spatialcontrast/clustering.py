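"""Spatial-domain assignment from the reconstructed expression H_s.

Spots are clustered with a shared-covariance Gaussian mixture (the mclust
EEE analogue) on a PCA reduction of H_s; the cluster count can be chosen by
silhouette score; an optional single synchronous refinement pass reassigns
each spot to the majority label inside a radius-r disc.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score, silhouette_score
from sklearn.mixture import GaussianMixture

logger = logging.getLogger(__name__)


@dataclass
class DomainLabels:
    labels: np.ndarray  # per-spot int in [0, n_domains)
    n_domains: int
    method: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)


def _pca_embed(H: np.ndarray, n_pcs: int, seed: int) -> np.ndarray:
    H = np.asarray(H, dtype=np.float64)
    n_comp = int(min(n_pcs, H.shape[0] - 1, H.shape[1]))
    pca = PCA(n_components=n_comp, svd_solver="full", random_state=seed)
    return pca.fit_transform(H)


def fit_mixture_clusters(
    H: np.ndarray, n_clusters: int, n_pcs: int = 20, seed: int = 0
) -> DomainLabels:
    """Shared-covariance (EEE-style) Gaussian mixture on ``n_pcs`` principal components.

    Falls back to diagonal covariance with a warning if the tied fit runs
    into a singular covariance.
    """
    H = np.asarray(H, dtype=np.float64)
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if H.shape[0] <= n_clusters:
        raise ValueError("need more spots than clusters")
    emb = _pca_embed(H, n_pcs, seed)
    try:
        gmm = GaussianMixture(
            n_components=n_clusters,
            covariance_type="tied",
            random_state=seed,
            n_init=5,
            max_iter=300,
        )
        labels = gmm.fit_predict(emb)
    except (np.linalg.LinAlgError, ValueError) as exc:
        warnings.warn(
            f"tied-covariance mixture failed ({exc}); falling back to diagonal covariance"
        )
        gmm = GaussianMixture(
            n_components=n_clusters,
            covariance_type="diag",
            random_state=seed,
            n_init=5,
            max_iter=300,
            reg_covar=1e-4,
        )
        labels = gmm.fit_predict(emb)
    return DomainLabels(labels=labels, n_domains=n_clusters, method="gmm_tied")


def choose_cluster_count(
    H: np.ndarray, k_range: tuple[int, int] | range, seed: int = 0, n_pcs: int = 20
) -> int:
    """Return the k in ``k_range`` (inclusive bounds) with the highest mean
    silhouette on the PCA embedding; ties go to the smaller k."""
    if isinstance(k_range, range):
        ks = list(k_range)
    else:
        lo, hi = k_range
        ks = list(range(lo, hi + 1))
    if not ks:
        raise ValueError("empty cluster-count range")
    H = np.asarray(H, dtype=np.float64)
    if min(ks) < 2 or max(ks) > H.shape[0] - 1:
        raise ValueError("k_range must lie within [2, N_spot - 1]")
    if len(ks) == 1:
        return ks[0]
    emb = _pca_embed(H, n_pcs, seed)
    best_k, best_score = None, -np.inf
    for k in ks:
        labels = fit_mixture_clusters(H, k, n_pcs=n_pcs, seed=seed).labels
        if len(np.unique(labels)) < 2:
            score = -np.inf
        else:
            score = silhouette_score(emb, labels)
        if score > best_score:  # strict: ties keep the smaller k
            best_k, best_score = k, score
    return best_k


def spatial_refine(labels: DomainLabels, coords: np.ndarray, r: float = 50.0) -> DomainLabels:
    """One synchronous majority-vote pass over radius-``r`` discs.

    Every spot is reassigned to the most frequent label among the *other*
    spots within Euclidean distance ``r`` (input coordinate units), computed
    from the pre-pass labels. Ties and empty neighborhoods keep the current
    label.
    """
    if r <= 0:
        raise ValueError("r must be > 0")
    coords = np.asarray(coords, dtype=np.float64)
    lab = labels.labels
    if coords.shape[0] != lab.shape[0]:
        raise ValueError("coords must align with labels")
    tree = cKDTree(coords)
    neighborhoods = tree.query_ball_point(coords, r)
    out = lab.copy()
    for i, idx in enumerate(neighborhoods):
        idx = [j for j in idx if j != i]
        if not idx:
            continue
        counts = np.bincount(lab[idx], minlength=labels.n_domains)
        m = counts.max()
        winners = np.flatnonzero(counts == m)
        if len(winners) == 1 and winners[0] != lab[i]:
            out[i] = winners[0]
    return DomainLabels(labels=out, n_domains=labels.n_domains, method=labels.method + "+refine")


def adjusted_rand_index(pred, truth) -> float:
    """Permutation-model ARI between two labelings of the same spots."""
    p = pred.labels if isinstance(pred, DomainLabels) else np.asarray(pred)
    t = truth.labels if isinstance(truth, DomainLabels) else np.asarray(truth)
    if len(p) != len(t):
        raise ValueError(f"length mismatch: {len(p)} vs {len(t)}")
    return float(adjusted_rand_score(t, p))
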