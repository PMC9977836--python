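"""Projecting a single-cell reference onto spots via a learned mapping matrix.

A plain autoencoder denoises the reference cells into H_c; a trainable
cells x spots matrix M (column-softmax of free logits, so every spot's
column is a probability distribution over cells) predicts spot expression
H'_s = M^T H_c. M is fit — with no use of cell annotations — by minimizing

    L_map = -alpha * sum_i sum_{j in N_i} log softmax_j(cos(h'_i, h_j)/tau)
            + beta * ||H_s - H'_s||_F^2

where the softmax runs over all spots p != i: spatial neighbors are the
positive pairs, non-neighbors the negatives (InfoNCE with cosine
similarity, temperature tau). Defaults alpha=1, beta=10, tau=1, Adam lr
1e-3 for 1200 epochs.

Annotation transfer is pure linear algebra: P_spot = M^T S_cell after
retaining only each spot's top 10% highest-probability cells (rest zeroed,
no renormalization), and P_domain = S_spot^T P_spot.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import jensenshannon
from scipy.special import softmax

from ._optim import Adam
from .preprocess import FeatureMatrix
from .spatial_graph import NeighborGraph

logger = logging.getLogger(__name__)


@dataclass
class ReferenceAutoencoder:
    """Single-hidden-layer denoising autoencoder over reference cells."""

    W1: np.ndarray  # (n_genes, d_latent)
    b1: np.ndarray
    W2: np.ndarray  # (d_latent, n_genes)
    b2: np.ndarray
    d_latent: int
    Q: np.ndarray  # latent cell representations
    H_c: np.ndarray  # reconstructed cell expression
    loss_history: list = field(default_factory=list)


@dataclass
class MappingMatrix:
    """Column-stochastic cells x spots probability matrix."""

    M: np.ndarray
    logits: np.ndarray

    def __post_init__(self) -> None:
        colsums = self.M.sum(axis=0)
        if np.any(self.M < 0) or np.any(np.abs(colsums - 1.0) > 1e-5):
            raise ValueError("M must be non-negative with unit column sums (+-1e-5)")


@dataclass
class MappingConfig:
    alpha: float = 1.0
    beta: float = 10.0
    tau: float = 1.0
    lr: float = 1e-3
    epochs: int = 1200
    seed: int = 0
    negatives: str = "all"  # "all": denominator over p != i; "non_neighbors": p outside N_i

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")


@dataclass
class AnnotationMatrix:
    """One-hot (items x labels) indicator matrix."""

    S: np.ndarray
    label_names: list[str]

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=np.float64)
        if not np.all(np.isin(self.S, [0.0, 1.0])) or not np.all(self.S.sum(axis=1) == 1.0):
            raise ValueError("S must be one-hot with each row summing to exactly 1")

    @classmethod
    def from_labels(cls, labels: Sequence, label_names: Optional[list[str]] = None
                    ) -> "AnnotationMatrix":
        labels = np.asarray(labels)
        if label_names is None:
            label_names = [str(x) for x in np.unique(labels)]
        pos = {name: j for j, name in enumerate(label_names)}
        S = np.zeros((len(labels), len(label_names)))
        for i, lab in enumerate(labels):
            S[i, pos[str(lab)]] = 1.0
        return cls(S=S, label_names=list(label_names))


def train_reference_autoencoder(
    X_c: FeatureMatrix | np.ndarray,
    d_latent: int = 64,
    lr: float = 1e-3,
    epochs: int = 1200,
    seed: int = 0,
) -> ReferenceAutoencoder:
    """Fit encoder (genes -> d_latent, ReLU) / decoder (d_latent -> genes,
    identity) by mean squared reconstruction error with Adam."""
    X = np.asarray(X_c.values if isinstance(X_c, FeatureMatrix) else X_c, dtype=np.float64)
    n, g = X.shape
    rng = np.random.default_rng(seed)

    def xavier(fi: int, fo: int) -> np.ndarray:
        bound = np.sqrt(6.0 / (fi + fo))
        return rng.uniform(-bound, bound, size=(fi, fo))

    params = {
        "W1": xavier(g, d_latent),
        "b1": np.zeros(d_latent),
        "W2": xavier(d_latent, g),
        "b2": np.zeros(g),
    }
    opt = Adam(params, lr=lr)
    history = []
    for epoch in range(epochs):
        pre = X @ params["W1"] + params["b1"]
        Q = np.maximum(pre, 0.0)
        Y = Q @ params["W2"] + params["b2"]
        R = Y - X
        loss = float(np.mean(R * R))
        if not math.isfinite(loss):
            raise RuntimeError(f"non-finite autoencoder loss at epoch {epoch}")
        history.append(loss)
        dY = 2.0 * R / R.size
        grads = {
            "W2": Q.T @ dY,
            "b2": dY.sum(axis=0),
        }
        dQ = dY @ params["W2"].T
        dpre = dQ * (pre > 0)
        grads["W1"] = X.T @ dpre
        grads["b1"] = dpre.sum(axis=0)
        opt.step(grads)

    pre = X @ params["W1"] + params["b1"]
    Q = np.maximum(pre, 0.0)
    H_c = Q @ params["W2"] + params["b2"]
    return ReferenceAutoencoder(
        W1=params["W1"], b1=params["b1"], W2=params["W2"], b2=params["b2"],
        d_latent=d_latent, Q=Q, H_c=H_c, loss_history=history,
    )


def spot_expression_from_mapping(M: MappingMatrix | np.ndarray, H_c: np.ndarray) -> np.ndarray:
    """Predicted spot expression H'_s = M^T H_c (probability-weighted cell average)."""
    Mv = M.M if isinstance(M, MappingMatrix) else np.asarray(M, dtype=np.float64)
    H_c = np.asarray(H_c, dtype=np.float64)
    if Mv.shape[0] != H_c.shape[0]:
        raise ValueError(f"M has {Mv.shape[0]} cells but H_c has {H_c.shape[0]} rows")
    return Mv.T @ H_c


def _row_normalize(H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    norms = np.linalg.norm(H, axis=1)
    if np.any(norms == 0):
        warnings.warn("zero-norm rows encountered; their cosine similarities are defined as 0")
    safe = np.where(norms == 0, 1.0, norms)
    return H / safe[:, None], norms


def _contrastive_terms(
    H_prime: np.ndarray, H_s: np.ndarray, g: NeighborGraph, cfg: MappingConfig
) -> tuple[float, np.ndarray]:
    """InfoNCE term of the mapping loss and its gradient w.r.t. H_prime."""
    n = H_s.shape[0]
    U, nu = _row_normalize(H_prime)
    V, _ = _row_normalize(H_s)
    S = U @ V.T  # cosine similarities, predicted i vs reconstructed j
    logits = S / cfg.tau
    mask = np.zeros((n, n), dtype=bool)
    np.fill_diagonal(mask, True)
    if cfg.negatives == "non_neighbors":
        # denominator: the positive itself plus non-neighbors
        for i, nbrs in enumerate(g.neighbor_sets):
            mask[i, nbrs] = True
    elif cfg.negatives != "all":
        raise ValueError("negatives must be 'all' or 'non_neighbors'")

    nbr_counts = np.array([len(nb) for nb in g.neighbor_sets], dtype=np.float64)
    B = np.zeros((n, n))
    for i, nbrs in enumerate(g.neighbor_sets):
        B[i, nbrs] = 1.0

    if cfg.negatives == "all":
        masked = np.where(mask, -np.inf, logits)
        mrow = masked.max(axis=1)
        W = np.exp(masked - mrow[:, None])
        sw = W.sum(axis=1)
        lse = mrow + np.log(sw)
        W /= sw[:, None]
        active = nbr_counts > 0
        loss = float(-np.sum((logits * B).sum(axis=1)[active] - (nbr_counts * lse)[active]))
        dS = (nbr_counts[:, None] * W - B) / cfg.tau
        dS[~active] = 0.0
    else:
        loss = 0.0
        dS = np.zeros((n, n))
        for i in range(n):
            if nbr_counts[i] == 0:
                continue
            li = logits[i]
            # per positive j: denominator over {j} + non-neighbors (excluding self)
            neg_idx = np.flatnonzero(~mask[i])
            for j in np.flatnonzero(B[i]):
                terms = np.concatenate(([li[j]], li[neg_idx]))
                lse = np.logaddexp.reduce(terms)
                w = np.exp(terms - lse)
                loss += -(li[j] - lse)
                dS[i, j] += (w[0] - 1.0) / cfg.tau
                dS[i, neg_idx] += w[1:] / cfg.tau

    loss *= cfg.alpha
    dS *= cfg.alpha
    # back through the cosine normalization of H_prime
    dU = dS @ V
    proj = np.einsum("id,id->i", dU, U)
    dH_prime = (dU - proj[:, None] * U)
    safe = np.where(nu == 0, 1.0, nu)
    dH_prime /= safe[:, None]
    dH_prime[nu == 0] = 0.0
    return float(loss), dH_prime


def mapping_objective(
    H_s: np.ndarray,
    H_prime: np.ndarray,
    g: NeighborGraph,
    cfg: Optional[MappingConfig] = None,
) -> float:
    """Spatially informed contrastive term plus beta-weighted Frobenius alignment."""
    cfg = cfg or MappingConfig()
    H_s = np.asarray(H_s, dtype=np.float64)
    H_prime = np.asarray(H_prime, dtype=np.float64)
    if H_s.shape != H_prime.shape:
        raise ValueError("H_s and H_prime must have the same shape")
    term1, _ = _contrastive_terms(H_prime, H_s, g, cfg)
    term2 = cfg.beta * float(np.sum((H_s - H_prime) ** 2))
    return term1 + term2


def fit_mapping_matrix(
    H_s: np.ndarray,
    H_c: np.ndarray,
    g: NeighborGraph,
    cfg: Optional[MappingConfig] = None,
) -> MappingMatrix:
    """Learn M by Adam on the mapping objective.

    M is parametrized as a per-column softmax over cells, so the unit
    column-sum constraint holds by construction after every step. Logits
    start at zero (uniform columns), which makes the fit exactly
    equivariant to permutations of the reference cells. Cell annotations
    are never consulted.
    """
    cfg = cfg or MappingConfig()
    H_s = np.asarray(H_s, dtype=np.float64)
    H_c = np.asarray(H_c, dtype=np.float64)
    if H_s.shape[1] != H_c.shape[1]:
        raise ValueError("spot and cell matrices must share the gene axis")
    if H_s.shape[0] != g.n_nodes:
        raise ValueError("graph must align with spots")
    n_cell, n_spot = H_c.shape[0], H_s.shape[0]

    params = {"logits": np.zeros((n_cell, n_spot))}
    opt = Adam(params, lr=cfg.lr)
    for epoch in range(cfg.epochs):
        M = softmax(params["logits"], axis=0)
        H_prime = M.T @ H_c
        term1, dH_prime = _contrastive_terms(H_prime, H_s, g, cfg)
        diff = H_prime - H_s
        loss = term1 + cfg.beta * float(np.sum(diff * diff))
        if not math.isfinite(loss):
            raise RuntimeError(f"non-finite mapping loss at epoch {epoch}")
        dH_prime = dH_prime + 2.0 * cfg.beta * diff
        dM = H_c @ dH_prime.T
        # softmax backward per column
        dlogits = M * (dM - np.sum(M * dM, axis=0, keepdims=True))
        opt.step({"logits": dlogits})

    M = softmax(params["logits"], axis=0)
    return MappingMatrix(M=M, logits=params["logits"])


def annotations_to_spots(
    M: MappingMatrix | np.ndarray,
    S_cell: AnnotationMatrix,
    top_frac: float = 0.1,
) -> np.ndarray:
    """P_spot = Mtilde^T S_cell, where Mtilde keeps only each spot's
    ceil(top_frac * N_cell) highest-probability cells (rest zeroed, no
    renormalization; probability ties broken toward the smaller cell index)."""
    if not (0 < top_frac <= 1):
        raise ValueError("top_frac must be in (0, 1]")
    Mv = (M.M if isinstance(M, MappingMatrix) else np.asarray(M, dtype=np.float64)).copy()
    n_cell = Mv.shape[0]
    n_keep = math.ceil(top_frac * n_cell)
    if n_keep < n_cell:
        # stable sort on (-prob, index): exactly n_keep survivors per spot
        order = np.argsort(-Mv, axis=0, kind="stable")
        drop = order[n_keep:, :]
        Mv[drop, np.arange(Mv.shape[1])[None, :]] = 0.0
    return Mv.T @ S_cell.S


def annotations_to_domains(P_spot: np.ndarray, S_spot: AnnotationMatrix) -> np.ndarray:
    """P_domain = S_spot^T P_spot (per-domain sums of member-spot rows)."""
    P_spot = np.asarray(P_spot, dtype=np.float64)
    if S_spot.S.shape[0] != P_spot.shape[0]:
        raise ValueError("S_spot rows must align with P_spot rows")
    return S_spot.S.T @ P_spot


def _ssim_1d(x: np.ndarray, y: np.ndarray, k1: float = 0.01, k2: float = 0.03) -> float:
    """Global (non-windowed) SSIM on min-max scaled vectors, L = 1."""
    c1, c2 = k1**2, k2**2
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cxy = ((x - mx) * (y - my)).mean()
    return float(
        (2 * mx * my + c1) * (2 * cxy + c2) / ((mx**2 + my**2 + c1) * (vx + vy + c2))
    )


def _minmax(x: np.ndarray) -> np.ndarray:
    rng = x.max() - x.min()
    if rng == 0:
        return np.zeros_like(x)
    return (x - x.min()) / rng


def deconvolution_metrics(est: np.ndarray, truth: np.ndarray) -> dict:
    """Per-cell-type PCC / SSIM / RMSE / JSD between estimated and true
    spot proportions, plus their means. JSD is base-2 (in [0, 1]); the base
    is recorded in the output."""
    est = np.asarray(est, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if est.shape != truth.shape:
        raise ValueError("est and truth must have the same shape")
    n_types = est.shape[1]
    pcc = np.empty(n_types)
    ssim = np.empty(n_types)
    rmse = np.empty(n_types)
    jsd = np.empty(n_types)
    for t in range(n_types):
        e, tr = est[:, t], truth[:, t]
        if e.std() == 0 or tr.std() == 0:
            warnings.warn(f"constant column for type {t}; PCC reported as 0")
            pcc[t] = 0.0
        else:
            pcc[t] = float(np.corrcoef(e, tr)[0, 1])
        es, ts = _minmax(e), _minmax(tr)
        ssim[t] = _ssim_1d(es, ts)
        rmse[t] = float(np.sqrt(np.mean((es - ts) ** 2)))
        pe = e / e.sum() if e.sum() > 0 else np.full_like(e, 1.0 / len(e))
        pt = tr / tr.sum() if tr.sum() > 0 else np.full_like(tr, 1.0 / len(tr))
        jsd[t] = float(jensenshannon(pe, pt, base=2) ** 2)
    return {
        "pcc": pcc,
        "ssim": ssim,
        "rmse": rmse,
        "jsd": jsd,
        "pcc_mean": float(pcc.mean()),
        "ssim_mean": float(ssim.mean()),
        "rmse_mean": float(rmse.mean()),
        "jsd_mean": float(jsd.mean()),
        "jsd_base": 2,
    }
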