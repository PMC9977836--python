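"""Graph-convolutional autoencoder with a symmetric local-context contrastive loss.

Model
-----
A single graph-convolution layer encodes scaled expression X into a latent
Z_s = ReLU(A_norm X W_e + b_e) and a symmetric single-layer decoder maps it
back to gene space, H_s = A_norm Z_s W_d + b_d. Training jointly minimizes

* the self-reconstruction loss  L_recon = ||X - H_s||_F^2, and
* a symmetric contrastive loss in the style of Deep Graph Infomax, but with
  a *local* readout: the context of spot i is g_i = sigmoid(mean of its
  neighbors' embeddings). A bilinear discriminator
  Phi(z, g) = sigmoid(z^T W g) is trained to score (z_i, g_i) pairs high
  (positive) and pairs built from the corrupted view — expression vectors
  shuffled across spots with the graph fixed — low (negative). The loss is
  symmetrized by repeating the construction with the corrupted view's own
  summaries.

Total objective: lambda1 * L_recon + lambda2 * (L_SCL + L_SCL_corrupt),
with lambda1=10, lambda2=1, optimized with Adam (lr 1e-3) for 600 epochs
(clustering / slice integration) or 1200 epochs (deconvolution-facing runs).

The models are small enough that forward passes and analytic gradients are
written directly in numpy; a fresh corruption permutation is drawn every
epoch from the config seed, so runs are bitwise reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._optim import Adam
from .preprocess import FeatureMatrix
from .spatial_graph import NeighborGraph, NormalizedAdjacency, symmetric_normalize

logger = logging.getLogger(__name__)


@dataclass
class EncoderParams:
    W_e: np.ndarray  # (n_genes, d_latent)
    b_e: np.ndarray  # (d_latent,)


@dataclass
class DecoderParams:
    W_d: np.ndarray  # (d_latent, n_genes)
    b_d: np.ndarray  # (n_genes,)


@dataclass
class DiscriminatorParams:
    W_disc: np.ndarray  # (d_latent, d_latent)


@dataclass
class TrainConfig:
    """Training hyperparameters for the representation module.

    ``epochs`` defaults to 600 (clustering / integration); deconvolution-facing
    runs use 1200.
    """

    d_latent: int = 64
    lr: float = 1e-3
    epochs: int = 600
    lambda1: float = 10.0
    lambda2: float = 1.0
    weight_decay: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("lambda1/lambda2 must be >= 0")


@dataclass
class RepresentationOutput:
    Z_s: np.ndarray
    H_s: np.ndarray
    loss_history: pd.DataFrame
    encoder: EncoderParams = None
    decoder: DecoderParams = None
    discriminator: DiscriminatorParams = None


def _as_sparse(a_norm: NormalizedAdjacency | sp.spmatrix | np.ndarray) -> sp.csr_matrix:
    if isinstance(a_norm, NormalizedAdjacency):
        return a_norm.matrix
    return sp.csr_matrix(a_norm)


def gcn_layer(
    X_in: np.ndarray,
    A_norm: NormalizedAdjacency | sp.spmatrix | np.ndarray,
    W: np.ndarray,
    b: np.ndarray,
    activation: str = "relu",
) -> np.ndarray:
    """One graph convolution: activation(A_norm @ X_in @ W + b)."""
    A = _as_sparse(A_norm)
    X_in = np.asarray(X_in, dtype=np.float64)
    if A.shape[1] != X_in.shape[0] or X_in.shape[1] != W.shape[0]:
        raise ValueError(
            f"non-conformable shapes: A {A.shape}, X {X_in.shape}, W {W.shape}"
        )
    out = A @ X_in @ W + b
    if activation == "relu":
        return np.maximum(out, 0.0)
    if activation == "identity":
        return out
    raise ValueError(f"unknown activation {activation!r}")


def reconstruction_loss(X: np.ndarray, H_s: np.ndarray) -> float:
    """Squared Frobenius norm of X - H_s (sum over spots of ||x_i - h_i||^2)."""
    X = np.asarray(X, dtype=np.float64)
    H_s = np.asarray(H_s, dtype=np.float64)
    if X.shape != H_s.shape:
        raise ValueError(f"shape mismatch {X.shape} vs {H_s.shape}")
    return float(np.sum((X - H_s) ** 2))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softplus(x: np.ndarray) -> np.ndarray:
    # log(1 + exp(x)), stable
    return np.logaddexp(0.0, x)


def _neighbor_mean_operator(g: NeighborGraph) -> sp.csr_matrix:
    """Row-stochastic operator averaging over N_i (self excluded).

    Spots with empty neighbor sets (cannot occur after graph construction)
    fall back to reading their own embedding.
    """
    n = g.n_nodes
    rows, cols, vals = [], [], []
    for i, nbrs in enumerate(g.neighbor_sets):
        if len(nbrs) == 0:
            rows.append(i)
            cols.append(i)
            vals.append(1.0)
        else:
            w = 1.0 / len(nbrs)
            for j in nbrs:
                rows.append(i)
                cols.append(int(j))
                vals.append(w)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def local_summary(Z: np.ndarray, g: NeighborGraph) -> np.ndarray:
    """Local context g_i = sigmoid(mean_{j in N_i} z_j), self excluded."""
    Z = np.asarray(Z, dtype=np.float64)
    if Z.shape[0] != g.n_nodes:
        raise ValueError("Z rows must align with graph nodes")
    return _sigmoid(_neighbor_mean_operator(g) @ Z)


def discriminator_score(
    z: np.ndarray, g: np.ndarray, p: DiscriminatorParams
) -> np.ndarray | float:
    """Phi(z, g) = sigmoid(z^T W_disc g); rowwise for matrix inputs."""
    z = np.asarray(z, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    if z.ndim == 1:
        return float(_sigmoid(np.atleast_1d(z @ p.W_disc @ g))[0])
    logits = np.einsum("id,id->i", z @ p.W_disc, g)
    return _sigmoid(logits)


def _pair_logits(Z: np.ndarray, G: np.ndarray, W: np.ndarray) -> np.ndarray:
    return np.einsum("id,id->i", Z @ W, G)


def symmetric_contrastive_loss(
    Z: np.ndarray,
    Z_prime: np.ndarray,
    g: NeighborGraph,
    p: DiscriminatorParams,
) -> tuple[float, float]:
    """Binary cross-entropy contrastive losses for the clean and corrupted views.

    L_SCL        = -(1/2N) sum_i [log Phi(z_i, g_i) + log(1 - Phi(z'_i, g_i))]
    L_SCL_corrupt= -(1/2N) sum_i [log Phi(z'_i, g'_i) + log(1 - Phi(z_i, g'_i))]

    Computed via softplus, which is the epsilon-free stable form of the
    clamped BCE.
    """
    Z = np.asarray(Z, dtype=np.float64)
    Z_prime = np.asarray(Z_prime, dtype=np.float64)
    if Z.shape != Z_prime.shape:
        raise ValueError("Z and Z_prime must have the same shape")
    G = local_summary(Z, g)
    Gp = local_summary(Z_prime, g)
    W = p.W_disc
    n = Z.shape[0]
    l_pos = _pair_logits(Z, G, W)
    l_neg = _pair_logits(Z_prime, G, W)
    l_pos_c = _pair_logits(Z_prime, Gp, W)
    l_neg_c = _pair_logits(Z, Gp, W)
    scl = float(np.sum(_softplus(-l_pos) + _softplus(l_neg)) / (2 * n))
    scl_c = float(np.sum(_softplus(-l_pos_c) + _softplus(l_neg_c)) / (2 * n))
    return scl, scl_c


def total_loss(L_recon: float, L_SCL: float, L_SCL_corrupt: float, cfg: TrainConfig) -> float:
    """lambda1 * L_recon + lambda2 * (L_SCL + L_SCL_corrupt)."""
    return cfg.lambda1 * L_recon + cfg.lambda2 * (L_SCL + L_SCL_corrupt)


def _init_params(n_genes: int, d_latent: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Xavier-uniform weights; discriminator starts at zero (chance level)."""

    def xavier(fan_in: int, fan_out: int) -> np.ndarray:
        bound = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-bound, bound, size=(fan_in, fan_out))

    return {
        "W_e": xavier(n_genes, d_latent),
        "b_e": np.zeros(d_latent),
        "W_d": xavier(d_latent, n_genes),
        "b_d": np.zeros(n_genes),
        "W_disc": np.zeros((d_latent, d_latent)),
    }


def _loss_and_grads(
    params: dict[str, np.ndarray],
    X: np.ndarray,
    Xp: np.ndarray,
    A: sp.csr_matrix,
    P: sp.csr_matrix,
    cfg: TrainConfig,
) -> tuple[dict[str, float], dict[str, np.ndarray]]:
    """One full forward/backward pass; gradients are exact (hand-derived)."""
    n = X.shape[0]
    W_e, b_e = params["W_e"], params["b_e"]
    W_d, b_d = params["W_d"], params["b_d"]
    W = params["W_disc"]

    AX = A @ X
    AXp = A @ Xp
    pre = AX @ W_e + b_e
    Z = np.maximum(pre, 0.0)
    prep = AXp @ W_e + b_e
    Zp = np.maximum(prep, 0.0)

    AZ = A @ Z
    H = AZ @ W_d + b_d
    R = H - X
    l_recon = float(np.sum(R * R))

    SG = P @ Z
    SGp = P @ Zp
    G = _sigmoid(SG)
    Gp = _sigmoid(SGp)

    ZW = Z @ W
    ZpW = Zp @ W
    l1 = np.einsum("id,id->i", ZW, G)  # positive, clean view
    l2 = np.einsum("id,id->i", ZpW, G)  # negative
    l3 = np.einsum("id,id->i", ZpW, Gp)  # positive, corrupted view
    l4 = np.einsum("id,id->i", ZW, Gp)  # negative, corrupted view
    scl = float(np.sum(_softplus(-l1) + _softplus(l2)) / (2 * n))
    scl_c = float(np.sum(_softplus(-l3) + _softplus(l4)) / (2 * n))
    total = cfg.lambda1 * l_recon + cfg.lambda2 * (scl + scl_c)

    # ---- backward ----
    lam2 = cfg.lambda2
    c1 = lam2 * (_sigmoid(l1) - 1.0) / (2 * n)
    c2 = lam2 * _sigmoid(l2) / (2 * n)
    c3 = lam2 * (_sigmoid(l3) - 1.0) / (2 * n)
    c4 = lam2 * _sigmoid(l4) / (2 * n)

    dW_disc = (
        Z.T @ (c1[:, None] * G)
        + Zp.T @ (c2[:, None] * G)
        + Zp.T @ (c3[:, None] * Gp)
        + Z.T @ (c4[:, None] * Gp)
    )
    dZ = (c1[:, None] * G + c4[:, None] * Gp) @ W.T
    dZp = (c2[:, None] * G + c3[:, None] * Gp) @ W.T
    dG = c1[:, None] * ZW + c2[:, None] * ZpW
    dGp = c3[:, None] * ZpW + c4[:, None] * ZW
    dZ += P.T @ (dG * G * (1.0 - G))
    dZp += P.T @ (dGp * Gp * (1.0 - Gp))

    dH = 2.0 * cfg.lambda1 * R
    dW_d = AZ.T @ dH
    db_d = dH.sum(axis=0)
    dZ += A.T @ (dH @ W_d.T)

    dpre = dZ * (pre > 0)
    dprep = dZp * (prep > 0)
    dW_e = AX.T @ dpre + AXp.T @ dprep
    db_e = dpre.sum(axis=0) + dprep.sum(axis=0)

    losses = {"total": total, "recon": l_recon, "scl": scl, "scl_corrupt": scl_c}
    grads = {"W_e": dW_e, "b_e": db_e, "W_d": dW_d, "b_d": db_d, "W_disc": dW_disc}
    return losses, grads


def train_representation(
    X: FeatureMatrix, g: NeighborGraph, cfg: TrainConfig
) -> RepresentationOutput:
    """Train the graph autoencoder with the symmetric contrastive objective.

    Every epoch draws a fresh corruption permutation, passes both views
    through the shared encoder, decodes the clean view, and takes one Adam
    step on the total loss. Fully deterministic given ``cfg.seed``.
    """
    Xv = np.asarray(X.values, dtype=np.float64)
    if Xv.shape[0] != g.n_nodes:
        raise ValueError("feature rows must align with graph nodes")

    rng = np.random.default_rng(cfg.seed)
    A = symmetric_normalize(g).matrix
    P = _neighbor_mean_operator(g)
    params = _init_params(Xv.shape[1], cfg.d_latent, rng)
    opt = Adam(params, lr=cfg.lr, weight_decay=cfg.weight_decay)

    history = {"epoch": [], "total": [], "recon": [], "scl": [], "scl_corrupt": []}
    for epoch in range(cfg.epochs):
        perm = rng.permutation(Xv.shape[0])
        losses, grads = _loss_and_grads(params, Xv, Xv[perm], A, P, cfg)
        if not np.isfinite(losses["total"]):
            raise RuntimeError(
                f"non-finite loss at epoch {epoch}: {losses} — "
                "check feature scaling or lower the learning rate"
            )
        opt.step(grads)
        history["epoch"].append(epoch)
        for key in ("total", "recon", "scl", "scl_corrupt"):
            history[key].append(losses[key])

    Z = gcn_layer(Xv, A, params["W_e"], params["b_e"], "relu")
    H = gcn_layer(Z, A, params["W_d"], params["b_d"], "identity")
    return RepresentationOutput(
        Z_s=Z,
        H_s=H,
        loss_history=pd.DataFrame(history),
        encoder=EncoderParams(params["W_e"], params["b_e"]),
        decoder=DecoderParams(params["W_d"], params["b_d"]),
        discriminator=DiscriminatorParams(params["W_disc"]),
    )
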