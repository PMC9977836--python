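"""End-to-end task orchestration: cluster, integrate, deconvolve, simulate.

Each run writes its outputs plus a manifest (inputs, config, seeds, package
version) into the output directory. A single global seed fans out to named
per-stage seeds so stages can be re-run in isolation. Errors are re-raised
tagged with the failing stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from . import __version__
from .clustering import DomainLabels, adjusted_rand_index, fit_mixture_clusters, spatial_refine
from .deconvolution import (
    AnnotationMatrix,
    MappingConfig,
    annotations_to_domains,
    annotations_to_spots,
    deconvolution_metrics,
    fit_mapping_matrix,
    train_reference_autoencoder,
)
from .integration import ilisi_score, integrate_slices
from .preprocess import (
    FeatureMatrix,
    SpatialDataset,
    intersect_genes,
    normalize_select_scale,
    read_spatial_dataset,
)
from .representation import TrainConfig, train_representation
from .spatial_graph import build_knn_graph
from .synthetic import FixtureSpec, simulate_domain_slide

logger = logging.getLogger(__name__)


class WorkflowError(RuntimeError):
    """Raised when a pipeline stage fails; message is '<stage>: <cause>'."""


@contextmanager
def _stage(name: str):
    try:
        yield
    except WorkflowError:
        raise
    except Exception as exc:
        raise WorkflowError(f"{name}: {exc}") from exc


def _stage_seed(seed: int, name: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from the global seed."""
    tag = zlib.crc32(name.encode()) % (2**31)
    return int(np.random.SeedSequence([seed, tag]).generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Flat configuration for one workflow run."""

    input: Optional[str] = None  # spatial input (cluster / deconvolve)
    slices: list[str] = field(default_factory=list)  # integrate
    reference: Optional[str] = None  # deconvolve: single-cell h5ad/csv
    format: str = "mtx_dir"
    out_dir: str = "run_out"
    seed: int = 0
    k: int = 3
    n_hvg: int = 3000
    n_clusters: Optional[int] = None
    n_pcs: int = 20
    refine: bool = False
    refine_radius: float = 50.0
    epochs: int = 600
    d_latent: int = 64
    lr: float = 1e-3
    lambda1: float = 10.0
    lambda2: float = 1.0
    mapping_epochs: int = 1200
    alpha: float = 1.0
    beta: float = 10.0
    tau: float = 1.0
    top_frac: float = 0.1
    transforms: Optional[str] = None  # JSON {slice_index: 2x3 matrix}


def _write_manifest(cfg: RunConfig, out: Path, extra: dict) -> None:
    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(cfg),
        **extra,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def _train_cfg(cfg: RunConfig, epochs: Optional[int] = None) -> TrainConfig:
    return TrainConfig(
        d_latent=cfg.d_latent,
        lr=cfg.lr,
        epochs=epochs if epochs is not None else cfg.epochs,
        lambda1=cfg.lambda1,
        lambda2=cfg.lambda2,
        seed=_stage_seed(cfg.seed, "representation"),
    )


def _write_labels(path: Path, spot_ids: list[str], labels: DomainLabels) -> None:
    pd.DataFrame({"spot_id": spot_ids, "domain": labels.labels}).to_csv(
        path, sep="\t", index=False
    )


def run_cluster(cfg: RunConfig) -> dict:
    """preprocess -> graph -> train -> cluster (-> refine) -> outputs + report."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with _stage("preprocess/read"):
        ds = read_spatial_dataset(cfg.input, format=cfg.format)
    with _stage("preprocess/normalize"):
        X = normalize_select_scale(ds, n_hvg=cfg.n_hvg)
    with _stage("graph/build"):
        graph = build_knn_graph(ds.coords, k=cfg.k)
    with _stage("represent/train"):
        rep = train_representation(X, graph, _train_cfg(cfg))
    with _stage("cluster/assign"):
        if cfg.n_clusters is None:
            raise ValueError("n_clusters is required for the cluster task")
        labels = fit_mixture_clusters(
            rep.H_s, cfg.n_clusters, n_pcs=cfg.n_pcs, seed=_stage_seed(cfg.seed, "gmm")
        )
        if cfg.refine:
            labels = spatial_refine(labels, ds.coords, r=cfg.refine_radius)

    _write_labels(out / "labels.tsv", ds.spot_ids, labels)
    np.savez(out / "embeddings.npz", Z_s=rep.Z_s, H_s=rep.H_s)
    rep.loss_history.to_csv(out / "loss_history.csv", index=False)
    report: dict = {"task": "cluster", "n_spots": ds.n_spots, "n_clusters": cfg.n_clusters}
    if ds.truth_labels is not None:
        report["ari"] = adjusted_rand_index(labels.labels, ds.truth_labels)
    (out / "report.json").write_text(json.dumps(report, indent=2))
    _write_manifest(cfg, out, {"task": "cluster"})
    return report


def run_integrate(cfg: RunConfig) -> dict:
    """integrate_slices -> joint clustering -> iLISI (+ per-slice ARI) report."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if len(cfg.slices) < 2:
        raise WorkflowError("validate/inputs: need at least 2 slices")
    with _stage("preprocess/read"):
        slices = [read_spatial_dataset(p, format=cfg.format) for p in cfg.slices]
    transforms = None
    if cfg.transforms:
        with _stage("preprocess/transforms"):
            tdict = json.loads(Path(cfg.transforms).read_text())
            transforms = [
                np.asarray(tdict[str(i)]) if str(i) in tdict else None
                for i in range(len(slices))
            ]
    with _stage("integrate/train"):
        integ = integrate_slices(
            slices, transforms=transforms, cfg=_train_cfg(cfg), k=cfg.k, n_hvg=cfg.n_hvg
        )
    with _stage("integrate/metrics"):
        batch = integ.combined.batch
        perplexity = min(30.0, integ.combined.n_spots / 4)
        ilisi_joint = ilisi_score(integ.Z_joint, batch, perplexity=perplexity)
        pca = PCA(
            n_components=min(cfg.n_pcs, integ.features.n_features, integ.features.n_items - 1),
            svd_solver="full",
            random_state=_stage_seed(cfg.seed, "pca"),
        ).fit_transform(integ.features.values)
        ilisi_pca = ilisi_score(pca, batch, perplexity=perplexity)

    report: dict = {
        "task": "integrate",
        "n_spots": integ.combined.n_spots,
        "ilisi_joint": ilisi_joint,
        "ilisi_uncorrected_pca": ilisi_pca,
    }
    if cfg.n_clusters is not None:
        with _stage("cluster/assign"):
            labels = fit_mixture_clusters(
                integ.H_joint, cfg.n_clusters, n_pcs=cfg.n_pcs,
                seed=_stage_seed(cfg.seed, "gmm"),
            )
        _write_labels(out / "joint_labels.tsv", integ.combined.spot_ids, labels)
        if integ.combined.truth_labels is not None:
            aris = {}
            for b in np.unique(batch):
                m = batch == b
                aris[str(b)] = adjusted_rand_index(
                    labels.labels[m], integ.combined.truth_labels[m]
                )
            report["per_slice_ari"] = aris
    np.savez(out / "joint_embeddings.npz", Z_joint=integ.Z_joint, H_joint=integ.H_joint)
    (out / "ilisi_report.json").write_text(json.dumps(report, indent=2))
    _write_manifest(cfg, out, {"task": "integrate"})
    return report


def _read_reference(path: str) -> tuple[SpatialDataset | None, np.ndarray, list[str], list[str], Optional[np.ndarray]]:
    """Read reference counts + optional labels from h5ad or csv (+ sidecar labels csv)."""
    p = Path(path)
    if p.suffix == ".h5ad":
        import anndata as ad
        import scipy.sparse as sp

        adata = ad.read_h5ad(p)
        X = adata.X
        counts = np.asarray(X.todense() if sp.issparse(X) else X, dtype=np.float64)
        labels = adata.obs["cell_type"].to_numpy() if "cell_type" in adata.obs else None
        return None, counts, list(adata.var_names), list(adata.obs_names), labels
    expr = pd.read_csv(p, index_col=0)
    label_path = p.with_suffix(".labels.csv")
    labels = None
    if label_path.exists():
        ldf = pd.read_csv(label_path, index_col=0)
        labels = ldf.iloc[:, 0].reindex(expr.index.astype(str)).to_numpy()
    return None, expr.to_numpy(dtype=np.float64), list(expr.columns), [str(i) for i in expr.index], labels


def run_deconvolve(cfg: RunConfig) -> dict:
    """preprocess both -> intersect -> train spot representation -> reference
    autoencoder -> fit mapping matrix -> annotation transfer -> metrics."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with _stage("preprocess/read"):
        ds = read_spatial_dataset(cfg.input, format=cfg.format)
        _, ref_counts, ref_genes, ref_cells, ref_labels = _read_reference(cfg.reference)
    with _stage("preprocess/normalize"):
        X_st = normalize_select_scale(ds, n_hvg=cfg.n_hvg)
        ref_ds = SpatialDataset(
            counts=ref_counts,
            gene_ids=ref_genes,
            spot_ids=ref_cells,
            coords=np.zeros((ref_counts.shape[0], 2)),
        )
        X_sc = normalize_select_scale(ref_ds, n_hvg=cfg.n_hvg)
    with _stage("preprocess/intersect"):
        X_st, X_sc = intersect_genes(X_st, X_sc)
    with _stage("graph/build"):
        graph = build_knn_graph(ds.coords, k=cfg.k)
    with _stage("represent/train"):
        rep = train_representation(X_st, graph, _train_cfg(cfg, epochs=cfg.mapping_epochs))
    with _stage("deconvolve/autoencoder"):
        auto = train_reference_autoencoder(
            X_sc, d_latent=cfg.d_latent, lr=cfg.lr, epochs=cfg.mapping_epochs,
            seed=_stage_seed(cfg.seed, "autoencoder"),
        )
    with _stage("deconvolve/mapping"):
        mcfg = MappingConfig(
            alpha=cfg.alpha, beta=cfg.beta, tau=cfg.tau, lr=cfg.lr,
            epochs=cfg.mapping_epochs, seed=_stage_seed(cfg.seed, "mapping"),
        )
        mapping = fit_mapping_matrix(rep.H_s, auto.H_c, graph, mcfg)
    np.savez(out / "mapping.npz", M=mapping.M)

    report: dict = {"task": "deconvolve", "n_spots": ds.n_spots, "n_cells": len(ref_cells)}
    if ref_labels is None:
        logger.warning("reference has no annotations; mapping matrix produced, transfer skipped")
        report["annotation_transfer"] = "skipped (no labels)"
    else:
        with _stage("deconvolve/transfer"):
            annot = AnnotationMatrix.from_labels(ref_labels)
            P_spot = annotations_to_spots(mapping, annot, top_frac=cfg.top_frac)
            pd.DataFrame(P_spot, index=ds.spot_ids, columns=annot.label_names).to_csv(
                out / "P_spot.tsv", sep="\t"
            )
            if ds.truth_labels is not None:
                S_spot = AnnotationMatrix.from_labels(ds.truth_labels)
                P_dom = annotations_to_domains(P_spot, S_spot)
                pd.DataFrame(P_dom, index=S_spot.label_names, columns=annot.label_names).to_csv(
                    out / "P_domain.tsv", sep="\t"
                )
    (out / "report.json").write_text(json.dumps(report, indent=2))
    _write_manifest(cfg, out, {"task": "deconvolve"})
    return report


def run_simulate(cfg: RunConfig, spec: Optional[FixtureSpec] = None) -> Path:
    """Write a domain-slide fixture as MTX + coords CSV + truth TSV, exercising
    the reader path end to end."""
    import scipy.io
    import scipy.sparse as sp

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = spec or FixtureSpec(seed=_stage_seed(cfg.seed, "fixture"))
    ds = simulate_domain_slide(spec)
    scipy.io.mmwrite(str(out / "matrix.mtx"), sp.csr_matrix(ds.counts.T))
    (out / "barcodes.tsv").write_text("\n".join(ds.spot_ids) + "\n")
    (out / "features.tsv").write_text("\n".join(ds.gene_ids) + "\n")
    pd.DataFrame(
        {"spot_id": ds.spot_ids, "x": ds.coords[:, 0], "y": ds.coords[:, 1]}
    ).to_csv(out / "coords.csv", index=False)
    pd.DataFrame({"spot_id": ds.spot_ids, "domain": ds.truth_labels}).to_csv(
        out / "truth.tsv", sep="\t", index=False
    )
    _write_manifest(cfg, out, {"task": "simulate", "fixture": dataclasses.asdict(spec)})
    return out
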