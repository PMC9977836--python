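"""Reading spatial / single-cell expression data and standard preprocessing.

The preprocessing pipeline is the scanpy convention: library-size
normalization to a fixed target sum, log1p, highly-variable-gene selection
(Seurat-flavor normalized dispersion), and per-gene z-scaling. Raw counts
come in as MatrixMarket triplet directories (10x layout), dense CSV/TSV, or
h5ad containers with coordinates in ``obsm["spatial"]``.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

# anndata emits chatty ImplicitModificationWarnings on plain attribute writes
warnings.filterwarnings("ignore", module="anndata")


def _dedupe_gene_ids(gene_ids: Sequence[str]) -> list[str]:
    """Resolve duplicate gene names first-wins, suffixing later copies ``name.1``, ``name.2``, ..."""
    seen: dict[str, int] = {}
    out = []
    for g in gene_ids:
        g = str(g)
        if g in seen:
            seen[g] += 1
            out.append(f"{g}.{seen[g]}")
        else:
            seen[g] = 0
            out.append(g)
    return out


@dataclass
class SpatialDataset:
    """Spot-level expression with 2-D coordinates.

    Attributes
    ----------
    counts
        Non-negative (spots x genes) raw count matrix, dense float64.
    gene_ids, spot_ids
        Axis labels; duplicate gene ids are deduplicated by numeric suffixing.
    coords
        (spots x 2) coordinates in platform units, row-aligned with counts.
    batch
        Optional per-spot slice label (multi-slice data).
    truth_labels
        Optional per-spot ground-truth domain label (fixtures / benchmarks).
    """

    counts: np.ndarray
    gene_ids: list[str]
    spot_ids: list[str]
    coords: np.ndarray
    batch: Optional[np.ndarray] = None
    truth_labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (spots x genes)")
        if np.any(self.counts < 0):
            raise ValueError("counts has negative entries")
        n_spot, n_gene = self.counts.shape
        if self.coords.shape != (n_spot, 2):
            raise ValueError(
                f"coords shape {self.coords.shape} does not align with counts ({n_spot} spots)"
            )
        if len(self.gene_ids) != n_gene:
            raise ValueError("gene_ids length does not match counts columns")
        if len(self.spot_ids) != n_spot:
            raise ValueError("spot_ids length does not match counts rows")
        self.gene_ids = _dedupe_gene_ids(self.gene_ids)
        self.spot_ids = [str(s) for s in self.spot_ids]
        zero_rows = np.flatnonzero(self.counts.sum(axis=1) == 0)
        if zero_rows.size:
            logger.info(
                "retaining %d all-zero spot(s): %s",
                zero_rows.size,
                [self.spot_ids[i] for i in zero_rows[:10]],
            )

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]


@dataclass
class FeatureMatrix:
    """Processed (items x features) matrix with the per-gene scaling record."""

    values: np.ndarray
    feature_ids: list[str]
    item_ids: list[str]
    scaling_stats: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)

    @property
    def n_items(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def _read_table(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def _read_coords_csv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"spot_id", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"coordinate file {path} must have columns spot_id,x,y")
    return df.set_index(df["spot_id"].astype(str))


def _align_coords(spot_ids: list[str], coord_df: pd.DataFrame) -> np.ndarray:
    missing = [s for s in spot_ids if s not in coord_df.index]
    if missing:
        raise ValueError(
            f"{len(missing)} spot(s) lack coordinates: {missing[:10]}"
            + ("..." if len(missing) > 10 else "")
        )
    return coord_df.loc[spot_ids, ["x", "y"]].to_numpy(dtype=np.float64)


def _find_one(directory: Path, stems: Sequence[str]) -> Path:
    for stem in stems:
        for cand in (directory / stem, directory / f"{stem}.gz"):
            if cand.exists():
                return cand
    raise FileNotFoundError(f"none of {stems} found in {directory}")


def _read_tsv_column(path: Path, col: int = 0) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [line.rstrip("\n").split("\t")[col] for line in fh if line.strip()]


def read_spatial_dataset(
    path: str | Path,
    format: str = "mtx_dir",
    coords: Optional[str | Path] = None,
) -> SpatialDataset:
    """Read a :class:`SpatialDataset` from disk.

    Parameters
    ----------
    path
        ``mtx_dir``: directory holding ``matrix.mtx[.gz]``, ``barcodes.tsv``,
        ``features.tsv`` (10x convention, genes as rows) and a ``coords.csv``
        sidecar with columns ``spot_id,x,y`` (optionally ``truth.tsv`` with
        per-spot domain labels). ``csv``: dense spots x genes table with spot
        ids as index and gene ids as header; coordinates come from the
        ``coords`` sidecar argument (default ``<stem>.coords.csv``).
        ``h5ad``: anndata container with coordinates in ``obsm["spatial"]``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    if format == "mtx_dir":
        mtx = _find_one(path, ["matrix.mtx"])
        barcodes = _read_tsv_column(_find_one(path, ["barcodes.tsv"]))
        features = _read_tsv_column(_find_one(path, ["features.tsv", "genes.tsv"]))
        mat = scipy.io.mmread(str(mtx))
        mat = sp.coo_matrix(mat).T.tocsr()  # genes-as-rows -> spots x genes
        if mat.shape[0] != len(barcodes):
            raise ValueError(
                f"matrix has {mat.shape[0]} columns(spots) but {len(barcodes)} barcodes listed"
            )
        if mat.shape[1] != len(features):
            raise ValueError(
                f"matrix has {mat.shape[1]} rows(genes) but {len(features)} features listed"
            )
        counts = np.asarray(mat.todense(), dtype=np.float64)
        coord_df = _read_coords_csv(path / "coords.csv")
        xy = _align_coords(barcodes, coord_df)
        truth = None
        truth_path = path / "truth.tsv"
        if truth_path.exists():
            tdf = pd.read_csv(truth_path, sep="\t", index_col=0)
            truth = tdf.iloc[:, 0].reindex(barcodes).to_numpy()
        return SpatialDataset(counts, features, barcodes, xy, truth_labels=truth)

    if format == "csv":
        expr = _read_table(path)
        coord_path = Path(coords) if coords is not None else path.with_suffix(".coords.csv")
        if not coord_path.exists():
            raise FileNotFoundError(f"coordinate sidecar {coord_path} not found")
        coord_df = _read_coords_csv(coord_path)
        spot_ids = [str(s) for s in expr.index]
        xy = _align_coords(spot_ids, coord_df)
        return SpatialDataset(
            expr.to_numpy(dtype=np.float64), list(expr.columns), spot_ids, xy
        )

    if format == "h5ad":
        adata = ad.read_h5ad(path)
        if "spatial" not in adata.obsm:
            raise ValueError(
                f"h5ad file {path} lacks obsm['spatial'] coordinates for spots "
                f"{list(adata.obs_names[:5])}..."
            )
        X = adata.X
        counts = np.asarray(X.todense() if sp.issparse(X) else X, dtype=np.float64)
        batch = adata.obs["batch"].to_numpy() if "batch" in adata.obs else None
        truth = adata.obs["domain"].to_numpy() if "domain" in adata.obs else None
        return SpatialDataset(
            counts,
            list(adata.var_names),
            list(adata.obs_names),
            np.asarray(adata.obsm["spatial"], dtype=np.float64),
            batch=batch,
            truth_labels=truth,
        )

    raise ValueError(f"unknown format {format!r}; expected mtx_dir, csv or h5ad")


def write_h5ad(ds: SpatialDataset, path: str | Path) -> None:
    """Write a dataset to h5ad with coordinates under ``obsm["spatial"]``."""
    adata = ad.AnnData(
        X=ds.counts.copy(),
        obs=pd.DataFrame(index=pd.Index(ds.spot_ids, name="spot_id")),
        var=pd.DataFrame(index=pd.Index(ds.gene_ids, name="gene_id")),
    )
    adata.obsm["spatial"] = ds.coords.copy()
    if ds.batch is not None:
        adata.obs["batch"] = pd.Categorical(ds.batch)
    if ds.truth_labels is not None:
        adata.obs["domain"] = pd.Categorical(ds.truth_labels)
    adata.write_h5ad(Path(path))


def lognormalize(ds: SpatialDataset, target_sum: float = 1e4) -> np.ndarray:
    """Library-size normalize each spot to ``target_sum`` then log1p.

    Rows with zero raw counts stay zero. This is the first half of
    :func:`normalize_select_scale`, exposed for reuse and inspection.
    """
    adata = ad.AnnData(
        X=ds.counts.astype(np.float64).copy(),
        obs=pd.DataFrame(index=pd.Index(ds.spot_ids, name="spot_id")),
        var=pd.DataFrame(index=pd.Index(ds.gene_ids, name="gene_id")),
    )
    sc.pp.normalize_total(adata, target_sum=target_sum)
    sc.pp.log1p(adata)
    return np.asarray(adata.X, dtype=np.float64)


def normalize_select_scale(
    ds: SpatialDataset,
    n_hvg: int = 3000,
    target_sum: float = 1e4,
) -> FeatureMatrix:
    """normalize(target_sum) -> log1p -> top-``n_hvg`` HVGs -> per-gene z-scale.

    Zero-variance genes are dropped before scaling. The fitted per-gene
    mean/std are recorded in ``scaling_stats`` so reference data can be put
    on the same scale.
    """
    if n_hvg < 1:
        raise ValueError("n_hvg must be >= 1")
    if ds.n_spots < 2:
        raise ValueError("need at least 2 spots")

    adata = ad.AnnData(
        X=lognormalize(ds, target_sum=target_sum),
        obs=pd.DataFrame(index=pd.Index(ds.spot_ids, name="spot_id")),
        var=pd.DataFrame(index=pd.Index(ds.gene_ids, name="gene_id")),
    )
    adata.uns["log1p"] = {"base": None}

    X = np.asarray(adata.X, dtype=np.float64)
    var = X.var(axis=0)
    keep = var > 0
    if keep.sum() < 2:
        raise ValueError("fewer than 2 genes with nonzero variance (all genes constant?)")
    adata = adata[:, keep].copy()

    n_top = int(min(n_hvg, adata.n_vars))
    sc.pp.highly_variable_genes(adata, flavor="seurat", n_top_genes=n_top)
    adata = adata[:, adata.var["highly_variable"].to_numpy()].copy()

    X = np.asarray(adata.X, dtype=np.float64)
    mean = X.mean(axis=0)
    std = X.std(axis=0)  # zero-variance columns already excluded
    X = (X - mean) / std
    return FeatureMatrix(
        values=X,
        feature_ids=list(adata.var_names),
        item_ids=list(adata.obs_names),
        scaling_stats={"mean": mean, "std": std, "target_sum": float(target_sum)},
    )


def intersect_genes(st: FeatureMatrix, sc_fm: FeatureMatrix) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Restrict two preprocessed matrices to their shared genes, ordered as in ``st``."""
    sc_set = set(sc_fm.feature_ids)
    shared = [g for g in st.feature_ids if g in sc_set]
    if not shared:
        raise ValueError(
            "empty gene intersection between inputs; "
            f"first genes were {st.feature_ids[:5]} vs {sc_fm.feature_ids[:5]}"
        )
    st_idx = [st.feature_ids.index(g) for g in shared]
    sc_pos = {g: i for i, g in enumerate(sc_fm.feature_ids)}
    sc_idx = [sc_pos[g] for g in shared]

    def _restrict(fm: FeatureMatrix, idx: list[int]) -> FeatureMatrix:
        stats = dict(fm.scaling_stats)
        for key in ("mean", "std"):
            if key in stats:
                stats[key] = np.asarray(stats[key])[idx]
        return FeatureMatrix(fm.values[:, idx], list(shared), list(fm.item_ids), stats)

    return _restrict(st, st_idx), _restrict(sc_fm, sc_idx)
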