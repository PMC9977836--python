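"""Seed-reproducible synthetic datasets with the statistical structure the
method assumes: contiguous spatial domains with marker-driven expression,
replicate slices with additive batch shifts, and spots formed as known
mixtures of reference cells with spatially autocorrelated proportions.

The generative model is log-linear: each gene has a baseline log-mean, the
markers of a domain (disjoint across domains) get an additive shift of
``effect_size`` in log space, and counts are drawn either log-normally
("gaussian" noise, sigma = 1 in log space) or from a negative binomial
(gamma-Poisson, dispersion 0.3) around the log-mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .deconvolution import AnnotationMatrix
from .preprocess import SpatialDataset

GAUSSIAN_SIGMA = 1.0  # log-space noise SD for the "gaussian" model
NB_DISPERSION = 0.3  # negative-binomial dispersion (1/size)
BASELINE_LOG_MEAN = 1.5
BASELINE_LOG_SD = 0.4


@dataclass
class FixtureSpec:
    """Study conditions for the domain-slide fixtures.

    Defaults: a 32 x 32 grid split into 4 contiguous quadrant domains, 500
    genes of which each domain elevates 30 disjoint markers by one
    log-space noise SD (effect_size = 1.0).
    """

    grid: tuple[int, int] = (32, 32)
    n_domains: int = 4
    n_genes: int = 500
    n_marker_per_domain: int = 30
    effect_size: float = 1.0
    noise_model: str = "gaussian"
    batch_shift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_domains < 2:
            raise ValueError("n_domains must be >= 2")
        if self.n_domains * self.n_marker_per_domain > self.n_genes:
            raise ValueError("marker sets must be disjoint: too few genes")
        if self.noise_model not in {"gaussian", "negative_binomial"}:
            raise ValueError("noise_model must be 'gaussian' or 'negative_binomial'")
        if self.grid[0] * self.grid[1] < self.n_domains:
            raise ValueError("more domains than spots")


def _domain_layout(grid: tuple[int, int], n_domains: int) -> np.ndarray:
    """Contiguous rectangular partition: rows x cols band product closest to
    square, falling back to column stripes for prime counts."""
    rows, cols = grid
    a = max(d for d in range(1, int(math.isqrt(n_domains)) + 1) if n_domains % d == 0)
    b = n_domains // a
    row_band = np.minimum((np.arange(rows) * a) // rows, a - 1)
    col_band = np.minimum((np.arange(cols) * b) // cols, b - 1)
    return (row_band[:, None] * b + col_band[None, :]).ravel()


def _grid_coords(grid: tuple[int, int]) -> np.ndarray:
    rows, cols = grid
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return np.column_stack([cc.ravel(), rr.ravel()]).astype(np.float64)


def _marker_matrix(spec: FixtureSpec) -> np.ndarray:
    """(n_domains x n_genes) additive log-mean shifts; markers disjoint."""
    shifts = np.zeros((spec.n_domains, spec.n_genes))
    for d in range(spec.n_domains):
        lo = d * spec.n_marker_per_domain
        shifts[d, lo : lo + spec.n_marker_per_domain] = spec.effect_size
    return shifts


def _draw_counts(
    log_mean: np.ndarray, noise_model: str, rng: np.random.Generator
) -> np.ndarray:
    if noise_model == "gaussian":
        x = np.exp(log_mean + rng.normal(0.0, GAUSSIAN_SIGMA, size=log_mean.shape))
        return np.round(x)
    mu = np.exp(log_mean)
    lam = rng.gamma(shape=1.0 / NB_DISPERSION, scale=mu * NB_DISPERSION)
    return rng.poisson(lam).astype(np.float64)


def simulate_domain_slide(spec: FixtureSpec) -> SpatialDataset:
    """One slide on a grid of spots partitioned into contiguous domains."""
    rng = np.random.default_rng(spec.seed)
    labels = _domain_layout(spec.grid, spec.n_domains)
    coords = _grid_coords(spec.grid)
    baseline = rng.normal(BASELINE_LOG_MEAN, BASELINE_LOG_SD, size=spec.n_genes)
    shifts = _marker_matrix(spec)
    log_mean = baseline[None, :] + shifts[labels]
    counts = _draw_counts(log_mean, spec.noise_model, rng)
    n = counts.shape[0]
    return SpatialDataset(
        counts=counts,
        gene_ids=[f"g{j:04d}" for j in range(spec.n_genes)],
        spot_ids=[f"s{i:04d}" for i in range(n)],
        coords=coords,
        truth_labels=labels.copy(),
    )


def simulate_replicate_slices(spec: FixtureSpec, n_slices: int = 2) -> list[SpatialDataset]:
    """Replicate slices sharing the domain layout and gene programs, with
    independent noise and an additive per-slice per-gene log-space offset of
    scale ``spec.batch_shift``."""
    if n_slices < 2:
        raise ValueError("n_slices must be >= 2")
    master = np.random.default_rng(spec.seed)
    labels = _domain_layout(spec.grid, spec.n_domains)
    coords = _grid_coords(spec.grid)
    baseline = master.normal(BASELINE_LOG_MEAN, BASELINE_LOG_SD, size=spec.n_genes)
    shifts = _marker_matrix(spec)
    log_mean = baseline[None, :] + shifts[labels]

    slices = []
    for s in range(n_slices):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, s + 1]))
        offset = rng.normal(0.0, spec.batch_shift, size=spec.n_genes) if spec.batch_shift else 0.0
        counts = _draw_counts(log_mean + offset, spec.noise_model, rng)
        n = counts.shape[0]
        slices.append(
            SpatialDataset(
                counts=counts,
                gene_ids=[f"g{j:04d}" for j in range(spec.n_genes)],
                spot_ids=[f"s{i:04d}" for i in range(n)],
                coords=coords.copy(),
                batch=np.asarray([f"slice{s}"] * n),
                truth_labels=labels.copy(),
            )
        )
    return slices


@dataclass
class CellReference:
    """Single-cell reference: counts with per-cell type labels (no coordinates)."""

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    labels: np.ndarray
    type_names: list[str] = field(default_factory=list)

    def annotation_matrix(self) -> AnnotationMatrix:
        return AnnotationMatrix.from_labels(self.labels, self.type_names)


def simulate_reference_and_spots(
    n_types: int = 5,
    cells_per_type: int = 60,
    n_spots: int = 100,
    dirichlet_alpha: Optional[np.ndarray] = None,
    spot_cell_count: int = 10,
    n_genes: int = 200,
    n_marker_per_type: int = 20,
    effect_size: float = 2.0,
    cell_noise_sd: float = 0.5,
    blend: float = 0.5,
    seed: int = 0,
) -> tuple[CellReference, AnnotationMatrix, SpatialDataset, np.ndarray]:
    """Reference cells drawn from per-type programs plus spots built as
    known cell mixtures.

    Each type elevates ``n_marker_per_type`` disjoint marker genes by
    ``effect_size`` in log space; cells add log-normal noise of SD
    ``cell_noise_sd``. Spot mixture weights are drawn from
    Dirichlet(``dirichlet_alpha``, default all-ones) on a square grid and
    then blended with the mean of their 4-neighbors (weight ``blend``) so
    neighboring spots have similar compositions — the locality the method
    assumes. Each spot sums the counts of ``spot_cell_count`` reference
    cells sampled per its weights; the returned truth matrix holds the
    realized per-spot type fractions.
    """
    if dirichlet_alpha is None:
        dirichlet_alpha = np.ones(n_types)
    dirichlet_alpha = np.asarray(dirichlet_alpha, dtype=np.float64)
    if dirichlet_alpha.shape != (n_types,):
        raise ValueError("dirichlet_alpha must have length n_types")
    if n_types * n_marker_per_type > n_genes:
        raise ValueError("marker sets must be disjoint: too few genes")

    rng = np.random.default_rng(seed)
    baseline = rng.normal(BASELINE_LOG_MEAN, BASELINE_LOG_SD, size=n_genes)
    programs = np.zeros((n_types, n_genes))
    for t in range(n_types):
        lo = t * n_marker_per_type
        programs[t, lo : lo + n_marker_per_type] = effect_size

    n_cells = n_types * cells_per_type
    cell_types = np.repeat(np.arange(n_types), cells_per_type)
    log_mean = baseline[None, :] + programs[cell_types]
    cell_counts = np.round(
        np.exp(log_mean + rng.normal(0.0, cell_noise_sd, size=(n_cells, n_genes)))
    )
    type_names = [f"type{t}" for t in range(n_types)]
    ref = CellReference(
        counts=cell_counts,
        gene_ids=[f"g{j:04d}" for j in range(n_genes)],
        cell_ids=[f"c{i:04d}" for i in range(n_cells)],
        labels=np.asarray([type_names[t] for t in cell_types]),
        type_names=type_names,
    )
    annot = ref.annotation_matrix()

    # spot grid and spatially blended Dirichlet weights
    side = int(math.ceil(math.sqrt(n_spots)))
    coords = _grid_coords((side, side))[:n_spots]
    W = rng.dirichlet(dirichlet_alpha, size=n_spots)
    nbr_means = np.zeros_like(W)
    for i in range(n_spots):
        d = np.abs(coords - coords[i]).sum(axis=1)
        nbrs = np.flatnonzero(d == 1)
        nbr_means[i] = W[nbrs].mean(axis=0) if nbrs.size else W[i]
    W = (1.0 - blend) * W + blend * nbr_means  # rows still sum to 1

    spot_counts = np.zeros((n_spots, n_genes))
    true_props = np.zeros((n_spots, n_types))
    cells_by_type = [np.flatnonzero(cell_types == t) for t in range(n_types)]
    for i in range(n_spots):
        drawn = rng.choice(n_types, size=spot_cell_count, p=W[i])
        for t in drawn:
            cell = rng.choice(cells_by_type[t])
            spot_counts[i] += cell_counts[cell]
        true_props[i] = np.bincount(drawn, minlength=n_types) / spot_cell_count

    spots = SpatialDataset(
        counts=spot_counts,
        gene_ids=list(ref.gene_ids),
        spot_ids=[f"s{i:04d}" for i in range(n_spots)],
        coords=coords,
    )
    return ref, annot, spots, true_props
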