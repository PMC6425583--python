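"""Count-matrix preprocessing and PCA representation.

The recipe is the standard scRNA-seq one: filter cells/genes, total-count
normalize each cell to a common target, log1p, restrict to highly variable
genes ranked by normalized dispersion, optionally z-scale genes with
clipping, then PCA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA


class EmptyAfterFilteringError(ValueError):
    """All cells (or genes) were removed by the filtering step."""


@dataclass
class CountMatrix:
    """A cells x genes expression matrix with string ids.

    ``values`` may hold raw non-negative counts or, after preprocessing,
    real-valued normalized expression.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression matrix must be 2-D")
        if not np.issubdtype(self.values.dtype, np.number) or not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix must be numeric and finite")
        n, g = self.values.shape
        if len(self.cell_ids) != n or len(self.gene_ids) != g:
            raise ValueError("id lists inconsistent with matrix shape")
        if len(set(self.cell_ids)) != n or len(set(self.gene_ids)) != g:
            raise ValueError("cell and gene ids must be unique")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class Representation:
    """Low-dimensional coordinates of cells (one row per cell)."""

    coords: np.ndarray
    basis_name: str = "pca"
    cell_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("representation coordinates must be finite")

    @property
    def n_comps(self) -> int:
        return self.coords.shape[1]


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing recipe.

    target_sum=None uses the median of per-cell totals (after filtering).
    n_top_genes=None keeps all genes; scale=False skips z-scaling.
    """

    min_genes: int = 1
    min_cells: int = 1
    target_sum: float | None = None
    n_top_genes: int | None = 1000
    scale: bool = True
    clip: float = 10.0
    normalize: bool = True
    log1p: bool = True
    n_bins: int = 20


def normalized_dispersion(values: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Dispersion (variance/mean) of each gene, z-scored within mean bins.

    Genes are binned by mean expression; within each bin the dispersion is
    standardized so that highly variable genes can be ranked across the
    whole dynamic range.  Degenerate bins (single gene, zero spread) get a
    z-score of 0 for that gene.
    """
    mean = values.mean(axis=0)
    var = values.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
    # bin on mean expression; quantile bins are robust to skewed means
    edges = np.quantile(mean, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if len(edges) < 2:
        bins = np.zeros(len(mean), dtype=int)
    else:
        bins = np.clip(np.searchsorted(edges, mean, side="right") - 1, 0, len(edges) - 2)
    z = np.zeros_like(disp)
    for b in np.unique(bins):
        m = bins == b
        mu, sd = disp[m].mean(), disp[m].std()
        z[m] = (disp[m] - mu) / sd if sd > 0 else 0.0
    return z


def preprocess_counts(counts: CountMatrix, config: PreprocessConfig | None = None) -> CountMatrix:
    """Filter, normalize, log-transform and select highly variable genes.

    Returns a new :class:`CountMatrix`; the input is left untouched.

    Raises
    ------
    EmptyAfterFilteringError
        If no cell (or no gene) survives the min_genes / min_cells filters.
    """
    cfg = config or PreprocessConfig()
    x = counts.values
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")

    cell_mask = (x > 0).sum(axis=1) >= cfg.min_genes
    if not cell_mask.any():
        raise EmptyAfterFilteringError("no cells left after filtering (min_genes=%d)" % cfg.min_genes)
    x = x[cell_mask]
    gene_mask = (x > 0).sum(axis=0) >= cfg.min_cells
    if not gene_mask.any():
        raise EmptyAfterFilteringError("no genes left after filtering (min_cells=%d)" % cfg.min_cells)
    x = x[:, gene_mask]
    cell_ids = [c for c, m in zip(counts.cell_ids, cell_mask) if m]
    gene_ids = [g for g, m in zip(counts.gene_ids, gene_mask) if m]

    if cfg.normalize:
        totals = x.sum(axis=1)
        if np.any(totals == 0):
            raise EmptyAfterFilteringError("cells with zero total counts survive filtering; raise min_genes")
        target = cfg.target_sum if cfg.target_sum is not None else float(np.median(totals))
        x = x * (target / totals)[:, None]
    if cfg.log1p:
        x = np.log1p(x)

    if cfg.n_top_genes is not None and cfg.n_top_genes < x.shape[1]:
        z = normalized_dispersion(x, n_bins=cfg.n_bins)
        # stable ranking: ties broken by lower gene index
        order = np.lexsort((np.arange(len(z)), -z))
        keep = np.sort(order[: cfg.n_top_genes])
        x = x[:, keep]
        gene_ids = [gene_ids[i] for i in keep]

    if cfg.scale:
        mu = x.mean(axis=0)
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        x = np.clip((x - mu) / sd, -cfg.clip, cfg.clip)

    return CountMatrix(values=x, cell_ids=cell_ids, gene_ids=gene_ids)


def compute_representation(
    counts: CountMatrix, n_comps: int = 50, seed: int = 0, center: bool = True
) -> Representation:
    """Principal-component scores of the (preprocessed) expression matrix.

    Uses a full deterministic SVD; component signs are fixed by requiring
    the entry of largest magnitude in each loading vector to be positive,
    so results are reproducible across runs.
    """
    n, g = counts.values.shape
    if not 1 <= n_comps < min(n, g):
        raise ValueError(f"n_comps must be in [1, min(cells, genes)) = [1, {min(n, g)})")
    pca = PCA(n_components=n_comps, svd_solver="full", random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scores = pca.fit_transform(counts.values if center else counts.values - 0.0)
    # deterministic sign convention
    comps = pca.components_
    signs = np.sign(comps[np.arange(comps.shape[0]), np.argmax(np.abs(comps), axis=1)])
    signs[signs == 0] = 1.0
    scores = scores * signs[None, :]
    return Representation(coords=scores, basis_name="pca", cell_ids=list(counts.cell_ids))
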