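"""UMAP projection, DBSCAN clustering, and marker-based cell typing.

Stage 1 embeds the full (filtered) expression matrix, projects it to 2-D
with UMAP, clusters the projection with DBSCAN, and assigns a cell type to
each cluster from lineage-marker expression.  Stage 2 repeats the whole
embed/project/cluster chain per cell type on the chromatin-panel-restricted
matrix, yielding within-type subclusters (CM1, CM2, ..., FB1, ...).

DBSCAN runs on the 2-D UMAP coordinates by default (pass the 10-D embedding
to :func:`cluster_density` to cluster in latent space instead).  When no
``eps`` is given it is set per-run to the 90th percentile of each point's
distance to its ``min_samples``-th neighbour — a scale-adaptive default.
Noise cells keep the reserved label -1 and are excluded from marker testing
and composition denominators downstream.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import umap
from sklearn.cluster import DBSCAN
from sklearn.neighbors import NearestNeighbors

from .embedding import (
    EmbeddingMatrix,
    NormalizedMatrix,
    encode,
    filter_rare_genes,
    normalize,
    train_autoencoder,
)
from .gene_panel import GenePanel, restrict_to_panel
from .io_formats import CellAnnotation, ExpressionMatrix

logger = logging.getLogger(__name__)

NOISE = -1

#: Short prefixes used to namespace within-type subclusters in outputs.
TYPE_PREFIXES = {
    "cardiomyocyte": "CM",
    "fibroblast": "FB",
    "endothelial": "EC",
    "smooth_muscle": "SMC",
    "macrophage": "MP",
    "lymphocyte": "LC",
}


@dataclass
class Projection2D:
    """2-D UMAP layout, row-aligned to the source embedding."""

    values: np.ndarray
    cell_ids: list[str]
    seed: int
    n_neighbors: int
    min_dist: float

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.cell_ids), 2):
            raise ValueError("projection must be cells x 2")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("projection contains non-finite coordinates")


@dataclass
class ClusterLabels:
    """Per-cell integer cluster assignment; -1 is reserved for DBSCAN noise."""

    labels: np.ndarray
    cell_ids: list[str]
    eps: float
    min_samples: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.cell_ids),):
            raise ValueError("labels not aligned to cell ids")
        if self.labels.size and self.labels.min() < NOISE:
            raise ValueError("labels below the reserved noise value -1")

    @property
    def n_clusters(self) -> int:
        return int(len(set(self.labels) - {NOISE}))

    @property
    def n_noise(self) -> int:
        return int(np.sum(self.labels == NOISE))

    def cluster_ids(self) -> list[int]:
        return sorted(set(self.labels) - {NOISE})


def subcluster_name(cell_type: str, label: int) -> str:
    prefix = TYPE_PREFIXES.get(
        cell_type, "".join(w[0].upper() for w in cell_type.split("_"))
    )
    return f"{prefix}_noise" if label == NOISE else f"{prefix}{label + 1}"


def project_umap(
    embedding: EmbeddingMatrix,
    seed: int = 0,
    n_neighbors: int = 30,
    min_dist: float = 0.3,
) -> Projection2D:
    """2-D UMAP layout of the embedding; reproducible for a fixed seed."""
    n = embedding.values.shape[0]
    if n < 3:
        raise ValueError(f"UMAP needs at least 3 cells, got {n}")
    eff_neighbors = min(n_neighbors, n - 1)
    if eff_neighbors != n_neighbors:
        logger.warning(
            "n_neighbors=%d >= n_cells=%d; clipped to %d", n_neighbors, n, eff_neighbors
        )
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=eff_neighbors,
        min_dist=min_dist,
        random_state=seed,
    )
    coords = reducer.fit_transform(embedding.values)
    return Projection2D(
        np.asarray(coords, dtype=float), list(embedding.cell_ids),
        seed=seed, n_neighbors=eff_neighbors, min_dist=min_dist,
    )


def default_eps(points: np.ndarray, min_samples: int) -> float:
    """90th percentile of each point's distance to its min_samples-th neighbour."""
    k = min(min_samples, points.shape[0] - 1)
    if k < 1:
        return 1.0
    nn = NearestNeighbors(n_neighbors=k + 1).fit(points)
    dist, _ = nn.kneighbors(points)
    return float(np.quantile(dist[:, k], 0.90))


def _renumber_by_size(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 0,1,... by descending size (noise stays -1)."""
    out = np.full_like(labels, NOISE)
    ids, counts = np.unique(labels[labels != NOISE], return_counts=True)
    order = ids[np.lexsort((ids, -counts))]
    for new, old in enumerate(order):
        out[labels == old] = new
    return out


def cluster_density(
    points: Projection2D | EmbeddingMatrix | np.ndarray,
    eps: float | None = None,
    min_samples: int = 10,
) -> ClusterLabels:
    """DBSCAN with standard core/border/noise semantics.

    Cluster ids are renumbered by descending size, so label 0 is always the
    largest cluster.  ``eps=None`` invokes the scale-adaptive default.
    """
    if isinstance(points, (Projection2D, EmbeddingMatrix)):
        X, cell_ids = points.values, list(points.cell_ids)
    else:
        X = np.asarray(points, dtype=float)
        cell_ids = [str(i) for i in range(X.shape[0])]
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    if eps is None:
        eps = default_eps(X, min_samples)
        logger.info("DBSCAN eps defaulted to %.4g", eps)
    if eps <= 0:
        raise ValueError("eps must be positive")
    raw = DBSCAN(eps=eps, min_samples=min_samples).fit(X).labels_
    labels = _renumber_by_size(raw)
    return ClusterLabels(labels, cell_ids, eps=float(eps), min_samples=min_samples)


@dataclass
class CellTypeAssignment:
    """Cluster -> cell type calls with the z-score evidence behind them."""

    types: dict[int, str]
    margins: dict[int, float]
    scores: "np.ndarray" = field(repr=False, default=None)
    score_index: tuple = field(repr=False, default=())

    def cell_types(self, labels: ClusterLabels) -> np.ndarray:
        """Per-cell type array (noise cells -> 'noise')."""
        return np.array(
            [self.types.get(l, "noise") if l != NOISE else "noise" for l in labels.labels]
        )


def assign_cell_types(
    normalized: NormalizedMatrix,
    labels: ClusterLabels,
    marker_map: dict[str, tuple[str, ...]],
) -> CellTypeAssignment:
    """Type each cluster by lineage-marker expression.

    For every cluster, each candidate type is scored as the mean (over its
    markers present in the matrix) of the cluster-mean expression z-scored
    across clusters; the argmax wins.  Ties break lexicographically on the
    type name, with a logged warning.  Markers absent from the matrix are
    dropped with a warning; a type with no present marker is excluded.
    """
    cluster_ids = labels.cluster_ids()
    if not cluster_ids:
        raise ValueError("no non-noise clusters to type")
    gene_pos = {g: i for i, g in enumerate(normalized.gene_symbols)}

    # cluster-mean expression per gene, then z-score each gene across clusters
    means = np.zeros((len(gene_pos), len(cluster_ids)))
    for j, cid in enumerate(cluster_ids):
        mask = labels.labels == cid
        means[:, j] = normalized.values[:, mask].mean(axis=1)
    mu = means.mean(axis=1, keepdims=True)
    sd = means.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (means - mu) / sd, 0.0)

    type_scores: dict[str, np.ndarray] = {}
    for ctype, markers in marker_map.items():
        present = [m for m in markers if m in gene_pos]
        absent = [m for m in markers if m not in gene_pos]
        if absent:
            logger.warning("markers %s for %s absent from matrix", absent, ctype)
        if not present:
            logger.warning("cell type %s has no present markers; excluded", ctype)
            continue
        type_scores[ctype] = z[[gene_pos[m] for m in present], :].mean(axis=0)
    if not type_scores:
        raise ValueError("no cell type has any marker present in the matrix")

    type_names = sorted(type_scores)
    score_mat = np.vstack([type_scores[t] for t in type_names])
    types: dict[int, str] = {}
    margins: dict[int, float] = {}
    for j, cid in enumerate(cluster_ids):
        col = score_mat[:, j]
        best = int(np.argmax(col))  # argmax takes the first = lexicographic on ties
        ranked = np.sort(col)[::-1]
        margin = float(ranked[0] - ranked[1]) if len(col) > 1 else float("inf")
        if len(col) > 1 and margin == 0.0:
            logger.warning(
                "cluster %d: tied type scores, lexicographic tie-break -> %s",
                cid, type_names[best],
            )
        types[cid] = type_names[best]
        margins[cid] = margin
    return CellTypeAssignment(types, margins, scores=score_mat, score_index=tuple(type_names))


@dataclass
class StageParams:
    """Hyperparameters for one embed -> project -> cluster chain."""

    latent_dim: int = 10
    epochs: int = 500
    learning_rate: float = 0.01
    activation: str = "tanh"
    min_gene_fraction: float = 0.01
    umap_neighbors: int = 30
    umap_min_dist: float = 0.3
    dbscan_eps: float | None = None
    dbscan_min_samples: int = 10
    seed: int = 0


def derive_seed(base_seed: int, stage: str) -> int:
    """Stable per-stage seed: adding a stage never perturbs earlier stages."""
    return (base_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class SubclusterResult:
    """Per-cell-type output of the stage-2 panel-restricted chain."""

    cell_type: str
    labels: ClusterLabels
    embedding: EmbeddingMatrix
    projection: Projection2D
    panel_genes: list[str]


def embed_project_cluster(
    matrix: ExpressionMatrix, params: StageParams
) -> tuple[ClusterLabels, EmbeddingMatrix, Projection2D, NormalizedMatrix]:
    """Run filter -> normalize -> autoencode -> UMAP -> DBSCAN on one matrix."""
    filtered = filter_rare_genes(matrix, params.min_gene_fraction)
    norm = normalize(filtered.matrix)
    model = train_autoencoder(
        norm,
        latent_dim=params.latent_dim,
        epochs=params.epochs,
        learning_rate=params.learning_rate,
        seed=derive_seed(params.seed, "autoencoder"),
        activation=params.activation,
    )
    emb = encode(model, norm)
    proj = project_umap(
        emb,
        seed=derive_seed(params.seed, "umap"),
        n_neighbors=params.umap_neighbors,
        min_dist=params.umap_min_dist,
    )
    labels = cluster_density(proj, eps=params.dbscan_eps, min_samples=params.dbscan_min_samples)
    return labels, emb, proj, norm


def subcluster_by_type(
    matrix: ExpressionMatrix,
    annotation: CellAnnotation,
    panel: GenePanel,
    params: StageParams | None = None,
    cell_types: list[str] | None = None,
) -> dict[str, SubclusterResult]:
    """Stage 2: per-cell-type panel-restricted embedding and subclustering.

    For each cell type (from the annotation's ``cell_type`` column), the
    matrix is restricted to that type's cells and to the chromatin panel,
    then the full filter/normalize/train/encode/project/cluster chain is
    re-run.  Types with fewer cells than ``dbscan_min_samples`` are skipped
    with a warning.  Per-type seeds derive from the global seed and the type
    name, so results for one type are invariant to which other types exist.
    """
    params = params or StageParams()
    ann = annotation.aligned_to(matrix.cell_ids)
    if "cell_type" not in ann.table.columns:
        raise ValueError("annotation lacks a cell_type column; run stage 1 first")
    type_of = ann.column("cell_type")
    results: dict[str, SubclusterResult] = {}
    wanted = cell_types if cell_types is not None else sorted(set(type_of) - {"noise"})
    for ctype in wanted:
        idx = np.flatnonzero(type_of == ctype)
        if idx.size < max(params.dbscan_min_samples, params.latent_dim + 1):
            logger.warning("cell type %s has %d cells; skipped", ctype, idx.size)
            continue
        sub = matrix.subset_cells(idx)
        sub = restrict_to_panel(sub, panel)
        type_params = StageParams(**{**params.__dict__, "seed": derive_seed(params.seed, f"type:{ctype}")})
        labels, emb, proj, _ = embed_project_cluster(sub, type_params)
        logger.info(
            "stage-2 %s: %d cells -> %d subclusters (+%d noise)",
            ctype, idx.size, labels.n_clusters, labels.n_noise,
        )
        results[ctype] = SubclusterResult(
            cell_type=ctype, labels=labels, embedding=emb, projection=proj,
            panel_genes=list(sub.gene_symbols),
        )
    return results
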