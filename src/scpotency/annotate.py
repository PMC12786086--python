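"""Embedding, clustering, and marker-based cell-type assignment.

PCA on the top-variance features (default 100 features, 7 components,
Euclidean geometry), modularity-based community detection on a symmetrised
kNN graph, and an scType-style marker score: per-gene z-scores of
log2(CPM + 1), positive markers down-weighted by how many cell types share
them, negative markers subtracted at full weight, cluster labels assigned by
summed member-cell scores with an "Unknown" fallback when the best score is
weak (below cluster size / 4).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io import MarkerTable
from .qc import ExpressionMatrix


@dataclass
class EmbeddingConfig:
    n_top_features: int = 100
    n_pcs: int = 7
    knn: int = 30
    cluster_resolution: float = 1.0
    seed: int = 0
    unknown_score_divisor: float = 4.0  # scType convention: Unknown below size/4

    def __post_init__(self) -> None:
        if self.n_pcs > self.n_top_features:
            raise ValueError("n_pcs must not exceed n_top_features")
        if self.knn < 2:
            raise ValueError("knn must be >= 2")


def select_top_features(e: ExpressionMatrix, n: int = 100) -> list[str]:
    """The ``n`` genes with highest log2(CPM+1) variance across cells.

    Ties are broken by lexicographic gene id; the transgene feature is never
    selected (it encodes treatment, not cell identity).
    """
    if e.scale != "log2CPM1":
        raise ValueError("feature selection operates on log2(CPM+1) values")
    keep = [i for i, g in enumerate(e.gene_ids) if g != e.transgene_id]
    if n > len(keep):
        raise ValueError(f"requested {n} features but only {len(keep)} genes available")
    var = e.values[keep].var(axis=1, ddof=0)
    order = sorted(range(len(keep)), key=lambda i: (-var[i], e.gene_ids[keep[i]]))
    return [e.gene_ids[keep[i]] for i in order[:n]]


def pca_embed(
    e: ExpressionMatrix, features: list[str], cfg: EmbeddingConfig | None = None
) -> np.ndarray:
    """Centred PCA of cells over the selected features.

    Deterministic up to component sign; the sign is fixed by making each
    component's largest-magnitude gene loading positive.  If the data rank is
    below ``n_pcs`` the returned embedding is truncated with a warning.
    """
    cfg = cfg or EmbeddingConfig()
    if not features:
        raise ValueError("feature list is empty")
    rows = [e.gene_index(g) for g in features]
    x = e.values[rows].T  # cells x features
    n_comp = min(cfg.n_pcs, min(x.shape))
    pca = PCA(n_components=n_comp, svd_solver="full")
    coords = pca.fit_transform(x)
    rank = int(np.sum(pca.explained_variance_ > 1e-12))
    if rank < cfg.n_pcs:
        warnings.warn(
            f"data rank {rank} below requested {cfg.n_pcs} components; truncating",
            stacklevel=2,
        )
        coords = coords[:, :max(rank, 1)]
    # fix component signs: largest-magnitude loading positive
    for j in range(coords.shape[1]):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, j] = -coords[:, j]
    return coords


def cluster_cells(coords: np.ndarray, cfg: EmbeddingConfig | None = None) -> np.ndarray:
    """Leiden community detection on the symmetrised Euclidean kNN graph."""
    cfg = cfg or EmbeddingConfig()
    n = coords.shape[0]
    if n <= cfg.knn:
        raise ValueError(f"need more than knn={cfg.knn} cells, got {n}")
    nn = NearestNeighbors(n_neighbors=cfg.knn + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    edges = {(min(i, j), max(i, j)) for i in range(n) for j in idx[i, 1:]}
    graph = ig.Graph(n=n, edges=sorted(edges))
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=cfg.cluster_resolution,
        seed=cfg.seed,
        n_iterations=2,
    )
    return np.asarray(part.membership, dtype=int)


def score_cell_types(e: ExpressionMatrix, markers: MarkerTable) -> pd.DataFrame:
    """scType-style per-cell type scores on log2(CPM+1) values.

    Per-gene z-scores across cells (zero-variance genes score 0); each
    positive marker is weighted 1 / (number of cell types claiming it);
    negative markers are subtracted unweighted; the per-type sum is scaled by
    sqrt(number of that type's markers present in the matrix).
    """
    if e.scale != "log2CPM1":
        raise ValueError("cell-type scoring operates on log2(CPM+1) values")
    present = set(e.gene_ids)
    entries = markers.entries
    absent = sorted(set(entries["gene"]) - present)
    if absent:
        warnings.warn(f"{len(absent)} marker gene(s) absent from matrix, ignored", stacklevel=2)
    entries = entries[entries["gene"].isin(present)]
    if entries.empty:
        raise ValueError("no marker genes present in the expression matrix")

    genes = sorted(set(entries["gene"]))
    rows = np.array([e.gene_index(g) for g in genes])
    x = e.values[rows]
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    zmap = {g: z[i] for i, g in enumerate(genes)}

    pos = entries[entries["direction"] == "positive"]
    n_types_per_gene = pos.groupby("gene")["cell_type"].nunique()

    scores = {}
    for t in markers.cell_types:
        pos_genes = entries[(entries["cell_type"] == t) & (entries["direction"] == "positive")]["gene"]
        neg_genes = entries[(entries["cell_type"] == t) & (entries["direction"] == "negative")]["gene"]
        total = np.zeros(len(e.cell_barcodes))
        for g in pos_genes:
            total += zmap[g] / n_types_per_gene[g]
        for g in neg_genes:
            total -= zmap[g]
        n_used = len(pos_genes) + len(neg_genes)
        scores[t] = total / np.sqrt(n_used) if n_used else total
    return pd.DataFrame(scores, index=e.cell_barcodes)


def assign_clusters(
    scores: pd.DataFrame,
    clusters: np.ndarray,
    cfg: EmbeddingConfig | None = None,
    overrides: dict[int, str] | None = None,
) -> dict[int, str]:
    """Label each cluster by its summed member-cell type scores.

    A cluster whose best summed score falls below (cluster size / divisor,
    default 4) is labelled "Unknown"; ties break alphabetically.  ``overrides``
    emulates manual re-annotation and wins over the automatic label.
    """
    cfg = cfg or EmbeddingConfig()
    assignment: dict[int, str] = {}
    for c in sorted(set(int(c) for c in clusters)):
        member = scores.iloc[np.flatnonzero(clusters == c)]
        total = member.sum(axis=0)
        best = total.max()
        # alphabetical tie-break via sorted index
        label = min(t for t in total.index if total[t] == best)
        if best < len(member) / cfg.unknown_score_divisor:
            label = "Unknown"
        assignment[c] = label
    if overrides:
        assignment.update({int(k): v for k, v in overrides.items()})
    return assignment


def annotate_cells(
    e: ExpressionMatrix,
    markers: MarkerTable,
    cfg: EmbeddingConfig | None = None,
    overrides: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Full annotation stage: features -> PCA -> clusters -> type labels.

    Returns a per-cell frame (barcode, cluster, cell_type).
    """
    cfg = cfg or EmbeddingConfig()
    features = select_top_features(e, min(cfg.n_top_features, len(e.gene_ids) - 1))
    coords = pca_embed(e, features, cfg)
    clusters = cluster_cells(coords, cfg)
    scores = score_cell_types(e, markers)
    assignment = assign_clusters(scores, clusters, cfg, overrides)
    return pd.DataFrame(
        {
            "barcode": e.cell_barcodes,
            "cluster": clusters,
            "cell_type": [assignment[int(c)] for c in clusters],
        }
    )
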