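"""PCA, section integration, graph clustering, UMAP and marker detection."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .io import NormalizedMatrix

__all__ = [
    "PCAEmbedding",
    "ClusterAssignment",
    "run_pca",
    "integrate_sections",
    "cluster_graph",
    "embed_umap",
    "find_markers",
]


@dataclass
class PCAEmbedding:
    """Spot scores in PC space plus the decomposition itself."""

    coords: np.ndarray                  # (n_spots, k)
    components: np.ndarray              # (k, n_genes) loadings
    explained_variance: np.ndarray      # (k,)
    spot_ids: list[str]
    gene_ids: list[str]
    section_of_spot: list[str] = field(default_factory=list)


def _center_scale(X: np.ndarray, scale: bool) -> np.ndarray:
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = X / sd
    return X


def _fix_signs(U: np.ndarray, Vt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # convention: the largest-magnitude loading of each component is positive
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.abs(Vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    return U * flip, Vt * flip[:, None]


def run_pca(norm: NormalizedMatrix, n_components: int = 20, scale: bool = True) -> PCAEmbedding:
    """PCA of the normalized matrix after per-gene centering (and scaling).

    Components are ordered by decreasing explained variance with a fixed
    sign convention.  If ``n_components`` exceeds the matrix rank it is
    reduced with a warning.
    """
    if n_components > min(norm.n_spots, norm.n_genes):
        raise ValueError("n_components exceeds min(spots, genes)")
    X = _center_scale(norm.values.copy(), scale)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    tol = S.max() * max(X.shape) * np.finfo(float).eps if S.size else 0.0
    rank = int((S > tol).sum())
    k = n_components
    if k > rank:
        warnings.warn(f"n_components={n_components} exceeds rank {rank}; reduced", stacklevel=2)
        k = rank
    U, Vt = _fix_signs(U, Vt)
    coords = U[:, :k] * S[:k]
    ev = (S[:k] ** 2) / max(X.shape[0] - 1, 1)
    return PCAEmbedding(
        coords=coords, components=Vt[:k], explained_variance=ev,
        spot_ids=list(norm.spot_ids), gene_ids=list(norm.gene_ids),
        section_of_spot=[norm.provenance.get("section_id", "section")] * norm.n_spots,
    )


def integrate_sections(norms: list[NormalizedMatrix], n_components: int = 20) -> PCAEmbedding:
    """Joint embedding of several sections over a shared gene universe.

    Each section's genes are centered and unit-scaled independently (a
    simple documented integration scheme, not an anchor-based method), the
    matrices concatenated and decomposed jointly.  Section labels are kept
    so residual separation can be checked downstream.
    """
    if len(norms) < 1:
        raise ValueError("need at least one section")
    ref = norms[0].gene_ids
    for nm in norms[1:]:
        if set(nm.gene_ids) != set(ref):
            diff = sorted(set(nm.gene_ids) ^ set(ref))
            raise ValueError(f"gene universes differ; symmetric difference: {diff[:10]}")
    blocks, spot_ids, sections = [], [], []
    for nm in norms:
        idx = nm.gene_index(ref)
        blocks.append(_center_scale(nm.values[:, idx].copy(), scale=True))
        spot_ids.extend(nm.spot_ids)
        sections.extend([nm.provenance.get("section_id", f"sec{len(sections)}")] * nm.n_spots)
    X = np.vstack(blocks)
    joint = NormalizedMatrix(values=X, spot_ids=spot_ids, gene_ids=list(ref),
                             provenance={"section_id": "joint"})
    emb = run_pca(joint, n_components=min(n_components, min(X.shape)), scale=False)
    emb.section_of_spot = sections
    return emb


@dataclass
class ClusterAssignment:
    """Graph-community labels for every embedded spot."""

    labels: np.ndarray              # contiguous ints from 0
    spot_ids: list[str]
    resolution: float
    modularity: float
    section_of_spot: list[str]

    def series(self) -> pd.Series:
        return pd.Series(self.labels, index=pd.Index(self.spot_ids), name="cluster")

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0


def cluster_graph(
    embedding: PCAEmbedding | np.ndarray,
    k_neighbors: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
    spot_ids: list[str] | None = None,
) -> ClusterAssignment:
    """Leiden community detection on a symmetric kNN graph of the embedding."""
    import igraph as ig
    import leidenalg

    if isinstance(embedding, PCAEmbedding):
        coords = embedding.coords
        spot_ids = spot_ids or embedding.spot_ids
        sections = embedding.section_of_spot
    else:
        coords = np.asarray(embedding, dtype=float)
        spot_ids = spot_ids or [f"spot{i}" for i in range(coords.shape[0])]
        sections = ["section"] * coords.shape[0]
    n = coords.shape[0]
    if k_neighbors >= n:
        raise ValueError("k_neighbors must be < number of spots")

    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    edges = {tuple(sorted((i, j))) for i, row in enumerate(idx) for j in row[1:]}
    g = ig.Graph(n=n, edges=sorted(edges), directed=False)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    labels = np.asarray(part.membership, dtype=int)
    # relabel contiguously by first appearance for stability
    _, labels = np.unique(labels, return_inverse=True)
    modularity = g.modularity(labels.tolist())
    return ClusterAssignment(
        labels=labels, spot_ids=list(spot_ids), resolution=resolution,
        modularity=float(modularity), section_of_spot=list(sections),
    )


def embed_umap(
    embedding: PCAEmbedding | np.ndarray,
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> np.ndarray:
    """2D UMAP layout of the PC-space coordinates; deterministic given seed."""
    from umap import UMAP

    coords = embedding.coords if isinstance(embedding, PCAEmbedding) else np.asarray(embedding)
    reducer = UMAP(
        n_components=2, n_neighbors=min(n_neighbors, coords.shape[0] - 1),
        min_dist=min_dist, random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return reducer.fit_transform(coords)


def find_markers(norm: NormalizedMatrix, clusters: ClusterAssignment | pd.Series) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum markers per cluster.

    Returns a tidy frame with one row per (cluster, gene): log_fc (mean
    in-cluster minus mean out-of-cluster on the normalized scale), the
    rank-sum statistic, p and BH q computed across all tests.
    """
    labels = clusters.series() if isinstance(clusters, ClusterAssignment) else clusters
    labels = labels.loc[[s for s in norm.spot_ids if s in labels.index]]
    rows = norm.spot_index(list(labels.index))
    X = norm.values[rows]
    uniq = np.unique(labels.to_numpy())
    if uniq.size < 2:
        raise ValueError("need >= 2 clusters for marker detection")

    out = []
    lab = labels.to_numpy()
    for c in uniq:
        mask = lab == c
        if mask.sum() == 1:
            warnings.warn(f"cluster {c} is a singleton; test has minimal power", stacklevel=2)
        a, b = X[mask], X[~mask]
        res = stats.mannwhitneyu(a, b, axis=0, alternative="two-sided")
        lfc = a.mean(axis=0) - b.mean(axis=0)
        out.append(pd.DataFrame({
            "cluster": c, "gene": norm.gene_ids,
            "log_fc": lfc, "statistic": res.statistic, "p": res.pvalue,
        }))
    table = pd.concat(out, ignore_index=True)
    table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    return table
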