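"""Centroid-MST trajectory inference, pseudotime, and bimodality splitting.

The trajectory is a minimum spanning tree over cluster centroids in PC
space; each spot is projected onto its nearest tree edge and pseudotime is
the geodesic tree distance from the root projection, min-max scaled to
[0, 1].  Bimodality of a pseudotime distribution is formalized as a
1-vs-2-component Gaussian mixture choice by BIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import minimum_spanning_tree, shortest_path
from sklearn.mixture import GaussianMixture

from .io import NormalizedMatrix, select_hvg, subset_genes
from .clustering import run_pca
from .spatialtime import SpatialTimeValues

__all__ = [
    "Trajectory",
    "MixtureFit",
    "infer_trajectory",
    "detect_bimodality",
    "compare_groups_spatialtime",
]


@dataclass
class Trajectory:
    """Centroid tree with per-spot projections and scaled pseudotime."""

    node_ids: list                  # cluster labels, one per node
    node_coords: np.ndarray         # (n_nodes, k) centroids in PC space
    edges: list[tuple]              # (u, v) node-index pairs of the MST
    spot_ids: list[str]
    spot_edge: np.ndarray           # (n_spots,) index into `edges`
    spot_offset: np.ndarray         # (n_spots,) position along the edge in [0, 1]
    pseudotime: np.ndarray          # (n_spots,) in [0, 1]
    root: object                    # root cluster label

    def series(self) -> pd.Series:
        return pd.Series(self.pseudotime, index=pd.Index(self.spot_ids), name="pseudotime")


def _project_to_segment(p: np.ndarray, a: np.ndarray, b: np.ndarray):
    ab = b - a
    denom = float(ab @ ab)
    t = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
    proj = a + t * ab
    return t, float(np.linalg.norm(p - proj))


def infer_trajectory(
    norm: NormalizedMatrix,
    clusters: pd.Series,
    root_cluster,
    trajectory_clusters=None,
    hvg_n: int = 2000,
    n_pcs: int = 10,
) -> Trajectory:
    """MST trajectory over cluster centroids with root-anchored pseudotime.

    PCA is computed on the top-``hvg_n`` variance genes restricted to the
    trajectory clusters.  Edge-weight ties in the MST are broken by node-id
    order (an infinitesimal deterministic perturbation).
    """
    if trajectory_clusters is None:
        trajectory_clusters = sorted(pd.unique(clusters), key=str)
    if root_cluster not in list(trajectory_clusters):
        raise ValueError(f"root cluster {root_cluster!r} not among trajectory clusters")
    if len(trajectory_clusters) < 2:
        raise ValueError("need >= 2 clusters for a trajectory")

    keep = clusters[clusters.isin(trajectory_clusters)]
    spots = [s for s in norm.spot_ids if s in set(keep.index)]
    sub = NormalizedMatrix(
        values=norm.values[norm.spot_index(spots)],
        spot_ids=spots, gene_ids=list(norm.gene_ids),
        provenance=dict(norm.provenance),
    )
    hvg = select_hvg(sub, n=min(hvg_n, sub.n_genes))
    sub = subset_genes(sub, hvg)
    emb = run_pca(sub, n_components=min(n_pcs, min(sub.values.shape)))
    coords = emb.coords
    lab = keep.loc[spots].to_numpy()

    node_ids = list(trajectory_clusters)
    centroids = np.vstack([coords[lab == c].mean(axis=0) for c in node_ids])
    n_nodes = len(node_ids)

    dist = np.linalg.norm(centroids[:, None] - centroids[None, :], axis=2)
    # deterministic tie-break by (i, j) order
    eps = np.finfo(float).eps * dist.max() if dist.max() > 0 else 0.0
    tie = np.fromfunction(lambda i, j: (i * n_nodes + j), (n_nodes, n_nodes))
    mst = minimum_spanning_tree(np.triu(dist + eps * tie / (n_nodes**2 + 1), k=1))
    mst = mst.tocoo()
    edges = [(int(u), int(v)) for u, v in zip(mst.row, mst.col)]
    edge_len = np.array([dist[u, v] for u, v in edges])

    # geodesic node distances from the root over the tree
    adj = np.zeros((n_nodes, n_nodes))
    for (u, v), L in zip(edges, edge_len):
        adj[u, v] = adj[v, u] = L if L > 0 else np.finfo(float).tiny
    root_idx = node_ids.index(root_cluster)
    node_dist = shortest_path(adj, method="D", indices=root_idx)

    n = coords.shape[0]
    spot_edge = np.zeros(n, dtype=int)
    spot_offset = np.zeros(n)
    pt = np.zeros(n)
    for i in range(n):
        best = (np.inf, 0, 0.0)
        for e, (u, v) in enumerate(edges):
            t, dperp = _project_to_segment(coords[i], centroids[u], centroids[v])
            if dperp < best[0]:
                best = (dperp, e, t)
        _, e, t = best
        u, v = edges[e]
        L = edge_len[e]
        spot_edge[i], spot_offset[i] = e, t
        pt[i] = min(node_dist[u] + t * L, node_dist[v] + (1.0 - t) * L)

    span = pt.max() - pt.min()
    pt = (pt - pt.min()) / span if span > 0 else np.zeros_like(pt)
    return Trajectory(
        node_ids=node_ids, node_coords=centroids, edges=edges,
        spot_ids=spots, spot_edge=spot_edge, spot_offset=spot_offset,
        pseudotime=pt, root=root_cluster,
    )


@dataclass
class MixtureFit:
    """1- or 2-component Gaussian mixture chosen by BIC."""

    n_components: int
    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    assignment: pd.Series           # "pseudotime-low" / "pseudotime-high" (or "all")
    delta_bic: float                # BIC(1) - BIC(2); positive favors 2 components

    @property
    def bimodal(self) -> bool:
        return self.n_components == 2


def detect_bimodality(values: pd.Series | np.ndarray, seed: int = 0, n_init: int = 10) -> MixtureFit:
    """Choose between 1 and 2 Gaussian components by BIC (EM, seeded restarts).

    With 2 components, the low-mean component is labeled "pseudotime-low"
    and the high-mean one "pseudotime-high".  Degenerate variances are
    regularized with a floor.
    """
    if not isinstance(values, pd.Series):
        values = pd.Series(np.asarray(values, dtype=float))
    if len(values) < 20:
        raise ValueError("need >= 20 values for bimodality detection")
    X = values.to_numpy(dtype=float).reshape(-1, 1)
    scale = max(X.var(), 1e-12)
    reg = 1e-6 * scale

    fits = {}
    for m in (1, 2):
        gm = GaussianMixture(
            n_components=m, n_init=n_init, random_state=seed,
            reg_covar=reg, covariance_type="full",
        ).fit(X)
        fits[m] = (gm, gm.bic(X))
    delta = fits[1][1] - fits[2][1]
    m = 2 if delta > 0 else 1
    gm = fits[m][0]
    means = gm.means_.ravel()
    variances = gm.covariances_.ravel()
    weights = gm.weights_.ravel()
    if m == 2:
        order = np.argsort(means)
        means, variances, weights = means[order], variances[order], weights[order]
        raw = gm.predict(X)
        remap = {int(order[0]): "pseudotime-low", int(order[1]): "pseudotime-high"}
        labels = [remap[int(r)] for r in raw]
    else:
        labels = ["all"] * len(values)
    return MixtureFit(
        n_components=m, means=means, variances=variances, weights=weights,
        assignment=pd.Series(labels, index=values.index, name="component"),
        delta_bic=float(delta),
    )


def compare_groups_spatialtime(fit: MixtureFit, st: SpatialTimeValues) -> dict:
    """Rank-sum test of the distance axis s between the two mixture components.

    Reports which component sits at greater median s ("direction").
    """
    if fit.n_components != 2:
        raise ValueError("bimodality split required: fit has a single component")
    s = st.series()
    shared = fit.assignment.index.intersection(s.index)
    if len(shared) == 0:
        raise ValueError("no spots shared between mixture assignment and the distance axis")
    lab = fit.assignment.loc[shared]
    sv = s.loc[shared]
    lo = sv[lab == "pseudotime-low"].to_numpy()
    hi = sv[lab == "pseudotime-high"].to_numpy()
    if lo.size == 0 or hi.size == 0:
        raise ValueError("one component has no spots on the distance axis")
    res = stats.mannwhitneyu(lo, hi, alternative="two-sided")
    direction = "pseudotime-low" if np.median(lo) > np.median(hi) else "pseudotime-high"
    return {
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "direction": direction,       # component with the greater median s
        "median_low": float(np.median(lo)),
        "median_high": float(np.median(hi)),
    }
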