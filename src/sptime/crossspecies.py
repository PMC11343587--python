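"""Ortholog-mediated correspondence between spatial clusters of two datasets."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "OrthologMap",
    "PairedLogFC",
    "CorrespondenceMatrix",
    "harmonize_orthologs",
    "cluster_correspondence",
]


@dataclass
class OrthologMap:
    """One-to-one symbol correspondence after filtering multi-mappings."""

    pairs: pd.DataFrame             # columns symbol_a, symbol_b
    n_dropped: int = 0

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.pairs).iloc[:, :2].copy()
        df.columns = ["symbol_a", "symbol_b"]
        for col in df.columns:
            if df[col].duplicated().any():
                raise ValueError(
                    f"OrthologMap must be one-to-one; duplicated {col}: "
                    f"{sorted(set(df[col][df[col].duplicated()]))[:5]}"
                )
        self.pairs = df.reset_index(drop=True)

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "OrthologMap":
        """Build from a raw two-column table, dropping all multi-mappings."""
        df = pd.DataFrame(table).iloc[:, :2].copy()
        df.columns = ["symbol_a", "symbol_b"]
        before = len(df)
        dup_a = df["symbol_a"].duplicated(keep=False)
        dup_b = df["symbol_b"].duplicated(keep=False)
        df = df[~dup_a & ~dup_b]
        dropped = before - len(df)
        if dropped:
            logger.info("dropped %d multi-mapping ortholog row(s)", dropped)
        return cls(pairs=df, n_dropped=dropped)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "OrthologMap":
        return cls.from_table(pd.read_csv(path, sep="\t"))

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class PairedLogFC:
    """Cluster x ortholog log-FC matrices aligned on a shared gene index."""

    a: pd.DataFrame                 # clusters_A x orthologs (indexed by symbol_a)
    b: pd.DataFrame                 # clusters_B x orthologs (same column order)
    orthologs: pd.DataFrame         # the rows of the map actually used


def _pivot_markers(markers: pd.DataFrame) -> pd.DataFrame:
    return markers.pivot_table(index="cluster", columns="gene", values="log_fc")


def harmonize_orthologs(
    markers_a: pd.DataFrame,
    markers_b: pd.DataFrame,
    table: OrthologMap,
    min_shared: int = 50,
) -> PairedLogFC:
    """Align per-cluster log-FC vectors of two datasets on shared orthologs.

    Genes are restricted to one-to-one orthologs present in both marker
    tables; fewer than ``min_shared`` shared orthologs is an error.
    """
    mat_a = _pivot_markers(markers_a)
    mat_b = _pivot_markers(markers_b)
    pairs = table.pairs
    ok = pairs["symbol_a"].isin(mat_a.columns) & pairs["symbol_b"].isin(mat_b.columns)
    used = pairs[ok]
    if len(used) < min_shared:
        raise ValueError(
            f"only {len(used)} shared orthologs (< {min_shared}); insufficient signal"
        )
    a = mat_a[used["symbol_a"].tolist()]
    b = mat_b[used["symbol_b"].tolist()]
    b.columns = used["symbol_a"].tolist()   # align on A-side symbols
    return PairedLogFC(a=a, b=b, orthologs=used.reset_index(drop=True))


@dataclass
class CorrespondenceMatrix:
    """Spearman similarity per cluster pair with permutation significance."""

    scores: pd.DataFrame            # clusters_A x clusters_B
    p_values: pd.DataFrame
    best_a_to_b: dict
    best_b_to_a: dict
    n_perm: int


def _rank_standardize(M: np.ndarray) -> np.ndarray:
    R = rankdata(M, axis=1)
    R = R - R.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(R, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return R / norm


def cluster_correspondence(
    paired: PairedLogFC,
    n_perm: int = 1000,
    seed: int = 0,
) -> CorrespondenceMatrix:
    """Spearman correlation of aligned log-FC vectors per cluster pair.

    The null permutes the shared gene index of side B; the two-sided p per
    cell is the add-one-corrected fraction of permuted |rho| at least as
    large as observed.  Best matches are argmax per row and per column.
    """
    A = paired.a.to_numpy(dtype=float)
    B = paired.b.to_numpy(dtype=float)
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("need >= 2 clusters on each side")
    Ra = _rank_standardize(A)
    Rb = _rank_standardize(B)
    obs = Ra @ Rb.T

    rng = np.random.default_rng(seed)
    g = Ra.shape[1]
    exceed = np.zeros_like(obs)
    for _ in range(n_perm):
        perm = rng.permutation(g)
        null = Ra @ Rb[:, perm].T
        exceed += np.abs(null) >= np.abs(obs)
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    idx_a = list(paired.a.index)
    idx_b = list(paired.b.index)
    scores = pd.DataFrame(obs, index=idx_a, columns=idx_b)
    p_df = pd.DataFrame(pvals, index=idx_a, columns=idx_b)
    best_ab = {ca: scores.loc[ca].idxmax() for ca in idx_a}
    best_ba = {cb: scores[cb].idxmax() for cb in idx_b}
    return CorrespondenceMatrix(
        scores=scores, p_values=p_df,
        best_a_to_b=best_ab, best_b_to_a=best_ba, n_perm=n_perm,
    )
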