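"""Gene-set module scores with expression-bin-matched control genes.

The score of a set in a spot is the mean normalized expression of the set
genes minus the mean of pooled control genes sampled from the same
average-expression bins, so baseline expression level cancels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import NormalizedMatrix

__all__ = ["GeneSet", "ModuleScoreResult", "load_gene_sets", "write_gene_sets", "score_module"]


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: tuple

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} has duplicate symbols")


def load_gene_sets(gmt_path: str | Path) -> list[GeneSet]:
    """Parse a GMT file (name, description, genes...).

    Duplicate symbols within a set are collapsed with a warning; an empty
    file yields an empty list; a line with fewer than 3 fields is an error
    naming the line number.
    """
    sets: list[GeneSet] = []
    for lineno, line in enumerate(Path(gmt_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line {lineno}: expected name, description, genes")
        name, genes = fields[0], [g for g in fields[2:] if g]
        if not genes:
            raise ValueError(f"malformed GMT line {lineno}: set {name!r} has no genes")
        uniq = list(dict.fromkeys(genes))
        if len(uniq) != len(genes):
            warnings.warn(
                f"set {name!r}: collapsed {len(genes) - len(uniq)} duplicate symbol(s)",
                stacklevel=2,
            )
        sets.append(GeneSet(name=name, genes=tuple(uniq)))
    return sets


def write_gene_sets(sets: list[GeneSet], path: str | Path) -> None:
    lines = ["\t".join([s.name, "na", *s.genes]) for s in sets]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


@dataclass
class ModuleScoreResult:
    """Per-spot bin-matched control-subtracted score for one gene set."""

    scores: pd.Series               # indexed by barcode
    gene_set: str
    genes_used: tuple
    genes_missing: tuple
    n_bins: int
    n_ctrl: int
    seed: int
    control_genes: tuple = field(default=(), repr=False)


def score_module(
    norm: NormalizedMatrix,
    gene_set: GeneSet,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> ModuleScoreResult:
    """Bin-matched control-gene module score per spot.

    All genes are ranked by mean normalized expression and cut into
    ``n_bins`` equal-size bins.  For each set gene present in the matrix,
    ``n_ctrl`` control genes are sampled without replacement from its bin
    (set genes excluded); the spot score is the mean over set genes minus
    the mean over the pooled controls.
    """
    present = [g for g in gene_set.genes if g in set(norm.gene_ids)]
    missing = tuple(g for g in gene_set.genes if g not in set(norm.gene_ids))
    if not present:
        raise ValueError(f"no genes of set {gene_set.name!r} present in the matrix")

    means = norm.values.mean(axis=0)
    order = sorted(range(norm.n_genes), key=lambda i: (means[i], norm.gene_ids[i]))
    bins = np.array_split(np.asarray(order), n_bins)
    bin_of = np.empty(norm.n_genes, dtype=int)
    for b, members in enumerate(bins):
        bin_of[members] = b

    set_idx = norm.gene_index(present)
    set_set = set(set_idx.tolist())
    rng = np.random.default_rng(seed)
    ctrl_pool: list[int] = []
    n_short = 0
    for gi in set_idx:
        candidates = [j for j in bins[bin_of[gi]] if j not in set_set]
        if len(candidates) < n_ctrl:
            n_short += 1
            chosen = candidates
        else:
            chosen = rng.choice(np.asarray(candidates), size=n_ctrl, replace=False).tolist()
        ctrl_pool.extend(chosen)
    if n_short:
        warnings.warn(
            f"set {gene_set.name!r}: {n_short} gene(s) fell in bins with fewer than "
            f"n_ctrl={n_ctrl} candidates; their whole bin was used",
            stacklevel=2,
        )

    set_mean = norm.values[:, set_idx].mean(axis=1)
    ctrl_mean = norm.values[:, np.asarray(ctrl_pool)].mean(axis=1)
    scores = pd.Series(set_mean - ctrl_mean, index=pd.Index(norm.spot_ids),
                       name=gene_set.name)
    return ModuleScoreResult(
        scores=scores, gene_set=gene_set.name,
        genes_used=tuple(present), genes_missing=missing,
        n_bins=n_bins, n_ctrl=n_ctrl, seed=seed,
        control_genes=tuple(norm.gene_ids[j] for j in ctrl_pool),
    )
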