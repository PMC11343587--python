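"""Reading, writing, filtering and normalization of spatial expression data.

On-disk layout follows the 10x spatial convention: ``matrix.mtx`` (integer
MatrixMarket), ``barcodes.tsv``, ``features.tsv`` (id, symbol) and
``tissue_positions.csv`` (barcode, in_tissue, array_row, array_col,
pxl_row, pxl_col).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "SpatialSection",
    "NormalizedMatrix",
    "SpatialDataError",
    "MissingFileError",
    "BarcodeMismatchError",
    "NonIntegerMatrixError",
    "ZeroCountSpotError",
    "read_spatial_dataset",
    "write_spatial_dataset",
    "filter_genes",
    "normalize_log_cpm",
    "select_hvg",
]


class SpatialDataError(ValueError):
    """Base class for malformed spatial datasets."""


class MissingFileError(SpatialDataError):
    """A required file of the on-disk layout is absent."""


class BarcodeMismatchError(SpatialDataError):
    """Barcodes in the matrix and the positions table do not agree."""


class NonIntegerMatrixError(SpatialDataError):
    """The count matrix contains non-integer entries."""


class ZeroCountSpotError(SpatialDataError):
    """An in-tissue spot has zero total counts and cannot be normalized."""


@dataclass
class SpatialSection:
    """One tissue section: spots, genes, sparse counts and spot metadata.

    ``counts`` is spots x genes.  ``metadata`` is indexed by ``spot_ids`` and
    must carry a boolean ``in_tissue`` column; analysis operations only use
    in-tissue spots.
    """

    spot_ids: list[str]
    coords: np.ndarray          # (n_spots, 2) pixel x/y, continuous
    array_pos: np.ndarray       # (n_spots, 2) integer lattice row/col
    counts: sp.csr_matrix       # spots x genes, nonnegative integers
    gene_ids: list[str]
    section_id: str = "section"
    metadata: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.spot_ids = list(map(str, self.spot_ids))
        self.gene_ids = list(map(str, self.gene_ids))
        self.coords = np.asarray(self.coords, dtype=float)
        self.array_pos = np.asarray(self.array_pos, dtype=int)
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(self.counts)
        self.counts = self.counts.tocsr()
        n, g = self.counts.shape
        if n != len(self.spot_ids) or g != len(self.gene_ids):
            raise SpatialDataError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.spot_ids)} spots x {len(self.gene_ids)} genes"
            )
        if self.coords.shape != (n, 2):
            raise SpatialDataError("coords must be (n_spots, 2)")
        if len(set(self.spot_ids)) != n:
            raise SpatialDataError("spot_ids are not unique")
        if len(set(self.gene_ids)) != g:
            raise SpatialDataError("gene_ids are not unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise SpatialDataError("counts must be nonnegative")
        if self.metadata is None:
            self.metadata = pd.DataFrame(index=pd.Index(self.spot_ids))
        if "in_tissue" not in self.metadata.columns:
            self.metadata = self.metadata.copy()
            self.metadata["in_tissue"] = True

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def in_tissue(self) -> np.ndarray:
        """Boolean mask over spots, aligned with ``spot_ids``."""
        return self.metadata["in_tissue"].to_numpy(dtype=bool)

    def gene_index(self, genes) -> np.ndarray:
        lut = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lut[g] for g in genes], dtype=int)


@dataclass
class NormalizedMatrix:
    """log2(CPM + 1) expression for in-tissue spots of one section."""

    values: np.ndarray          # (n_spots_in_tissue, n_genes), dense
    spot_ids: list[str]
    gene_ids: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.spot_ids), len(self.gene_ids)):
            raise SpatialDataError("values shape inconsistent with id lists")

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_index(self, genes) -> np.ndarray:
        lut = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lut[g] for g in genes], dtype=int)

    def spot_index(self, spots) -> np.ndarray:
        lut = {s: i for i, s in enumerate(self.spot_ids)}
        return np.array([lut[s] for s in spots], dtype=int)


_POSITION_COLUMNS = ["barcode", "in_tissue", "array_row", "array_col", "pxl_row", "pxl_col"]


def read_spatial_dataset(path: str | Path, section_id: str | None = None) -> SpatialSection:
    """Read a 10x-style spatial directory into a :class:`SpatialSection`.

    The MatrixMarket file may be stored either spots x genes or the
    conventional genes x spots; orientation is resolved by matching the
    header dimensions against the barcode/feature list lengths.  Barcodes
    are joined to positions by exact string match and any mismatch in
    either direction is an error naming the offending barcode.
    """
    path = Path(path)
    files = {
        "matrix": path / "matrix.mtx",
        "barcodes": path / "barcodes.tsv",
        "features": path / "features.tsv",
        "positions": path / "tissue_positions.csv",
    }
    for name, f in files.items():
        if not f.exists():
            raise MissingFileError(f"required file missing: {f}")

    barcodes = files["barcodes"].read_text().split()
    features = pd.read_csv(files["features"], sep="\t", header=None, dtype=str)
    gene_ids = features.iloc[:, 1].tolist() if features.shape[1] > 1 else features.iloc[:, 0].tolist()

    mat = scipy.io.mmread(files["matrix"])
    data = mat.tocoo().data
    if data.size and not np.allclose(data, np.round(data)):
        raise NonIntegerMatrixError("matrix.mtx contains non-integer entries")
    mat = sp.csr_matrix(mat).astype(np.int64)

    n_spots, n_genes = len(barcodes), len(gene_ids)
    if mat.shape == (n_genes, n_spots) and mat.shape != (n_spots, n_genes):
        mat = mat.T.tocsr()
    elif mat.shape == (n_genes, n_spots) and n_genes == n_spots:
        # square and ambiguous: the writer stores genes x spots
        mat = mat.T.tocsr()
    elif mat.shape != (n_spots, n_genes):
        raise SpatialDataError(
            f"matrix shape {mat.shape} matches neither ({n_spots}, {n_genes}) "
            f"nor its transpose"
        )

    pos = pd.read_csv(files["positions"], float_precision="round_trip")
    if list(pos.columns[: len(_POSITION_COLUMNS)]) != _POSITION_COLUMNS:
        pos.columns = _POSITION_COLUMNS[: len(pos.columns)]
    pos["barcode"] = pos["barcode"].astype(str)
    pos_barcodes = set(pos["barcode"])
    unknown = [b for b in pos["barcode"] if b not in set(barcodes)]
    if unknown:
        raise BarcodeMismatchError(f"positions file contains unknown barcode(s): {unknown[:5]}")
    missing = [b for b in barcodes if b not in pos_barcodes]
    if missing:
        raise BarcodeMismatchError(f"barcode(s) absent from positions file: {missing[:5]}")
    pos = pos.set_index("barcode").loc[barcodes]

    coords = pos[["pxl_col", "pxl_row"]].to_numpy(dtype=float)  # (x, y)
    array_pos = pos[["array_row", "array_col"]].to_numpy(dtype=int)
    meta = pd.DataFrame(
        {"in_tissue": pos["in_tissue"].to_numpy(dtype=int).astype(bool)},
        index=pd.Index(barcodes),
    )
    return SpatialSection(
        spot_ids=barcodes,
        coords=coords,
        array_pos=array_pos,
        counts=mat,
        gene_ids=gene_ids,
        section_id=section_id or path.name,
        metadata=meta,
    )


def write_spatial_dataset(section: SpatialSection, path: str | Path) -> Path:
    """Write a section in the same layout :func:`read_spatial_dataset` reads.

    The matrix is stored genes x spots (the conventional orientation).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(path / "matrix.mtx", section.counts.T.astype(np.int64))
    (path / "barcodes.tsv").write_text("\n".join(section.spot_ids) + "\n")
    feats = pd.DataFrame({"id": section.gene_ids, "symbol": section.gene_ids})
    feats.to_csv(path / "features.tsv", sep="\t", header=False, index=False)
    pos = pd.DataFrame(
        {
            "barcode": section.spot_ids,
            "in_tissue": section.in_tissue.astype(int),
            "array_row": section.array_pos[:, 0],
            "array_col": section.array_pos[:, 1],
            "pxl_row": section.coords[:, 1],
            "pxl_col": section.coords[:, 0],
        }
    )
    pos.to_csv(path / "tissue_positions.csv", index=False)
    return path


def filter_genes(section: SpatialSection, min_fraction: float = 0.003) -> SpatialSection:
    """Drop genes detected in at most ``min_fraction`` of in-tissue spots.

    A gene survives iff its nonzero fraction over in-tissue spots is
    strictly greater than ``min_fraction``.  Gene order is preserved.
    Idempotent.
    """
    if not 0 <= min_fraction <= 1:
        raise ValueError("min_fraction must lie in [0, 1]")
    mask = section.in_tissue
    if mask.sum() == 0:
        raise SpatialDataError("no in-tissue spots")
    frac = np.asarray((section.counts[mask] > 0).mean(axis=0)).ravel()
    keep = frac > min_fraction
    return SpatialSection(
        spot_ids=section.spot_ids,
        coords=section.coords,
        array_pos=section.array_pos,
        counts=section.counts[:, keep].tocsr(),
        gene_ids=[g for g, k in zip(section.gene_ids, keep) if k],
        section_id=section.section_id,
        metadata=section.metadata,
    )


def normalize_log_cpm(section: SpatialSection) -> NormalizedMatrix:
    """Per-spot log2(counts-per-million + 1) over in-tissue spots.

    value_ig = log2(1 + 1e6 * c_ig / sum_g c_ig).  Spots with zero total
    counts cannot be scaled; they raise with the offending barcodes listed.
    """
    mask = section.in_tissue
    counts = section.counts[mask]
    totals = np.asarray(counts.sum(axis=1)).ravel()
    spot_ids = [s for s, m in zip(section.spot_ids, mask) if m]
    zero = totals == 0
    if zero.any():
        bad = [s for s, z in zip(spot_ids, zero) if z]
        raise ZeroCountSpotError(f"in-tissue spot(s) with zero total counts: {bad[:10]}")
    cpm = counts.multiply(1e6 / totals[:, None]).toarray()
    values = np.log2(1.0 + cpm)
    return NormalizedMatrix(
        values=values,
        spot_ids=spot_ids,
        gene_ids=list(section.gene_ids),
        provenance={"section_id": section.section_id, "transform": "log2(CPM+1)"},
    )


def select_hvg(norm: NormalizedMatrix, n: int = 2000) -> list[str]:
    """Top-``n`` genes by variance of normalized expression.

    Ties are broken by lexical gene-symbol order (smaller symbol first).
    """
    if n > norm.n_genes:
        raise ValueError(f"n={n} exceeds gene count {norm.n_genes}")
    var = norm.values.var(axis=0, ddof=1) if norm.n_spots > 1 else np.zeros(norm.n_genes)
    order = sorted(range(norm.n_genes), key=lambda i: (-var[i], norm.gene_ids[i]))
    return [norm.gene_ids[i] for i in order[:n]]


def subset_genes(norm: NormalizedMatrix, genes) -> NormalizedMatrix:
    """Restrict a normalized matrix to the given genes, in the given order."""
    idx = norm.gene_index(genes)
    return NormalizedMatrix(
        values=norm.values[:, idx],
        spot_ids=list(norm.spot_ids),
        gene_ids=list(genes),
        provenance=dict(norm.provenance),
    )
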