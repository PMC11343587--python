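"""Distance-from-plane axis: assignment, trend testing, dynamic classes.

The per-spot statistic s is the Euclidean distance from the spot center to
the nearest point of a reference polyline, min-max normalized over the
included spots so the nearest spot maps to 0 and the farthest to 1.  Gene
trends over s are tested with a natural-cubic-spline likelihood-ratio test
and significant genes are grouped into dynamic classes by Ward clustering
of their standardized fitted curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from statsmodels.stats.multitest import multipletests

from .io import NormalizedMatrix, SpatialSection

__all__ = [
    "FracturePlane",
    "SpatialTimeValues",
    "GeneTrend",
    "BinnedCurve",
    "GenotypeComparison",
    "assign_spatialtime",
    "fit_gene_trends",
    "classify_trends",
    "summarize_over_spatialtime",
    "compare_genotypes",
    "natural_spline_basis",
    "CANONICAL_PEAKS",
]

CANONICAL_PEAKS = (0.05, 0.30, 0.60, 0.95)
_CLASS_NAMES_4 = ("early", "midearly", "midlate", "late")


@dataclass
class FracturePlane:
    """An ordered polyline (>= 2 points) in the section's pixel space."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2 or self.points.shape[0] < 2:
            raise ValueError("plane requires >= 2 points of shape (m, 2)")
        seg = np.diff(self.points, axis=0)
        lengths = np.hypot(seg[:, 0], seg[:, 1])
        if np.any(lengths == 0):
            raise ValueError("consecutive plane points must be distinct")
        if lengths.sum() <= 0:
            raise ValueError("degenerate polyline with zero total length")

    @classmethod
    def from_csv(cls, path: str | Path) -> "FracturePlane":
        pts = pd.read_csv(path, header=None).to_numpy(dtype=float)
        return cls(points=pts[:, :2])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.points).to_csv(path, header=False, index=False)


def _polyline_distances(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Min Euclidean distance from each point to any polyline segment.

    Uses point-to-segment projection (clamped), not point-to-vertex.
    """
    points = np.asarray(points, dtype=float)
    a = poly[:-1]                       # (m, 2) segment starts
    b = poly[1:]                        # (m, 2) segment ends
    ab = b - a                          # (m, 2)
    denom = np.einsum("md,md->m", ab, ab)
    diff = points[:, None, :] - a[None, :, :]       # (n, m, 2)
    t = np.einsum("nmd,md->nm", diff, ab) / denom   # (n, m)
    t = np.clip(t, 0.0, 1.0)
    proj = a[None, :, :] + t[:, :, None] * ab[None, :, :]
    d = np.linalg.norm(points[:, None, :] - proj, axis=2)
    return d.min(axis=1)


@dataclass
class SpatialTimeValues:
    """Per-spot normalized distance s in [0, 1] with an inclusion mask."""

    spot_ids: list[str]
    distance: np.ndarray        # raw distance, all spots
    s: np.ndarray               # normalized; NaN for excluded spots
    included: np.ndarray        # boolean mask over spot_ids

    def series(self) -> pd.Series:
        """s over included spots, indexed by barcode."""
        idx = pd.Index(self.spot_ids)[self.included]
        return pd.Series(self.s[self.included], index=idx, name="spatialtime")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "barcode": self.spot_ids,
            "d": self.distance,
            "s": self.s,
            "included": self.included.astype(int),
        })


def assign_spatialtime(
    section: SpatialSection,
    plane: FracturePlane,
    include_clusters=None,
    cluster_col: str = "cluster",
) -> SpatialTimeValues:
    """Assign each included spot its normalized distance to the plane.

    ``include_clusters`` restricts the axis to spots whose ``cluster_col``
    metadata value is listed (the analysis' "skeletal" subset); ``None``
    includes every in-tissue spot.  s is min-max normalized over included
    spots; if all included distances are equal, all s are 0.
    """
    mask = section.in_tissue.copy()
    if include_clusters is not None:
        incl = set(include_clusters)
        if not incl:
            raise ValueError("include_clusters must be nonempty (or None for all)")
        if cluster_col not in section.metadata.columns:
            raise KeyError(f"metadata lacks column {cluster_col!r}")
        mask &= section.metadata[cluster_col].isin(incl).to_numpy()
    if not mask.any():
        raise ValueError("no included spots for the distance axis")

    lo, hi = section.coords.min(axis=0), section.coords.max(axis=0)
    if np.any(plane.points.max(axis=0) < lo) or np.any(plane.points.min(axis=0) > hi):
        warnings.warn("plane lies outside the spots' bounding box", stacklevel=2)

    d = _polyline_distances(section.coords, plane.points)
    s = np.full(d.size, np.nan)
    d_in = d[mask]
    span = d_in.max() - d_in.min()
    s[mask] = (d_in - d_in.min()) / span if span > 0 else 0.0
    return SpatialTimeValues(
        spot_ids=list(section.spot_ids), distance=d, s=s, included=mask
    )


def natural_spline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis (linear beyond boundary knots).

    Given K knots (boundaries included) returns K-1 basis columns:
    N_1(x) = x and N_{j+1}(x) = d_j(x) - d_{K-1}(x) with
    d_j(x) = [(x - k_j)_+^3 - (x - k_K)_+^3] / (k_K - k_j).
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    K = knots.size
    if K < 2:
        raise ValueError("need at least 2 knots")

    def d(j: int) -> np.ndarray:
        num = np.clip(x - knots[j], 0, None) ** 3 - np.clip(x - knots[K - 1], 0, None) ** 3
        return num / (knots[K - 1] - knots[j])

    cols = [x]
    dK1 = d(K - 2)
    for j in range(K - 2):
        cols.append(d(j) - dK1)
    return np.column_stack(cols)


@dataclass
class GeneTrend:
    """Fitted expression curve of one gene over the s-grid, with its test."""

    gene: str
    curve: np.ndarray           # fitted values on `grid`
    statistic: float            # likelihood-ratio statistic
    p: float
    q: float = np.nan
    class_label: str = "none"
    grid: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]


def fit_gene_trends(
    norm: NormalizedMatrix,
    st: SpatialTimeValues,
    df: int = 3,
    q_threshold: float = 0.05,
    grid_size: int = 100,
) -> list[GeneTrend]:
    """Spline-vs-intercept likelihood-ratio test per gene along s.

    For each gene, a natural cubic spline of s with ``df`` degrees of
    freedom is regressed on the normalized expression (Gaussian working
    model); the statistic is n*log(RSS0/RSS1) against chi-square with
    ``df`` degrees of freedom, BH-corrected across genes.  Constant genes
    get p = 1 by convention.
    """
    s_series = st.series()
    shared = [b for b in norm.spot_ids if b in set(s_series.index)]
    if len(shared) < df + 2:
        raise ValueError(f"need >= {df + 2} included spots, have {len(shared)}")
    rows = norm.spot_index(shared)
    s = s_series.loc[shared].to_numpy()
    Y = norm.values[rows]
    n = s.size

    knots = np.quantile(s, np.linspace(0, 1, df + 1))
    knots = np.unique(knots)
    X = np.column_stack([np.ones(n), natural_spline_basis(s, knots)])
    grid = np.linspace(s.min(), s.max(), grid_size)
    Xg = np.column_stack([np.ones(grid_size), natural_spline_basis(grid, knots)])

    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    rss1 = np.einsum("ij,ij->j", resid, resid)
    centered = Y - Y.mean(axis=0)
    rss0 = np.einsum("ij,ij->j", centered, centered)

    with np.errstate(divide="ignore", invalid="ignore"):
        lr = n * np.log(rss0 / np.maximum(rss1, 1e-300))
    lr = np.where(rss0 <= 0, 0.0, np.maximum(lr, 0.0))
    dof = X.shape[1] - 1
    p = stats.chi2.sf(lr, dof)
    p = np.where(rss0 <= 0, 1.0, p)
    q = multipletests(p, method="fdr_bh")[1]

    curves = Xg @ beta
    return [
        GeneTrend(
            gene=g, curve=curves[:, j], statistic=float(lr[j]),
            p=float(p[j]), q=float(q[j]), grid=grid,
        )
        for j, g in enumerate(norm.gene_ids)
    ]


def trends_frame(trends: list[GeneTrend]) -> pd.DataFrame:
    return pd.DataFrame({
        "gene": [t.gene for t in trends],
        "statistic": [t.statistic for t in trends],
        "p": [t.p for t in trends],
        "q": [t.q for t in trends],
        "class": [t.class_label for t in trends],
    })


def _class_names(k: int) -> tuple:
    if k == 1:
        return ("early..late",)
    if k == 4:
        return _CLASS_NAMES_4
    return tuple(f"class{i + 1}" for i in range(k))


def classify_trends(
    trends: list[GeneTrend],
    k: int = 4,
    q_threshold: float = 0.05,
    canonical_peaks=CANONICAL_PEAKS,
) -> list[GeneTrend]:
    """Group significant trends into k dynamic classes; label in place.

    Each significant gene's fitted curve is z-standardized over the s-grid
    and Ward-clustered (Euclidean); the k clusters are named by the argmax
    position of their mean curve, ordered nearest-to-farthest.  With fewer
    than k significant genes each is labeled by the canonical peak nearest
    its own curve argmax, with a warning.
    """
    sig = [t for t in trends if t.q < q_threshold]
    names = _class_names(k)
    if not sig:
        warnings.warn("no significant trends to classify", stacklevel=2)
        return trends

    grid = sig[0].grid
    Z = np.vstack([t.curve for t in sig])
    sd = Z.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    Z = (Z - Z.mean(axis=1, keepdims=True)) / sd[:, None]

    if len(sig) < k:
        warnings.warn(
            f"only {len(sig)} significant genes for k={k}; labeling by nearest canonical peak",
            stacklevel=2,
        )
        peaks = np.asarray(canonical_peaks[: len(names)], dtype=float)
        for t, z in zip(sig, Z):
            pos = grid[int(np.argmax(z))]
            t.class_label = names[int(np.argmin(np.abs(peaks - pos)))]
        return trends

    if k == 1:
        for t in sig:
            t.class_label = names[0]
        return trends

    link = linkage(Z, method="ward", metric="euclidean")
    raw = fcluster(link, t=k, criterion="maxclust")
    argmax_pos = {}
    for c in np.unique(raw):
        mean_curve = Z[raw == c].mean(axis=0)
        argmax_pos[c] = grid[int(np.argmax(mean_curve))]
    order = sorted(argmax_pos, key=lambda c: argmax_pos[c])
    label_of = {c: names[i] for i, c in enumerate(order)}
    for t, c in zip(sig, raw):
        t.class_label = label_of[c]
    return trends


@dataclass
class BinnedCurve:
    """Binned mean curve of a per-spot quantity over s, with 95% CI."""

    centers: np.ndarray
    mean: np.ndarray            # NaN where a bin is empty
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    n: np.ndarray
    peak: float                 # bin center of the maximum mean

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "center": self.centers, "mean": self.mean,
            "ci_lo": self.ci_lo, "ci_hi": self.ci_hi, "n": self.n,
        })


def _bin_index(s: np.ndarray, n_bins: int) -> np.ndarray:
    idx = np.minimum((s * n_bins).astype(int), n_bins - 1)
    return idx


def summarize_over_spatialtime(
    values: pd.Series,
    st: SpatialTimeValues,
    n_bins: int = 20,
) -> BinnedCurve:
    """Equal-width-binned mean of a per-spot scalar over s in [0, 1].

    ``values`` is indexed by barcode; only spots included in ``st`` and
    present in ``values`` contribute.  Empty bins are reported as NaN.
    """
    s_series = st.series()
    shared = s_series.index.intersection(values.index)
    if len(shared) == 0:
        raise ValueError("no spots shared between values and the distance axis")
    s = s_series.loc[shared].to_numpy()
    v = values.loc[shared].to_numpy(dtype=float)

    idx = _bin_index(s, n_bins)
    centers = (np.arange(n_bins) + 0.5) / n_bins
    mean = np.full(n_bins, np.nan)
    lo = np.full(n_bins, np.nan)
    hi = np.full(n_bins, np.nan)
    n = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        vb = v[idx == b]
        n[b] = vb.size
        if vb.size:
            m = vb.mean()
            sem = vb.std(ddof=1) / np.sqrt(vb.size) if vb.size > 1 else 0.0
            mean[b], lo[b], hi[b] = m, m - 1.96 * sem, m + 1.96 * sem
    peak = float(centers[np.nanargmax(mean)]) if np.any(~np.isnan(mean)) else np.nan
    return BinnedCurve(centers=centers, mean=mean, ci_lo=lo, ci_hi=hi, n=n, peak=peak)


@dataclass
class GenotypeComparison:
    delta_auc: float            # area(control curve) - area(mutant curve)
    peak_shift: float
    p_value: float
    curve_a: BinnedCurve
    curve_b: BinnedCurve
    n_perm: int


def _curve_auc(mean_a: np.ndarray, mean_b: np.ndarray, centers: np.ndarray) -> float:
    ok = ~np.isnan(mean_a) & ~np.isnan(mean_b)
    if ok.sum() < 2:
        return float("nan")
    return float(np.trapezoid(mean_a[ok] - mean_b[ok], centers[ok]))


def compare_genotypes(
    values_a: pd.Series,
    st_a: SpatialTimeValues,
    values_b: pd.Series,
    st_b: SpatialTimeValues,
    n_bins: int = 20,
    n_perm: int = 1000,
    seed: int = 0,
) -> GenotypeComparison:
    """Permutation test for a genotype difference in a binned s-curve.

    delta_auc is the trapezoid area between the two binned mean curves
    (A minus B).  The null is built by permuting genotype labels across
    spots *within each s-bin*, preserving the spatial composition of the
    two groups; the two-sided p is the fraction of permuted |delta_auc|
    at least as large as observed (add-one corrected).
    """
    curve_a = summarize_over_spatialtime(values_a, st_a, n_bins)
    curve_b = summarize_over_spatialtime(values_b, st_b, n_bins)
    centers = curve_a.centers
    delta = _curve_auc(curve_a.mean, curve_b.mean, centers)
    peak_shift = curve_a.peak - curve_b.peak

    sa, sb = st_a.series(), st_b.series()
    ia = sa.index.intersection(values_a.index)
    ib = sb.index.intersection(values_b.index)
    s_all = np.concatenate([sa.loc[ia].to_numpy(), sb.loc[ib].to_numpy()])
    v_all = np.concatenate([
        values_a.loc[ia].to_numpy(dtype=float),
        values_b.loc[ib].to_numpy(dtype=float),
    ])
    is_a = np.concatenate([np.ones(len(ia), bool), np.zeros(len(ib), bool)])
    bins = _bin_index(s_all, n_bins)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for r in range(n_perm):
        lab = is_a.copy()
        for b in np.unique(bins):
            sel = np.flatnonzero(bins == b)
            lab[sel] = lab[sel][rng.permutation(sel.size)]
        ma = np.full(n_bins, np.nan)
        mb = np.full(n_bins, np.nan)
        for b in range(n_bins):
            in_bin = bins == b
            va = v_all[in_bin & lab]
            vb = v_all[in_bin & ~lab]
            if va.size:
                ma[b] = va.mean()
            if vb.size:
                mb[b] = vb.mean()
        null[r] = _curve_auc(ma, mb, centers)
    valid = ~np.isnan(null)
    p = (1.0 + np.sum(np.abs(null[valid]) >= abs(delta))) / (1.0 + valid.sum())
    return GenotypeComparison(
        delta_auc=delta, peak_shift=peak_shift, p_value=float(p),
        curve_a=curve_a, curve_b=curve_b, n_perm=n_perm,
    )
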