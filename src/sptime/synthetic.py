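"""Synthetic fracture-callus-like sections with full ground truth.

Spots form a hexagonal lattice partitioned into tissue domains by their
distance to a reference polyline (the "fracture plane").  Gene means follow
a Gaussian-bump trend family over the normalized distance axis; counts are
negative binomial with spot-level size factors.  Everything is deterministic
given the config seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import SpatialSection, write_spatial_dataset
from .spatialtime import FracturePlane, _polyline_distances

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_section",
    "generate_pair",
    "generate_ortholog_pair",
    "write_synthetic_dataset",
    "CLASS_NAMES_4",
]

CLASS_NAMES_4 = ("early", "midearly", "midlate", "late")

# fixed seed offsets for derived sub-streams
_OFF_SIZE_FACTORS = 1
_OFF_COUNTS = 2
_OFF_CONTROL = 0
_OFF_MUTANT = 104729
_OFF_ORTHOLOG = 15485863

_DEFAULT_DOMAINS = (
    ("progenitor", (0.0, 0.25)),
    ("cartilage", (0.25, 0.5)),
    ("woven_bone", (0.5, 0.75)),
    ("cortical_bone", (0.75, 1.0)),
)

# module name -> (gene count, peak position, genotype multiplier in mutant)
_DEFAULT_MODULES = {
    "TGFB": (25, 0.20, 1.0),
    "WNT": (25, 0.45, 0.0),
    "BMP": (25, 0.60, 0.0),
    "MAPK": (25, 0.50, 2.0),
}


@dataclass
class SyntheticConfig:
    n_rows: int = 40
    n_cols: int = 50
    spot_pitch: float = 100.0
    plane_points: tuple | None = None  # defaults to vertical line at x = 0
    domain_spec: tuple = _DEFAULT_DOMAINS
    n_marker_genes_per_domain: int = 25
    n_gradient_genes_per_class: int = 50
    class_peaks: tuple = (0.05, 0.30, 0.60, 0.95)
    class_width: float = 0.12
    amplitude: float = 2.0
    n_noise_genes: int = 500
    module_spec: dict = field(default_factory=lambda: dict(_DEFAULT_MODULES))
    baseline_mean: float = 5.0
    dispersion: float = 0.5
    libsize_cv: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        peaks = np.asarray(self.class_peaks, dtype=float)
        if peaks.size and (np.any(np.diff(peaks) <= 0) or peaks.min() < 0 or peaks.max() > 1):
            raise ValueError("class_peaks must be strictly increasing within [0, 1]")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("lattice dimensions must be positive")
        if self.spot_pitch <= 0:
            raise ValueError("spot_pitch must be > 0")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be > 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.class_width <= 0:
            raise ValueError("class_width must be > 0")
        if self.libsize_cv < 0:
            raise ValueError("libsize_cv must be >= 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        names = [n for n, _ in self.domain_spec]
        if len(set(names)) != len(names):
            raise ValueError("domain names must be unique")

    @property
    def class_names(self) -> tuple:
        if len(self.class_peaks) == 4:
            return CLASS_NAMES_4
        return tuple(f"class{i + 1}" for i in range(len(self.class_peaks)))

    def gene_names(self) -> tuple[list, dict, dict]:
        """Gene universe with class and module truth maps.

        Order: domain markers, gradient genes, module genes, noise genes.
        """
        genes: list[str] = []
        class_of: dict[str, str] = {}
        module_of: dict[str, str] = {}
        for dom, _ in self.domain_spec:
            for i in range(self.n_marker_genes_per_domain):
                genes.append(f"MK-{dom}-{i:03d}")
        for cname in self.class_names:
            for i in range(self.n_gradient_genes_per_class):
                g = f"GR-{cname}-{i:03d}"
                genes.append(g)
                class_of[g] = cname
        for mod, (count, _, _) in self.module_spec.items():
            for i in range(count):
                g = f"MOD-{mod}-{i:03d}"
                genes.append(g)
                module_of[g] = mod
        for i in range(self.n_noise_genes):
            genes.append(f"NS-{i:04d}")
        if len(set(genes)) != len(genes):
            raise ValueError("gene names collide; check domain/module names")
        return genes, class_of, module_of

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(json.dumps(d, indent=2, default=list))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticConfig":
        d = json.loads(Path(path).read_text())
        if d.get("domain_spec") is not None:
            d["domain_spec"] = tuple((n, tuple(b)) for n, b in d["domain_spec"])
        if d.get("module_spec") is not None:
            d["module_spec"] = {k: tuple(v) for k, v in d["module_spec"].items()}
        for key in ("class_peaks", "plane_points"):
            if d.get(key) is not None:
                d[key] = tuple(tuple(p) if isinstance(p, list) else p for p in d[key])
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Ground truth for one generated section."""

    domain_of_spot: pd.Series       # spot id -> domain name
    true_spatialtime: pd.Series     # spot id -> s in [0, 1]
    class_of_gene: pd.Series        # gene -> class name or "none"
    module_of_gene: pd.Series       # gene -> module name or "none"
    genotype: str
    config: SyntheticConfig

    def module_genes(self, module: str) -> list[str]:
        return list(self.module_of_gene.index[self.module_of_gene == module])

    def class_genes(self, cls: str) -> list[str]:
        return list(self.class_of_gene.index[self.class_of_gene == cls])


def _hex_lattice(n_rows: int, n_cols: int, pitch: float) -> tuple[np.ndarray, np.ndarray]:
    """Hexagonal lattice: odd rows offset by half a pitch; rows sqrt(3)/2 apart."""
    rows, cols = np.mgrid[0:n_rows, 0:n_cols]
    rows, cols = rows.ravel(), cols.ravel()
    x = pitch * (cols + 0.5 * (rows % 2))
    y = pitch * rows * (np.sqrt(3.0) / 2.0)
    coords = np.column_stack([x, y])
    array_pos = np.column_stack([rows, cols])
    return coords, array_pos


def _default_plane(coords: np.ndarray) -> FracturePlane:
    """Vertical polyline along the left edge of the lattice."""
    ymin, ymax = coords[:, 1].min(), coords[:, 1].max()
    return FracturePlane(points=np.array([[0.0, ymin - 1.0], [0.0, ymax + 1.0]]))


def _size_factors(n: int, cv: float, rng: np.random.Generator) -> np.ndarray:
    if cv == 0:
        return np.ones(n)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=n)


def _nb_sample(mu: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """NB with var = mu + dispersion * mu^2 (gamma-Poisson mixture)."""
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def _mean_matrix(
    config: SyntheticConfig,
    s: np.ndarray,
    domains: np.ndarray,
    genotype: str,
) -> tuple[np.ndarray, list]:
    """Per-spot x per-gene trend factor f_g(s_i); excludes size factors."""
    genes, class_of, module_of = config.gene_names()
    f = np.ones((s.size, len(genes)))
    peaks = {c: p for c, p in zip(config.class_names, config.class_peaks)}
    sigma2 = 2.0 * config.class_width**2
    for j, g in enumerate(genes):
        if g.startswith("MK-"):
            dom = g.split("-")[1]
            f[:, j] = 1.0 + config.amplitude * (domains == dom)
        elif g in class_of:
            pk = peaks[class_of[g]]
            f[:, j] = 1.0 + config.amplitude * np.exp(-((s - pk) ** 2) / sigma2)
        elif g in module_of:
            _, pk, mult = config.module_spec[module_of[g]]
            amp = config.amplitude * (mult if genotype == "mutant" else 1.0)
            f[:, j] = 1.0 + amp * np.exp(-((s - pk) ** 2) / sigma2)
    return f, genes


def generate_section(
    config: SyntheticConfig,
    genotype: str = "control",
    seed_offset: int = 0,
    section_id: str | None = None,
) -> tuple[SpatialSection, SyntheticTruth]:
    """Generate one section plus its ground truth.

    Gene g in spot i has mean ``baseline_mean * sf_i * f_g(s_i)`` where s_i
    is the min-max-normalized distance to the plane polyline and f_g is 1
    for noise genes, a domain-indicator uplift for marker genes, and a
    Gaussian bump in s for gradient/module genes.  In the mutant genotype,
    module amplitudes are multiplied by the module's genotype multiplier.
    """
    if genotype not in ("control", "mutant"):
        raise ValueError(f"genotype must be 'control' or 'mutant', got {genotype!r}")
    config.validate()
    coords, array_pos = _hex_lattice(config.n_rows, config.n_cols, config.spot_pitch)
    plane = (
        FracturePlane(points=np.asarray(config.plane_points, dtype=float))
        if config.plane_points is not None
        else _default_plane(coords)
    )
    d = _polyline_distances(coords, plane.points)
    rng_span = d.max() - d.min()
    s = (d - d.min()) / rng_span if rng_span > 0 else np.zeros_like(d)

    domains = np.empty(s.size, dtype=object)
    domains[:] = ""
    for name, (lo, hi) in config.domain_spec:
        band = (s >= lo) & (s <= hi if hi >= 1.0 else s < hi)
        domains[(domains == "") & band] = name
    for name, _ in config.domain_spec:
        if not np.any(domains == name):
            raise ValueError(f"lattice too small: distance band for domain {name!r} is empty")
    if np.any(domains == ""):
        raise ValueError("domain_spec does not cover all spots' distance range")

    f, genes = _mean_matrix(config, s, domains, genotype)
    base = config.seed + seed_offset
    sf = _size_factors(s.size, config.libsize_cv, np.random.default_rng(base + _OFF_SIZE_FACTORS))
    mu = config.baseline_mean * sf[:, None] * f
    counts = _nb_sample(mu, config.dispersion, np.random.default_rng(base + _OFF_COUNTS))

    sid = section_id or f"synthetic-{genotype}"
    spot_ids = [f"{sid}-S{i:05d}" for i in range(s.size)]
    meta = pd.DataFrame(
        {
            "in_tissue": True,
            "domain": domains,
            "genotype": genotype,
        },
        index=pd.Index(spot_ids),
    )
    section = SpatialSection(
        spot_ids=spot_ids,
        coords=coords,
        array_pos=array_pos,
        counts=sp.csr_matrix(counts),
        gene_ids=genes,
        section_id=sid,
        metadata=meta,
    )
    _, class_of, module_of = config.gene_names()
    truth = SyntheticTruth(
        domain_of_spot=pd.Series(domains, index=spot_ids, name="domain"),
        true_spatialtime=pd.Series(s, index=spot_ids, name="true_spatialtime"),
        class_of_gene=pd.Series([class_of.get(g, "none") for g in genes], index=genes, name="class"),
        module_of_gene=pd.Series([module_of.get(g, "none") for g in genes], index=genes, name="module"),
        genotype=genotype,
        config=config,
    )
    return section, truth


def generate_pair(config: SyntheticConfig) -> dict:
    """Control and mutant sections sharing gene universe, lattice and plane.

    The two sections differ only in the genotype multipliers applied to
    module genes and in the noise realization (distinct derived seeds).
    """
    control = generate_section(config, "control", seed_offset=_OFF_CONTROL, section_id="control")
    mutant = generate_section(config, "mutant", seed_offset=_OFF_MUTANT, section_id="mutant")
    return {"control": control, "mutant": mutant}


@dataclass
class OrthologTable:
    """Strictly one-to-one symbol correspondence between two gene universes."""

    pairs: pd.DataFrame  # columns: symbol_a, symbol_b

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.pairs)
        df.columns = ["symbol_a", "symbol_b"][: df.shape[1]]
        for col in ("symbol_a", "symbol_b"):
            dup = df[col][df[col].duplicated()]
            if len(dup):
                raise ValueError(f"ortholog table has duplicated symbol(s) in {col}: "
                                 f"{sorted(set(dup))[:5]}")
        self.pairs = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.pairs)

    def to_tsv(self, path: str | Path) -> None:
        self.pairs.to_csv(path, sep="\t", index=False)


def generate_ortholog_pair(
    config: SyntheticConfig,
    n_shared: int | None = None,
    scramble: float = 0.0,
) -> tuple:
    """Two 'species' sections linked by a one-to-one ortholog table.

    Section B is generated with section A's domain structure but a fresh
    noise realization and renamed symbols (``<gene>:B``).  The ortholog
    table covers ``n_shared`` genes (marker genes first).  A fraction
    ``scramble`` of the shared genes have their ortholog links permuted
    among themselves, so their section-B counterparts carry unrelated
    structure: at ``scramble=1`` the table is a random gene-to-gene pairing
    and cluster correspondence degrades to the permutation null.

    Returns ``(section_a, section_b, ortholog_table, truth)`` where truth
    holds both sections' ground truth plus the scrambled-link gene list.
    """
    if not 0.0 <= scramble <= 1.0:
        raise ValueError("scramble must lie in [0, 1]")
    genes, _, _ = config.gene_names()
    if n_shared is None:
        n_shared = len(genes)
    if n_shared > len(genes):
        raise ValueError(f"n_shared={n_shared} exceeds gene count {len(genes)}")

    section_a, truth_a = generate_section(config, "control", section_id="speciesA")
    section_b, truth_b = generate_section(
        config, "control", seed_offset=_OFF_ORTHOLOG, section_id="speciesB"
    )
    section_b = SpatialSection(
        spot_ids=[f"speciesB-S{i:05d}" for i in range(section_b.n_spots)],
        coords=section_b.coords,
        array_pos=section_b.array_pos,
        counts=section_b.counts,
        gene_ids=[f"{g}:B" for g in section_b.gene_ids],
        section_id="speciesB",
        metadata=section_b.metadata.set_axis(
            pd.Index([f"speciesB-S{i:05d}" for i in range(section_b.n_spots)])
        ),
    )
    truth_b = SyntheticTruth(
        domain_of_spot=truth_b.domain_of_spot.set_axis(pd.Index(section_b.spot_ids)),
        true_spatialtime=truth_b.true_spatialtime.set_axis(pd.Index(section_b.spot_ids)),
        class_of_gene=truth_b.class_of_gene.set_axis(pd.Index(section_b.gene_ids)),
        module_of_gene=truth_b.module_of_gene.set_axis(pd.Index(section_b.gene_ids)),
        genotype="control",
        config=config,
    )

    markers = [g for g in genes if g.startswith("MK-")]
    ordered = markers + [g for g in genes if not g.startswith("MK-")]
    shared = ordered[:n_shared]

    rng = np.random.default_rng(config.seed + _OFF_ORTHOLOG)
    n_scramble = int(round(scramble * len(shared)))
    links = {g: g for g in shared}
    scrambled: list[str] = []
    if n_scramble >= 2:
        scrambled = sorted(rng.choice(shared, size=n_scramble, replace=False))
        perm = rng.permutation(n_scramble)
        for g, p in zip(scrambled, perm):
            links[g] = scrambled[p]
    table = OrthologTable(pd.DataFrame({
        "symbol_a": shared,
        "symbol_b": [f"{links[g]}:B" for g in shared],
    }))
    truth = {
        "a": truth_a,
        "b": truth_b,
        "scrambled_links": scrambled,
        "scramble": scramble,
    }
    return section_a, section_b, table, truth


def write_synthetic_dataset(
    section: SpatialSection, truth: SyntheticTruth, path: str | Path
) -> Path:
    """Write the 10x-style layout plus truth tables and the config JSON."""
    path = write_spatial_dataset(section, path)
    spot_truth = pd.DataFrame({
        "barcode": truth.domain_of_spot.index,
        "domain": truth.domain_of_spot.values,
        "true_spatialtime": truth.true_spatialtime.values,
    })
    spot_truth.to_csv(path / "truth_spots.tsv", sep="\t", index=False)
    gene_truth = pd.DataFrame({
        "gene": truth.class_of_gene.index,
        "class": truth.class_of_gene.values,
        "module": truth.module_of_gene.values,
    })
    gene_truth.to_csv(path / "truth_genes.tsv", sep="\t", index=False)
    truth.config.to_json(path / "config.json")
    return path
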