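"""End-to-end orchestration: simulate -> preprocess -> cluster -> distance
axis -> module scores -> trajectory -> cross-species map -> enrichment.

A single JSON config drives every stage; per-stage seeds derive from the
global seed by fixed offsets so reruns are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, crossspecies, enrichment, scoring, spatialtime, synthetic, trajectory
from .io import filter_genes, normalize_log_cpm

logger = logging.getLogger(__name__)

STAGE_ORDER = (
    "simulate", "preprocess", "cluster", "spatialtime",
    "score", "trajectory", "crossmap", "gsea",
)

# per-stage seed offsets from the global seed
_SEED_OFFSETS = {name: 1000 * (i + 1) for i, name in enumerate(STAGE_ORDER)}

# stages that cannot run if an upstream stage is disabled
_REQUIRES = {
    "preprocess": ("simulate",),
    "cluster": ("preprocess",),
    "spatialtime": ("preprocess",),
    "score": ("preprocess", "spatialtime"),
    "trajectory": ("cluster", "spatialtime"),
    "gsea": ("spatialtime",),
    "crossmap": (),
}


@dataclass
class PipelineConfig:
    out_dir: str = "run"
    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in STAGE_ORDER})
    synthetic: dict = field(default_factory=dict)       # SyntheticConfig overrides
    preprocess: dict = field(default_factory=lambda: {"min_fraction": 0.003})
    cluster: dict = field(default_factory=lambda: {
        "n_components": 20, "k_neighbors": 15, "resolution": 1.0, "umap": False})
    spatialtime_params: dict = field(default_factory=lambda: {
        "df": 3, "q_threshold": 0.05, "n_classes": 4})
    score: dict = field(default_factory=lambda: {"n_bins": 24, "n_ctrl": 100, "curve_bins": 20,
                                                 "n_perm": 500})
    trajectory_params: dict = field(default_factory=lambda: {"hvg_n": 2000, "n_pcs": 10})
    crossmap: dict = field(default_factory=lambda: {"n_shared": None, "scramble": 0.0,
                                                    "n_perm": 500, "min_shared": 50})
    gsea: dict = field(default_factory=lambda: {"n_perm": 500, "weight": 1.0})

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=list))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))

    def stage_seed(self, stage: str) -> int:
        return self.seed + _SEED_OFFSETS[stage]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run enabled stages in dependency order; return the manifest.

    A stage failure halts the run (the manifest written so far names the
    stage and cause); stages whose prerequisites are disabled are skipped
    with a logged reason.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "outputs": {}}
    state: dict = {}

    enabled = dict(config.stages)
    for stage in STAGE_ORDER:
        if not enabled.get(stage, False):
            continue
        missing = [r for r in _REQUIRES.get(stage, ()) if not enabled.get(r, False)]
        if missing:
            logger.warning("stage %s disabled: requires %s", stage, missing)
            enabled[stage] = False
            manifest["stages"][stage] = {"skipped": f"requires disabled stage(s) {missing}"}

    for stage in STAGE_ORDER:
        if not enabled.get(stage, False):
            continue
        t0 = time.monotonic()
        logger.info("stage %s starting", stage)
        try:
            outputs = _STAGE_FN[stage](config, state, out)
        except Exception as exc:
            manifest["stages"][stage] = {"failed": str(exc)}
            _write_manifest(manifest, out)
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        elapsed = time.monotonic() - t0
        manifest["stages"][stage] = {
            "elapsed_s": round(elapsed, 3),
            "seed": config.stage_seed(stage),
            "params": _stage_params(config, stage),
        }
        for f in outputs:
            manifest["outputs"][str(f.relative_to(out))] = _sha256(f)
        logger.info("stage %s done in %.2fs", stage, elapsed)

    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _stage_params(config: PipelineConfig, stage: str) -> dict:
    return {
        "simulate": config.synthetic, "preprocess": config.preprocess,
        "cluster": config.cluster, "spatialtime": config.spatialtime_params,
        "score": config.score, "trajectory": config.trajectory_params,
        "crossmap": config.crossmap, "gsea": config.gsea,
    }[stage]


def _stage_simulate(config: PipelineConfig, state: dict, out: Path) -> list[Path]:
    cfg = synthetic.SyntheticConfig(**{**config.synthetic, "seed": config.stage_seed("simulate")})
    pair = synthetic.generate_pair(cfg)
    files = []
    for genotype, (section, truth) in pair.items():
        d = synthetic.write_synthetic_dataset(section, truth, out / "simulate" / genotype)
        files.extend(sorted(d.iterdir()))
    state["config_synthetic"] = cfg
    state["pair"] = pair
    return files


def _stage_preprocess(config: PipelineConfig, state: dict, out: Path) -> list[Path]:
    d = out / "preprocess"
    d.mkdir(parents=True, exist_ok=True)
    files = []
    state["norm"] = {}
    for genotype, (section, _) in state["pair"].items():
        filtered = filter_genes(section, **config.preprocess)
        norm = normalize_log_cpm(filtered)
        state["norm"][genotype] = norm
        state["pair"][genotype] = (filtered, state["pair"][genotype][1])
        f = d / f"genes_kept_{genotype}.tsv"
        pd.Series(filtered.gene_ids, name="gene").to_csv(f, sep="\t", index=False)
        files.append(f)
    return files


def _stage_cluster(config: PipelineConfig, state: dict, out: Path) -> list[Path]:
    d = out / "cluster"
    d.mkdir(parents=True, exist_ok=True)
    p = config.cluster
    emb = clustering.integrate_sections(list(state["norm"].values()), n_components=p["n_components"])
    assign = clustering.cluster_graph(
        emb, k_neighbors=p["k_neighbors"], resolution=p["resolution"],
        seed=config.stage_seed("cluster"),
    )
    state["embedding"], state["clusters"] = emb, assign
    files = []
    tbl = pd.DataFrame({"barcode": assign.spot_ids, "section": assign.section_of_spot,
                        "cluster": assign.labels})
    f = d / "clusters.tsv"
    tbl.to_csv(f, sep="\t", index=False)
    files.append(f)
    markers = clustering.find_markers(state["norm"]["control"], assign.series())
    f = d / "markers_control.tsv"
    markers.to_csv(f, sep="\t", index=False)
    state["markers_control"] = markers
    files.append(f)
    if p.get("umap"):
        xy = clustering.embed_umap(emb, seed=config.stage_seed("cluster"))
        f = d / "umap.csv"
        pd.DataFrame(xy, columns=["umap1", "umap2"], index=assign.spot_ids).to_csv(f)
        files.append(f)
    return files


def _stage_spatialtime(config: PipelineConfig, state: dict, out: Path) -> list[Path]:
    d = out / "spatialtime"
    d.mkdir(parents=True, exist_ok=True)
    p = config.spatialtime_params
    cfg = state["config_synthetic"]
    coords = state["pair"]["control"][0].coords
    if cfg.plane_points is not None:
        plane = spatialtime.FracturePlane(points=np.asarray(cfg.plane_points, dtype=float))
    else:
        plane = synthetic._default_plane(coords)
    files = [d / "plane.csv"]
    plane.to_csv(files[0])
    state["st"] = {}
    for genotype, (section, _) in state["pair"].items():
        st = spatialtime.assign_spatialtime(section, plane)
        state["st"][genotype] = st
        f = d / f"spatialtime_{genotype}.tsv"
        st.to_frame().to_csv(f, sep="\t", index=False)
        files.append(f)
    trends = spatialtime.fit_gene_trends(
        state["norm"]["control"], state["st"]["control"],
        df=p["df"], q_threshold=p["q_threshold"],
    )
    trends = spatialtime.classify_trends(trends, k=p["n_classes"], q_threshold=p["q_threshold"])
    state["trends"] = trends
    f = d / "trends.tsv"
    spatialtime.trends_frame(trends).to_csv(f, sep="\t", index=False)
    files.append(f)
    return files


def _stage_score(config: PipelineConfig, state: dict, out: Path) -> list[Path]:
    d = out / "score"
    d.mkdir(parents=True, exist_ok=True)
    p = config.score
    truth = state["pair"]["control"][1]
    modules = sorted(set(truth.module_of_gene) - {"none"})
    seed = config.stage_seed("score")
    all_scores, comparisons = {}, {}
    for mod in modules:
        gs = scoring.GeneSet(name=mod, genes=tuple(truth.module_genes(mod)))
        per_genotype = {}
        for genotype, norm in state["norm"].items():
            res = scoring.score_module(norm, gs, n_bins=p["n_bins"], n_ctrl=p["n_ctrl"], seed=seed)
            per_genotype[genotype] = res.scores
            all_scores[(mod, genotype)] = res.scores
        cmp = spatialtime.compare_genotypes(
            per_genotype["control"], state["st"]["control"],
            per_genotype["mutant"], state["st"]["mutant"],
            n_bins=p["curve_bins"], n_perm=p["n_perm"], seed=seed,
        )
        comparisons[mod] = {
            "delta_auc": cmp.delta_auc, "peak_shift": cmp.peak_shift,
            "p_value": cmp.p_value, "peak_control": cmp.curve_a.peak,
            "peak_mutant": cmp.curve_b.peak,
        }
    files = []
    score_tbl = pd.concat(
        {k: v for k, v in all_scores.items()}, axis=1
    )
    score_tbl.columns = [f"{m}:{g}" for m, g in score_tbl.columns]
    f = d / "scores.tsv"
    score_tbl.to_csv(f, sep="\t")
    files.append(f)
    f = d / "genotype_comparison.json"
    f.write_text(json.dumps(comparisons, indent=2))
    files.append(f)
    state["comparisons"] = comparisons
    return files


def _stage_trajectory(config: PipelineConfig, state: dict, out: Path) -> list[Path]:
    d = out / "trajectory"
    d.mkdir(parents=True, exist_ok=True)
    p = config.trajectory_params
    labels = state["clusters"].series()
    norm = state["norm"]["control"]
    labels = labels.loc[labels.index.intersection(norm.spot_ids)]
    s = state["st"]["control"].series()
    # root = cluster with the lowest mean distance-axis value (nearest the plane)
    mean_s = s.groupby(labels.loc[s.index.intersection(labels.index)]).mean()
    root = mean_s.idxmin()
    traj = trajectory.infer_trajectory(norm, labels, root_cluster=root,
                                       hvg_n=p["hvg_n"], n_pcs=p["n_pcs"])
    pt = traj.series()
    terminal = mean_s.idxmax()
    sub = pt.loc[labels[labels == terminal].index.intersection(pt.index)]
    result = {"root_cluster": int(root), "terminal_cluster": int(terminal)}
    if len(sub) >= 20:
        fit = trajectory.detect_bimodality(sub, seed=config.stage_seed("trajectory"))
        result["n_components"] = fit.n_components
        result["delta_bic"] = fit.delta_bic
        if fit.bimodal:
            cmp = trajectory.compare_groups_spatialtime(fit, state["st"]["control"])
            result["spatialtime_comparison"] = cmp
        comp = fit.assignment.reindex(pt.index).fillna("other")
    else:
        comp = pd.Series("other", index=pt.index)
    tbl = pd.DataFrame({"barcode": pt.index, "pseudotime": pt.values,
                        "cluster": labels.reindex(pt.index).values,
                        "component": comp.values})
    files = [d / "pseudotime.tsv", d / "bimodality.json"]
    tbl.to_csv(files[0], sep="\t", index=False)
    files[1].write_text(json.dumps(result, indent=2, default=float))
    return files


def _stage_crossmap(config: PipelineConfig, state: dict, out: Path) -> list[Path]:
    d = out / "crossmap"
    d.mkdir(parents=True, exist_ok=True)
    p = config.crossmap
    cfg = synthetic.SyntheticConfig(
        **{**config.synthetic, "seed": config.stage_seed("crossmap")})
    sec_a, sec_b, table, _truth = synthetic.generate_ortholog_pair(
        cfg, n_shared=p["n_shared"], scramble=p["scramble"])
    norm_a = normalize_log_cpm(filter_genes(sec_a, **config.preprocess))
    norm_b = normalize_log_cpm(filter_genes(sec_b, **config.preprocess))
    dom_a = sec_a.metadata["domain"]
    dom_b = sec_b.metadata["domain"]
    mk_a = clustering.find_markers(norm_a, dom_a)
    mk_b = clustering.find_markers(norm_b, dom_b)
    omap = crossspecies.OrthologMap.from_table(table.pairs)
    paired = crossspecies.harmonize_orthologs(mk_a, mk_b, omap, min_shared=p["min_shared"])
    corr = crossspecies.cluster_correspondence(
        paired, n_perm=p["n_perm"], seed=config.stage_seed("crossmap"))
    files = [d / "correspondence.tsv", d / "best_matches.json", d / "orthologs.tsv"]
    corr.scores.to_csv(files[0], sep="\t")
    files[1].write_text(json.dumps(
        {"a_to_b": {str(k): str(v) for k, v in corr.best_a_to_b.items()},
         "b_to_a": {str(k): str(v) for k, v in corr.best_b_to_a.items()}}, indent=2))
    table.to_tsv(files[2])
    return files


def _stage_gsea(config: PipelineConfig, state: dict, out: Path) -> list[Path]:
    d = out / "gsea"
    d.mkdir(parents=True, exist_ok=True)
    p = config.gsea
    trends = state["trends"]
    ranked = enrichment.RankedList(
        genes=np.array([t.gene for t in trends], dtype=object),
        metric=np.array([t.statistic for t in trends]),
    )
    truth = state["pair"]["control"][1]
    sets = [
        scoring.GeneSet(name=c, genes=tuple(truth.class_genes(c)))
        for c in sorted(set(truth.class_of_gene) - {"none"})
    ]
    res = enrichment.preranked_significance(
        ranked, sets, n_perm=p["n_perm"], seed=config.stage_seed("gsea"),
        weight=p["weight"],
    )
    f = d / "enrichment.tsv"
    res.table.to_csv(f, sep="\t", index=False)
    return [f]


_STAGE_FN = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "cluster": _stage_cluster,
    "spatialtime": _stage_spatialtime,
    "score": _stage_score,
    "trajectory": _stage_trajectory,
    "crossmap": _stage_crossmap,
    "gsea": _stage_gsea,
}
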