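"""Stage orchestration: one config, file-based stages, recorded provenance.

Each stage consumes only files written by upstream stages (no hidden state),
writes its outputs plus a manifest with SHA-256 hashes of its inputs and
outputs, and is byte-identical on rerun with identical inputs.  Stages:

    simulate   -> synthetic bundle (expression, metadata, GMT, PPI, truth)
    preprocess -> filtered log2 matrix, sample PCA
    network    -> soft-threshold scan (optional), module partition, eigengenes
    shared     -> stage trajectories, shared-module report
    enrich     -> per-module over-representation tables
    hubs       -> induced-PPI centralities, hub reports, coverage
    assays     -> qPCR fold changes and viability percentages from small TSVs
    run_all    -> all of the above in order
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import assays as assay_ops
from . import enrichment as enrich_ops
from . import ppi as ppi_ops
from .errors import ConfigError, StageError
from .expression import filter_genes, log_transform, pca_samples, read_expression
from .network import (
    cluster_modules,
    correlation_matrix,
    module_eigengenes,
    pick_soft_threshold,
    signed_adjacency,
    topological_overlap,
    ModulePartition,
)
from .simulate import SimConfig, generate_bundle
from .trajectories import shared_module_report, stage_trajectories

log = logging.getLogger("cochnet")

STAGES = ("simulate", "preprocess", "network", "shared", "enrich", "hubs",
          "assays")


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline, with study defaults."""

    bundle_dir: str = "bundle"
    out_dir: str = "results"
    # preprocess
    fpkm_threshold: float = 0.5
    min_fraction: float = 0.5
    pca_components: int = 2
    # network
    beta: float | None = 15.0  # None -> run the soft-threshold scan
    scan_candidates: tuple[float, ...] = (1, 2, 3, 4, 5, 6, 8, 10, 12, 15, 18, 20)
    scan_r2_target: float = 0.85
    min_module_size: int = 30
    cut_height: float | None = 0.95
    cut_quantile: float = 0.99
    merge_cutoff: float = 0.75
    # shared modules
    r_threshold: float = 0.85
    min_pairs: int = 1
    avg_highlight: float = 0.92
    flat_tol: float = 0.0
    min_amplitude: float | None = None  # None -> 0.5/sqrt(n_samples)
    # enrichment
    enrich_top_k: int = 5
    fdr_line: float = 0.05
    # PPI hubs
    score_threshold: int = 400
    hub_k: int = 15
    # assays (optional input tables; built-in demo rows when absent)
    qpcr_path: str | None = None
    viability_path: str | None = None
    seed: int = 42
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0 <= self.min_fraction <= 1:
            raise ConfigError("min_fraction must lie in [0, 1]")
        if self.fpkm_threshold < 0:
            raise ConfigError("fpkm_threshold must be >= 0")
        if self.beta is not None and self.beta < 1:
            raise ConfigError("beta must be >= 1 (or null to scan)")
        if self.min_module_size < 2:
            raise ConfigError("min_module_size must be >= 2")
        for name in ("r_threshold", "avg_highlight", "merge_cutoff"):
            v = getattr(self, name)
            if not -1 <= v <= 1:
                raise ConfigError(f"{name} must lie in [-1, 1]")
        if self.min_pairs not in (1, 2, 3):
            raise ConfigError("min_pairs must be 1, 2 or 3")
        if self.cut_height is not None and not 0 < self.cut_height <= 1:
            raise ConfigError("cut_height must lie in (0, 1]")
        if not 0 < self.cut_quantile <= 1:
            raise ConfigError("cut_quantile must lie in (0, 1]")
        if self.enrich_top_k <= 0 or self.hub_k <= 0:
            raise ConfigError("enrich_top_k and hub_k must be positive")
        if not 0 <= self.score_threshold <= 999:
            raise ConfigError("score_threshold must lie in [0, 999]")

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("sim", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d) if sim is None else cls(**d, sim=_sim_from_dict(sim))
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _sim_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(d) - known
    if unknown:
        raise ConfigError(f"unknown sim config keys: {sorted(unknown)}")
    for key in ("module_sizes", "module_profiles", "loading_range",
                "score_range"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    return SimConfig(**d)


# ---------------------------------------------------------------------------
# manifest helpers


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(stage: str, cfg: PipelineConfig, out_dir: Path,
                    inputs: list[Path], outputs: list[Path]) -> Path:
    manifest = {
        "stage": stage,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "inputs": {p.name: _sha256(p) for p in sorted(inputs)},
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
    }
    path = out_dir / f"{stage}_manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return path


def _require(path: Path, producing_stage: str) -> Path:
    if not path.exists():
        raise StageError(
            f"missing upstream artifact {path.name}; "
            f"run the '{producing_stage}' stage first"
        )
    return path


def _outdir(cfg: PipelineConfig) -> Path:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


# ---------------------------------------------------------------------------
# stages


def run_simulate(cfg: PipelineConfig) -> dict:
    """Generate the synthetic bundle into ``cfg.bundle_dir``."""
    sim = dataclasses.replace(cfg.sim, seed=cfg.seed)
    generate_bundle(sim, cfg.bundle_dir, overwrite=True)
    log.info("simulate: wrote bundle to %s (seed=%d)", cfg.bundle_dir, cfg.seed)
    out = _outdir(cfg)
    bundle = Path(cfg.bundle_dir)
    _write_manifest("simulate", cfg, out, [], sorted(bundle.iterdir()))
    return {"bundle_dir": cfg.bundle_dir}


def run_preprocess(cfg: PipelineConfig) -> dict:
    bundle = Path(cfg.bundle_dir)
    expr_path = _require(bundle / "expression.tsv", "simulate")
    meta_path = _require(bundle / "metadata.tsv", "simulate")
    m = read_expression(expr_path, meta_path)
    filtered = filter_genes(m, cfg.fpkm_threshold, cfg.min_fraction)
    logm = log_transform(filtered)
    pca = pca_samples(logm, n_components=cfg.pca_components)
    out = _outdir(cfg)
    log2_path = out / "log2_expression.tsv"
    logm.values.to_csv(log2_path, sep="\t")
    pca_path = out / "pca_coordinates.tsv"
    pca.coordinates.rename_axis("sample_id").to_csv(pca_path, sep="\t")
    var_path = out / "pca_variance.tsv"
    pd.DataFrame({
        "component": [f"PC{i + 1}" for i in range(len(pca.variance_ratio))],
        "variance_fraction": pca.variance_ratio,
    }).to_csv(var_path, sep="\t", index=False)
    log.info("preprocess: %d/%d genes retained", filtered.values.shape[0],
             m.values.shape[0])
    _write_manifest("preprocess", cfg, out, [expr_path, meta_path],
                    [log2_path, pca_path, var_path])
    return {"n_genes_in": int(m.values.shape[0]),
            "n_genes_retained": int(filtered.values.shape[0])}


def _read_log2(cfg: PipelineConfig):
    out = Path(cfg.out_dir)
    log2_path = _require(out / "log2_expression.tsv", "preprocess")
    meta_path = _require(Path(cfg.bundle_dir) / "metadata.tsv", "simulate")
    m = read_expression(log2_path, meta_path)
    # re-tag: file holds log2 values
    m.scale = "log2"
    return m, log2_path, meta_path


def run_network(cfg: PipelineConfig) -> dict:
    m, log2_path, meta_path = _read_log2(cfg)
    out = _outdir(cfg)
    outputs = []
    if cfg.beta is None:
        scan = pick_soft_threshold(m, cfg.scan_candidates, cfg.scan_r2_target)
        beta = scan.beta
        scan_path = out / "soft_threshold_scan.tsv"
        scan.table.to_csv(scan_path, sep="\t", index=False)
        outputs.append(scan_path)
    else:
        beta = cfg.beta
    cor, constant = correlation_matrix(m)
    a = signed_adjacency(cor, beta)
    tom = topological_overlap(a)
    part = cluster_modules(
        pd.DataFrame(tom, index=cor.index, columns=cor.columns), m,
        min_module_size=cfg.min_module_size, cut_height=cfg.cut_height,
        cut_quantile=cfg.cut_quantile, merge_cutoff=cfg.merge_cutoff,
    )
    me = module_eigengenes(m, part)
    part_path = out / "module_partition.tsv"
    part.labels.rename("module").to_csv(part_path, sep="\t")
    me_path = out / "module_eigengenes.tsv"
    me.rename_axis("module").to_csv(me_path, sep="\t")
    summary = {
        "beta": beta,
        "n_modules": len(part.modules()),
        "n_unassigned": int((part.labels == "M0").sum()),
        "n_constant_genes": len(constant),
        "module_sizes": {lab: len(part.members(lab)) for lab in part.modules()},
    }
    summary_path = out / "network_summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    outputs += [part_path, me_path, summary_path]
    log.info("network: beta=%s, %d modules", beta, summary["n_modules"])
    _write_manifest("network", cfg, out, [log2_path, meta_path], outputs)
    return summary


def run_shared(cfg: PipelineConfig) -> dict:
    out = _outdir(cfg)
    me_path = _require(out / "module_eigengenes.tsv", "network")
    meta_path = _require(Path(cfg.bundle_dir) / "metadata.tsv", "simulate")
    me = pd.read_csv(me_path, sep="\t", index_col=0)
    design = pd.read_csv(meta_path, sep="\t")
    traj = stage_trajectories(me, design)
    report = shared_module_report(
        traj, r_threshold=cfg.r_threshold, min_pairs=cfg.min_pairs,
        avg_highlight=cfg.avg_highlight, flat_tol=cfg.flat_tol,
        min_amplitude=cfg.min_amplitude,
    )
    traj_path = out / "stage_trajectories.tsv"
    traj.values.to_csv(traj_path, sep="\t")
    report_path = out / "shared_modules.tsv"
    report.to_csv(report_path, sep="\t", index=False)
    summary = {
        "selected": report.loc[report["selected"], "module"].tolist(),
        "highlighted": report.loc[report["highlighted"], "module"].tolist(),
        "directions": dict(zip(report["module"], report["direction"])),
    }
    summary_path = out / "shared_summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    log.info("shared: %d selected, %d highlighted",
             len(summary["selected"]), len(summary["highlighted"]))
    _write_manifest("shared", cfg, out, [me_path, meta_path],
                    [traj_path, report_path, summary_path])
    return summary


def _read_partition(out: Path) -> ModulePartition:
    part_path = _require(out / "module_partition.tsv", "network")
    labels = pd.read_csv(part_path, sep="\t", index_col=0)["module"]
    return ModulePartition(labels)


def run_enrich(cfg: PipelineConfig) -> dict:
    out = _outdir(cfg)
    gmt_path = _require(Path(cfg.bundle_dir) / "annotations.gmt", "simulate")
    part = _read_partition(out)
    sets = enrich_ops.read_gmt(gmt_path)
    members = {lab: part.members(lab) for lab in part.modules()}
    full, tops = enrich_ops.enrich_modules(
        members, sets, top_k=cfg.enrich_top_k, fdr_line=cfg.fdr_line,
    )
    full_path = out / "enrichment.tsv"
    full.to_csv(full_path, sep="\t", index=False)
    top_path = out / "enrichment_top.tsv"
    tops.to_csv(top_path, sep="\t", index=False)
    log.info("enrich: %d modules x %d terms", len(members), len(sets))
    _write_manifest("enrich", cfg, out,
                    [gmt_path, out / "module_partition.tsv"],
                    [full_path, top_path])
    return {"n_terms": len(sets), "n_modules": len(members)}


def run_hubs(cfg: PipelineConfig) -> dict:
    out = _outdir(cfg)
    edges_path = _require(Path(cfg.bundle_dir) / "ppi_edges.tsv", "simulate")
    shared_path = _require(out / "shared_summary.json", "shared")
    part = _read_partition(out)
    with open(shared_path) as fh:
        shared = json.load(fh)
    g = ppi_ops.read_edge_list(edges_path, score_threshold=cfg.score_threshold)

    # the paper's grouping: pooled co-up-regulated and co-down-regulated
    # genes of the selected modules, plus each selected module on its own
    groups: dict[str, list[str]] = {}
    for direction in ("up", "down"):
        pooled: list[str] = []
        for lab in shared["selected"]:
            if shared["directions"].get(lab) == direction:
                pooled += part.members(lab)
        if pooled:
            groups[f"{direction}_selected"] = pooled
    for lab in shared["selected"]:
        groups[lab] = part.members(lab)

    reports = {}
    outputs = []
    for name, genes in groups.items():
        try:
            table, report, missing = ppi_ops.module_hub_analysis(
                g, genes, k=cfg.hub_k
            )
        except Exception as exc:  # no module gene in the network
            log.warning("hubs: skipping %s (%s)", name, exc)
            continue
        cent_path = out / f"centrality_{name}.tsv"
        table.to_csv(cent_path, sep="\t", index=False)
        outputs.append(cent_path)
        rep = report.to_dict()
        rep["genes_absent_from_network"] = len(missing)
        reports[name] = rep
    hubs_path = out / "hub_reports.json"
    with open(hubs_path, "w") as fh:
        json.dump(reports, fh, indent=1, sort_keys=True)
    outputs.append(hubs_path)
    log.info("hubs: analysed %d gene groups", len(reports))
    _write_manifest("hubs", cfg, out,
                    [edges_path, shared_path, out / "module_partition.tsv"],
                    outputs)
    return reports


# built-in demonstration rows for the assays stage when no tables are given:
# Ct quadruples (target/ref under treatment/control) and OD triples.
_DEMO_QPCR = [
    ("IL1B_demo", 25.0, 20.0, 24.0, 20.0),
    ("CCL2_demo", 23.0, 20.0, 24.0, 20.0),
    ("flat_demo", 24.0, 20.0, 24.0, 20.0),
]
_DEMO_VIABILITY = [
    ("untreated_demo", 1.20, 0.10, 1.20),
    ("low_dose_demo", 0.65, 0.10, 1.20),
    ("high_dose_demo", 0.21, 0.10, 1.20),
]


def run_assays(cfg: PipelineConfig) -> dict:
    out = _outdir(cfg)
    inputs = []
    if cfg.qpcr_path is not None:
        qpcr = pd.read_csv(_require(Path(cfg.qpcr_path), "assays input"),
                           sep="\t")
        inputs.append(Path(cfg.qpcr_path))
    else:
        qpcr = pd.DataFrame(
            _DEMO_QPCR,
            columns=["label", "ct_target_trt", "ct_ref_trt", "ct_target_ctl",
                     "ct_ref_ctl"],
        )
    qpcr = qpcr.copy()
    qpcr["fold_change"] = [
        assay_ops.delta_delta_ct(r.ct_target_trt, r.ct_ref_trt,
                                 r.ct_target_ctl, r.ct_ref_ctl)
        for r in qpcr.itertuples(index=False)
    ]
    if cfg.viability_path is not None:
        via = pd.read_csv(_require(Path(cfg.viability_path), "assays input"),
                          sep="\t")
        inputs.append(Path(cfg.viability_path))
    else:
        via = pd.DataFrame(
            _DEMO_VIABILITY, columns=["label", "od_exp", "od_pos", "od_neg"]
        )
    via = via.copy()
    results = [
        assay_ops.relative_viability(r.od_exp, r.od_pos, r.od_neg)
        for r in via.itertuples(index=False)
    ]
    via["viability_pct"] = [v for v, _ in results]
    via["out_of_range"] = [f for _, f in results]
    qpcr_path = out / "qpcr_fold_changes.tsv"
    qpcr.to_csv(qpcr_path, sep="\t", index=False)
    via_path = out / "viability.tsv"
    via.to_csv(via_path, sep="\t", index=False)
    log.info("assays: %d qPCR rows, %d viability rows", len(qpcr), len(via))
    _write_manifest("assays", cfg, out, inputs, [qpcr_path, via_path])
    return {"n_qpcr": len(qpcr), "n_viability": len(via)}


_STAGE_FUNCS = {
    "simulate": run_simulate,
    "preprocess": run_preprocess,
    "network": run_network,
    "shared": run_shared,
    "enrich": run_enrich,
    "hubs": run_hubs,
    "assays": run_assays,
}


def run_stage(name: str, cfg: PipelineConfig) -> dict:
    """Run one named stage; raises :class:`StageError` on unknown names."""
    if name not in _STAGE_FUNCS:
        raise StageError(f"unknown stage {name!r}; choose from {STAGES}")
    return _STAGE_FUNCS[name](cfg)


def run_all(cfg: PipelineConfig) -> dict[str, dict]:
    """Run every stage in dependency order; returns per-stage summaries."""
    return {name: run_stage(name, cfg) for name in STAGES}
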