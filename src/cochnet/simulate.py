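"""Synthetic FPKM bundles with planted co-expression structure.

The generator emulates a three-model sensorineural hearing-loss (SNHL) study
design: aging, noise-exposure and cisplatin-ototoxicity mouse cochleae sampled
at a shared healthy control stage plus an early and a late damage stage per
model, 27 bulk RNA-seq samples in total by default.  Every planted quantity —
gene-to-module assignment, per-model stage templates, enriched annotation
terms, PPI hub genes — is recorded in a :class:`GroundTruth` object so that
downstream recovery can be scored.

The expression model is a loading/template factor model on the log2 scale:

    x_gs = mu_g + lambda_g * E_m(model(s), stage(s)) + eps_gs

with eps ~ Normal(0, noise_sd^2) i.i.d., lambda_g = 0 for background genes,
and emitted FPKM = 2**x - 1 clipped at zero (the exact inverse of the
pipeline's log2(FPKM + 1) transform).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import BundleError, ConfigError, DesignError

MODELS = ("aging", "noise", "cisplatin")
STAGES = ("control", "early", "late")
#: sentinel model label for the control group shared by all three models
SHARED = "shared"

# Stage templates on the log2 scale, (control, early, late) per model.
_ARCHETYPES = {
    "shared_up": {m: (0.0, 1.0, 2.0) for m in MODELS},
    "shared_down": {m: (0.0, -1.0, -2.0) for m in MODELS},
    "null_flat": {m: (0.0, 0.0, 0.0) for m in MODELS},
}


def archetype_templates(name: str) -> dict[str, tuple[float, float, float]]:
    """Resolve a profile archetype name to per-model stage templates.

    ``model_specific:<model>`` rises (0, 1, 2) in the named model and stays
    flat in the other two; the control value is 0 for every archetype so the
    shared control group is consistent across models.
    """
    if name in _ARCHETYPES:
        return {m: tuple(v) for m, v in _ARCHETYPES[name].items()}
    if name.startswith("model_specific:"):
        target = name.split(":", 1)[1]
        if target not in MODELS:
            raise ConfigError(f"unknown model in archetype {name!r}")
        return {
            m: (0.0, 1.0, 2.0) if m == target else (0.0, 0.0, 0.0) for m in MODELS
        }
    raise ConfigError(f"unknown profile archetype {name!r}")


@dataclass
class SimConfig:
    """Configuration of one synthetic bundle.

    Defaults emulate the 27-sample cochlear design: a single control group of
    12 shared replicates plus, for each of the three models, 3 early- and 2
    late-stage replicates, and six planted modules (shared up, shared down,
    one model-specific module per model, and one flat null module).
    """

    n_genes: int = 2000
    module_sizes: tuple[int, ...] = (200, 200, 200, 200, 200, 100)
    module_profiles: tuple[str, ...] = (
        "shared_up",
        "shared_down",
        "model_specific:aging",
        "model_specific:noise",
        "model_specific:cisplatin",
        "null_flat",
    )
    n_background_genes: int | None = None  # default: n_genes - sum(module_sizes)
    control_replicates: int = 12
    model_replicates: dict[str, dict[str, int]] = field(
        default_factory=lambda: {
            m: {"early": 3, "late": 2} for m in MODELS
        }
    )
    noise_sd: float = 0.4
    loading_range: tuple[float, float] = (0.7, 1.3)
    baseline_mean: float = 3.0
    baseline_sd: float = 1.0
    # annotation generator
    terms_per_module: int = 1
    planted_overlap: float = 0.8
    n_decoy_terms: int = 30
    # PPI generator
    hubs_per_module: int = 3
    within_density: float = 0.05
    background_edges: int = 2000
    score_range: tuple[int, int] = (400, 999)
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_background_genes is None:
            self.n_background_genes = self.n_genes - sum(self.module_sizes)
        self.validate()

    def validate(self) -> None:
        if len(self.module_sizes) != len(self.module_profiles):
            raise ConfigError("module_sizes and module_profiles lengths differ")
        if any(s < 1 for s in self.module_sizes):
            raise ConfigError("module sizes must be positive")
        if sum(self.module_sizes) > self.n_genes - self.n_background_genes:
            raise ConfigError(
                "module_sizes sum exceeds n_genes - n_background_genes"
            )
        if self.noise_sd < 0 or self.baseline_sd < 0:
            raise ConfigError("standard deviations must be >= 0")
        if not 0.0 <= self.planted_overlap <= 1.0:
            raise ConfigError("planted_overlap must lie in [0, 1]")
        if self.control_replicates < 2:
            raise DesignError("control group needs at least 2 replicates")
        for m, stages in self.model_replicates.items():
            if m not in MODELS:
                raise ConfigError(f"unknown model {m!r}")
            for stage, r in stages.items():
                if stage not in ("early", "late"):
                    raise ConfigError(f"unknown stage {stage!r}")
                if r < 2:
                    raise DesignError(
                        f"group ({m}, {stage}) has {r} replicates; need >= 2"
                    )
        lo, hi = self.loading_range
        if lo > hi:
            raise ConfigError("loading_range must be (low, high) with low <= high")
        if not 0.0 <= self.within_density <= 1.0:
            raise ConfigError("within_density must lie in [0, 1]")
        s_lo, s_hi = self.score_range
        if not (0 <= s_lo <= s_hi <= 999):
            raise ConfigError("score_range must lie within [0, 999]")
        # every archetype must resolve
        for name in self.module_profiles:
            archetype_templates(name)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class GroundTruth:
    """Record of everything the generator planted, for recovery scoring."""

    gene_module: dict[str, str]  # gene id -> planted module name (signal + null)
    module_profiles: dict[str, str]  # module name -> archetype
    templates: dict[str, dict[str, tuple[float, float, float]]]
    planted_terms: dict[str, list[str]]  # module name -> term ids
    term_genes: dict[str, list[str]]  # term id -> member genes
    hub_genes: dict[str, list[str]]  # module name -> planted hub gene ids
    seed: int

    def signal_modules(self) -> list[str]:
        """Planted modules whose templates carry non-zero signal."""
        return [
            m for m, prof in self.module_profiles.items() if prof != "null_flat"
        ]

    def module_members(self, module: str) -> list[str]:
        return [g for g, m in self.gene_module.items() if m == module]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        d = dict(d)
        d["templates"] = {
            mod: {m: tuple(v) for m, v in t.items()}
            for mod, t in d["templates"].items()
        }
        return cls(**d)


def generate_design(cfg: SimConfig) -> pd.DataFrame:
    """Build the sample table: one shared control group + early/late per model.

    Returns a DataFrame with columns ``sample_id, model, stage, replicate``.
    Control rows carry the sentinel model label ``"shared"`` because the
    single control group belongs to all three models.
    """
    cfg.validate()
    rows = []
    for r in range(1, cfg.control_replicates + 1):
        rows.append((f"ctrl_{r:02d}", SHARED, "control", r))
    for m in MODELS:
        for stage in ("early", "late"):
            n = cfg.model_replicates[m][stage]
            for r in range(1, n + 1):
                rows.append((f"{m}_{stage}_{r:02d}", m, stage, r))
    return pd.DataFrame(rows, columns=["sample_id", "model", "stage", "replicate"])


def _module_names(cfg: SimConfig) -> list[str]:
    return [f"planted_{i + 1}" for i in range(len(cfg.module_sizes))]


def generate_expression(
    cfg: SimConfig, design: pd.DataFrame
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate the FPKM matrix (genes x samples) and its ground truth.

    Module genes get a per-gene loading lambda_g drawn uniformly from
    ``loading_range`` and follow their module's stage template; background
    genes have zero loading.  FPKM = 2**x - 1 clipped at zero.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_planted = sum(cfg.module_sizes)
    genes = [f"gene_{i:05d}" for i in range(cfg.n_genes)]
    names = _module_names(cfg)

    gene_module: dict[str, str] = {}
    templates: dict[str, dict[str, tuple[float, float, float]]] = {}
    profiles: dict[str, str] = {}
    start = 0
    for name, size, prof in zip(names, cfg.module_sizes, cfg.module_profiles):
        for g in genes[start : start + size]:
            gene_module[g] = name
        templates[name] = archetype_templates(prof)
        profiles[name] = prof
        start += size

    mu = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    lam = np.zeros(cfg.n_genes)
    lam[:n_planted] = rng.uniform(*cfg.loading_range, size=n_planted)

    # per-sample template value for each gene
    stage_idx = {"control": 0, "early": 1, "late": 2}
    n_samples = len(design)
    effect = np.zeros((cfg.n_genes, n_samples))
    for j, row in enumerate(design.itertuples(index=False)):
        si = stage_idx[row.stage]
        for gi, g in enumerate(genes[:n_planted]):
            tpl = templates[gene_module[g]]
            if row.model == SHARED:
                effect[gi, j] = tpl[MODELS[0]][0]  # control: identical across models
            else:
                effect[gi, j] = tpl[row.model][si]

    x = mu[:, None] + lam[:, None] * effect
    if cfg.noise_sd > 0:
        x = x + rng.normal(0.0, cfg.noise_sd, size=x.shape)
    fpkm = np.clip(np.exp2(x) - 1.0, 0.0, None)

    matrix = pd.DataFrame(fpkm, index=pd.Index(genes, name="gene_id"),
                          columns=design["sample_id"].tolist())
    truth = GroundTruth(
        gene_module=gene_module,
        module_profiles=profiles,
        templates=templates,
        planted_terms={},
        term_genes={},
        hub_genes={},
        seed=cfg.seed,
    )
    return matrix, truth


def generate_annotations(cfg: SimConfig, truth: GroundTruth) -> dict[str, list[str]]:
    """Plant one or more enriched annotation terms per module, plus decoys.

    Each planted term takes ``planted_overlap x module_size`` genes from its
    module and pads to the module size with filler genes sampled outside the
    module.  Decoy terms are uniform samples of all genes.  Updates ``truth``
    in place and returns ``{term_id: [genes...]}`` (GMT-serialisable).
    """
    rng = np.random.default_rng(_derive_seed(cfg.seed, "annotations"))
    all_genes = [f"gene_{i:05d}" for i in range(cfg.n_genes)]
    sets: dict[str, list[str]] = {}
    truth.planted_terms = {}
    for name in _module_names(cfg):
        members = truth.module_members(name)
        size = len(members)
        n_in = int(round(cfg.planted_overlap * size))
        if n_in < 1:
            warnings.warn(
                f"planted_overlap x module size < 1 for {name}; using 1 gene",
                stacklevel=2,
            )
            n_in = 1
        outside = [g for g in all_genes if truth.gene_module.get(g) != name]
        truth.planted_terms[name] = []
        for t in range(cfg.terms_per_module):
            term = f"TERM_{name}_{t + 1}"
            picked = [str(g) for g in rng.choice(members, size=n_in,
                                                 replace=False)]
            n_fill = size - n_in
            if n_fill > 0:
                picked += [str(g) for g in rng.choice(outside, size=n_fill,
                                                      replace=False)]
            sets[term] = sorted(picked)
            truth.planted_terms[name].append(term)
    mean_size = int(round(np.mean(cfg.module_sizes))) if cfg.module_sizes else 50
    for d in range(cfg.n_decoy_terms):
        term = f"DECOY_{d + 1:03d}"
        sets[term] = sorted(
            str(g) for g in rng.choice(all_genes,
                                       size=min(mean_size, cfg.n_genes),
                                       replace=False)
        )
    truth.term_genes = {t: list(g) for t, g in sets.items()}
    return sets


def generate_ppi(cfg: SimConfig, truth: GroundTruth) -> nx.Graph:
    """STRING-style undirected PPI network with planted within-module hubs.

    Designated hub genes connect to every other member of their module; the
    remaining within-module pairs get an edge with probability
    ``within_density``; ``background_edges`` additional edges are sampled
    uniformly over all gene pairs.  Edge scores are integers drawn uniformly
    from ``score_range``.  Updates ``truth.hub_genes`` in place.
    """
    rng = np.random.default_rng(_derive_seed(cfg.seed, "ppi"))
    all_genes = [f"gene_{i:05d}" for i in range(cfg.n_genes)]
    g = nx.Graph()
    truth.hub_genes = {}
    for name in _module_names(cfg):
        members = sorted(truth.module_members(name))
        n_hubs = min(cfg.hubs_per_module, len(members))
        if cfg.hubs_per_module > len(members):
            warnings.warn(
                f"hub count clipped to module size for {name}", stacklevel=2
            )
        hubs = sorted(str(g) for g in rng.choice(members, size=n_hubs,
                                                 replace=False))
        truth.hub_genes[name] = list(hubs)
        hub_set = set(hubs)
        for h in hubs:
            for other in members:
                if other != h:
                    g.add_edge(h, other)
        if cfg.within_density > 0:
            non_hub = [m for m in members if m not in hub_set]
            for i in range(len(non_hub)):
                for j in range(i + 1, len(non_hub)):
                    if rng.random() < cfg.within_density:
                        g.add_edge(non_hub[i], non_hub[j])
    # background edges, uniform over gene pairs, skipping dups/self-loops
    added = 0
    while added < cfg.background_edges:
        a, b = rng.choice(len(all_genes), size=2, replace=False)
        u, v = all_genes[a], all_genes[b]
        if not g.has_edge(u, v):
            g.add_edge(u, v)
            added += 1
    lo, hi = cfg.score_range
    for u, v in sorted(g.edges()):
        g.edges[u, v]["combined_score"] = int(rng.integers(lo, hi + 1))
    return g


def _derive_seed(seed: int, label: str) -> int:
    h = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# bundle I/O

BUNDLE_FILES = {
    "expression": "expression.tsv",
    "metadata": "metadata.tsv",
    "annotations": "annotations.gmt",
    "ppi": "ppi_edges.tsv",
    "truth": "ground_truth.json",
    "manifest": "manifest.json",
}


def write_bundle(
    dir_path: str | Path,
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    sets: dict[str, list[str]],
    graph: nx.Graph,
    truth: GroundTruth,
    cfg: SimConfig,
    overwrite: bool = False,
) -> dict:
    """Serialise a bundle to ``dir_path`` and return its manifest.

    Refuses to write into an existing non-empty directory unless
    ``overwrite`` is set.  The manifest records the seed and a hash of the
    generating configuration so reruns can be matched to their config.
    """
    out = Path(dir_path)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise BundleError(f"{out} exists and is not empty (pass overwrite=True)")
    out.mkdir(parents=True, exist_ok=True)

    matrix.to_csv(out / BUNDLE_FILES["expression"], sep="\t")
    design.to_csv(out / BUNDLE_FILES["metadata"], sep="\t", index=False)
    with open(out / BUNDLE_FILES["annotations"], "w") as fh:
        for term in sorted(sets):
            genes = "\t".join(sets[term])
            fh.write(f"{term}\tsynthetic term\t{genes}\n")
    edges = pd.DataFrame(
        [
            (u, v, d["combined_score"])
            for u, v, d in sorted(graph.edges(data=True), key=lambda e: (e[0], e[1]))
        ],
        columns=["protein1", "protein2", "combined_score"],
    )
    edges.to_csv(out / BUNDLE_FILES["ppi"], sep="\t", index=False)
    with open(out / BUNDLE_FILES["truth"], "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)
    manifest = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "files": sorted(v for k, v in BUNDLE_FILES.items() if k != "manifest"),
        "n_genes": int(matrix.shape[0]),
        "n_samples": int(matrix.shape[1]),
    }
    with open(out / BUNDLE_FILES["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def generate_bundle(cfg: SimConfig, dir_path: str | Path | None = None,
                    overwrite: bool = False):
    """Generate all components from one config; optionally write to disk.

    Returns ``(matrix, design, sets, graph, truth)``.
    """
    design = generate_design(cfg)
    matrix, truth = generate_expression(cfg, design)
    sets = generate_annotations(cfg, truth)
    graph = generate_ppi(cfg, truth)
    if dir_path is not None:
        write_bundle(dir_path, matrix, design, sets, graph, truth, cfg,
                     overwrite=overwrite)
    return matrix, design, sets, graph, truth


def read_truth(dir_path: str | Path) -> GroundTruth:
    path = Path(dir_path) / BUNDLE_FILES["truth"]
    if not path.exists():
        raise BundleError(f"missing bundle component: {path.name}")
    with open(path) as fh:
        return GroundTruth.from_dict(json.load(fh))


def read_manifest(dir_path: str | Path) -> dict:
    path = Path(dir_path) / BUNDLE_FILES["manifest"]
    if not path.exists():
        raise BundleError(f"missing bundle component: {path.name}")
    with open(path) as fh:
        return json.load(fh)


def check_bundle(dir_path: str | Path) -> None:
    """Raise :class:`BundleError` naming the first missing component."""
    out = Path(dir_path)
    for key, fname in BUNDLE_FILES.items():
        if not (out / fname).exists():
            raise BundleError(f"missing bundle component: {fname}")
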