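"""Shared fixtures: generated bundles and the networks built from them.

Everything is generated programmatically at test time; the heavy default
bundle and its network are session-scoped so the recovery, trajectory,
enrichment and hub tests all reuse one computation.
"""

from __future__ import annotations

import dataclasses
from types import SimpleNamespace

import pandas as pd
import pytest

import cochnet as cn


def build_network(bundle: SimpleNamespace, beta: float = 15.0,
                  min_module_size: int = 30) -> SimpleNamespace:
    """Run filter -> log2 -> correlation -> TOM -> modules -> eigengenes."""
    em = cn.ExpressionMatrix(bundle.matrix, bundle.design)
    filtered = cn.filter_genes(em)
    logm = cn.log_transform(filtered)
    cor, constant = cn.correlation_matrix(logm)
    adj = cn.signed_adjacency(cor, beta)
    tom = pd.DataFrame(cn.topological_overlap(adj),
                       index=cor.index, columns=cor.columns)
    part = cn.cluster_modules(tom, logm, min_module_size=min_module_size)
    me = cn.module_eigengenes(logm, part)
    traj = cn.stage_trajectories(me, bundle.design)
    report = cn.shared_module_report(traj)
    return SimpleNamespace(
        expr=em, logm=logm, cor=cor, constant=constant, adj=adj, tom=tom,
        part=part, me=me, traj=traj, report=report,
    )


def make_bundle(cfg: cn.SimConfig) -> SimpleNamespace:
    matrix, design, sets, graph, truth = cn.generate_bundle(cfg)
    return SimpleNamespace(cfg=cfg, matrix=matrix, design=design, sets=sets,
                           graph=graph, truth=truth)


@pytest.fixture(scope="session")
def default_bundle() -> SimpleNamespace:
    """The study-default bundle: 2000 genes, 27 samples, 6 planted modules."""
    return make_bundle(cn.SimConfig())


@pytest.fixture(scope="session")
def default_network(default_bundle) -> SimpleNamespace:
    return build_network(default_bundle)


@pytest.fixture(scope="session")
def noisefree_bundle() -> SimpleNamespace:
    return make_bundle(dataclasses.replace(cn.SimConfig(), noise_sd=0.0))


@pytest.fixture(scope="session")
def noisefree_network(noisefree_bundle) -> SimpleNamespace:
    return build_network(noisefree_bundle)


def small_sim_config(seed: int = 7) -> cn.SimConfig:
    """A fast three-module bundle for pipeline/CLI tests."""
    return cn.SimConfig(
        n_genes=300,
        module_sizes=(60, 60, 40),
        module_profiles=("shared_up", "shared_down", "model_specific:aging"),
        n_background_genes=140,
        n_decoy_terms=10,
        background_edges=200,
        seed=seed,
    )


@pytest.fixture()
def small_pipeline_config(tmp_path) -> cn.PipelineConfig:
    return cn.PipelineConfig(
        bundle_dir=str(tmp_path / "bundle"),
        out_dir=str(tmp_path / "out"),
        min_module_size=20,
        seed=7,
        sim=small_sim_config(),
    )
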