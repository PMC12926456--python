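"""Shared fixtures: small meshes and synthetic cohorts built at test time."""

from __future__ import annotations

import pytest

import cortexgnn as cg


@pytest.fixture(scope="session")
def ico1():
    return cg.build_icosphere(1)


@pytest.fixture(scope="session")
def ico1_graph(ico1):
    return cg.mesh_to_graph(ico1)


@pytest.fixture(scope="session")
def small_cohort():
    """Six subjects, order-2 spheres (162 vertices), 10 regions, both hemispheres."""
    params = cg.CohortParams(n_subjects=6, subdivisions=2, k_regions=10, seed=42)
    return cg.generate_cohort(params)


@pytest.fixture(scope="session")
def benchmark_ablation():
    """The synthetic Table-1-style benchmark: n=20 subjects, 642 vertices,
    K=35 regions, three feature sets × {GCN, GAT}, 3 folds over the 12
    non-holdout subjects, holdout of 8.  Session-scoped: trained once."""
    cohort = cg.generate_cohort(
        cg.CohortParams(n_subjects=20, hemispheres=("L",), seed=0)
    )
    specs = [
        cg.FeatureSpec(coords=True),
        cg.FeatureSpec(coords=True, thickness=True, curvature=True),
        cg.FeatureSpec(coords=True, thickness=True, curvature=True, conductance=True),
    ]
    configs = [
        cg.ModelConfig(architecture="gcn", hidden=(64, 32), n_classes=35, seed=0),
        cg.ModelConfig(architecture="gat", hidden=(16, 8), heads=4, n_classes=35, seed=0),
    ]
    hyper = cg.HyperParams(epochs=30, seed=0)
    return cg.run_ablation(cohort, specs, configs, hyper,
                           n_holdout=8, k=3, split_seed=0)


def cell(result, feature_set: str, architecture: str) -> float:
    t = result.table
    row = t[(t.feature_set == feature_set) & (t.architecture == architecture)]
    assert len(row) == 1
    return float(row.mean_dice.iloc[0])
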