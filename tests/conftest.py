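"""Shared fixtures: toy graphs and synthetic cohorts."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from modcart import cartography, community, graphs, stats, synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_cliques_bridge():
    """Two 4-cliques joined by a single edge; clique partition is optimal."""
    edges = []
    for base in (0, 4):
        for i in range(4):
            for j in range(i + 1, 4):
                edges.append((base + i, base + j))
    edges.append((0, 4))
    g = graphs.BinaryGraph.from_edges(8, edges)
    labels = np.array([1, 1, 1, 1, 2, 2, 2, 2])
    return g, labels


@pytest.fixture
def clique_ring_12():
    """Ring of three 4-cliques (12 nodes), one bridge edge between cliques."""
    edges = []
    for base in (0, 4, 8):
        for i in range(4):
            for j in range(i + 1, 4):
                edges.append((base + i, base + j))
    edges += [(3, 4), (7, 8), (11, 0)]
    g = graphs.BinaryGraph.from_edges(12, edges)
    labels = np.repeat([1, 2, 3], 4)
    return g, labels


def random_graph(rng, n_nodes, p=0.3):
    """Random Erdos-Renyi binary graph with at least one edge."""
    while True:
        upper = np.triu(rng.random((n_nodes, n_nodes)) < p, 1)
        edges = np.argwhere(upper)
        if len(edges):
            return graphs.BinaryGraph.from_edges(n_nodes, edges)


def random_partition(rng, n_nodes, max_modules=4):
    labels = rng.integers(1, max_modules + 1, size=n_nodes)
    return community.canonicalize_labels(labels)


#: spatial blob of effect nodes inside planted module 1 on the 200-node lattice
EFFECT_BLOB = (0, 1, 2, 6, 7, 8, 12, 13, 14, 36, 37, 38, 42, 43, 44)


def cohort_spec_200(effect_size: float = 0.4, seed: int = 11) -> synthetic.CohortSpec:
    """The planted-effect study conditions used for pipeline-level checks."""
    return synthetic.CohortSpec(
        n_subjects=200,
        n_nodes=200,
        n_volumes=150,
        module_sizes=(50, 50, 50, 50),
        within_corr=0.4,
        between_corr=0.05,
        effect_nodes=EFFECT_BLOB,
        effect_size=effect_size,
        fd_mean=0.1,
        fd_sd=0.04,
        seed=seed,
    )


@pytest.fixture(scope="session")
def cohort200():
    """200-subject planted-effect cohort with threshold-averaged nodal maps.

    Expensive; computed once per session and shared by the pipeline-level
    calibration and recovery checks.  Louvain restarts are reduced to 3 at
    this scale.
    """
    spec = cohort_spec_200()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cohort = synthetic.generate_cohort(spec)
    coords = cohort.coordinates[["x", "y", "z"]].to_numpy()
    p_maps, z_maps = [], []
    for ts in cohort.timeseries:
        conn = graphs.apply_distance_exclusion(graphs.correlation_matrix(ts), coords)
        gset = graphs.build_graph_set(conn=conn)
        parts = {
            d: community.louvain_partition(g, seed=0, n_restarts=3)
            for d, g in gset.items()
        }
        maps = cartography.threshold_averaged_maps(gset, parts)
        p_maps.append(maps["p_mean"])
        z_maps.append(maps["z_mean"])
    design = stats.covariate_design(cohort.phenotypes)
    return {
        "spec": spec,
        "cohort": cohort,
        "coords": coords,
        "p_maps": np.array(p_maps),
        "z_maps": np.array(z_maps),
        "design": design,
        "y": cohort.phenotypes["adhd_index"].to_numpy(dtype=float),
        "blob": np.array(EFFECT_BLOB),
        "adjacency": stats.lattice_adjacency(coords),
    }


@pytest.fixture(scope="session")
def small_cohort_dir(tmp_path_factory):
    """A written 20-subject, 60-node cohort directory for pipeline tests."""
    spec = synthetic.CohortSpec(
        n_subjects=20,
        n_nodes=60,
        n_volumes=120,
        module_sizes=(15, 15, 15, 15),
        within_corr=0.4,
        between_corr=0.05,
        fd_mean=0.1,
        fd_sd=0.04,
        seed=7,
    )
    cohort = synthetic.generate_cohort(spec)
    out = tmp_path_factory.mktemp("cohort")
    synthetic.write_cohort(cohort, out)
    return out
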