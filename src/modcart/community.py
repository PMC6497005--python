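"""Louvain community detection and whole-brain modularity statistics.

Modularity of a partition of an undirected binary graph:

    Q = sum_s [ l_in_s / L  -  ( k_s / (2 L) )^2 ]

where the sum runs over modules s, ``l_in_s`` is the number of edges inside
module s, ``L`` the total edge count and ``k_s`` the summed degree of module
s's nodes.  The first term is the realized fraction of within-module edges,
the second its degree-preserving chance expectation; Q > 0.3 is the
conventional indication of modular organization.

Partitions are found with the Louvain heuristic (local moves with random
node order, then aggregation, iterated to convergence) at resolution 1.
Louvain is order-dependent, so ``louvain_partition`` runs ``n_restarts``
seeded restarts and returns the highest-Q result; ties go to the partition
with fewer modules, then to the lexicographically smallest canonical
labelling.  Module labels are canonicalized as 1..m ordered by descending
module size, then by smallest contained node id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .graphs import BinaryGraph


@dataclass(frozen=True)
class ModularityDecomposition:
    """Q with its per-module bookkeeping terms."""

    q: float
    n_modules: int
    l_in: np.ndarray   # within-module edge counts, one per module label 1..m
    k_s: np.ndarray    # summed degrees per module
    total_edges: int


@dataclass(frozen=True)
class GlobalModularityStats:
    """The four whole-brain modular-organization measures for one graph."""

    q: float
    number_of_modules: int
    average_module_size: float
    variability_in_module_size: float


class EmptyGraphError(ValueError):
    """Raised when a modularity quantity is undefined because L = 0."""


def canonicalize_labels(labels) -> np.ndarray:
    """Relabel modules 1..m by (descending size, smallest contained node id)."""
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    order = sorted(
        uniq,
        key=lambda u: (-int(np.sum(labels == u)), int(np.min(np.where(labels == u)[0]))),
    )
    out = np.empty(labels.shape, dtype=int)
    for new, old in enumerate(order, start=1):
        out[labels == old] = new
    return out


def _check_partition(graph: BinaryGraph, labels) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (graph.n_nodes,):
        raise ValueError(
            f"partition labels {labels.shape} do not cover the "
            f"{graph.n_nodes}-node graph"
        )
    return labels


def modularity_q(graph: BinaryGraph, labels) -> ModularityDecomposition:
    """Evaluate Q and its decomposition for a given partition.

    Raises :class:`EmptyGraphError` when the graph has no edges (Q undefined).
    """
    labels = _check_partition(graph, labels)
    total = graph.n_edges
    if total == 0:
        raise EmptyGraphError("modularity undefined for a graph with no edges")
    labels = canonicalize_labels(labels)
    m = int(labels.max())
    deg = graph.degrees()
    k_s = np.array([deg[labels == s].sum() for s in range(1, m + 1)], dtype=float)
    same = labels[graph.edges[:, 0]] == labels[graph.edges[:, 1]]
    l_in = np.zeros(m, dtype=float)
    if same.any():
        np.add.at(l_in, labels[graph.edges[:, 0]][same] - 1, 1.0)
    q = float(np.sum(l_in / total - (k_s / (2.0 * total)) ** 2))
    return ModularityDecomposition(
        q=q, n_modules=m, l_in=l_in, k_s=k_s, total_edges=total
    )


def _restart_seed(seed: int, restart: int) -> int:
    """Deterministic per-restart seed below 2^31."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(int(restart),))
    return int(ss.generate_state(1)[0] % (2**31))


def louvain_partition(
    graph: BinaryGraph, seed: int = 0, n_restarts: int = 20
) -> np.ndarray:
    """Best-of-``n_restarts`` Louvain partition, canonically labelled 1..m.

    Deterministic given ``seed``: restart r runs Louvain with a child seed
    derived from (seed, r).  The winner maximizes Q; exact Q ties prefer
    fewer modules, then the lexicographically smallest label vector.
    """
    if graph.n_edges == 0:
        raise EmptyGraphError(
            "Louvain on an edgeless graph: every node is its own module and "
            "Q is undefined"
        )
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    g = graph.to_networkx()
    best = None
    for r in range(n_restarts):
        comms = nx.community.louvain_communities(
            g, seed=_restart_seed(seed, r), resolution=1.0
        )
        labels = np.empty(graph.n_nodes, dtype=int)
        for idx, comm in enumerate(comms, start=1):
            labels[list(comm)] = idx
        labels = canonicalize_labels(labels)
        q = modularity_q(graph, labels).q
        key = (-q, int(labels.max()), tuple(labels))
        if best is None or key < best[0]:
            best = (key, labels)
    return best[1]


def global_module_stats(labels, q: float | None = None, ddof: int = 1) -> GlobalModularityStats:
    """Number of modules, mean module size, and SD of module sizes.

    ``ddof=1`` (sample SD) by default; set ``ddof=0`` for the population
    convention.  A single-module partition has variability 0.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("empty partition")
    _, sizes = np.unique(labels, return_counts=True)
    m = sizes.size
    var = 0.0 if m <= ddof else float(np.std(sizes, ddof=ddof))
    return GlobalModularityStats(
        q=float("nan") if q is None else float(q),
        number_of_modules=int(m),
        average_module_size=float(sizes.mean()),
        variability_in_module_size=var,
    )


def average_across_thresholds(values) -> float:
    """Arithmetic mean of a per-density metric vector; NaN entries dropped.

    Subject-level analyses use this average over the five graph densities.
    """
    vals = np.asarray(values, dtype=float)
    finite = np.isfinite(vals)
    if not finite.any():
        raise ValueError("all per-density values are NaN")
    if not finite.all():
        warnings.warn(
            f"dropping {int((~finite).sum())} NaN density value(s) from average",
            stacklevel=2,
        )
    return float(vals[finite].mean())
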