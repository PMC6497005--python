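"""Nodal modularity metrics and functional cartography.

Two per-node measures describe a node's role in the modular architecture:

* participation coefficient  p_i = 1 - sum_m (k_i(m) / k_i)^2 — the
  diversity of node i's edges across modules; 0 when all edges stay in one
  module, approaching 1 - 1/M when spread evenly over all M modules.
* within-module degree  z_i = (k_i(m_i) - mean_k(m_i)) / sd_k(m_i) — node
  i's within-module connection count standardized against its own module's
  distribution (population-SD convention by default).

The Guimerà–Amaral cartography assigns each node one of seven roles from
(p_i, z_i): nodes with z_i >= 1 are hubs, split by p into provincial
(p <= 0.30), connector (0.30 < p <= 0.75) and kinless (p > 0.75) hubs;
nonhubs (z < 1) split into ultra-peripheral (p <= 0.05), peripheral
(0.05 < p <= 0.62), nonhub connector (0.62 < p <= 0.80) and nonhub kinless
(p > 0.80).  Metrics are computed per graph density and averaged across the
five densities per subject; node types are assigned per density and the
seven proportions averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import _check_partition, canonicalize_labels
from .graphs import BinaryGraph

#: the seven node roles, peripheral -> hub order
NODE_TYPES = (
    "ultra-peripheral",
    "peripheral",
    "nonhub-connector",
    "nonhub-kinless",
    "provincial-hub",
    "connector-hub",
    "kinless-hub",
)


@dataclass(frozen=True)
class CartographyScheme:
    """Cutoffs defining the seven (p, z) role classes.

    Intervals are closed on the left-hand class (``p <= cut``) and the hub
    rule is ``z >= hub_z``; together the classes partition the (p, z) plane
    exactly.
    """

    hub_z: float = 1.0
    nonhub_p: tuple[float, float, float] = (0.05, 0.62, 0.80)
    hub_p: tuple[float, float] = (0.30, 0.75)


DEFAULT_SCHEME = CartographyScheme()


def _module_edge_counts(graph: BinaryGraph, labels: np.ndarray) -> np.ndarray:
    """k_i(m): (n_nodes, n_modules) count of node i's edges into module m."""
    m = int(labels.max())
    counts = np.zeros((graph.n_nodes, m), dtype=float)
    if graph.n_edges:
        i, j = graph.edges[:, 0], graph.edges[:, 1]
        np.add.at(counts, (i, labels[j] - 1), 1.0)
        np.add.at(counts, (j, labels[i] - 1), 1.0)
    return counts


def participation_coefficient(graph: BinaryGraph, labels) -> np.ndarray:
    """p_i per node; a degree-0 node gets p_i = 0 by convention."""
    labels = canonicalize_labels(_check_partition(graph, labels))
    counts = _module_edge_counts(graph, labels)
    k = counts.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = 1.0 - np.sum((counts / k[:, None]) ** 2, axis=1)
    p[k == 0] = 0.0
    return p


def within_module_degree(graph: BinaryGraph, labels, ddof: int = 0) -> np.ndarray:
    """z_i per node; modules with zero within-degree spread give z_i = 0.

    ``ddof=0`` (population SD) follows the original cartography usage;
    ``ddof=1`` switches to the sample convention.
    """
    labels = canonicalize_labels(_check_partition(graph, labels))
    counts = _module_edge_counts(graph, labels)
    within = counts[np.arange(graph.n_nodes), labels - 1]
    z = np.zeros(graph.n_nodes)
    for s in range(1, int(labels.max()) + 1):
        idx = labels == s
        w = within[idx]
        sd = np.std(w, ddof=ddof) if w.size > ddof else 0.0
        if sd > 0:
            z[idx] = (w - w.mean()) / sd
    return z


def classify_node(p: float, z: float, scheme: CartographyScheme = DEFAULT_SCHEME) -> str:
    """Assign the single role label for one (p, z) pair."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"participation coefficient {p} outside [0, 1]")
    if z >= scheme.hub_z:
        c1, c2 = scheme.hub_p
        if p <= c1:
            return "provincial-hub"
        if p <= c2:
            return "connector-hub"
        return "kinless-hub"
    c1, c2, c3 = scheme.nonhub_p
    if p <= c1:
        return "ultra-peripheral"
    if p <= c2:
        return "peripheral"
    if p <= c3:
        return "nonhub-connector"
    return "nonhub-kinless"


def classify_nodes(p, z, scheme: CartographyScheme = DEFAULT_SCHEME) -> np.ndarray:
    """Vectorized role assignment; one label per node."""
    p = np.asarray(p, dtype=float)
    z = np.asarray(z, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("participation coefficient outside [0, 1]")
    out = np.empty(p.shape, dtype=object)
    hub = z >= scheme.hub_z
    c1, c2 = scheme.hub_p
    out[hub & (p <= c1)] = "provincial-hub"
    out[hub & (p > c1) & (p <= c2)] = "connector-hub"
    out[hub & (p > c2)] = "kinless-hub"
    n1, n2, n3 = scheme.nonhub_p
    nh = ~hub
    out[nh & (p <= n1)] = "ultra-peripheral"
    out[nh & (p > n1) & (p <= n2)] = "peripheral"
    out[nh & (p > n2) & (p <= n3)] = "nonhub-connector"
    out[nh & (p > n3)] = "nonhub-kinless"
    return out


def node_type_proportions(types) -> pd.Series:
    """Fraction of nodes per role, indexed by :data:`NODE_TYPES` (sums to 1)."""
    types = np.asarray(types, dtype=object)
    if types.size == 0:
        raise ValueError("no nodes to classify")
    counts = pd.Series(0.0, index=list(NODE_TYPES))
    vals, n = np.unique(types, return_counts=True)
    for v, c in zip(vals, n):
        if v not in counts.index:
            raise ValueError(f"unknown node type {v!r}")
        counts[v] = c
    return counts / types.size


def threshold_averaged_maps(
    graph_set: dict[float, BinaryGraph],
    partitions: dict[float, np.ndarray],
    scheme: CartographyScheme = DEFAULT_SCHEME,
) -> dict:
    """Subject-level maps averaged across graph densities.

    Per density, computes p_i, z_i and node roles; returns the nodewise mean
    p and z maps, the role proportions averaged across densities, and the
    per-density values.
    """
    if set(graph_set) != set(partitions):
        missing = set(graph_set) ^ set(partitions)
        raise ValueError(f"density mismatch between graphs and partitions: {missing}")
    if not graph_set:
        raise ValueError("empty graph set")
    per_density = {}
    for d in sorted(graph_set):
        g = graph_set[d]
        lab = partitions[d]
        p = participation_coefficient(g, lab)
        z = within_module_degree(g, lab)
        types = classify_nodes(p, z, scheme)
        per_density[d] = {
            "p": p,
            "z": z,
            "types": types,
            "proportions": node_type_proportions(types),
        }
    p_mean = np.mean([v["p"] for v in per_density.values()], axis=0)
    z_mean = np.mean([v["z"] for v in per_density.values()], axis=0)
    proportions = sum(v["proportions"] for v in per_density.values()) / len(per_density)
    return {
        "p_mean": p_mean,
        "z_mean": z_mean,
        "proportions": proportions,
        "per_density": per_density,
    }
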