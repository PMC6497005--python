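"""Construction of binarized functional-connectivity graphs.

A subject's node-by-node Pearson correlation matrix is turned into a set of
undirected, unweighted graphs:

1. edges between physically close nodes (Euclidean distance < 20 mm) are
   excluded as likely motion/shared-signal artifacts;
2. the remaining ("admissible") node pairs are proportionally thresholded —
   the top 10, 15, 20, 25 and 30 % strongest (most positively correlated)
   pairs define five graphs of fixed density;
3. any selected pair with a non-positive correlation is dropped, so graphs
   never contain negative edges;
4. graphs are binarized (edge present / absent).

Graph metrics computed downstream are averaged across the five densities.

Conventions chosen for bit-reproducibility: the density denominator is the
number of *admissible* pairs (after distance exclusion); the edge-count is
``round-half-away-from-zero(density * n_admissible)``; rank ties at the
cutoff correlation are broken by (smaller node id, larger node id).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: the five proportional edge densities
DENSITIES = (0.10, 0.15, 0.20, 0.25, 0.30)
#: minimum inter-node distance for an admissible edge, mm
MIN_DISTANCE_MM = 20.0


@dataclass(frozen=True)
class MaskedConnectivity:
    """Correlation matrix plus the admissible-pair mask after distance pruning."""

    r: np.ndarray          # (n, n) Pearson correlations, symmetric, unit diag
    admissible: np.ndarray  # (n, n) bool, symmetric, False on the diagonal

    @property
    def n_nodes(self) -> int:
        return self.r.shape[0]

    @property
    def n_admissible_pairs(self) -> int:
        return int(np.triu(self.admissible, 1).sum())


@dataclass(frozen=True)
class BinaryGraph:
    """Undirected unweighted graph stored as a sorted upper-triangular edge list."""

    n_nodes: int
    edges: np.ndarray       # (m, 2) int, each row i < j, lexicographically sorted
    density: float | None = None

    @property
    def n_edges(self) -> int:
        return int(self.edges.shape[0])

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes), dtype=np.int8)
        if self.n_edges:
            i, j = self.edges[:, 0], self.edges[:, 1]
            a[i, j] = 1
            a[j, i] = 1
        return a

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        if self.n_edges:
            np.add.at(deg, self.edges[:, 0], 1)
            np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(map(tuple, self.edges))
        return g

    @classmethod
    def from_edges(cls, n_nodes: int, edges, density=None) -> "BinaryGraph":
        e = np.asarray(edges, dtype=int).reshape(-1, 2)
        e = np.sort(e, axis=1)
        if e.size and (e[:, 0] == e[:, 1]).any():
            raise ValueError("self-loops are not allowed")
        order = np.lexsort((e[:, 1], e[:, 0]))
        e = e[order]
        return cls(n_nodes=n_nodes, edges=e, density=density)


def correlation_matrix(ts) -> np.ndarray:
    """Pearson correlation between all node pairs over volumes.

    Raises ``ValueError`` naming the first zero-variance node, since a
    constant series has no defined correlation.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2 or ts.shape[0] < 3:
        raise ValueError("time series must be (n_volumes >= 3, n_nodes)")
    if not np.isfinite(ts).all():
        raise ValueError("time series contains NaN/inf")
    sd = ts.std(axis=0)
    bad = np.where(sd == 0)[0]
    if bad.size:
        raise ValueError(f"zero-variance node(s): {bad.tolist()}")
    r = np.corrcoef(ts, rowvar=False)
    # enforce exact symmetry / unit diagonal against rounding
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def pairwise_distances(coords) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be (n_nodes, 3) in mm")
    if not np.isfinite(coords).all():
        raise ValueError("non-finite node coordinate")
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=-1))


def apply_distance_exclusion(
    r, coords, min_dist: float = MIN_DISTANCE_MM
) -> MaskedConnectivity:
    """Mark node pairs closer than ``min_dist`` mm (strict ``<``) inadmissible.

    A pair at exactly ``min_dist`` remains admissible.
    """
    r = np.asarray(r, dtype=float)
    d = pairwise_distances(coords)
    if d.shape != r.shape:
        raise ValueError("coordinate table does not cover all nodes")
    admissible = d >= min_dist
    np.fill_diagonal(admissible, False)
    return MaskedConnectivity(r=r, admissible=admissible)


def round_half_away(x: float) -> int:
    """Round half away from zero (2.5 -> 3), unlike banker's rounding."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def proportional_threshold(conn: MaskedConnectivity, density: float) -> BinaryGraph:
    """Keep the top-``density`` fraction of strongest admissible pairs, binarized.

    Selection is by descending correlation with ties broken by
    (smaller node id, larger node id); selected pairs with r <= 0 are then
    dropped, so the graph can hold fewer edges than nominal when positive
    correlations are scarce.
    """
    if not (0 < density <= 1):
        raise ValueError(f"density must be in (0, 1], got {density}")
    iu, ju = np.where(np.triu(conn.admissible, 1))
    vals = conn.r[iu, ju]
    n_pairs = iu.size
    k = round_half_away(density * n_pairs)
    if k == 0 or n_pairs == 0:
        warnings.warn(f"density {density} yields 0 edges", stacklevel=2)
        return BinaryGraph(conn.n_nodes, np.empty((0, 2), dtype=int), density)
    order = np.lexsort((ju, iu, -vals))  # primary: -r, then i, then j
    sel = order[:k]
    sel = sel[vals[sel] > 0]  # negative-edge removal after rank selection
    edges = np.column_stack([iu[sel], ju[sel]])
    return BinaryGraph.from_edges(conn.n_nodes, edges, density)


def build_graph_set(
    ts=None,
    coords=None,
    densities=DENSITIES,
    min_dist: float = MIN_DISTANCE_MM,
    conn: MaskedConnectivity | None = None,
) -> dict[float, BinaryGraph]:
    """One binarized graph per proportional density for a single subject.

    Either pass raw ``ts`` + ``coords`` or a precomputed ``conn``.
    """
    if conn is None:
        r = correlation_matrix(ts)
        conn = apply_distance_exclusion(r, coords, min_dist)
    if len(densities) == 0:
        raise ValueError("at least one density required")
    return {float(d): proportional_threshold(conn, float(d)) for d in densities}


# ---------------------------------------------------------------------------
# I/O

def read_timeseries_tsv(path) -> tuple[np.ndarray, list]:
    """Read a volumes x nodes TSV with a header row of node ids."""
    df = pd.read_csv(path, sep="\t")
    return df.to_numpy(dtype=float), list(df.columns)


def write_timeseries_tsv(ts, node_ids, path) -> None:
    pd.DataFrame(np.asarray(ts), columns=list(node_ids)).to_csv(
        path, sep="\t", index=False, float_format="%.8g"
    )


def read_coordinates_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"node_id", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"coordinates CSV must have columns {sorted(required)}")
    return df


def write_edge_list(graph: BinaryGraph, path) -> None:
    np.savetxt(path, graph.edges, fmt="%d", delimiter="\t")


def graph_manifest(graphs: dict[float, BinaryGraph], conn: MaskedConnectivity) -> dict:
    return {
        "n_admissible_pairs": conn.n_admissible_pairs,
        "densities": {
            f"{d:.2f}": {"n_edges": g.n_edges} for d, g in graphs.items()
        },
    }


def load_nifti_timeseries(img_path, mask_path) -> tuple[np.ndarray, np.ndarray]:
    """Flatten in-mask voxels of a 4-D NIfTI to a (volumes, nodes) matrix.

    Returns the time-series matrix and the voxel centre coordinates in mm
    (from the image affine), one row per in-mask voxel in C order.
    """
    import nibabel as nib

    img = nib.load(str(img_path))
    mask = nib.load(str(mask_path))
    data = np.asanyarray(img.dataobj)
    m = np.asanyarray(mask.dataobj) > 0
    if data.ndim != 4:
        raise ValueError("expected a 4-D NIfTI image")
    if m.shape != data.shape[:3]:
        raise ValueError("mask shape does not match image grid")
    ijk = np.array(np.nonzero(m)).T
    coords = nib.affines.apply_affine(img.affine, ijk)
    ts = data[m].T.astype(float)  # (volumes, nodes)
    return ts, coords
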