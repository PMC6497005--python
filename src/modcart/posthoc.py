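"""Post hoc control and characterization analyses.

Four procedures complement the main correlative analyses:

* extreme-group comparison — the 20 highest vs the 20 lowest scorers on the
  symptom index compared on a graph measure (Welch t test, or one-tailed
  Mann-Whitney U for small/uneven groups);
* canonical 7-network block connectivity — mean functional connectivity
  within and between the seven canonical resting-state networks (visual,
  somato-motor, dorsal attention, ventral attention, limbic,
  fronto-parietal, default-mode), 28 unique values per subject;
* distance-dependent motion diagnostic — per edge, the across-subject
  correlation of its connectivity strength with mean FD, related to edge
  length; a negative length relationship flags residual motion artifact;
* cluster rank position — where a cluster's group-average nodal metric sits
  in the whole-brain distribution (percentile bands <20 %, 20-80 %, >80 %).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .graphs import MaskedConnectivity

#: canonical seven resting-state networks
NETWORKS_7 = (
    "visual",
    "somato-motor",
    "dorsal-attention",
    "ventral-attention",
    "limbic",
    "fronto-parietal",
    "default-mode",
)


@dataclass(frozen=True)
class ExtremeGroupResult:
    statistic: float
    p_value: float
    test: str
    high_idx: np.ndarray
    low_idx: np.ndarray


@dataclass(frozen=True)
class RankReport:
    """Percentile position of a cluster's group-average value."""

    value: float
    percentile: float
    band: str


def extreme_group_compare(
    metric,
    scores,
    n_per_group: int = 20,
    test: str = "t",
    alternative: str = "greater",
    subject_ids=None,
) -> ExtremeGroupResult:
    """Compare the top-n vs bottom-n scorers on a graph metric.

    Group membership is by score with ties broken by subject id (input
    order when ids are absent), so selection is deterministic.  ``test='t'``
    runs a two-sided Welch t test; ``test='mann_whitney'`` a one-tailed
    Mann-Whitney U with ``alternative`` giving the direction of the
    high-score group.
    """
    metric = np.asarray(metric, dtype=float)
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    if metric.size != n:
        raise ValueError("metric and scores must align")
    if n < 2 * n_per_group:
        raise ValueError(
            f"cohort of {n} cannot form two disjoint groups of {n_per_group}"
        )
    ids = np.arange(n) if subject_ids is None else np.asarray(subject_ids)
    order = np.lexsort((ids, scores))  # ascending score, ties by id
    low = order[:n_per_group]
    high = order[-n_per_group:]
    if np.intersect1d(low, high).size:
        raise ValueError("extreme groups overlap (massive score ties)")
    if test == "t":
        if np.all(metric[high] == metric[high][0]) and np.all(
            metric[low] == metric[high][0]
        ):
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.ttest_ind(metric[high], metric[low], equal_var=False)
    elif test == "mann_whitney":
        stat, p = stats.mannwhitneyu(
            metric[high], metric[low], alternative=alternative
        )
    else:
        raise ValueError(f"unknown test {test!r}")
    return ExtremeGroupResult(
        statistic=float(stat),
        p_value=float(p),
        test=test,
        high_idx=high,
        low_idx=low,
    )


def network_block_fc(conn, node_to_network, networks=NETWORKS_7) -> pd.DataFrame:
    """Mean connectivity within/between canonical networks for one subject.

    ``conn`` is a :class:`MaskedConnectivity` (distance-masked pairs and the
    diagonal are excluded from the averages) or a plain correlation matrix.
    Returns a symmetric 7x7 DataFrame; the diagonal holds within-network
    means.
    """
    if isinstance(conn, MaskedConnectivity):
        r, admissible = conn.r, conn.admissible
    else:
        r = np.asarray(conn, dtype=float)
        admissible = ~np.eye(r.shape[0], dtype=bool)
    assign = np.asarray(node_to_network, dtype=object)
    if assign.size != r.shape[0]:
        raise ValueError("every node needs a network assignment")
    unknown = set(assign) - set(networks)
    if unknown:
        raise ValueError(f"unassigned/unknown network label(s): {sorted(unknown)}")
    block = np.full((len(networks), len(networks)), np.nan)
    masks = [assign == nw for nw in networks]
    for a in range(len(networks)):
        for b in range(a, len(networks)):
            pair_mask = np.outer(masks[a], masks[b])
            if a == b:
                pair_mask = np.triu(pair_mask, 1) | np.tril(pair_mask, -1)
            pair_mask &= admissible
            if pair_mask.any():
                block[a, b] = block[b, a] = float(r[pair_mask].mean())
    return pd.DataFrame(block, index=list(networks), columns=list(networks))


def distance_dependence_qc(
    edge_fc, mean_fd, edge_lengths
) -> tuple[np.ndarray, float, float]:
    """Distance-dependent motion-artifact diagnostic.

    For every edge, the Pearson correlation across subjects between its
    connectivity strength and mean FD is computed; those edgewise r values
    are then correlated with the edges' Euclidean lengths.  Residual motion
    artifact inflates short-range connectivity in high-motion subjects,
    producing a negative length relationship.

    Parameters
    ----------
    edge_fc : (n_subjects, n_edges) connectivity strengths
    mean_fd : (n_subjects,) mean FD per subject
    edge_lengths : (n_edges,) Euclidean edge lengths, mm

    Returns
    -------
    (edge_r, distance_r, distance_p)
    """
    edge_fc = np.asarray(edge_fc, dtype=float)
    mean_fd = np.asarray(mean_fd, dtype=float)
    lengths = np.asarray(edge_lengths, dtype=float)
    if edge_fc.ndim != 2 or edge_fc.shape != (mean_fd.size, lengths.size):
        raise ValueError("edge_fc must be (n_subjects, n_edges) matching inputs")
    if mean_fd.size < 3:
        raise ValueError("need at least 3 subjects (>= 10 recommended)")
    if mean_fd.std() == 0:
        raise ValueError("zero-variance mean FD")
    fd_c = mean_fd - mean_fd.mean()
    fc_c = edge_fc - edge_fc.mean(axis=0)
    denom = np.sqrt((fc_c**2).sum(axis=0)) * np.sqrt((fd_c**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        edge_r = (fc_c.T @ fd_c) / denom
    valid = np.isfinite(edge_r)
    dist_r, dist_p = stats.pearsonr(edge_r[valid], lengths[valid])
    return edge_r, float(dist_r), float(dist_p)


def cluster_rank_position(
    group_map, cluster_nodes, bands=(20.0, 80.0)
) -> RankReport:
    """Percentile rank of a cluster's mean group-average value.

    The cluster's mean metric is ranked against the whole-brain node-value
    distribution with the mean-rank (midpoint) percentile convention, then
    banded at the 20 %/80 % cutoffs.
    """
    group_map = np.asarray(group_map, dtype=float)
    nodes = np.asarray(cluster_nodes, dtype=int)
    if nodes.size == 0:
        raise ValueError("empty cluster")
    if nodes.min() < 0 or nodes.max() >= group_map.size:
        raise ValueError("cluster nodes outside the map support")
    value = float(group_map[nodes].mean())
    pct = float(stats.percentileofscore(group_map, value, kind="mean"))
    lo, hi = bands
    if pct < lo:
        band = f"<{lo:g}%"
    elif pct > hi:
        band = f">{hi:g}%"
    else:
        band = f"{lo:g}-{hi:g}%"
    return RankReport(value=value, percentile=pct, band=band)
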