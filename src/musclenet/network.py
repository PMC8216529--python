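"""Band-wise functional muscle networks and their graph-topology metrics.

Muscles are nodes; the edge weight between two muscles is their band-averaged
magnitude-squared coherence, giving a symmetric, nonnegative 6x6 weighted
adjacency matrix per subject, task and band.  A proportional threshold keeps
the same connection density across subjects (the strongest ceil(p * 15)
of the 15 distinct edges, weights retained, not binarised).  Two node metrics
are computed: strength (sum of incident weights) and betweenness centrality
(fraction of shortest paths through the node, edge length 1/weight,
normalised to [0, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from musclenet import coherence as _coherence
from musclenet import stats as _stats

N_NODES = 6
N_EDGES = N_NODES * (N_NODES - 1) // 2  # 15


@dataclass
class BandNetwork:
    """One subject's weighted muscle network in one frequency band."""

    subject: str
    task: str
    band: str
    nodes: tuple[str, ...]
    W: np.ndarray
    density_retained: float = 1.0

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        n = len(self.nodes)
        if self.W.shape != (n, n):
            raise ValueError("W must be square with one row per node")
        if not np.allclose(self.W, self.W.T):
            raise ValueError("W must be symmetric")
        if np.any(np.diag(self.W) != 0):
            raise ValueError("W must have a zero diagonal")
        if np.any(self.W < 0):
            raise ValueError("W must be nonnegative")


def build_adjacency(
    trials: list[np.ndarray],
    fs: float,
    channel_labels: tuple[str, ...],
    band: _coherence.BandDefinition,
    cfg: _coherence.CoherenceConfig | None = None,
    subject: str = "",
    task: str = "",
    within_side_only: bool = False,
) -> BandNetwork:
    """Band-MSC adjacency over all 15 unordered channel pairs.

    ``within_side_only=True`` restricts edges to same-side pairs (the
    feature-extraction convention); the default includes cross-side pairs so
    the 6-node graph is connected and betweenness is non-degenerate.
    """
    cfg = cfg or _coherence.CoherenceConfig()
    n = len(channel_labels)
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if within_side_only:
                side_i = channel_labels[i].rsplit("-", 1)[1]
                side_j = channel_labels[j].rsplit("-", 1)[1]
                if side_i != side_j:
                    continue
            spec = _coherence.msc(
                [tr[i] for tr in trials],
                [tr[j] for tr in trials],
                fs,
                cfg,
                pair=(channel_labels[i], channel_labels[j]),
            )
            W[i, j] = W[j, i] = _coherence.band_msc(spec, band)
    return BandNetwork(
        subject=subject, task=task, band=band.name, nodes=tuple(channel_labels), W=W
    )


def proportional_threshold(W: np.ndarray, p: float) -> np.ndarray:
    """Keep the ceil(p * n_edges) largest upper-triangle weights, zero the rest.

    Retained edges keep their weights.  Ties are broken by lexicographic
    node-pair order so the retained count is identical for every subject.
    """
    if p <= 0:
        raise ValueError("threshold proportion p must be positive")
    p = min(p, 1.0)
    W = np.asarray(W, dtype=float)
    if not np.allclose(W, W.T):
        raise ValueError("W must be symmetric")
    n = W.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    m_keep = int(np.ceil(p * len(iu)))
    order = sorted(range(len(iu)), key=lambda k: (-W[iu[k], ju[k]], iu[k], ju[k]))
    keep = order[:m_keep]
    out = np.zeros_like(W)
    for k in keep:
        out[iu[k], ju[k]] = out[ju[k], iu[k]] = W[iu[k], ju[k]]
    return out


def node_strength(W: np.ndarray) -> np.ndarray:
    """Strength: sum of weights of links connected to each node."""
    W = np.asarray(W, dtype=float)
    return W.sum(axis=1)


def node_degree(W: np.ndarray) -> np.ndarray:
    """Number of nonzero incident edges per node."""
    W = np.asarray(W, dtype=float)
    return (W > 0).sum(axis=1)


def node_strength_mean(W: np.ndarray) -> np.ndarray:
    """Mean weight of the nonzero incident edges per node (0 if isolated).

    On a proportionally thresholded matrix this is on the scale of a single
    edge weight, the scale on which per-node connectivity is usually tabled.
    """
    W = np.asarray(W, dtype=float)
    deg = node_degree(W)
    s = node_strength(W)
    out = np.zeros_like(s)
    nz = deg > 0
    out[nz] = s[nz] / deg[nz]
    return out


def betweenness(W: np.ndarray) -> np.ndarray:
    """Normalised weighted betweenness centrality per node, in [0, 1].

    Edges carry length 1/weight (strong coherence = short path); shortest
    paths are computed exactly (Brandes/Dijkstra) with fractional counting of
    equal-length ties; normalisation is by (n-1)(n-2)/2 pairs for undirected
    graphs.  Disconnected components simply contribute no paths.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    G = nx.Graph()
    G.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if W[i, j] > 0:
                G.add_edge(i, j, length=1.0 / W[i, j])
    bc = nx.betweenness_centrality(G, weight="length", normalized=True)
    return np.array([bc[i] for i in range(n)])


NODE_METRICS = {
    "strength": node_strength,
    "strength_mean": node_strength_mean,
    "bc": betweenness,
    "degree": node_degree,
}


def node_metrics(W: np.ndarray, nodes: tuple[str, ...]) -> pd.DataFrame:
    """All node metrics of one (possibly thresholded) adjacency matrix."""
    return pd.DataFrame(
        {name: fn(W) for name, fn in NODE_METRICS.items()}, index=list(nodes)
    )


def group_network_analysis(
    networks: list[BandNetwork],
    groups: dict[str, str],
    p: float = 0.5,
    metric: str = "strength",
) -> dict:
    """Group comparison of a node-averaged metric on thresholded networks.

    Each subject's metric is averaged across the 6 nodes; groups are compared
    with the pooled-variance two-sample t-test.  Also returns the per-group
    average adjacency (of thresholded matrices) for graph export.
    """
    if metric not in NODE_METRICS:
        raise ValueError(f"unknown metric {metric!r}; one of {sorted(NODE_METRICS)}")
    fn = NODE_METRICS[metric]
    per_subject: dict[str, float] = {}
    thresholded: dict[str, np.ndarray] = {}
    nodes = None
    for net in networks:
        nodes = net.nodes
        Wt = proportional_threshold(net.W, p)
        thresholded[net.subject] = Wt
        per_subject[net.subject] = float(np.mean(fn(Wt)))
    by_group: dict[str, list[float]] = {}
    members: dict[str, list[str]] = {}
    for subject, value in per_subject.items():
        g = groups[subject]
        by_group.setdefault(g, []).append(value)
        members.setdefault(g, []).append(subject)
    for g, vals in by_group.items():
        if len(vals) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
    gnames = sorted(by_group)
    if len(gnames) != 2:
        raise ValueError("exactly two groups are required")
    a, b = (np.array(by_group[g]) for g in gnames)
    test = _stats.ttest_two_sample(a, b)
    mean_adj = {
        g: np.mean([thresholded[s] for s in members[g]], axis=0) for g in gnames
    }
    return {
        "metric": metric,
        "p_threshold": p,
        "nodes": nodes,
        "per_subject": per_subject,
        "group_means": {g: float(np.mean(by_group[g])) for g in gnames},
        "group_sds": {g: float(np.std(by_group[g], ddof=1)) for g in gnames},
        "test": test,
        "group_mean_adjacency": mean_adj,
    }


def edge_list(W: np.ndarray, nodes: tuple[str, ...]) -> pd.DataFrame:
    """Nonzero edges of a symmetric matrix as (node_a, node_b, weight) rows."""
    W = np.asarray(W, dtype=float)
    rows = []
    n = W.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            if W[i, j] > 0:
                rows.append({"node_a": nodes[i], "node_b": nodes[j], "weight": W[i, j]})
    return pd.DataFrame(rows, columns=["node_a", "node_b", "weight"])
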