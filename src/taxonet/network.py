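"""Significance-filtered Spearman co-occurrence networks and their
edge-betweenness partition.

Nodes are taxa (relative abundance per sample) and, optionally, metadata
variables (percent of range per sample). For every unordered node pair the
number of joint observations is counted first — a taxon is observed where
its value is positive, a metadata variable where it is non-missing — and
pairs jointly observed fewer than ``min_obs`` times are discarded before
any correlation is computed. Surviving pairs become edges when the absolute
Spearman coefficient strictly exceeds ``rho_min`` and the t-approximation
p-value is strictly below ``p_max``. The resulting graph (a
:class:`networkx.Graph` with ``rho``/``p``/``n_obs`` edge attributes and a
``kind`` node attribute; isolated nodes excluded) is partitioned by the
Girvan-Newman procedure: repeatedly remove a highest-betweenness edge,
recomputing betweenness after every removal, and keep the component
partition of the sequence that maximises Newman-Girvan modularity on the
original graph. Betweenness, modularity and shortest paths treat the graph
as unweighted and ignore edge sign; the signed coefficient is kept as an
edge attribute for reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "NodeTable",
    "ClusterAssignment",
    "assemble_node_table",
    "observed_mask",
    "count_cooccurrence",
    "spearman_with_p",
    "edge_passes",
    "build_network",
    "edge_betweenness",
    "modularity",
    "girvan_newman_partition",
    "node_degree",
    "edge_list_frame",
    "membership_frame",
    "write_graphml",
]

TAXON = "taxon"
METADATA = "metadata"


@dataclass
class NodeTable:
    """Common-scale node values: a nodes × samples DataFrame plus a kind
    ('taxon' or 'metadata') per node."""

    values: pd.DataFrame
    kinds: pd.Series

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.kinds.index):
            raise ValueError("values and kinds must share the same node index")
        bad = set(self.kinds) - {TAXON, METADATA}
        if bad:
            raise ValueError(f"unknown node kinds: {sorted(bad)}")


@dataclass
class ClusterAssignment:
    """Node → cluster labels (contiguous from 1) with the modularity of the
    chosen partition and the edge-removal trace that produced it."""

    labels: dict
    kinds: dict
    modularity: float
    removal_order: list = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))

    def members(self, label: int) -> list:
        return sorted(n for n, c in self.labels.items() if c == label)


def assemble_node_table(
    rel: pd.DataFrame,
    scaled_meta: pd.DataFrame | None = None,
    min_shared: int = 5,
) -> NodeTable:
    """Stack taxa and scaled metadata variables as nodes over shared samples."""
    if scaled_meta is None or scaled_meta.shape[1] == 0:
        shared = list(rel.columns)
    else:
        shared = [s for s in rel.columns if s in scaled_meta.index]
    if len(shared) < min_shared:
        raise ValueError(
            f"only {len(shared)} samples shared between abundance and metadata "
            f"tables (need >= {min_shared})"
        )
    taxa = rel[shared]
    kinds = {fid: TAXON for fid in taxa.index}
    blocks = [taxa]
    if scaled_meta is not None and scaled_meta.shape[1] > 0:
        meta_block = scaled_meta.loc[shared].T
        clash = set(meta_block.index) & set(taxa.index)
        if clash:
            raise ValueError(f"metadata variable names collide with feature ids: {sorted(clash)}")
        kinds.update({v: METADATA for v in meta_block.index})
        blocks.append(meta_block)
    values = pd.concat(blocks, axis=0)
    return NodeTable(values=values, kinds=pd.Series(kinds).loc[values.index])


def observed_mask(values: np.ndarray, kind: str) -> np.ndarray:
    """Boolean per-sample observation mask for one node."""
    if kind == TAXON:
        return ~np.isnan(values) & (values > 0)
    if kind == METADATA:
        return ~np.isnan(values)
    raise ValueError(f"unknown node kind {kind!r}")


def count_cooccurrence(x: np.ndarray, y: np.ndarray, kind_x: str = TAXON, kind_y: str = TAXON) -> int:
    """Number of samples where both nodes are observed."""
    return int((observed_mask(np.asarray(x, float), kind_x) & observed_mask(np.asarray(y, float), kind_y)).sum())


def spearman_with_p(x, y) -> tuple[float, float, int]:
    """Spearman rank correlation with its t-approximation p-value.

    rho is the Pearson correlation of average-ranked values (midranks for
    ties); the two-sided p-value comes from
    t = rho * sqrt((n - 2) / (1 - rho^2)) on n - 2 degrees of freedom, with
    p = 0 at |rho| = 1. Returns (nan, nan, n) when either ranked vector has
    zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan"), float("nan"), n
    rx -= rx.mean()
    ry -= ry.mean()
    rho = float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        return rho, 0.0, n
    if n < 3:
        return rho, float("nan"), n
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return rho, p, n


def edge_passes(rho: float, p: float, rho_min: float = 0.6, p_max: float = 0.05) -> bool:
    """Strict-inequality edge filter: |rho| > rho_min and p < p_max.

    Boundary values (|rho| == rho_min or p == p_max) are excluded.
    """
    if np.isnan(rho) or np.isnan(p):
        return False
    return abs(rho) > rho_min and p < p_max


def build_network(
    nodes: NodeTable,
    min_obs: int = 5,
    rho_min: float = 0.6,
    p_max: float = 0.05,
    min_detect: float = 0.0,
    bh_correct: bool = False,
    allow_meta_meta: bool = True,
) -> nx.Graph:
    """Build the filtered co-occurrence graph over all node pairs.

    Correlations use pairwise-complete observations: exactly the samples
    where both nodes are observed. ``min_detect`` optionally raises the
    taxon detection floor above zero. ``bh_correct`` applies
    Benjamini-Hochberg adjustment to the candidate p-values before the
    ``p_max`` filter (off by default, matching a raw-p filter).
    """
    if nodes.values.shape[0] < 2:
        raise ValueError("need at least 2 nodes")
    ids = list(nodes.values.index)
    mat = nodes.values.to_numpy(dtype=float)
    kinds = nodes.kinds.to_dict()
    masks = np.empty(mat.shape, dtype=bool)
    for i, nid in enumerate(ids):
        row = mat[i]
        if kinds[nid] == TAXON:
            masks[i] = ~np.isnan(row) & (row > min_detect)
        else:
            masks[i] = ~np.isnan(row)

    candidates = []  # (u, v, rho, p, n_obs) with u < v as strings
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            u, v = ids[i], ids[j]
            if not allow_meta_meta and kinds[u] == METADATA and kinds[v] == METADATA:
                continue
            joint = masks[i] & masks[j]
            n_obs = int(joint.sum())
            if n_obs < min_obs:
                continue
            rho, p, _ = spearman_with_p(mat[i][joint], mat[j][joint])
            if np.isnan(rho):
                logger.debug("skipping pair (%s, %s): zero rank variance", u, v)
                continue
            candidates.append((u, v, rho, p, n_obs))

    if bh_correct and candidates:
        pvals = np.array([c[3] for c in candidates])
        order = np.argsort(pvals, kind="stable")
        m = len(pvals)
        adj = np.empty(m)
        running = 1.0
        for rank_idx in range(m - 1, -1, -1):
            k = order[rank_idx]
            running = min(running, pvals[k] * m / (rank_idx + 1))
            adj[k] = running
        candidates = [(u, v, r, q, n) for (u, v, r, _, n), q in zip(candidates, adj)]

    graph = nx.Graph(min_obs=min_obs, rho_min=rho_min, p_max=p_max)
    for u, v, rho, p, n_obs in sorted(candidates, key=lambda c: (str(c[0]), str(c[1]))):
        if edge_passes(rho, p, rho_min, p_max):
            for node in (u, v):
                if node not in graph:
                    graph.add_node(node, kind=kinds[node])
            graph.add_edge(u, v, rho=float(rho), p=float(p), n_obs=n_obs)
    return graph


def _sorted_edge(u, v) -> tuple:
    return tuple(sorted((u, v), key=str))


def edge_betweenness(net: nx.Graph) -> dict:
    """Unweighted edge betweenness: shortest-path counts per edge over all
    unordered node pairs, with fractional credit for tied paths."""
    if net.number_of_nodes() == 0:
        raise ValueError("network is empty")
    raw = nx.edge_betweenness_centrality(net, normalized=False)
    return {_sorted_edge(u, v): value for (u, v), value in raw.items()}


def modularity(net: nx.Graph, partition) -> float:
    """Newman-Girvan modularity Q = sum_c (e_c/m - (d_c/2m)^2) of a node
    partition, evaluated on ``net`` as an unweighted graph."""
    m = net.number_of_edges()
    if m == 0:
        raise ValueError("modularity undefined for an edgeless graph")
    q = 0.0
    for community in partition:
        community = set(community)
        e_c = sum(1 for u, v in net.edges() if u in community and v in community)
        d_c = sum(d for _, d in net.degree(community))
        q += e_c / m - (d_c / (2.0 * m)) ** 2
    return q


def girvan_newman_partition(net: nx.Graph) -> ClusterAssignment:
    """Partition the network by iterative highest-betweenness edge removal.

    Betweenness is recomputed after every removal (classic Girvan-Newman);
    the component partition is recorded at each step and the one maximising
    modularity on the original graph is returned. Ties on betweenness are
    broken toward the lexicographically smallest (u, v) edge; ties on
    modularity toward fewer clusters, then earlier in the removal sequence.
    Components of the input are never merged. Cluster labels are assigned
    1..k in order of each cluster's smallest node id.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("network is empty")
    work = net.copy()
    partitions = [frozenset(frozenset(c) for c in nx.connected_components(work))]
    removal_order: list[tuple] = []
    while work.number_of_edges() > 0:
        eb = edge_betweenness(work)
        best = min(eb, key=lambda e: (-round(eb[e], 10), str(e[0]), str(e[1])))
        work.remove_edge(*best)
        removal_order.append(best)
        partitions.append(frozenset(frozenset(c) for c in nx.connected_components(work)))

    best_q = -np.inf
    best_partition = None
    for idx, partition in enumerate(partitions):
        q = round(modularity(net, partition), 12)
        key = (-q, len(partition), idx)
        if best_partition is None or key < best_key:
            best_q, best_partition, best_key = q, partition, key

    clusters = sorted(best_partition, key=lambda c: min(str(n) for n in c))
    labels = {node: i for i, cluster in enumerate(clusters, start=1) for node in cluster}
    kinds = {node: data.get("kind", TAXON) for node, data in net.nodes(data=True)}
    return ClusterAssignment(
        labels=labels,
        kinds=kinds,
        modularity=float(best_q),
        removal_order=removal_order,
    )


def node_degree(net: nx.Graph) -> dict:
    """Incident-edge count per node."""
    return {node: int(degree) for node, degree in net.degree()}


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------


def edge_list_frame(net: nx.Graph, assign: ClusterAssignment | None = None) -> pd.DataFrame:
    """Flat edge list (u, v, rho, p, n_obs[, cluster_u, cluster_v])."""
    rows = []
    for u, v, data in net.edges(data=True):
        u, v = _sorted_edge(u, v)
        row = {"u": u, "v": v, "rho": data["rho"], "p": data["p"], "n_obs": data["n_obs"]}
        if assign is not None:
            row["cluster_u"] = assign.labels[u]
            row["cluster_v"] = assign.labels[v]
        rows.append(row)
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame = frame.sort_values(["u", "v"], kind="stable").reset_index(drop=True)
    return frame


def membership_frame(net: nx.Graph, assign: ClusterAssignment) -> pd.DataFrame:
    """Cluster membership table (node_id, kind, cluster, degree)."""
    degrees = node_degree(net)
    rows = [
        {
            "node_id": node,
            "kind": assign.kinds.get(node, TAXON),
            "cluster": assign.labels[node],
            "degree": degrees.get(node, 0),
        }
        for node in sorted(assign.labels, key=str)
    ]
    return pd.DataFrame(rows)


def write_graphml(
    net: nx.Graph,
    path,
    assign: ClusterAssignment | None = None,
    taxonomy: dict | None = None,
) -> None:
    """Write the network as GraphML with cluster/degree/taxonomy node
    attributes and rho/p/n_obs edge attributes."""
    out = net.copy()
    degrees = node_degree(out)
    for node in out.nodes:
        out.nodes[node]["degree"] = degrees[node]
        if assign is not None:
            out.nodes[node]["cluster"] = assign.labels.get(node, 0)
        if taxonomy is not None and node in taxonomy:
            out.nodes[node]["taxonomy"] = ";".join(taxonomy[node])
    nx.write_graphml(out, path)
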