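"""Typed signed signaling-network model and per-node topology metrics.

The network mixes directed activating (+) and repressing (−) edges with
undirected physical (PPI) edges. Signed degrees consider only the
directed edges; the PPI-only degree ignores them; paths and the
path-based centralities treat PPI edges as traversable in both
directions (they are physical adapter links — dropping them would
disconnect the network), while activate/repress edges respect their
direction.

The "relative level" locates a node between the upstream receptors and
the downstream effectors: d_up / (d_up + d_down), where d_up is the
shortest directed distance from any receptor to the node and d_down the
shortest directed distance from the node to any effector. 0 means
receptor-level, 1 means effector-level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SignalingNetwork",
    "load_network",
    "signed_degrees",
    "centralities",
    "ppi_only_degree",
    "partner_mean_ppi_degree",
    "remove_feedback_edges",
    "identify_effectors",
    "relative_level",
    "compute_node_topology",
]

EDGE_TYPES = ("activate", "repress", "ppi")


@dataclass
class SignalingNetwork:
    """Signed signaling network with receptor and TF annotations.

    ``edges`` holds one row per typed edge (source, target, edge_type);
    activate/repress edges are directed, ppi edges are stored once and
    traversed both ways. Duplicate identical rows collapse on
    construction; a ppi edge and its reverse are the same edge.
    """

    edges: pd.DataFrame
    receptor_set: frozenset = field(default_factory=frozenset)
    tf_set: frozenset = field(default_factory=frozenset)
    extra_nodes: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        df = self.edges.copy()
        bad = ~df["edge_type"].isin(EDGE_TYPES)
        if bad.any():
            row = df[bad].iloc[0]
            raise ValueError(
                f"unknown edge type {row['edge_type']!r} in edge "
                f"{row['source']}->{row['target']} (allowed: {EDGE_TYPES})"
            )
        is_ppi = df["edge_type"] == "ppi"
        ppi = df[is_ppi].copy()
        if len(ppi):
            uv = np.sort(ppi[["source", "target"]].to_numpy(dtype=object), axis=1)
            ppi[["source", "target"]] = uv
        df = pd.concat([df[~is_ppi], ppi], ignore_index=True)
        n_before = len(df)
        df = df.drop_duplicates(subset=["source", "target", "edge_type"]).reset_index(drop=True)
        if len(df) < n_before:
            logger.info("collapsed %d duplicate edge row(s)", n_before - len(df))
        self.edges = df
        self.receptor_set = frozenset(self.receptor_set)
        self.tf_set = frozenset(self.tf_set)
        stray = (self.receptor_set | self.tf_set) - self.nodes
        if stray:
            # annotated genes with no interactions become isolated nodes
            logger.warning("%d receptor/TF gene(s) have no edges; kept as isolated nodes", len(stray))
            self.extra_nodes = frozenset(self.extra_nodes) | stray
        else:
            self.extra_nodes = frozenset(self.extra_nodes)

    @property
    def nodes(self) -> set:
        return (
            set(self.edges["source"]) | set(self.edges["target"]) | set(self.extra_nodes)
        )

    def directed_signed(self) -> nx.MultiDiGraph:
        """Activate/repress edges only; parallel opposite signs coexist."""
        g = nx.MultiDiGraph()
        g.add_nodes_from(self.nodes)
        for _, r in self.edges[self.edges["edge_type"] != "ppi"].iterrows():
            g.add_edge(r["source"], r["target"], sign="+" if r["edge_type"] == "activate" else "-")
        return g

    def traversal(self) -> nx.DiGraph:
        """Directed graph for paths: signed edges directed, ppi both ways."""
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for _, r in self.edges.iterrows():
            g.add_edge(r["source"], r["target"])
            if r["edge_type"] == "ppi":
                g.add_edge(r["target"], r["source"])
        return g

    def undirected(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges[["source", "target"]].itertuples(index=False, name=None))
        return g

    def ppi_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        ppi = self.edges[self.edges["edge_type"] == "ppi"]
        g.add_edges_from(ppi[["source", "target"]].itertuples(index=False, name=None))
        return g


def _read_gene_list(path: str | Path) -> frozenset:
    with open(path) as fh:
        return frozenset(line.strip() for line in fh if line.strip())


def load_network(
    edge_file: str | Path,
    receptor_file: str | Path | None = None,
    tf_file: str | Path | None = None,
) -> SignalingNetwork:
    """Build a :class:`SignalingNetwork` from TSV edge and gene-list files.

    The edge file needs columns source, target, edge_type; rows with an
    unrecognized type are rejected with a message naming the row.
    Receptor/TF files hold one gene id per line.
    """
    edges = pd.read_csv(edge_file, sep="\t", dtype=str)
    required = {"source", "target", "edge_type"}
    if not required <= set(edges.columns):
        raise ValueError(f"edge file must have columns {sorted(required)}, got {list(edges.columns)}")
    receptors = _read_gene_list(receptor_file) if receptor_file else frozenset()
    tfs = _read_gene_list(tf_file) if tf_file else frozenset()
    net = SignalingNetwork(edges=edges, receptor_set=receptors, tf_set=tfs)
    counts = net.edges["edge_type"].value_counts().to_dict()
    logger.info("loaded network: %d nodes, edges by type %s", len(net.nodes), counts)
    return net


def signed_degrees(net: SignalingNetwork) -> pd.DataFrame:
    """Directional signed degrees per node (ppi edges excluded)."""
    g = net.directed_signed()
    nodes = sorted(net.nodes)
    out = pd.DataFrame(
        0,
        index=pd.Index(nodes, name="gene_id"),
        columns=["deg_act_in", "deg_act_out", "deg_rep_in", "deg_rep_out"],
    )
    for u, v, data in g.edges(data=True):
        if data["sign"] == "+":
            out.loc[u, "deg_act_out"] += 1
            out.loc[v, "deg_act_in"] += 1
        else:
            out.loc[u, "deg_rep_out"] += 1
            out.loc[v, "deg_rep_in"] += 1
    out["deg_directed_total"] = out.sum(axis=1)
    return out


def centralities(net: SignalingNetwork) -> pd.DataFrame:
    """Betweenness, closeness, eigenvector and transitivity per node.

    Betweenness and closeness run on the directed traversal graph
    (normalized; closeness uses outgoing distances and averages over the
    reachable set only). Eigenvector centrality and transitivity (the
    local clustering coefficient) run on the undirected projection.
    Isolated nodes get 0 by convention.
    """
    t = net.traversal()
    u = net.undirected()
    nodes = sorted(net.nodes)
    bet = nx.betweenness_centrality(t, normalized=True) if len(nodes) > 2 else {n: 0.0 for n in nodes}
    clo = nx.closeness_centrality(t.reverse(), wf_improved=False)
    try:
        eig = nx.eigenvector_centrality_numpy(u)
    except (nx.NetworkXException, ValueError, TypeError):
        eig = {n: 0.0 for n in nodes}
    tra = nx.clustering(u)
    return pd.DataFrame(
        {
            "betweenness": [bet.get(n, 0.0) for n in nodes],
            "closeness": [clo.get(n, 0.0) for n in nodes],
            "eigenvector": [abs(eig.get(n, 0.0)) for n in nodes],
            "transitivity": [tra.get(n, 0.0) for n in nodes],
        },
        index=pd.Index(nodes, name="gene_id"),
    )


def ppi_only_degree(net: SignalingNetwork) -> pd.Series:
    """Distinct ppi partners per node, activating/repressing edges ignored."""
    g = net.ppi_graph()
    return pd.Series(
        {n: g.degree(n) for n in sorted(net.nodes)}, name="ppi_only_degree"
    ).rename_axis("gene_id")


def partner_mean_ppi_degree(net: SignalingNetwork) -> pd.Series:
    """Mean ppi-only degree over a node's ppi partners (NaN if none)."""
    g = net.ppi_graph()
    out = {}
    for n in sorted(net.nodes):
        partners = list(g.neighbors(n))
        out[n] = float(np.mean([g.degree(p) for p in partners])) if partners else np.nan
    return pd.Series(out, name="partner_mean_ppi_degree").rename_axis("gene_id")


def remove_feedback_edges(net: SignalingNetwork) -> nx.MultiDiGraph:
    """Directed acyclic residual of the signed subnetwork.

    Every activate/repress edge lying on a directed cycle — i.e. whose
    endpoints share a strongly connected component — is removed; ppi
    edges are ignored here entirely.
    """
    g = net.directed_signed()
    comp = {}
    for i, scc in enumerate(nx.strongly_connected_components(g)):
        for n in scc:
            comp[n] = i
    residual = nx.MultiDiGraph()
    residual.add_nodes_from(g.nodes)
    for u, v, data in g.edges(data=True):
        if comp[u] != comp[v]:
            residual.add_edge(u, v, **data)
    return residual


def identify_effectors(net: SignalingNetwork, mode: str = "topology") -> frozenset:
    """Downstream-effector node set.

    ``topology``: nodes with zero out-degree after feedback-edge removal
    (no signal leaves them, so they sit at cascade bottoms).
    ``tf``: the annotated transcription-factor set verbatim, which is
    robust to missing edges in incomplete networks.
    """
    if mode == "tf":
        if not net.tf_set:
            logger.warning("tf effector mode with empty tf_set: downstream levels will be undefined")
        return net.tf_set
    if mode != "topology":
        raise ValueError(f"unknown effector mode {mode!r} (use 'topology' or 'tf')")
    residual = remove_feedback_edges(net)
    eff = frozenset(n for n in residual.nodes if residual.out_degree(n) == 0)
    if not eff:
        logger.warning("no zero-out-degree effectors found: downstream levels will be undefined")
    return eff


def _multi_source_bfs(g: nx.DiGraph, sources: frozenset) -> dict:
    dist = {}
    frontier = [s for s in sources if s in g]
    for s in frontier:
        dist[s] = 0
    d = 0
    while frontier:
        d += 1
        nxt = []
        for u in frontier:
            for v in g.successors(u):
                if v not in dist:
                    dist[v] = d
                    nxt.append(v)
        frontier = nxt
    return dist


def relative_level(
    net: SignalingNetwork, receptors: frozenset | None = None, effectors: frozenset | None = None
) -> pd.Series:
    """Relative position between receptors and effectors, in [0, 1].

    level = d_up / (d_up + d_down) with both distances taken along
    direction-respecting shortest paths (ppi edges usable both ways).
    Undefined (NaN) when either distance is infinite. A node that is
    both receptor and effector (d_up = d_down = 0) gets 0.5 by the
    symmetric convention.
    """
    receptors = frozenset(receptors if receptors is not None else net.receptor_set)
    effectors = frozenset(effectors if effectors is not None else identify_effectors(net))
    if not receptors or not effectors:
        raise ValueError("relative_level needs nonempty receptor and effector sets")
    t = net.traversal()
    d_up = _multi_source_bfs(t, receptors)
    d_down = _multi_source_bfs(t.reverse(copy=False), effectors)
    out = {}
    for n in sorted(net.nodes):
        up, down = d_up.get(n), d_down.get(n)
        if up is None or down is None:
            out[n] = np.nan
        elif up == 0 and down == 0:
            out[n] = 0.5
        else:
            out[n] = up / (up + down)
    return pd.Series(out, name="relative_level").rename_axis("gene_id")


def compute_node_topology(net: SignalingNetwork, effector_mode: str = "tf") -> pd.DataFrame:
    """Full per-node topology record table.

    Includes both relative-level variants (topology-defined effectors
    and TF-defined effectors) when the corresponding effector set is
    nonempty.
    """
    parts = [signed_degrees(net), centralities(net), ppi_only_degree(net), partner_mean_ppi_degree(net)]
    out = pd.concat(parts, axis=1)
    for mode, col in (("topology", "relative_level_topo"), ("tf", "relative_level_tf")):
        try:
            eff = identify_effectors(net, mode=mode)
            if net.receptor_set and eff:
                out[col] = relative_level(net, net.receptor_set, eff)
            else:
                out[col] = np.nan
        except ValueError:
            out[col] = np.nan
    out["relative_level"] = out[
        "relative_level_tf" if effector_mode == "tf" else "relative_level_topo"
    ]
    return out
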