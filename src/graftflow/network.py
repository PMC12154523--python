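"""Transcriptome / mobile-transcriptome / metabolome correlation networks.

Abundance profiles of RNAs, mobile RNAs, and metabolites measured across
the same samples are correlated pairwise (Spearman rank correlation) and
thresholded into an undirected typed network: nodes carry their omics
type, edges the correlation and its sign. With condition-mean profiles of
only four samples the attainable rho values form a small finite set
(enumerable via :func:`attainable_rho_values`), so replicate-level
profiles are the recommended default.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OmicsNode", "CorrelationEdge", "NetworkResult", "spearman",
    "build_network", "pathway_subnetwork", "attainable_rho_values",
    "nodes_from_frame",
]

NODE_TYPES = ("rna", "mobile_rna", "metabolite")


@dataclass(frozen=True)
class OmicsNode:
    """A typed molecular profile across samples."""

    node_id: str
    node_type: str
    profile: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.node_type not in NODE_TYPES:
            raise ValueError(f"node_type must be one of {NODE_TYPES}")
        object.__setattr__(self, "profile", tuple(float(v) for v in self.profile))


@dataclass(frozen=True)
class CorrelationEdge:
    """Undirected correlation edge in canonical (node_a < node_b) order."""

    node_a: str
    node_b: str
    rho: float

    def __post_init__(self) -> None:
        if self.node_a == self.node_b:
            raise ValueError("self-edges are not allowed")
        if self.node_a > self.node_b:
            raise ValueError("edges must be in canonical node_a < node_b order")

    @property
    def sign(self) -> str:
        return "+" if self.rho >= 0 else "-"


def spearman(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of average ranks.

    Ties receive their mean rank. Returns NaN (flagged missing) when either
    vector is constant, where rank correlation is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("profiles must be finite")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def nodes_from_frame(frame: pd.DataFrame, node_type: str) -> list[OmicsNode]:
    """One typed node per row of an abundance table (rows x samples)."""
    return [OmicsNode(str(idx), node_type, tuple(row))
            for idx, row in frame.iterrows()]


@dataclass
class NetworkResult:
    nodes: list[OmicsNode]
    edges: list[CorrelationEdge]
    rho_min: float

    @property
    def edge_frame(self) -> pd.DataFrame:
        types = {n.node_id: n.node_type for n in self.nodes}
        return pd.DataFrame([{
            "node_a": e.node_a, "node_b": e.node_b, "rho": e.rho,
            "sign": e.sign, "type_a": types[e.node_a], "type_b": types[e.node_b],
        } for e in self.edges],
            columns=["node_a", "node_b", "rho", "sign", "type_a", "type_b"])

    @property
    def degree_summary(self) -> pd.DataFrame:
        deg = {n.node_id: 0 for n in self.nodes}
        for e in self.edges:
            deg[e.node_a] += 1
            deg[e.node_b] += 1
        types = {n.node_id: n.node_type for n in self.nodes}
        return pd.DataFrame({
            "node_id": list(deg), "node_type": [types[k] for k in deg],
            "degree": list(deg.values())}).set_index("node_id")

    @property
    def type_counts(self) -> dict[str, int]:
        out = {t: 0 for t in NODE_TYPES}
        for n in self.nodes:
            out[n.node_type] += 1
        return out

    def to_graph(self):
        """The network as a networkx Graph (nodes typed, edges weighted)."""
        import networkx as nx

        g = nx.Graph()
        for n in self.nodes:
            g.add_node(n.node_id, node_type=n.node_type)
        for e in self.edges:
            g.add_edge(e.node_a, e.node_b, rho=e.rho, sign=e.sign)
        return g

    def write_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_graph(), str(path))


def build_network(nodes: list[OmicsNode], rho_min: float = 0.9) -> NetworkResult:
    """All-pairs Spearman network thresholded at |rho| >= rho_min.

    Profiles must share one length; constant profiles yield undefined
    correlations and contribute no edges.
    """
    if len(nodes) < 2:
        raise ValueError("need at least 2 nodes")
    lengths = {len(n.profile) for n in nodes}
    if len(lengths) != 1:
        raise ValueError(f"mixed profile lengths: {sorted(lengths)}")
    edges: list[CorrelationEdge] = []
    ordered = sorted(nodes, key=lambda n: n.node_id)
    ids = [n.node_id for n in ordered]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate node ids")
    for a_i in range(len(ordered)):
        for b_i in range(a_i + 1, len(ordered)):
            a, b = ordered[a_i], ordered[b_i]
            rho = spearman(a.profile, b.profile)
            if np.isfinite(rho) and abs(rho) >= rho_min:
                edges.append(CorrelationEdge(a.node_id, b.node_id, rho))
    return NetworkResult(nodes=list(nodes), edges=edges, rho_min=rho_min)


def pathway_subnetwork(
    network: NetworkResult,
    membership: dict[str, set[str]],
    tags,
) -> NetworkResult:
    """Restrict a network to nodes carrying one of the requested pathway tags.

    ``membership`` maps node id -> set of pathway tags (nodes may be
    untagged). An edge survives when both endpoints carry a requested tag.
    Unknown requested tags raise, listing the available ones.
    """
    available = set().union(*membership.values()) if membership else set()
    tags = set(tags)
    unknown = tags - available
    if unknown:
        raise KeyError(
            f"unknown pathway tags {sorted(unknown)}; available: "
            f"{sorted(available)}")
    tagged = {nid for nid, t in membership.items() if t & tags}
    nodes = [n for n in network.nodes if n.node_id in tagged]
    edges = [e for e in network.edges
             if e.node_a in tagged and e.node_b in tagged]
    return NetworkResult(nodes=nodes, edges=edges, rho_min=network.rho_min)


def attainable_rho_values(n: int) -> list[float]:
    """All Spearman values attainable by two tie-free profiles of length n.

    Enumerates rank permutations against the identity; e.g. for n = 4 the
    set is {-1, -0.8, -0.6, -0.4, -0.2, 0, 0.2, 0.4, 0.6, 0.8, 1} — a
    reminder of how coarse condition-mean (four-sample) correlations are.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    base = np.arange(1, n + 1, dtype=float)
    vals = {round(float(stats.spearmanr(base, np.array(p)).statistic), 12)
            for p in permutations(base)}
    return sorted(vals)
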