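"""Directed AOP network assembly.

Nodes are canonical harmonised events; edges point cause -> effect and carry
adjacency, recoded evidence / quantitative-understanding categories and the
set of source AOPs.  Parallel assertions of the same (upstream, downstream)
relationship across AOPs are merged into a single edge: adjacency resolves
adjacent-wins (the more direct mechanistic claim) and evidence strongest-wins,
with every contributing raw label retained for audit.  Self-loops are part of
the core model and only dropped on request at export time.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import networkx as nx

from .harmonise import HarmonisationResult, RemapResult
from .records import HarmonisedNode, KERRecord
from .util import pct
from .vocab import Adjacency, Category, Role, recode_evidence, recode_quant, strongest


@dataclass(frozen=True)
class NetworkEdge:
    """One merged directed relationship between two canonical nodes."""

    upstream: str
    downstream: str
    adjacency: Adjacency
    evidence: Category
    quant: Category
    source_aops: frozenset[str]
    raw_evidence: tuple[str, ...] = ()
    raw_quant: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.source_aops:
            raise ValueError("source_aops must be non-empty")

    @property
    def self_loop(self) -> bool:
        return self.upstream == self.downstream


@dataclass
class AOPNetwork:
    """Directed network of harmonised nodes with merged, annotated edges."""

    graph: nx.DiGraph
    provenance: dict = field(default_factory=dict)

    # -- convenience accessors -------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def node(self, title: str) -> HarmonisedNode:
        d = self.graph.nodes[title]
        return HarmonisedNode(title, d["member_ids"], d["role"], d["aops"])

    def nodes_by_role(self, role: Role) -> list[str]:
        return sorted(t for t, d in self.graph.nodes(data=True) if d["role"] is role)

    def edges(self) -> list[NetworkEdge]:
        out = []
        for u, v, d in self.graph.edges(data=True):
            out.append(
                NetworkEdge(
                    u, v, d["adjacency"], d["evidence"], d["quant"],
                    d["source_aops"], d["raw_evidence"], d["raw_quant"],
                )
            )
        return out

    def self_loops(self) -> list[str]:
        return sorted(u for u, v in self.graph.edges() if u == v)

    def path_graph(self, include_non_adjacent: bool = True) -> nx.DiGraph:
        """Self-loop-free view used by all path-based metrics."""
        H = nx.DiGraph()
        H.add_nodes_from(self.graph.nodes(data=True))
        for u, v, d in self.graph.edges(data=True):
            if u == v:
                continue
            if not include_non_adjacent and d["adjacency"] is Adjacency.NON_ADJACENT:
                continue
            H.add_edge(u, v, **d)
        return H


def build_network(
    harmonised: HarmonisationResult,
    remapped: RemapResult,
    provenance: dict | None = None,
) -> AOPNetwork:
    """Assemble the network from a canonical roster and remapped KERs.

    The build is order-independent: permuting input KER rows yields an
    identical network because merged attributes are resolved from unordered
    label sets and raw labels are stored sorted.
    """
    G = nx.DiGraph()
    for title in sorted(harmonised.roster):
        node = harmonised.roster[title]
        G.add_node(title, role=node.role, member_ids=node.member_ids, aops=node.aop_membership)

    grouped: dict[tuple[str, str], list[KERRecord]] = defaultdict(list)
    for up, down, ker in remapped.edges:
        grouped[(up, down)].append(ker)

    for (up, down), kers in grouped.items():
        adjacency = (
            Adjacency.ADJACENT
            if any(k.adjacency is Adjacency.ADJACENT for k in kers)
            else Adjacency.NON_ADJACENT
        )
        raw_evidence = tuple(sorted(k.evidence_raw for k in kers))
        raw_quant = tuple(sorted(k.quant_raw for k in kers))
        evidence = strongest(recode_evidence(r) for r in raw_evidence)
        quant = strongest(recode_quant(r) for r in raw_quant)
        source_aops = frozenset(k.aop_id for k in kers)
        G.add_edge(
            up, down,
            adjacency=adjacency, evidence=evidence, quant=quant,
            source_aops=source_aops, raw_evidence=raw_evidence, raw_quant=raw_quant,
        )
    return AOPNetwork(graph=G, provenance=dict(provenance or {}))


@dataclass
class CompositionSummary:
    """Printed-statistics view of a network's composition."""

    n_nodes: int
    n_edges: int
    role_counts: dict[Role, int]
    adjacency_counts: dict[Adjacency, int]
    adjacency_pcts: dict[Adjacency, float | None]
    self_loop_count: int
    sharing_histogram: dict[int, int]
    sharing_pcts: dict[int, float | None]


def composition_summary(network: AOPNetwork) -> CompositionSummary:
    """Node counts by role, edge counts by adjacency, self-loops and the
    KE-sharing histogram (node -> number of AOPs it belongs to)."""
    role_counts = Counter(d["role"] for _, d in network.graph.nodes(data=True))
    adj_counts = Counter(d["adjacency"] for _, _, d in network.graph.edges(data=True))
    sharing = Counter(len(d["aops"]) for _, d in network.graph.nodes(data=True))
    n_nodes, n_edges = network.n_nodes, network.n_edges
    return CompositionSummary(
        n_nodes=n_nodes,
        n_edges=n_edges,
        role_counts={r: role_counts.get(r, 0) for r in Role},
        adjacency_counts={a: adj_counts.get(a, 0) for a in Adjacency},
        adjacency_pcts={a: pct(adj_counts.get(a, 0), n_edges) for a in Adjacency},
        self_loop_count=len(network.self_loops()),
        sharing_histogram=dict(sorted(sharing.items())),
        sharing_pcts={k: pct(v, n_nodes) for k, v in sorted(sharing.items())},
    )


def subnetwork(network: AOPNetwork, node_pred=None, edge_pred=None) -> AOPNetwork:
    """Induced subnetwork keeping nodes/edges for which the predicates hold.

    ``node_pred(title, attrs)`` and ``edge_pred(u, v, attrs)`` default to
    keep-everything; dropping a node drops its incident edges.
    """
    node_pred = node_pred or (lambda t, d: True)
    edge_pred = edge_pred or (lambda u, v, d: True)
    H = nx.DiGraph()
    for t, d in network.graph.nodes(data=True):
        if node_pred(t, d):
            H.add_node(t, **d)
    for u, v, d in network.graph.edges(data=True):
        if u in H and v in H and edge_pred(u, v, d):
            H.add_edge(u, v, **d)
    return AOPNetwork(graph=H, provenance=dict(network.provenance))


def drop_self_loops(network: AOPNetwork) -> AOPNetwork:
    """Convenience view without self-loops (interactive-platform parity)."""
    return subnetwork(network, edge_pred=lambda u, v, d: u != v)
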