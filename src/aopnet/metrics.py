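"""Per-node topology metrics for directed AOP networks.

The suite mirrors what toxicological network studies report: in/out/total
degree, shortest-path betweenness, stress centrality (integer counts of
shortest paths through a node), out-eccentricity (how far a node's influence
has to travel), a combined min-max-normalised importance score, a
convergent/divergent/balanced flow classification, and MIE-to-AO simple-path
occurrence with the path-length distribution.

Conventions: self-loops contribute 2 to total degree (one in, one out) but
are excluded from every path-based metric; disconnected pairs are skipped
(no infinite distances); ranking ties break lexicographically by title.
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass, field
from enum import Enum

import networkx as nx
import pandas as pd

from .network import AOPNetwork
from .util import round_half_up
from .vocab import Role


class FlowClass(str, Enum):
    CONVERGENT = "convergent"
    DIVERGENT = "divergent"
    BALANCED = "balanced"


class PathCountExceeded(RuntimeError):
    """Raised when MIE->AO simple-path enumeration exceeds the configured cap."""


def classify_flow(in_degree: int, out_degree: int) -> FlowClass:
    """Convergent if in > out, divergent if out > in, balanced if equal."""
    if in_degree < 0 or out_degree < 0:
        raise ValueError("degrees must be non-negative")
    if in_degree > out_degree:
        return FlowClass.CONVERGENT
    if out_degree > in_degree:
        return FlowClass.DIVERGENT
    return FlowClass.BALANCED


def degree_stats(network: AOPNetwork) -> tuple[pd.DataFrame, float | None]:
    """Exact integer degrees per node and the mean total degree (2 decimals).

    Self-loops count once toward in-degree and once toward out-degree, so
    mean total degree is always 2|E| / |N|.
    """
    G = network.graph
    nodes = sorted(G.nodes())
    if not nodes:
        return pd.DataFrame(columns=["in_degree", "out_degree", "total_degree"]), None
    frame = pd.DataFrame(
        {
            "in_degree": [G.in_degree(n) for n in nodes],
            "out_degree": [G.out_degree(n) for n in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )
    frame["total_degree"] = frame["in_degree"] + frame["out_degree"]
    mean = round_half_up(float(frame["total_degree"].mean()), 2)
    return frame, mean


def _bfs_sigma(G: nx.DiGraph, source):
    """Unweighted single-source distances and shortest-path counts."""
    dist = {source: 0}
    sigma = {source: 1}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for w in G.successors(u):
            if w not in dist:
                dist[w] = dist[u] + 1
                sigma[w] = 0
                queue.append(w)
            if dist[w] == dist[u] + 1:
                sigma[w] += sigma[u]
    return dist, sigma


def betweenness(
    network: AOPNetwork,
    mode: str = "raw",
    include_non_adjacent: bool = True,
) -> dict[str, float]:
    """Shortest-path betweenness over ordered reachable pairs (s != v != t).

    ``mode="raw"`` reports unnormalised values; ``mode="pair_normalised"``
    divides by (N-1)(N-2).  Self-loops are ignored.
    """
    if mode not in {"raw", "pair_normalised"}:
        raise ValueError(f"unknown betweenness mode: {mode!r}")
    H = network.path_graph(include_non_adjacent)
    bc = nx.betweenness_centrality(H, normalized=(mode == "pair_normalised"))
    return {n: float(v) for n, v in bc.items()}


def stress_centrality(
    network: AOPNetwork, include_non_adjacent: bool = True
) -> dict[str, int]:
    """Total number of shortest s-t paths (s != v != t) passing through each node."""
    H = network.path_graph(include_non_adjacent)
    nodes = list(H.nodes())
    dist: dict[str, dict] = {}
    sigma: dict[str, dict] = {}
    for s in nodes:
        dist[s], sigma[s] = _bfs_sigma(H, s)
    stress = {n: 0 for n in nodes}
    for s in nodes:
        ds, ss = dist[s], sigma[s]
        for v in ds:
            if v == s:
                continue
            dv, sv = dist[v], sigma[v]
            for t in dv:
                if t == v or t == s:
                    continue
                if t in ds and ds[v] + dv[t] == ds[t]:
                    stress[v] += ss[v] * sv[t]
    return stress


def out_eccentricity(
    network: AOPNetwork, include_non_adjacent: bool = True
) -> dict[str, int]:
    """Maximum shortest-path distance from each node to any node it can reach.

    Sinks (nothing reachable) score 0; unreachable nodes are excluded from
    the maximum rather than treated as infinite.
    """
    H = network.path_graph(include_non_adjacent)
    ecc = {}
    for n in H.nodes():
        dist, _ = _bfs_sigma(H, n)
        ecc[n] = max((d for v, d in dist.items() if v != n), default=0)
    return ecc


def simple_path_occurrence(
    network: AOPNetwork,
    include_non_adjacent: bool = True,
    path_cap: int = 1_000_000,
) -> tuple[dict[str, int], dict[int, int]]:
    """MIE->AO simple-path occurrence per node plus the path-length histogram.

    Every simple directed path from every MIE-role node to every AO-role node
    is enumerated (self-loops excluded by simple-path semantics); a node's
    occurrence is the number of such paths in which it is internal (neither
    endpoint).  The histogram is keyed by path length in edges.  Enumeration
    aborts with :class:`PathCountExceeded` past ``path_cap`` paths, which
    signals a pathological input rather than a scientific result.
    """
    H = network.path_graph(include_non_adjacent)
    mies = [n for n, d in H.nodes(data=True) if d["role"] is Role.MIE]
    aos = set(n for n, d in H.nodes(data=True) if d["role"] is Role.AO)
    occurrence = {n: 0 for n in H.nodes()}
    histogram: Counter[int] = Counter()
    n_paths = 0
    for source in sorted(mies):
        for path in nx.all_simple_paths(H, source, sorted(aos)) if aos else []:
            n_paths += 1
            if n_paths > path_cap:
                raise PathCountExceeded(
                    f"more than {path_cap} MIE->AO simple paths; raise path_cap "
                    "only if this input is genuinely expected to be that dense"
                )
            histogram[len(path) - 1] += 1
            for internal in path[1:-1]:
                occurrence[internal] += 1
    return occurrence, dict(sorted(histogram.items()))


def combined_importance(
    frame: pd.DataFrame,
    components: tuple[str, ...] = ("total_degree", "betweenness", "stress"),
) -> pd.DataFrame:
    """Min-max normalise each component to [0, 1] over nodes and sum.

    A zero-range component contributes 0 for every node.  Returns a copy of
    the frame with ``combined_score`` and a stable descending ``rank`` whose
    ties break lexicographically by node title.
    """
    for c in components:
        if c not in frame.columns:
            raise ValueError(f"unknown combined-importance component: {c!r}")
    out = frame.copy()
    score = pd.Series(0.0, index=out.index)
    for c in components:
        col = out[c].astype(float)
        rng = col.max() - col.min()
        if rng > 0:
            score = score + (col - col.min()) / rng
    out["combined_score"] = score
    order = sorted(out.index, key=lambda t: (-out.loc[t, "combined_score"], t))
    out["rank"] = pd.Series({t: i + 1 for i, t in enumerate(order)})
    return out


@dataclass
class MetricsTable:
    """Per-node topology table plus table-level aggregates."""

    frame: pd.DataFrame
    mean_total_degree: float | None
    path_length_histogram: dict[int, int] = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t")


def compute_metrics(
    network: AOPNetwork,
    betweenness_mode: str = "raw",
    include_non_adjacent: bool = True,
    path_cap: int = 1_000_000,
) -> MetricsTable:
    """Compute the full per-node metric suite on one network."""
    frame, mean_total = degree_stats(network)
    if frame.empty:
        return MetricsTable(frame=frame, mean_total_degree=None)
    bc = betweenness(network, betweenness_mode, include_non_adjacent)
    stress = stress_centrality(network, include_non_adjacent)
    ecc = out_eccentricity(network, include_non_adjacent)
    occ, histogram = simple_path_occurrence(network, include_non_adjacent, path_cap)
    frame["betweenness"] = pd.Series(bc)
    frame["stress"] = pd.Series(stress)
    frame["eccentricity"] = pd.Series(ecc)
    frame["simple_path_occurrence"] = pd.Series(occ)
    frame["flow_class"] = [
        classify_flow(i, o).value
        for i, o in zip(frame["in_degree"], frame["out_degree"])
    ]
    frame = combined_importance(frame)
    return MetricsTable(
        frame=frame, mean_total_degree=mean_total, path_length_histogram=histogram
    )
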