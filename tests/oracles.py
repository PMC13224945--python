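"""Brute-force oracles for path-based metrics.

These deliberately avoid the library code paths (no networkx): plain
recursive enumeration over adjacency dicts, feasible on the <=12-node graphs
used in property tests.  Self-loops are dropped before enumeration, matching
the semantics of the metrics under test.
"""

from __future__ import annotations


def adjacency_dict(nodes, edges) -> dict:
    adj = {n: [] for n in nodes}
    for u, v in edges:
        if u != v:
            adj[u].append(v)
    return adj


def enumerate_simple_paths(adj, source, target):
    """All simple directed paths source -> target, by recursive DFS."""
    paths = []

    def walk(node, path):
        if node == target:
            paths.append(list(path))
            return
        for nxt in adj[node]:
            if nxt not in path:
                path.append(nxt)
                walk(nxt, path)
                path.pop()

    if source in adj:
        walk(source, [source])
    return paths


def shortest_paths(adj, source, target):
    """All shortest source -> target paths (subset of the simple paths)."""
    paths = enumerate_simple_paths(adj, source, target)
    if not paths:
        return []
    best = min(len(p) for p in paths)
    return [p for p in paths if len(p) == best]


def oracle_betweenness(nodes, edges):
    adj = adjacency_dict(nodes, edges)
    bc = {n: 0.0 for n in nodes}
    for s in nodes:
        for t in nodes:
            if s == t:
                continue
            sps = shortest_paths(adj, s, t)
            if not sps:
                continue
            for v in nodes:
                if v in (s, t):
                    continue
                through = sum(1 for p in sps if v in p[1:-1])
                bc[v] += through / len(sps)
    return bc


def oracle_stress(nodes, edges):
    adj = adjacency_dict(nodes, edges)
    stress = {n: 0 for n in nodes}
    for s in nodes:
        for t in nodes:
            if s == t:
                continue
            for p in shortest_paths(adj, s, t):
                for v in p[1:-1]:
                    stress[v] += 1
    return stress


def oracle_out_eccentricity(nodes, edges):
    adj = adjacency_dict(nodes, edges)
    ecc = {}
    for n in nodes:
        dists = []
        for t in nodes:
            if t == n:
                continue
            sps = shortest_paths(adj, n, t)
            if sps:
                dists.append(len(sps[0]) - 1)
        ecc[n] = max(dists, default=0)
    return ecc


def oracle_occurrence(nodes, edges, mies, aos):
    adj = adjacency_dict(nodes, edges)
    occ = {n: 0 for n in nodes}
    histogram: dict[int, int] = {}
    for s in mies:
        for t in aos:
            if s == t:
                continue
            for p in enumerate_simple_paths(adj, s, t):
                length = len(p) - 1
                histogram[length] = histogram.get(length, 0) + 1
                for v in p[1:-1]:
                    occ[v] += 1
    return occ, dict(sorted(histogram.items()))
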