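from __future__ import annotations

import networkx as nx
import pytest
from hypothesis import strategies as st

from aopnet import AOPNetwork
from aopnet.vocab import Adjacency, Category, Role


def make_network(edges, roles=None, nodes=None, adjacency=None) -> AOPNetwork:
    """Build a minimal AOPNetwork from an edge list for metric tests.

    ``roles`` maps node -> Role (default KE); ``adjacency`` maps edge ->
    Adjacency (default adjacent).  Every node is its own single-member,
    single-AOP harmonised event.
    """
    roles = roles or {}
    adjacency = adjacency or {}
    G = nx.DiGraph()
    all_nodes = set(nodes or [])
    for u, v in edges:
        all_nodes.update((u, v))
    for n in sorted(all_nodes):
        G.add_node(
            n,
            role=roles.get(n, Role.KE),
            member_ids=frozenset({n}),
            aops=frozenset({"AOP:X"}),
        )
    for u, v in edges:
        G.add_edge(
            u,
            v,
            adjacency=adjacency.get((u, v), Adjacency.ADJACENT),
            evidence=Category.NOT_SPECIFIED,
            quant=Category.NOT_SPECIFIED,
            source_aops=frozenset({"AOP:X"}),
            raw_evidence=("NA",),
            raw_quant=("NA",),
        )
    return AOPNetwork(graph=G)


@st.composite
def small_digraphs(draw, max_nodes=12, max_edges=20):
    """Random digraphs (<=12 nodes) with roles, self-loops permitted."""
    n = draw(st.integers(min_value=2, max_value=max_nodes))
    names = [f"N{i:02d}" for i in range(n)]
    edges = sorted(
        draw(
            st.sets(
                st.tuples(st.sampled_from(names), st.sampled_from(names)),
                max_size=max_edges,
            )
        )
    )
    roles = {
        name: draw(st.sampled_from([Role.MIE, Role.KE, Role.AO]))
        for name in names
    }
    return names, edges, roles


@pytest.fixture(scope="session")
def reference():
    """Reference bundle + built network, computed once per session."""
    from aopnet import cardiotox_reference_network

    bundle, network = cardiotox_reference_network()
    return bundle, network
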