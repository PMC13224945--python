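"""Interchange exports: SIF, GraphML and MINERVA-style categorical overlays.

SIF and GraphML target general graph tooling; the overlay writer produces the
tab-separated categorical overlay format used by the MINERVA platform
(comment header lines ``#VERSION=`` / ``#NAME=`` / ``#DESCRIPTION=`` followed
by ``name<TAB>value<TAB>color`` rows) with a fixed, documented colour palette
per category.  Self-loops can be dropped at export time for parity with
interactive renderers that cannot display them.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx

from .network import AOPNetwork, drop_self_loops as _drop_self_loops
from .vocab import Adjacency, Category, Role

#: Fixed category -> colour palette for overlays (hex, colour-blind safe).
PALETTE: dict[str, str] = {
    Category.HIGH.value: "#1a9850",
    Category.MODERATE.value: "#fee08b",
    Category.LOW.value: "#f46d43",
    Category.NOT_SPECIFIED.value: "#bdbdbd",
    Adjacency.ADJACENT.value: "#2166ac",
    Adjacency.NON_ADJACENT.value: "#b2182b",
    Role.MIE.value: "#66bd63",
    Role.KE.value: "#fdd835",
    Role.AO.value: "#d73027",
}


def export_network(
    network: AOPNetwork,
    path: str | Path,
    format: str,
    drop_self_loops: bool = False,
    **kwargs,
) -> Path:
    """Write ``network`` to ``path`` in one of {"sif", "graphml", "overlay"}."""
    writers = {"sif": write_sif, "graphml": write_graphml, "overlay": write_overlay}
    if format not in writers:
        raise ValueError(f"unknown export format: {format!r}")
    if drop_self_loops:
        network = _drop_self_loops(network)
    return writers[format](network, path, **kwargs)


def write_sif(network: AOPNetwork, path: str | Path) -> Path:
    """One line per edge: ``upstream<TAB>relation<TAB>downstream``."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for u, v, d in sorted(network.graph.edges(data=True)):
            fh.write(f"{u}\t{d['adjacency'].value}\t{v}\n")
    return path


def write_graphml(network: AOPNetwork, path: str | Path) -> Path:
    """GraphML with all node/edge attributes serialised as typed strings."""
    path = Path(path)
    G = nx.DiGraph()
    for t, d in network.graph.nodes(data=True):
        G.add_node(
            t,
            role=d["role"].value,
            member_ids="|".join(sorted(d["member_ids"])),
            aops="|".join(sorted(d["aops"])),
        )
    for u, v, d in network.graph.edges(data=True):
        G.add_edge(
            u,
            v,
            adjacency=d["adjacency"].value,
            evidence=d["evidence"].value,
            quant=d["quant"].value,
            source_aops="|".join(sorted(d["source_aops"])),
            raw_evidence="|".join(d["raw_evidence"]),
            raw_quant="|".join(d["raw_quant"]),
        )
    nx.write_graphml(G, path)
    return path


def read_graphml(path: str | Path) -> AOPNetwork:
    """Re-import a network written by :func:`write_graphml` (round-trip)."""
    G = nx.read_graphml(path)
    H = nx.DiGraph()
    for t, d in G.nodes(data=True):
        H.add_node(
            t,
            role=Role(d["role"]),
            member_ids=frozenset(d["member_ids"].split("|")),
            aops=frozenset(d["aops"].split("|")),
        )
    for u, v, d in G.edges(data=True):
        H.add_edge(
            u,
            v,
            adjacency=Adjacency(d["adjacency"]),
            evidence=Category(d["evidence"]),
            quant=Category(d["quant"]),
            source_aops=frozenset(d["source_aops"].split("|")),
            raw_evidence=tuple(d["raw_evidence"].split("|")) if d["raw_evidence"] else (),
            raw_quant=tuple(d["raw_quant"].split("|")) if d["raw_quant"] else (),
        )
    return AOPNetwork(graph=H)


def write_overlay(
    network: AOPNetwork,
    path: str | Path,
    attribute: str = "evidence",
    kind: str = "edge",
    name: str | None = None,
    description: str = "Categorical overlay generated by aopnet",
    version: str = "1.0",
    palette: dict[str, str] | None = None,
) -> Path:
    """Write a categorical overlay TSV for nodes or edges.

    ``kind="edge"`` overlays an edge attribute (adjacency / evidence /
    quant); ``kind="node"`` overlays the node role.  Element names follow the
    "upstream - downstream" convention for edges.
    """
    palette = palette or PALETTE
    path = Path(path)
    name = name or f"{kind} {attribute}"
    rows: list[tuple[str, str]] = []
    if kind == "edge":
        for u, v, d in sorted(network.graph.edges(data=True)):
            value = d[attribute]
            value = value.value if hasattr(value, "value") else str(value)
            rows.append((f"{u} - {v}", value))
    elif kind == "node":
        for t, d in sorted(network.graph.nodes(data=True)):
            value = d[attribute]
            value = value.value if hasattr(value, "value") else str(value)
            rows.append((t, value))
    else:
        raise ValueError(f"unknown overlay kind: {kind!r}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#VERSION={version}\n")
        fh.write(f"#NAME={name}\n")
        fh.write(f"#DESCRIPTION={description}\n")
        fh.write("name\tvalue\tcolor\n")
        for element, value in rows:
            fh.write(f"{element}\t{value}\t{palette.get(value, '#000000')}\n")
    return path
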