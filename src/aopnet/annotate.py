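"""Evidence recoding, KC mapping, measurement-method catalogue and the
summary report.

This module joins the non-topological annotation layers onto a built network:
the four-level evidence / quantitative-understanding recoding of edge labels,
the mapping of events to key characteristics (KCs) of cardiovascular
toxicants (KC1-KC12), the catalogue of "how it is measured or detected"
texts with a keyword-lexicon modality tagging (in vivo / in vitro /
in silico), and a summary report that reproduces every headline percentage
family with half-up rounding at the reported precision.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from importlib.resources import files

from .network import AOPNetwork
from .util import pct
from .vocab import Adjacency, Category, Role, has_quant, recode_evidence, recode_quant

__all__ = [
    "recode_evidence",
    "recode_quant",
    "ALL_KCS",
    "KCCoverage",
    "kc_coverage",
    "MethodCatalogueEntry",
    "load_modality_lexicon",
    "build_method_catalogue",
    "SummaryReport",
    "summary_report",
]

#: The twelve key characteristics of cardiovascular toxicants.
ALL_KCS: tuple[str, ...] = tuple(f"KC{i}" for i in range(1, 13))


@dataclass
class KCCoverage:
    """Node-level KC mapping: per-node sets, coverage counts, absent KCs."""

    node_kcs: dict[str, frozenset[str]]
    mapped_count: int
    unmapped_count: int
    per_kc_counts: dict[str, int]
    absent_kcs: tuple[str, ...]

    @property
    def mapped_pct(self) -> float | None:
        return pct(self.mapped_count, self.mapped_count + self.unmapped_count)


def kc_coverage(network: AOPNetwork, kc_map: dict[str, set[str]]) -> KCCoverage:
    """Join an event-id-keyed KC table onto the network's nodes.

    A node's KC set is the union over its member event ids; a node counts as
    mapped when that union is non-empty.
    """
    node_kcs: dict[str, frozenset[str]] = {}
    per_kc: Counter[str] = Counter()
    for title, d in network.graph.nodes(data=True):
        kcs: set[str] = set()
        for member in d["member_ids"]:
            kcs |= set(kc_map.get(member, ()))
        node_kcs[title] = frozenset(kcs)
        for kc in kcs:
            per_kc[kc] += 1
    mapped = sum(1 for k in node_kcs.values() if k)
    return KCCoverage(
        node_kcs=node_kcs,
        mapped_count=mapped,
        unmapped_count=len(node_kcs) - mapped,
        per_kc_counts={kc: per_kc.get(kc, 0) for kc in ALL_KCS},
        absent_kcs=tuple(kc for kc in ALL_KCS if per_kc.get(kc, 0) == 0),
    )


@dataclass
class MethodCatalogueEntry:
    """Detection-method record for one node of the network."""

    node: str
    member_ids: tuple[str, ...]
    measurement_text: str
    modality_tags: frozenset[str]
    has_method: bool


def load_modality_lexicon() -> dict[str, str]:
    """Keyword -> modality lexicon shipped as editable package data."""
    lexicon: dict[str, str] = {}
    text = (files("aopnet") / "data" / "modality_lexicon.tsv").read_text(encoding="utf-8")
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        keyword, modality = line.split("\t")[:2]
        lexicon[keyword.strip().lower()] = modality.strip()
    return lexicon


def tag_modalities(text: str, lexicon: dict[str, str] | None = None) -> frozenset[str]:
    """Assign in vivo / in vitro / in silico tags by substring lexicon match."""
    lexicon = lexicon if lexicon is not None else load_modality_lexicon()
    low = text.lower()
    return frozenset(m for k, m in lexicon.items() if k in low)


def build_method_catalogue(
    network: AOPNetwork,
    sections: dict[str, str],
    lexicon: dict[str, str] | None = None,
) -> list[MethodCatalogueEntry]:
    """Build the per-node detection-method catalogue.

    Node-level text concatenates the member events' sections (member-id
    provenance preserved in brackets); ``has_method`` is true exactly when
    the concatenated text is non-empty after whitespace normalisation, which
    makes the coverage count independent of member ordering.
    """
    lexicon = lexicon if lexicon is not None else load_modality_lexicon()
    entries = []
    for title in sorted(network.graph.nodes()):
        members = tuple(sorted(network.graph.nodes[title]["member_ids"]))
        parts = [
            f"[{m}] {sections[m].strip()}"
            for m in members
            if sections.get(m, "").strip()
        ]
        text = "\n".join(parts)
        entries.append(
            MethodCatalogueEntry(
                node=title,
                member_ids=members,
                measurement_text=text,
                modality_tags=tag_modalities(text, lexicon),
                has_method=bool(text.strip()),
            )
        )
    return entries


@dataclass
class SummaryReport:
    """Headline counts and percentages of one network, ready to print.

    Percentages are half-up rounded to 2 decimals, except the share of
    relationships with any quantitative understanding, reported to 1 decimal
    as is conventional for that statistic.
    """

    n_nodes: int
    n_edges: int
    role_counts: dict[str, int]
    adjacency: dict[str, dict] = field(default_factory=dict)
    sharing: dict[int, dict] = field(default_factory=dict)
    evidence: dict[str, dict] = field(default_factory=dict)
    quant: dict[str, dict] = field(default_factory=dict)
    quant_any: dict = field(default_factory=dict)
    self_loop_count: int = 0
    mean_total_degree: float | None = None
    flow_classes: dict[str, int] = field(default_factory=dict)
    kc: dict = field(default_factory=dict)
    methods: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "role_counts": self.role_counts,
            "adjacency": self.adjacency,
            "sharing": {str(k): v for k, v in self.sharing.items()},
            "evidence": self.evidence,
            "quant": self.quant,
            "quant_any": self.quant_any,
            "self_loop_count": self.self_loop_count,
            "mean_total_degree": self.mean_total_degree,
            "flow_classes": self.flow_classes,
            "kc": self.kc,
            "methods": self.methods,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_markdown(self) -> str:
        lines = [
            "# AOP network summary",
            "",
            f"- Nodes: {self.n_nodes} "
            f"({', '.join(f'{v} {k}' for k, v in self.role_counts.items())})",
            f"- Edges: {self.n_edges} ({self.self_loop_count} self-loops)",
            f"- Mean total degree: {self.mean_total_degree}",
            "",
            "## Relationship adjacency",
        ]
        for k, v in self.adjacency.items():
            lines.append(f"- {k}: {v['count']} ({v['pct']}%)")
        lines += ["", "## Evidence levels"]
        for k, v in self.evidence.items():
            lines.append(f"- {k}: {v['count']} ({v['pct']}%)")
        lines += [
            "",
            "## Quantitative understanding",
            f"- Any quantitative understanding: {self.quant_any.get('count')} "
            f"({self.quant_any.get('pct')}%)",
            "",
            "## Sharing across AOPs",
        ]
        for k, v in self.sharing.items():
            lines.append(f"- in {k} AOP(s): {v['count']} ({v['pct']}%)")
        if self.kc:
            lines += [
                "",
                "## Key characteristics",
                f"- Mapped to >=1 KC: {self.kc['mapped']} ({self.kc['pct']}%)",
                f"- Absent KCs: {', '.join(self.kc['absent']) or 'none'}",
            ]
        if self.methods:
            lines += [
                "",
                "## Detection methods",
                f"- With described methods: {self.methods['count']} "
                f"({self.methods['pct']}%)",
            ]
        return "\n".join(lines) + "\n"


def summary_report(
    network: AOPNetwork,
    metrics=None,
    kc: KCCoverage | None = None,
    catalogue: list[MethodCatalogueEntry] | None = None,
) -> SummaryReport:
    """Assemble the summary report from a network and optional annotations."""
    from .network import composition_summary

    comp = composition_summary(network)
    edges = network.edges()
    n_edges = len(edges)
    evidence_counts = Counter(e.evidence for e in edges)
    quant_counts = Counter(e.quant for e in edges)
    n_quant = sum(1 for e in edges if has_quant(e.quant))

    report = SummaryReport(
        n_nodes=comp.n_nodes,
        n_edges=n_edges,
        role_counts={r.value: comp.role_counts[r] for r in Role},
        adjacency={
            a.value: {"count": comp.adjacency_counts[a], "pct": comp.adjacency_pcts[a]}
            for a in Adjacency
        },
        sharing={
            k: {"count": comp.sharing_histogram[k], "pct": comp.sharing_pcts[k]}
            for k in comp.sharing_histogram
        },
        evidence={
            c.value: {"count": evidence_counts.get(c, 0), "pct": pct(evidence_counts.get(c, 0), n_edges)}
            for c in Category
        },
        quant={
            c.value: {"count": quant_counts.get(c, 0), "pct": pct(quant_counts.get(c, 0), n_edges)}
            for c in Category
        },
        quant_any={"count": n_quant, "pct": pct(n_quant, n_edges, ndigits=1)},
        self_loop_count=comp.self_loop_count,
    )
    if metrics is not None:
        report.mean_total_degree = metrics.mean_total_degree
        report.flow_classes = dict(Counter(metrics.frame["flow_class"]))
    if kc is not None:
        report.kc = {
            "mapped": kc.mapped_count,
            "unmapped": kc.unmapped_count,
            "pct": kc.mapped_pct,
            "absent": list(kc.absent_kcs),
            "per_kc": kc.per_kc_counts,
        }
    if catalogue is not None:
        n_with = sum(1 for e in catalogue if e.has_method)
        report.methods = {"count": n_with, "total": len(catalogue), "pct": pct(n_with, len(catalogue))}
    return report
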