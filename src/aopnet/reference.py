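"""Synthetic reference fixture matching the published cardiotoxicity
network's aggregate composition.

The published AOP-Wiki-derived cardiotoxicity network is not redistributable
row by row, but its aggregate composition is: 13 AOPs pooling 71 raw key
event ids that harmonise to 64 nodes (11 MIEs, 48 KEs, 5 AOs) joined by 94
directed relationships (81 adjacent, 13 non-adjacent, including two
self-loops on oxidative stress and mitochondrial dysfunction), with a
sharing profile of 47/10/5/1/1 nodes appearing in 1/2/3/4/8 AOPs, evidence
levels 51/15/4/24 (High/Moderate/Low/Not Specified), 35 relationships with
any quantitative understanding, 28 nodes with described detection methods
and 50 nodes mapped to key characteristics of cardiovascular toxicants
(KC7 absent).

This module constructs a *synthetic stand-in* with exactly that composition:
the aggregates are pinned, the topology within them is one deliberate,
deterministic choice (backbone chains per AOP plus forward skip links).
Event ids live in a synthetic namespace (KE9xxx / AOP:Txx) so they can never
be mistaken for real AOP-Wiki identifiers.
"""

from __future__ import annotations

import random

from .harmonise import MergeMap, apply_merge_map, remap_kers
from .network import AOPNetwork, build_network
from .records import KERRecord, KeyEventRecord
from .synthetic import FixtureBundle
from .vocab import Adjacency, Role

# -- node catalogue --------------------------------------------------------
# key -> (canonical title, role, member titles)
# Multi-member nodes model the expert merge map (71 raw ids -> 64 nodes).
_NODES: dict[str, tuple[str, Role, tuple[str, ...]]] = {
    # molecular initiating events
    "M1": ("Inhibition, acetylcholinesterase", Role.MIE, ()),
    "M2": ("Activation, AhR", Role.MIE, ()),
    "M3": ("Inhibition, sodium channel", Role.MIE, ()),
    "M4": ("hERG channel blockade", Role.MIE, ()),
    "M5": ("Inhibition, mitochondrial electron transport chain complexes", Role.MIE, ()),
    "M6": ("Blockade, L-type calcium channels", Role.MIE, ()),
    "M7": ("Inhibition, organic anion transporter 1", Role.MIE, ()),
    "M8": ("Inhibition, cyclooxygenase 1 activity", Role.MIE, ()),
    "M9": ("Impaired, ion channels", Role.MIE, ()),
    "M10": ("Activation, nicotinic acetylcholine receptor", Role.MIE, ()),
    "M11": ("Increase, reactive oxygen species production", Role.MIE, ()),
    # adverse outcomes
    "AO_mort": (
        "Increased mortality", Role.AO,
        ("Increased mortality", "Increase, mortality", "Mortality increased"),
    ),
    "AO_hf": ("Heart failure", Role.AO, ("Heart failure", "Sudden cardiac death")),
    "AO_els": ("Increase, early life stage mortality", Role.AO, ()),
    "AO_lv": ("Decrease, left ventricular function", Role.AO, ()),
    "AO_pgr": ("Decrease, population growth rate", Role.AO, ()),
    # cross-cutting key events
    "OX": ("Oxidative stress", Role.KE, ("Oxidative stress", "Increase, oxidative stress")),
    "MITO": ("Mitochondrial dysfunction", Role.KE, ("Mitochondrial dysfunction", "Dysfunction, mitochondria")),
    "ECD": ("Endothelial cell dysfunction", Role.KE, ("Endothelial cell dysfunction", "Endothelial dysfunction")),
    "K3a": (
        "Altered, cardiovascular development/function", Role.KE,
        ("Altered, cardiovascular development/function", "Altered, cardiovascular development"),
    ),
    "K3b": ("Decrease, cardiac contractility", Role.KE, ()),
    "K3c": ("Increased, cardiac arrhythmia", Role.KE, ()),
    "K3d": ("Cell injury/death", Role.KE, ()),
    "K3e": ("Increased, blood uric acid concentration", Role.KE, ()),
    "K2a": ("Increased, secretion of catecholamine", Role.KE, ()),
    "K2b": ("Dimerization, AHR/ARNT", Role.KE, ()),
    "K2c": ("Cardiovascular dysregulation", Role.KE, ()),
    "K2d": ("Decrease, calcium currents", Role.KE, ()),
    "K2e": ("Ventricular remodeling", Role.KE, ()),
    "K2f": ("Increased, vascular smooth muscle cell activation", Role.KE, ()),
    # single-AOP key events
    "s1": ("Increase, intracellular calcium overload", Role.KE, ()),
    "s2": ("Impaired, excitation-contraction coupling", Role.KE, ()),
    "s3": ("Decrease, cardiac ejection fraction", Role.KE, ()),
    "s4": ("Respiratory distress/arrest", Role.KE, ()),
    "s5": ("Increase, COX-2 expression", Role.KE, ()),
    "s6": ("Reduction, VEGF availability", Role.KE, ()),
    "s7": ("Decrease, sox9 expression", Role.KE, ()),
    "s8": ("Decrease, ATP production", Role.KE, ()),
    "s9": ("Cardiomyocyte apoptosis", Role.KE, ()),
    "s10": ("Myocardial fibrosis", Role.KE, ()),
    "s11": ("Prolongation, QT interval", Role.KE, ()),
    "s12": ("Torsades de Pointes", Role.KE, ()),
    "s13": ("Decreased, cardiac conduction velocity", Role.KE, ()),
    "s14": ("Accumulation, acetylcholine in synaptic cleft", Role.KE, ()),
    "s15": ("Overstimulation, muscarinic receptors", Role.KE, ()),
    "s16": ("Bradycardia", Role.KE, ()),
    "s17": ("Increase, systemic inflammation", Role.KE, ()),
    "s18": ("Vascular remodeling", Role.KE, ()),
    "s19": ("Atherosclerosis", Role.KE, ()),
    "s20": ("Increased, vascular permeability", Role.KE, ()),
    "s21": ("Decrease, sodium currents", Role.KE, ()),
    "s22": ("Decreased, action potential upstroke velocity", Role.KE, ()),
    "s23": ("Conduction block", Role.KE, ()),
    "s24": ("Occurrence, renal proximal tubular necrosis", Role.KE, ()),
    "s25": ("Occurrence, renal ischemia", Role.KE, ()),
    "s26": ("Decreased, renal clearance of uremic toxins", Role.KE, ()),
    "s27": ("Increase, serum indoxyl sulphate", Role.KE, ()),
    "s28": ("Cardiac hypertrophy", Role.KE, ()),
    "s29": ("Hypoxia", Role.KE, ()),
    "s30": ("Increase, cardiac remodelling", Role.KE, ()),
    "s31": ("Altered, cardiac looping morphogenesis", Role.KE, ()),
    "s32": ("Increase, slincR expression", Role.KE, ()),
    "s33": ("Occurrence, tophi (urate) deposition", Role.KE, ()),
    "s34": ("Increase, blood pressure", Role.KE, ()),
}

# Per-AOP backbone chains (node keys, cause -> effect).  The orders follow a
# single global ranking, so the pooled network is acyclic apart from the two
# deliberate self-loops.  AOP:T13 is the analogue of a pathway lacking formal
# MIE/AO annotations: every record carries the KE role.
_CHAINS: dict[str, tuple[str, ...]] = {
    "AOP:T01": ("M1", "K2a", "OX", "s1", "ECD", "K3a", "s2", "s3", "s4", "AO_els", "AO_mort"),
    "AOP:T02": ("M2", "s5", "OX", "ECD", "s6", "K3a", "K3b", "K2b", "s7", "AO_mort"),
    "AOP:T03": ("M3", "OX", "MITO", "s8", "K3a", "s9", "K3b", "K2c", "s10", "AO_mort"),
    "AOP:T04": ("M4", "OX", "MITO", "s11", "K3b", "s12", "s13", "K2d", "AO_mort"),
    "AOP:T05": ("M5", "K2a", "s14", "s15", "K3c", "s16", "AO_mort"),
    "AOP:T06": ("M5", "K3c", "K2b", "K3d", "s17", "s18", "AO_mort"),
    "AOP:T07": ("M6", "K2c", "K3c", "s19", "s20", "K3d", "AO_mort"),
    "AOP:T08": ("M7", "K2d", "s21", "s22", "s23", "K3d", "AO_mort"),
    "AOP:T09": ("M8", "K3e", "s24", "K2e", "s25", "AO_hf"),
    "AOP:T10": ("M9", "K3e", "s26", "s27", "s28", "AO_hf"),
    "AOP:T11": ("M10", "K2e", "s29", "s30", "s31", "AO_lv"),
    "AOP:T12": ("M11", "K2f", "s32", "s33", "AO_pgr"),
    "AOP:T13": ("K3e", "K2f", "s34"),
}

#: AOP analogue curated without formal MIE/AO annotations.
_NO_MIE_AO = ("AOP:T13",)

# Long-range (non-adjacent) relationships: forward skips within one chain.
_SKIPS: tuple[tuple[str, str, str], ...] = (
    ("M1", "OX", "AOP:T01"),
    ("OX", "AO_mort", "AOP:T01"),
    ("M2", "OX", "AOP:T02"),
    ("MITO", "AO_mort", "AOP:T03"),
    ("M4", "K3b", "AOP:T04"),
    ("M5", "AO_mort", "AOP:T05"),
    ("K3c", "K3d", "AOP:T06"),
    ("M6", "K3c", "AOP:T07"),
    ("M7", "K3d", "AOP:T08"),
    ("M8", "AO_hf", "AOP:T09"),
    ("K3e", "AO_hf", "AOP:T10"),
    ("M10", "AO_lv", "AOP:T11"),
    ("M11", "AO_pgr", "AOP:T12"),
)

# Which member id a multi-member node contributes to each AOP.  Index into
# the node's member tuple; single-member nodes always use index 0.
_MEMBER_BY_AOP: dict[str, dict[str, int]] = {
    "AO_mort": {"AOP:T01": 0, "AOP:T02": 0, "AOP:T03": 0,
                "AOP:T04": 1, "AOP:T05": 1, "AOP:T06": 1,
                "AOP:T07": 2, "AOP:T08": 2},
    "OX": {"AOP:T01": 0, "AOP:T02": 0, "AOP:T03": 1, "AOP:T04": 1},
    "MITO": {"AOP:T03": 0, "AOP:T04": 0},
    "ECD": {"AOP:T01": 0, "AOP:T02": 1},
    "AO_hf": {"AOP:T09": 0, "AOP:T10": 1},
    "K3a": {"AOP:T01": 0, "AOP:T02": 1, "AOP:T03": 1},
}

# Nodes with a described detection method (28 of 64).
_WITH_METHODS: tuple[str, ...] = (
    "M1", "M2", "M3", "M4", "M5", "M6", "M7", "M8", "M9", "M10", "M11",
    "OX", "MITO", "ECD", "K3b", "K3c", "K3e", "K2b", "K2d",
    "s1", "s3", "s11", "s12", "s24", "s29",
    "AO_mort", "AO_hf", "AO_lv",
)

_METHOD_TEXTS: tuple[str, ...] = (
    "Quantified by whole-cell patch clamp recording in cardiomyocyte cell culture.",
    "Assessed in vivo by echocardiography and electrocardiogram telemetry in rodent models.",
    "Estimated in silico with a computational model of the human ventricular action potential.",
    "Measured with a biochemical assay (fluorescent probe for reactive oxygen species) and ELISA on serum.",
)

# Nodes without any KC mapping (14 of 64: four adverse outcomes plus ten
# peripheral key events).  KC7 (dyslipidaemia) is deliberately unused.
_WITHOUT_KC: tuple[str, ...] = (
    "AO_hf", "AO_els", "AO_lv", "AO_pgr",
    "s25", "s26", "s27", "s28", "s29", "s30", "s31", "s32", "s33", "s34",
)
_KC_SPECIAL: dict[str, tuple[str, ...]] = {
    "OX": ("KC10",),
    "MITO": ("KC8",),
    "M4": ("KC1",),
    "K2d": ("KC1",),
    "s12": ("KC1",),
}
_KC_CYCLE: tuple[str, ...] = (
    "KC1", "KC2", "KC3", "KC4", "KC5", "KC6", "KC8", "KC9", "KC10", "KC11", "KC12",
)


def _member_ids() -> dict[str, tuple[str, ...]]:
    """Mint the 71 raw ids (KE9xxx) in a fixed, documented order."""
    ids: dict[str, tuple[str, ...]] = {}
    counter = 9001
    for key, (title, _role, members) in _NODES.items():
        n = max(1, len(members))
        ids[key] = tuple(f"KE{counter + i}" for i in range(n))
        counter += n
    return ids


def _member_titles(key: str) -> tuple[str, ...]:
    title, _role, members = _NODES[key]
    return members if members else (title,)


def _member_for(key: str, aop_id: str, ids: dict[str, tuple[str, ...]]) -> str:
    idx = _MEMBER_BY_AOP.get(key, {}).get(aop_id, 0)
    return ids[key][idx]


def cardiotox_reference_fixture() -> FixtureBundle:
    """Build the deterministic reference bundle (constants embedded)."""
    ids = _member_ids()

    ke_dataset: list[KeyEventRecord] = []
    for aop_id, chain in _CHAINS.items():
        for key in chain:
            role = Role.KE if aop_id in _NO_MIE_AO else _NODES[key][1]
            member = _member_for(key, aop_id, ids)
            title = _member_titles(key)[ids[key].index(member)]
            ke_dataset.append(
                KeyEventRecord(aop_id=aop_id, event_id=member, title=title, role=role)
            )
    # Second members of the self-loop nodes also appear in the wiki-style
    # export of the AOP carrying the self-relationship.
    for key, aop_id in (("OX", "AOP:T01"), ("MITO", "AOP:T03")):
        ke_dataset.append(
            KeyEventRecord(
                aop_id=aop_id,
                event_id=ids[key][1],
                title=_member_titles(key)[1],
                role=Role.KE,
            )
        )

    # Edge slots in construction order: backbone pairs (duplicated pairs
    # asserted once, by their first AOP), the two self-relationships, then
    # the non-adjacent skips.
    edge_slots: list[tuple[str, str, str, Adjacency]] = []
    seen: set[tuple[str, str]] = set()
    for aop_id, chain in _CHAINS.items():
        for u, v in zip(chain, chain[1:]):
            if (u, v) in seen:
                continue
            seen.add((u, v))
            edge_slots.append((u, v, aop_id, Adjacency.ADJACENT))
    edge_slots.append(("OX", "OX", "AOP:T01", Adjacency.ADJACENT))
    edge_slots.append(("MITO", "MITO", "AOP:T03", Adjacency.ADJACENT))
    for u, v, aop_id in _SKIPS:
        edge_slots.append((u, v, aop_id, Adjacency.NON_ADJACENT))

    # Raw evidence labels: 51 High (26 "High" + 25 "Strong"), 15 Moderate,
    # 4 Low, 24 Not Specified (12 "Not Specified" + 12 "NA"); quantitative
    # understanding positive for 35 relationships.  The assignment order is
    # a fixed deterministic shuffle - only the totals are meaningful.
    evidence = (
        ["High"] * 26 + ["Strong"] * 25 + ["Moderate"] * 15 + ["Low"] * 4
        + ["Not Specified"] * 12 + ["NA"] * 12
    )
    quant = ["High"] * 12 + ["Moderate"] * 12 + ["Low"] * 11 + ["NA"] * 59
    random.Random(94).shuffle(evidence)
    random.Random(64).shuffle(quant)

    ker_table: list[KERRecord] = []
    for (u, v, aop_id, adjacency), ev, qu in zip(edge_slots, evidence, quant):
        if u == v:
            up, down = ids[u][0], ids[u][1]
        else:
            up = _member_for(u, aop_id, ids)
            down = _member_for(v, aop_id, ids)
        ker_table.append(
            KERRecord(
                upstream_event=up, downstream_event=down, adjacency=adjacency,
                evidence_raw=ev, quant_raw=qu, aop_id=aop_id,
            )
        )

    sections: dict[str, str] = {}
    for i, key in enumerate(_NODES):
        text = _METHOD_TEXTS[i % len(_METHOD_TEXTS)] if key in _WITH_METHODS else ""
        sections[ids[key][0]] = text
        for extra in ids[key][1:]:
            sections[extra] = ""

    kc_table: dict[str, frozenset[str]] = {}
    cycle = 0
    for key in _NODES:
        if key in _WITHOUT_KC:
            continue
        if key in _KC_SPECIAL:
            kcs = frozenset(_KC_SPECIAL[key])
        else:
            kcs = frozenset(
                _KC_CYCLE[(cycle + j) % len(_KC_CYCLE)] for j in range(1 + cycle % 2)
            )
            cycle += 1
        kc_table[ids[key][0]] = kcs

    manifest = {
        "generator": "aopnet.reference.cardiotox_reference_fixture",
        "synthetic": True,
        "n_aops": len(_CHAINS),
        "n_raw_event_ids": sum(max(1, len(m)) for _, _, m in _NODES.values()),
        "aops_without_mie_ao": list(_NO_MIE_AO),
    }
    bundle = FixtureBundle(
        ke_dataset=ke_dataset,
        ker_table=ker_table,
        measurement_sections=sections,
        kc_table=kc_table,
        manifest=manifest,
    )
    bundle.validate()
    return bundle


def cardiotox_reference_merge_map() -> MergeMap:
    """The expert merge map for the reference fixture (6 merged nodes)."""
    ids = _member_ids()
    entries = [
        (_NODES[key][0], ids[key])
        for key in _NODES
        if len(_NODES[key][2]) > 1
    ]
    return MergeMap(entries)


def cardiotox_reference_network() -> tuple[FixtureBundle, AOPNetwork]:
    """Run the full pipeline on the reference fixture: harmonise and build."""
    bundle = cardiotox_reference_fixture()
    harmonised = apply_merge_map(bundle.ke_dataset, cardiotox_reference_merge_map())
    remapped = remap_kers(bundle.ker_table, harmonised)
    network = build_network(
        harmonised, remapped, provenance=dict(bundle.manifest)
    )
    return bundle, network
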