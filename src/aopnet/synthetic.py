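"""Synthetic AOP-Wiki-like fixture generation.

The generator emulates the inputs of an AOP-network study without any
download: a multi-AOP key-events dataset with MIE/KE/AO roles, per-AOP KER
tables with adjacency and raw evidence labels, XML-style measurement
sections, and a KC mapping table.  Each AOP is a backbone chain
MIE -> KE ... -> AO (mirroring how AOPs are curated as linear constructs),
with middle events optionally drawn from a shared pool so that networks with
cross-cutting hubs arise; non-adjacent relationships are added as forward
skip links within chains.  Shared middles are ordered by creation index
inside every chain, which keeps the pooled network acyclic.

Evidence labels are sampled from the *raw* vocabulary (High, Strong,
Moderate, Low, Not Specified, NA) so that downstream recoding is genuinely
exercised.  Fixed seeds give byte-identical bundles.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from . import aopwiki_io
from .records import KERRecord, KeyEventRecord
from .vocab import Adjacency, Category, Role

_RAW_LABELS: dict[Category, tuple[str, ...]] = {
    Category.HIGH: ("High", "Strong"),
    Category.MODERATE: ("Moderate",),
    Category.LOW: ("Low",),
    Category.NOT_SPECIFIED: ("Not Specified", "NA"),
}

_TEXT_TEMPLATES = (
    "Measured by whole-cell patch clamp recording in cardiomyocyte cell culture.",
    "Assessed by echocardiography and electrocardiogram telemetry in rodent studies.",
    "Estimated in silico with a computational model of the cardiac action potential.",
    "Quantified with a biochemical assay (ELISA) on serum samples.",
)


class FixtureSpecError(ValueError):
    """Invalid fixture specification; the message names the offending field."""


@dataclass(frozen=True)
class FixtureSpec:
    """Statistical recipe for one synthetic fixture bundle."""

    n_aops: int = 8
    events_per_aop: tuple[int, int] = (4, 8)
    ke_share_prob: float = 0.25
    adjacency_fraction: float = 0.85
    evidence_counts: dict = field(
        default_factory=lambda: {
            "High": 0.5, "Moderate": 0.2, "Low": 0.05, "Not Specified": 0.25,
        }
    )
    quant_counts: dict = field(
        default_factory=lambda: {
            "High": 0.15, "Moderate": 0.15, "Low": 0.1, "Not Specified": 0.6,
        }
    )
    methods_coverage: float = 0.45
    kc_coverage: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if self.n_aops <= 0:
            raise FixtureSpecError("n_aops must be a positive integer")
        lo, hi = self.events_per_aop
        if lo < 2 or hi < lo:
            raise FixtureSpecError(
                "events_per_aop must be a (lo, hi) range with lo >= 2"
            )
        for name in ("ke_share_prob", "adjacency_fraction", "methods_coverage", "kc_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise FixtureSpecError(f"{name} must be in [0, 1]")
        for name in ("evidence_counts", "quant_counts"):
            table = getattr(self, name)
            if not table:
                raise FixtureSpecError(f"{name} must be non-empty")
            for cat, v in table.items():
                if Category(cat) and v < 0:
                    raise FixtureSpecError(f"{name}[{cat!r}] must be non-negative")

    @property
    def counts_are_exact(self) -> bool:
        return all(isinstance(v, int) for v in self.evidence_counts.values())


@dataclass
class FixtureBundle:
    """A complete synthetic input set plus its generation manifest."""

    ke_dataset: list[KeyEventRecord]
    ker_table: list[KERRecord]
    measurement_sections: dict[str, str]
    kc_table: dict[str, frozenset[str]]
    manifest: dict

    def __post_init__(self) -> None:
        self.kc_table = {k: frozenset(v) for k, v in self.kc_table.items()}

    def event_ids(self) -> set[str]:
        return {r.event_id for r in self.ke_dataset}

    def aop_ids(self) -> set[str]:
        return {r.aop_id for r in self.ke_dataset}

    def validate(self) -> None:
        """Check referential integrity and per-AOP role coverage."""
        known = self.event_ids()
        for ker in self.ker_table:
            for endpoint in (ker.upstream_event, ker.downstream_event):
                if endpoint not in known:
                    raise ValueError(f"KER references unknown event id {endpoint!r}")
        exempt = set(self.manifest.get("aops_without_mie_ao", ()))
        roles: dict[str, set[Role]] = {}
        for rec in self.ke_dataset:
            roles.setdefault(rec.aop_id, set()).add(rec.role)
        for aop_id, rs in roles.items():
            if aop_id in exempt:
                continue
            if Role.MIE not in rs or Role.AO not in rs:
                raise ValueError(
                    f"AOP {aop_id} lacks an MIE or AO record and is not declared exempt"
                )


def _draw_categories(rng: random.Random, table: dict, n: int, what: str) -> list[Category]:
    cats = [Category(c) for c in table]
    if all(isinstance(v, int) for v in table.values()):
        total = sum(table.values())
        if total != n:
            raise FixtureSpecError(
                f"{what} counts sum to {total} but {n} relationships were generated; "
                "give probabilities or matching counts"
            )
        pool = [c for c in cats for _ in range(table[c.value])]
        rng.shuffle(pool)
        return pool
    weights = [float(table[c.value]) for c in cats]
    return rng.choices(cats, weights=weights, k=n)


def generate_fixture(spec: FixtureSpec) -> FixtureBundle:
    """Generate one bundle; deterministic for a fixed seed."""
    spec.validate()
    rng = random.Random(spec.seed)

    next_id = [1]

    def mint(prefix: str = "KE") -> str:
        i = next_id[0]
        next_id[0] += 1
        return f"{prefix}{i:04d}"

    mint_order: dict[str, int] = {}
    titles: dict[str, str] = {}
    shared_pool: list[str] = []

    ke_dataset: list[KeyEventRecord] = []
    ker_table: list[KERRecord] = []
    chains: list[tuple[str, list[str]]] = []

    for a in range(1, spec.n_aops + 1):
        aop_id = f"AOP:S{a:03d}"
        n_events = rng.randint(*spec.events_per_aop)
        n_middle = n_events - 2

        mie = mint()
        mint_order[mie] = len(mint_order)
        titles[mie] = f"Receptor perturbation {mie}"

        middles: list[str] = []
        for _ in range(n_middle):
            pick_shared = (
                shared_pool
                and rng.random() < spec.ke_share_prob
                and any(e not in middles for e in shared_pool)
            )
            if pick_shared:
                candidates = [e for e in shared_pool if e not in middles]
                event = rng.choice(candidates)
            else:
                event = mint()
                mint_order[event] = len(mint_order)
                titles[event] = f"Intermediate key event {event}"
                shared_pool.append(event)
            middles.append(event)
        middles.sort(key=mint_order.__getitem__)

        ao = mint()
        mint_order[ao] = len(mint_order)
        titles[ao] = f"Adverse outcome {ao}"

        chain = [mie, *middles, ao]
        chains.append((aop_id, chain))
        for event in chain:
            role = Role.MIE if event == mie else Role.AO if event == ao else Role.KE
            ke_dataset.append(
                KeyEventRecord(aop_id=aop_id, event_id=event, title=titles[event], role=role)
            )

    # Adjacent backbone relationships, then non-adjacent forward skip links
    # so the adjacent fraction approximates the configured value.
    edge_slots: list[tuple[str, str, str, Adjacency]] = []
    seen_pairs: set[tuple[str, str]] = set()
    for aop_id, chain in chains:
        for u, v in zip(chain, chain[1:]):
            edge_slots.append((u, v, aop_id, Adjacency.ADJACENT))
            seen_pairs.add((u, v))
    n_adjacent = len(edge_slots)
    f = spec.adjacency_fraction
    n_skip = 0 if f >= 1.0 else round(n_adjacent * (1.0 - f) / f) if f > 0 else 0
    attempts = 0
    while n_skip > 0 and attempts < 50 * (n_skip + 1):
        attempts += 1
        aop_id, chain = chains[rng.randrange(len(chains))]
        if len(chain) < 3:
            continue
        i = rng.randrange(len(chain) - 2)
        j = rng.randrange(i + 2, len(chain))
        pair = (chain[i], chain[j])
        if pair in seen_pairs:
            continue
        seen_pairs.add(pair)
        edge_slots.append((*pair, aop_id, Adjacency.NON_ADJACENT))
        n_skip -= 1

    evidence = _draw_categories(rng, spec.evidence_counts, len(edge_slots), "evidence_counts")
    quant = _draw_categories(rng, spec.quant_counts, len(edge_slots), "quant_counts")
    for (u, v, aop_id, adjacency), ev, qu in zip(edge_slots, evidence, quant):
        raw_ev = rng.choice(_RAW_LABELS[ev])
        raw_qu = rng.choice(_RAW_LABELS[qu])
        ker_table.append(
            KERRecord(
                upstream_event=u, downstream_event=v, adjacency=adjacency,
                evidence_raw=raw_ev, quant_raw=raw_qu, aop_id=aop_id,
            )
        )

    unique_events = sorted(mint_order, key=mint_order.__getitem__)
    n_methods = round(spec.methods_coverage * len(unique_events))
    with_methods = rng.sample(unique_events, n_methods)
    sections = {
        e: (_TEXT_TEMPLATES[i % len(_TEXT_TEMPLATES)] if e in set(with_methods) else "")
        for i, e in enumerate(unique_events)
    }

    n_kc = round(spec.kc_coverage * len(unique_events))
    with_kc = rng.sample(unique_events, n_kc)
    kc_ids = [f"KC{i}" for i in range(1, 13)]
    kc_table = {
        e: frozenset(rng.sample(kc_ids, rng.randint(1, 3))) for e in sorted(with_kc)
    }

    manifest = {
        "generator": "aopnet.synthetic.generate_fixture",
        "seed": spec.seed,
        "n_aops": spec.n_aops,
        "events_per_aop": list(spec.events_per_aop),
        "ke_share_prob": spec.ke_share_prob,
        "adjacency_fraction": spec.adjacency_fraction,
        "evidence_counts": dict(spec.evidence_counts),
        "quant_counts": dict(spec.quant_counts),
        "methods_coverage": spec.methods_coverage,
        "kc_coverage": spec.kc_coverage,
        "n_kers": len(ker_table),
        "n_unique_events": len(unique_events),
        "aops_without_mie_ao": [],
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


# -- on-disk round trip ----------------------------------------------------

_FILES = {
    "ke": "ke_dataset.tsv",
    "ker": "ker_table.tsv",
    "xml": "measurements.xml",
    "kc": "kc_table.tsv",
    "manifest": "manifest.json",
}


def write_fixture(bundle: FixtureBundle, directory: str | Path, dialect: str = "default") -> dict[str, Path]:
    """Write a bundle as TSV/XML/JSON files in the given dialect."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {k: directory / v for k, v in _FILES.items()}
    aopwiki_io.write_ke_dataset(bundle.ke_dataset, paths["ke"], dialect=dialect)
    aopwiki_io.write_ker_table(bundle.ker_table, paths["ker"], dialect=dialect)
    aopwiki_io.write_measurement_xml(bundle.measurement_sections, paths["xml"])
    aopwiki_io.write_kc_table({k: set(v) for k, v in bundle.kc_table.items()}, paths["kc"], dialect=dialect)
    with open(paths["manifest"], "w", encoding="utf-8") as fh:
        json.dump(bundle.manifest, fh, indent=2, sort_keys=True)
    return paths


def read_fixture(directory: str | Path, dialect: str = "default") -> FixtureBundle:
    """Read a bundle previously written by :func:`write_fixture` (lossless)."""
    directory = Path(directory)
    ke, ke_issues = aopwiki_io.read_ke_dataset(directory / _FILES["ke"], dialect=dialect)
    ker, ker_issues = aopwiki_io.read_ker_table(directory / _FILES["ker"], dialect=dialect)
    if ke_issues or ker_issues:
        raise ValueError(f"fixture failed validation on re-read: {ke_issues + ker_issues}")
    sections = aopwiki_io.read_measurement_map(directory / _FILES["xml"])
    kc = aopwiki_io.read_kc_table(directory / _FILES["kc"], dialect=dialect)
    with open(directory / _FILES["manifest"], encoding="utf-8") as fh:
        manifest = json.load(fh)
    return FixtureBundle(
        ke_dataset=ke,
        ker_table=ker,
        measurement_sections=sections,
        kc_table={k: frozenset(v) for k, v in kc.items()},
        manifest=manifest,
    )
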