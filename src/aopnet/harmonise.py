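"""Key-event harmonisation: title standardisation, merge maps, role resolution.

AOP-Wiki records the same biological event under several ids and title
spellings ("Oxidative stress" vs "Increase, oxidative stress").  Harmonisation
collapses such duplicates into canonical nodes via an expert-curated merge
map, standardises titles (leading capital, NA entries dropped), resolves each
node's role with the precedence AO > MIE > KE, and takes the union of AOP
memberships over members.  No automatic semantic matching is attempted: the
merge map is data.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

from .records import HarmonisedNode, KERRecord, KeyEventRecord, normalise_event_id
from .vocab import Role

#: Titles starting with these tokens keep their casing (gene-symbol initials).
DEFAULT_PRESERVE: frozenset[str] = frozenset({"hERG", "mRNA", "miRNA", "qPCR"})


def standardise_title(raw: str, preserve: frozenset[str] = DEFAULT_PRESERVE) -> str | None:
    """Standardise one title; return ``None`` as the drop-signal for "NA".

    Leading/trailing whitespace is trimmed, the first alphabetic character is
    upper-cased and internal case is preserved.  Titles whose first token is
    in ``preserve`` (gene symbols such as "hERG") are kept verbatim.
    """
    t = str(raw).strip()
    if t == "NA":
        return None
    first_token = t.split(" ", 1)[0].rstrip(",;:")
    if first_token in preserve:
        return t
    chars = list(t)
    for i, c in enumerate(chars):
        if c.isalpha():
            chars[i] = c.upper()
            break
    return "".join(chars)


@dataclass
class MergeMap:
    """Expert merge map: canonical title -> member event ids (injective)."""

    entries: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen_ids: dict[str, str] = {}
        seen_titles: set[str] = set()
        norm_entries = []
        for title, ids in self.entries:
            std = standardise_title(title)
            if std is None:
                raise ValueError(f"merge map canonical title standardises to NA: {title!r}")
            if std in seen_titles:
                raise ValueError(f"duplicate canonical title in merge map: {std!r}")
            seen_titles.add(std)
            norm_ids = tuple(normalise_event_id(i) for i in ids)
            for i in norm_ids:
                if i in seen_ids:
                    raise ValueError(f"event id {i!r} appears in two merge-map entries")
                seen_ids[i] = std
            norm_entries.append((std, norm_ids))
        self.entries = norm_entries

    def lookup(self) -> dict[str, str]:
        """event id -> canonical title."""
        return {i: title for title, ids in self.entries for i in ids}

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MergeMap":
        """Read a two-column TSV (canonical_title, event_id), header row first."""
        grouped: dict[str, list[str]] = defaultdict(list)
        order: list[str] = []
        with open(path, encoding="utf-8") as fh:
            next(fh, None)
            for line in fh:
                if not line.strip():
                    continue
                title, event_id = line.rstrip("\n").split("\t")[:2]
                if title not in grouped:
                    order.append(title)
                grouped[title].append(event_id)
        return cls([(t, tuple(grouped[t])) for t in order])

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("canonical_title\tevent_id\n")
            for title, ids in self.entries:
                for i in ids:
                    fh.write(f"{title}\t{i}\n")


def resolve_role(member_roles) -> Role:
    """Resolve a merged node's role with precedence AO > MIE > KE.

    Terminal outcomes win over initiating events, which win over
    intermediates, so merging never hides an adverse outcome.
    """
    roles = list(member_roles)
    if not roles:
        raise ValueError("cannot resolve role of an empty member set")
    if Role.AO in roles:
        return Role.AO
    if Role.MIE in roles:
        return Role.MIE
    return Role.KE


@dataclass
class HarmonisationResult:
    """Canonical roster plus the audit trail of the merge."""

    roster: dict[str, HarmonisedNode]
    id_to_title: dict[str, str]
    dropped: list[KeyEventRecord] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def apply_merge_map(
    records: list[KeyEventRecord],
    merge_map: MergeMap | None = None,
    preserve: frozenset[str] = DEFAULT_PRESERVE,
) -> HarmonisationResult:
    """Collapse key-event records into canonical :class:`HarmonisedNode`s.

    Ids named by the merge map join their canonical node; every other id
    becomes (part of) a node keyed by its standardised title, so two unmapped
    events whose titles standardise identically are auto-merged (with a
    warning).  Records whose title standardises to the NA drop-signal are
    dropped and reported.
    """
    merge_map = merge_map or MergeMap()
    id_lookup = merge_map.lookup()
    warnings_: list[str] = []
    dropped: list[KeyEventRecord] = []

    known_ids = {r.event_id for r in records}
    for mapped_id in id_lookup:
        if mapped_id not in known_ids:
            warnings_.append(f"merge map references unknown event id {mapped_id!r}")

    members: dict[str, set[str]] = defaultdict(set)
    roles: dict[str, list[Role]] = defaultdict(list)
    aops: dict[str, set[str]] = defaultdict(set)
    title_origin: dict[str, set[str]] = defaultdict(set)

    for rec in records:
        if rec.event_id in id_lookup:
            canonical = id_lookup[rec.event_id]
        else:
            std = standardise_title(rec.title, preserve)
            if std is None:
                dropped.append(rec)
                continue
            canonical = std
            title_origin[canonical].add(rec.event_id)
        members[canonical].add(rec.event_id)
        roles[canonical].append(rec.role)
        aops[canonical].add(rec.aop_id)

    for title, ids in title_origin.items():
        if len(ids) > 1:
            warnings_.append(
                f"unmapped events {sorted(ids)} share standardised title {title!r}; auto-merged"
            )

    roster = {
        title: HarmonisedNode(
            canonical_title=title,
            member_ids=frozenset(members[title]),
            role=resolve_role(roles[title]),
            aop_membership=frozenset(aops[title]),
        )
        for title in members
    }
    id_to_title = {i: t for t, node in roster.items() for i in node.member_ids}
    return HarmonisationResult(roster=roster, id_to_title=id_to_title, dropped=dropped, warnings=warnings_)


@dataclass
class RemapResult:
    """KERs re-expressed between canonical nodes, plus unresolved leftovers."""

    edges: list[tuple[str, str, KERRecord]]
    unresolved: list[KERRecord] = field(default_factory=list)


def remap_kers(kers: list[KERRecord], result: HarmonisationResult) -> RemapResult:
    """Replace KER endpoints by canonical nodes.

    Relationships whose endpoints merge into the same node become self-loops
    and are retained; relationships with an endpoint outside the roster are
    collected in ``unresolved`` rather than failing the build.
    """
    edges: list[tuple[str, str, KERRecord]] = []
    unresolved: list[KERRecord] = []
    for ker in kers:
        up = result.id_to_title.get(ker.upstream_event)
        down = result.id_to_title.get(ker.downstream_event)
        if up is None or down is None:
            unresolved.append(ker)
            continue
        edges.append((up, down, ker))
    return RemapResult(edges=edges, unresolved=unresolved)
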