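"""Typed records for AOP-Wiki-style inputs.

These are the validated in-memory forms of the tabular exports: one
:class:`KeyEventRecord` per (AOP, event) row of the key-events dataset, one
:class:`KERRecord` per key-event relationship, and one
:class:`MeasurementSection` per "how it is measured or detected" text block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .vocab import Adjacency, Role, normalise_label


def normalise_event_id(raw: str) -> str:
    """Canonicalise an event id: trim and strip internal whitespace.

    AOP-Wiki-derived material prints both "KE1964" and "KE 1964" for the
    same event; both normalise to "KE1964".
    """
    return "".join(str(raw).split())


@dataclass(frozen=True)
class KeyEventRecord:
    """One row of the key-events dataset: an event as used by one AOP."""

    aop_id: str
    event_id: str
    title: str
    role: Role

    def __post_init__(self) -> None:
        if not str(self.aop_id).strip():
            raise ValueError("aop_id must be non-empty")
        object.__setattr__(self, "event_id", normalise_event_id(self.event_id))
        if not self.event_id:
            raise ValueError("event_id must be non-empty")
        if not isinstance(self.role, Role):
            object.__setattr__(self, "role", Role.from_raw(str(self.role)))


@dataclass(frozen=True)
class KERRecord:
    """One key-event relationship: a directed, annotated causal link."""

    upstream_event: str
    downstream_event: str
    adjacency: Adjacency
    evidence_raw: str
    quant_raw: str
    aop_id: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "upstream_event", normalise_event_id(self.upstream_event)
        )
        object.__setattr__(
            self, "downstream_event", normalise_event_id(self.downstream_event)
        )
        if not self.upstream_event or not self.downstream_event:
            raise ValueError("KER endpoints must be non-empty")
        if not isinstance(self.adjacency, Adjacency):
            object.__setattr__(self, "adjacency", Adjacency.from_raw(str(self.adjacency)))
        object.__setattr__(self, "evidence_raw", normalise_label(self.evidence_raw))
        object.__setattr__(self, "quant_raw", normalise_label(self.quant_raw))

    @property
    def self_loop(self) -> bool:
        """An explicit self-relationship (permitted; retained downstream)."""
        return self.upstream_event == self.downstream_event


@dataclass(frozen=True)
class MeasurementSection:
    """The "How It Is Measured or Detected" text attached to one event."""

    event_id: str
    text: str = ""
    source: str = "xml"
    missing: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "event_id", normalise_event_id(self.event_id))
        if not self.event_id:
            raise ValueError("event_id must be non-empty")

    @property
    def has_text(self) -> bool:
        return bool(self.text.strip())


@dataclass(frozen=True)
class HarmonisedNode:
    """Canonical network node: one merged, role-resolved biological event."""

    canonical_title: str
    member_ids: frozenset[str]
    role: Role
    aop_membership: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "member_ids", frozenset(self.member_ids))
        object.__setattr__(self, "aop_membership", frozenset(self.aop_membership))
        if not self.member_ids:
            raise ValueError("member_ids must be non-empty")
        if not self.aop_membership:
            raise ValueError("aop_membership must be non-empty")


@dataclass
class RowIssue:
    """A validation problem on one input row; collected, never silently dropped."""

    row: int
    message: str
    data: dict = field(default_factory=dict)
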