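"""Controlled vocabularies: event roles, edge adjacency, evidence categories.

AOP-Wiki exports are loose about labels ("MIE" vs "MolecularInitiatingEvent",
"NA" vs blank vs "Not Specified"), so every enum here ships with a
``from_raw`` parser, and evidence / quantitative-understanding labels are
recoded onto a fixed four-level scale before any counting happens:
"High" and "Strong" collapse to High, while "Not Specified", "NA" and blanks
collapse to Not Specified.
"""

from __future__ import annotations

import warnings
from enum import Enum

#: Sentinel used for blank / missing free-text labels before recoding.
NA_SENTINEL = "NA"


def normalise_label(raw: str | None) -> str:
    """Strip a raw label; blanks and NA spellings become the ``"NA"`` sentinel."""
    if raw is None:
        return NA_SENTINEL
    s = raw.strip()
    if s == "" or s.lower() in {"na", "n/a", "nan", "none"}:
        return NA_SENTINEL
    return s


class Role(str, Enum):
    """Role of a key event within an AOP."""

    MIE = "MIE"
    KE = "KE"
    AO = "AO"

    @classmethod
    def from_raw(cls, raw: str) -> "Role":
        aliases = {
            "mie": cls.MIE,
            "molecularinitiatingevent": cls.MIE,
            "molecular initiating event": cls.MIE,
            "ke": cls.KE,
            "keyevent": cls.KE,
            "key event": cls.KE,
            "ao": cls.AO,
            "adverseoutcome": cls.AO,
            "adverse outcome": cls.AO,
        }
        key = raw.strip().lower()
        if key not in aliases:
            raise ValueError(f"unknown event role: {raw!r}")
        return aliases[key]


class Adjacency(str, Enum):
    """Whether a KER links two consecutive events or skips intermediate biology."""

    ADJACENT = "adjacent"
    NON_ADJACENT = "non-adjacent"

    @classmethod
    def from_raw(cls, raw: str) -> "Adjacency":
        key = raw.strip().lower().replace("_", "-").replace(" ", "-")
        if key in {"adjacent", "direct"}:
            return cls.ADJACENT
        if key in {"non-adjacent", "nonadjacent", "indirect"}:
            return cls.NON_ADJACENT
        raise ValueError(f"unknown adjacency label: {raw!r}")


class Category(str, Enum):
    """Recoded evidence / quantitative-understanding level."""

    HIGH = "High"
    MODERATE = "Moderate"
    LOW = "Low"
    NOT_SPECIFIED = "Not Specified"


#: Strongest-first ordering used when parallel relationships are merged.
CATEGORY_STRENGTH = (
    Category.HIGH,
    Category.MODERATE,
    Category.LOW,
    Category.NOT_SPECIFIED,
)

_RECODE = {
    "high": Category.HIGH,
    "strong": Category.HIGH,
    "moderate": Category.MODERATE,
    "medium": Category.MODERATE,
    "low": Category.LOW,
    "weak": Category.LOW,
    "not specified": Category.NOT_SPECIFIED,
    "notspecified": Category.NOT_SPECIFIED,
    "na": Category.NOT_SPECIFIED,
    "n/a": Category.NOT_SPECIFIED,
    "": Category.NOT_SPECIFIED,
}


def recode_evidence(raw: str | None) -> Category:
    """Map a raw evidence label onto the four-level scale (case-insensitive).

    Unknown labels fall back to ``Not Specified`` with a warning so that a
    mis-typed label is auditable instead of silently dropped.
    """
    key = normalise_label(raw).lower()
    if key == NA_SENTINEL.lower():
        key = ""
    if key in _RECODE:
        return _RECODE[key]
    warnings.warn(f"unknown evidence label {raw!r}; recoded as Not Specified")
    return Category.NOT_SPECIFIED


def recode_quant(raw: str | None) -> Category:
    """Recode a quantitative-understanding label; same scheme as evidence."""
    return recode_evidence(raw)


def has_quant(category: Category) -> bool:
    """True when a relationship carries any quantitative understanding."""
    return category is not Category.NOT_SPECIFIED


def strongest(categories) -> Category:
    """Strongest category present (High > Moderate > Low > Not Specified)."""
    cats = set(categories)
    if not cats:
        return Category.NOT_SPECIFIED
    for c in CATEGORY_STRENGTH:
        if c in cats:
            return c
    return Category.NOT_SPECIFIED
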