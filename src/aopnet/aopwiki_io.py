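"""Readers and writers for AOP-Wiki-style inputs.

Four inputs are supported: the key-events dataset (TSV; one row per AOP and
event, with role), KER tables (TSV; upstream/downstream event, adjacency,
evidence and quantitative-understanding labels), an XML subset carrying the
"How It Is Measured or Detected" text per key event, and the two-column KC
mapping table.  The default dialect is UTF-8 TSV with a header row and no
quoting; because real exports do not fix their headers, every reader accepts
a ``column_map`` and an alternative ``aopwiki`` dialect with verbose headers
and role aliases is shipped.  Readers validate rows into typed records and
collect failures as :class:`RowIssue` reports instead of dropping them.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from lxml import etree

from .records import (
    KERRecord,
    KeyEventRecord,
    MeasurementSection,
    RowIssue,
    normalise_event_id,
)
from .vocab import normalise_label


@dataclass(frozen=True)
class Dialect:
    """Column naming convention of one export flavour."""

    ke_columns: dict[str, str]
    ker_columns: dict[str, str]
    kc_columns: dict[str, str]


DIALECTS: dict[str, Dialect] = {
    "default": Dialect(
        ke_columns={"aop": "aop_id", "event": "event_id", "title": "title", "role": "role"},
        ker_columns={
            "upstream": "upstream_event",
            "downstream": "downstream_event",
            "adjacency": "adjacency",
            "evidence": "evidence",
            "quant": "quantitative_understanding",
            "aop": "aop_id",
        },
        kc_columns={"event": "event_id", "kc": "kc_id"},
    ),
    "aopwiki": Dialect(
        ke_columns={"aop": "AOP", "event": "Key Event ID", "title": "Key Event Title", "role": "Key Event Type"},
        ker_columns={
            "upstream": "Upstream Event",
            "downstream": "Downstream Event",
            "adjacency": "Adjacency",
            "evidence": "Evidence",
            "quant": "Quantitative Understanding",
            "aop": "AOP",
        },
        kc_columns={"event": "Key Event ID", "kc": "Key Characteristic"},
    ),
}


def _resolve_columns(df: pd.DataFrame, column_map: dict[str, str], what: str) -> None:
    missing = [c for c in column_map.values() if c not in df.columns]
    if missing:
        raise ValueError(
            f"{what}: mapped column(s) {missing} not found; available headers: "
            f"{list(df.columns)}"
        )


def _read_tsv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def read_ke_dataset(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    dialect: str = "default",
) -> tuple[list[KeyEventRecord], list[RowIssue]]:
    """Read the key-events dataset into validated records.

    Returns ``(records, issues)``: rows failing validation are reported with
    their row number, never silently dropped.
    """
    cmap = column_map or _dialect(dialect).ke_columns
    df = _read_tsv(path)
    if df.empty and not len(df.columns):
        return [], []
    _resolve_columns(df, cmap, "key-events dataset")
    records, issues = [], []
    for i, row in df.iterrows():
        try:
            records.append(
                KeyEventRecord(
                    aop_id=row[cmap["aop"]],
                    event_id=row[cmap["event"]],
                    title=row[cmap["title"]],
                    role=row[cmap["role"]],
                )
            )
        except ValueError as exc:
            issues.append(RowIssue(row=int(i) + 2, message=str(exc), data=dict(row)))
    return records, issues


def write_ke_dataset(records: list[KeyEventRecord], path: str | Path, dialect: str = "default") -> Path:
    cmap = _dialect(dialect).ke_columns
    path = Path(path)
    df = pd.DataFrame(
        {
            cmap["aop"]: [r.aop_id for r in records],
            cmap["event"]: [r.event_id for r in records],
            cmap["title"]: [r.title for r in records],
            cmap["role"]: [r.role.value for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def read_ker_table(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    dialect: str = "default",
) -> tuple[list[KERRecord], list[RowIssue]]:
    """Read a KER table; blank evidence/quant labels normalise to "NA"."""
    cmap = column_map or _dialect(dialect).ker_columns
    df = _read_tsv(path)
    if df.empty and not len(df.columns):
        return [], []
    _resolve_columns(df, cmap, "KER table")
    records, issues = [], []
    for i, row in df.iterrows():
        try:
            records.append(
                KERRecord(
                    upstream_event=row[cmap["upstream"]],
                    downstream_event=row[cmap["downstream"]],
                    adjacency=row[cmap["adjacency"]],
                    evidence_raw=normalise_label(row[cmap["evidence"]]),
                    quant_raw=normalise_label(row[cmap["quant"]]),
                    aop_id=row[cmap["aop"]],
                )
            )
        except ValueError as exc:
            issues.append(RowIssue(row=int(i) + 2, message=str(exc), data=dict(row)))
    return records, issues


def write_ker_table(records: list[KERRecord], path: str | Path, dialect: str = "default") -> Path:
    cmap = _dialect(dialect).ker_columns
    path = Path(path)
    df = pd.DataFrame(
        {
            cmap["upstream"]: [r.upstream_event for r in records],
            cmap["downstream"]: [r.downstream_event for r in records],
            cmap["adjacency"]: [r.adjacency.value for r in records],
            cmap["evidence"]: [r.evidence_raw for r in records],
            cmap["quant"]: [r.quant_raw for r in records],
            cmap["aop"]: [r.aop_id for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def _dialect(name: str) -> Dialect:
    if name not in DIALECTS:
        raise ValueError(f"unknown dialect {name!r}; known: {sorted(DIALECTS)}")
    return DIALECTS[name]


# -- measurement-section XML subset --------------------------------------
#
# The supported XML subset is:
#   <key-events>
#     <key-event id="KE123">
#       <how-it-is-measured>free text</how-it-is-measured>
#     </key-event>
#   </key-events>


def extract_measurement_sections(
    xml_path: str | Path, event_ids: list[str]
) -> list[MeasurementSection]:
    """Extract "how it is measured" text for the requested event ids.

    One section is returned per requested id, in request order; ids absent
    from the XML yield an empty-text section flagged ``missing``.  Malformed
    XML raises :class:`lxml.etree.XMLSyntaxError`, which carries the line
    number.
    """
    tree = etree.parse(str(xml_path))
    by_id: dict[str, str] = {}
    for ke in tree.iter("key-event"):
        event_id = normalise_event_id(ke.get("id", ""))
        if not event_id:
            continue
        measured = ke.find("how-it-is-measured")
        by_id[event_id] = (measured.text or "") if measured is not None else ""
    sections = []
    for raw_id in event_ids:
        event_id = normalise_event_id(raw_id)
        if event_id in by_id:
            sections.append(MeasurementSection(event_id=event_id, text=by_id[event_id]))
        else:
            sections.append(MeasurementSection(event_id=event_id, text="", missing=True))
    return sections


def read_measurement_map(xml_path: str | Path) -> dict[str, str]:
    """Read every measurement section in the XML as an event-id -> text map."""
    tree = etree.parse(str(xml_path))
    out: dict[str, str] = {}
    for ke in tree.iter("key-event"):
        event_id = normalise_event_id(ke.get("id", ""))
        if not event_id:
            continue
        measured = ke.find("how-it-is-measured")
        out[event_id] = (measured.text or "") if measured is not None else ""
    return out


def write_measurement_xml(sections: dict[str, str], path: str | Path) -> Path:
    """Write a measurement-section map as the supported XML subset."""
    path = Path(path)
    root = etree.Element("key-events")
    for event_id in sorted(sections):
        ke = etree.SubElement(root, "key-event", id=event_id)
        measured = etree.SubElement(ke, "how-it-is-measured")
        measured.text = sections[event_id]
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="utf-8"
    )
    return path


# -- KC mapping table ------------------------------------------------------


def read_kc_table(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    dialect: str = "default",
) -> dict[str, set[str]]:
    """Read the two-column (event id, KC id) table into a set-valued map.

    KC ids outside KC1-KC12 are rejected with a validation error.
    """
    cmap = column_map or _dialect(dialect).kc_columns
    df = _read_tsv(path)
    if df.empty and not len(df.columns):
        return {}
    _resolve_columns(df, cmap, "KC table")
    valid = {f"KC{i}" for i in range(1, 13)}
    out: dict[str, set[str]] = defaultdict(set)
    for i, row in df.iterrows():
        kc = str(row[cmap["kc"]]).strip()
        if kc not in valid:
            raise ValueError(f"row {int(i) + 2}: KC id {kc!r} outside KC1-KC12")
        out[normalise_event_id(row[cmap["event"]])].add(kc)
    return dict(out)


def write_kc_table(kc_map: dict[str, set[str]], path: str | Path, dialect: str = "default") -> Path:
    cmap = _dialect(dialect).kc_columns
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{cmap['event']}\t{cmap['kc']}\n")
        for event_id in sorted(kc_map):
            for kc in sorted(kc_map[event_id], key=lambda k: int(k[2:])):
                fh.write(f"{event_id}\t{kc}\n")
    return path
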