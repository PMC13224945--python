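"""Screening funnel: keyword search, title search, exclusions, re-inclusions.

Candidate AOPs are found by case-insensitive *substring* matching of cardiac
keywords against key-event / adverse-outcome titles ("cardio" must hit
"Cardiovascular", "atrio" must hit "atrioventricular"), plus a second pass
over AOP titles.  Exclusions are expert inputs — categorised id sets, first
matching rule wins — and an excluded AOP may be explicitly re-included (with
justification).  The report keeps every intermediate set so the whole funnel
is auditable from the sets alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .records import KeyEventRecord

#: Default cardiac keyword list used for the cardiotoxicity screen.
DEFAULT_KEYWORDS: tuple[str, ...] = (
    "heart",
    "cardio",
    "cardiac",
    "ventricular",
    "ventricle",
    "myocardial",
    "myocardium",
    "atrial",
    "atrio",
    "atrium",
)


@dataclass
class ScreeningConfig:
    """Keywords, categorised exclusion rules and justified re-inclusions."""

    keywords: tuple[str, ...] = DEFAULT_KEYWORDS
    exclusion_rules: list[tuple[str, frozenset[str]]] = field(default_factory=list)
    reinclusions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.keywords:
            raise ValueError("keywords must be non-empty")
        labels = [label for label, _ in self.exclusion_rules]
        if len(labels) != len(set(labels)):
            raise ValueError("exclusion categories must have distinct labels")
        self.exclusion_rules = [
            (label, frozenset(str(i) for i in ids)) for label, ids in self.exclusion_rules
        ]
        self.reinclusions = {str(k): v for k, v in self.reinclusions.items()}


@dataclass
class ScreeningReport:
    """Full audit trail of one screening run."""

    candidates_keyword: frozenset[str]
    candidates_title: frozenset[str]
    excluded: dict[str, str]
    reincluded: frozenset[str]
    included: frozenset[str]
    warnings: list[str] = field(default_factory=list)

    @property
    def candidates(self) -> frozenset[str]:
        return self.candidates_keyword | self.candidates_title

    def funnel_counts(self) -> dict[str, int]:
        return {
            "candidates_keyword": len(self.candidates_keyword),
            "candidates_title": len(self.candidates_title),
            "candidates_total": len(self.candidates),
            "excluded": len(self.excluded),
            "reincluded": len(self.reincluded),
            "included": len(self.included),
        }

    def to_dict(self) -> dict:
        return {
            "candidates_keyword": sorted(self.candidates_keyword),
            "candidates_title": sorted(self.candidates_title),
            "excluded": dict(sorted(self.excluded.items())),
            "reincluded": sorted(self.reincluded),
            "included": sorted(self.included),
            "funnel": self.funnel_counts(),
            "warnings": list(self.warnings),
        }


def _matches(title: str, keywords) -> bool:
    low = str(title).casefold()
    return any(k.casefold() in low for k in keywords)


def keyword_screen(
    records: list[KeyEventRecord], config: ScreeningConfig | None = None
) -> frozenset[str]:
    """AOP ids with at least one KE/AO title containing at least one keyword.

    All roles are scanned — an adverse outcome named "Heart failure" flags
    its AOP just as a mid-chain key event does.
    """
    config = config or ScreeningConfig()
    return frozenset(
        r.aop_id for r in records if _matches(r.title, config.keywords)
    )


def title_screen(
    aop_titles: dict[str, str], config: ScreeningConfig | None = None
) -> frozenset[str]:
    """AOP ids whose own title matches the keyword rule."""
    config = config or ScreeningConfig()
    return frozenset(
        aop_id for aop_id, title in aop_titles.items() if _matches(title, config.keywords)
    )


def apply_exclusions(
    candidates: frozenset[str] | set[str],
    config: ScreeningConfig,
    candidates_keyword: frozenset[str] | None = None,
    candidates_title: frozenset[str] | None = None,
) -> ScreeningReport:
    """Apply categorised exclusions then re-inclusions to the candidate set.

    Every excluded AOP carries exactly one category (first matching rule in
    config order wins; overlapping rules are reported as warnings).
    Re-including an id that no exclusion rule names is an error, because it
    signals a mis-specified config rather than a judgement call.
    """
    candidates = frozenset(str(c) for c in candidates)
    all_excludable = frozenset().union(
        *(ids for _, ids in config.exclusion_rules)
    ) if config.exclusion_rules else frozenset()
    bad = set(config.reinclusions) - set(all_excludable)
    if bad:
        raise ValueError(
            f"re-inclusion of never-excluded AOP id(s): {sorted(bad)}"
        )

    warnings: list[str] = []
    excluded: dict[str, str] = {}
    for label, ids in config.exclusion_rules:
        for aop_id in sorted(ids & candidates):
            if aop_id in excluded:
                warnings.append(
                    f"AOP {aop_id} matches both {excluded[aop_id]!r} and {label!r}; "
                    f"keeping first"
                )
            else:
                excluded[aop_id] = label

    reincluded = frozenset(config.reinclusions) & frozenset(excluded)
    included = (candidates - frozenset(excluded)) | reincluded
    return ScreeningReport(
        candidates_keyword=candidates_keyword if candidates_keyword is not None else candidates,
        candidates_title=candidates_title if candidates_title is not None else frozenset(),
        excluded=excluded,
        reincluded=reincluded,
        included=included,
        warnings=warnings,
    )


def run_screen(
    records: list[KeyEventRecord],
    aop_titles: dict[str, str],
    config: ScreeningConfig,
) -> ScreeningReport:
    """Convenience wrapper: keyword screen + title screen + exclusions."""
    kw = keyword_screen(records, config)
    ti = title_screen(aop_titles, config)
    return apply_exclusions(
        kw | ti, config, candidates_keyword=kw, candidates_title=ti
    )
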