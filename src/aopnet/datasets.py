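"""Published inputs of the August-2025 AOP-Wiki cardiotoxicity screen.

These constants are the expert inputs of the published screening funnel for
the cardiotoxicity network: the AOP ids flagged by the key-event keyword
search, the ids added by the AOP-title search, the categorised exclusion
rules, and the single justified re-inclusion.  They are data, not code —
judging licences, taxonomy applicability or disease relevance is expert
work and enters the pipeline through these sets.
"""

from __future__ import annotations

from .screening import DEFAULT_KEYWORDS, ScreeningConfig

#: AOPs flagged because >=1 key event / adverse outcome title matched a keyword.
KEYWORD_CANDIDATES: frozenset[str] = frozenset(
    {
        "16", "21", "94", "104", "138", "150", "177", "186", "261", "304",
        "377", "426", "427", "433", "436", "456", "479", "480", "539",
    }
)

#: AOPs added by the follow-up keyword search over AOP titles.
TITLE_CANDIDATES: frozenset[str] = frozenset({"438", "448", "515"})

#: Categorised exclusion rules, in published order (first match wins).
EXCLUSION_RULES: list[tuple[str, frozenset[str]]] = [
    ("no KER information", frozenset({"186", "377", "448"})),
    ("all rights reserved", frozenset({"438", "515"})),
    ("COVID-19 related", frozenset({"426", "427"})),
    ("vasculature/development related", frozenset({"304", "436"})),
    ("fish specific", frozenset({"539"})),
]

#: AOP:448 lacks KER records in the wiki but is fully described in an
#: associated peer-reviewed publication, so it re-enters the corpus.
REINCLUSIONS: dict[str, str] = {
    "448": "KERs reconstructed from the associated peer-reviewed publication",
}

#: The 13 AOPs retained in the final cardiotoxicity network.
INCLUDED_AOPS: frozenset[str] = frozenset(
    {"16", "21", "94", "104", "138", "150", "177", "261", "433", "448", "456", "479", "480"}
)

#: Titles of the retained AOPs (used by examples and the title screen).
AOP_TITLES: dict[str, str] = {
    "16": "Acetylcholinesterase inhibition leading to acute mortality",
    "21": "Aryl hydrocarbon receptor activation leading to early life stage mortality, via increased COX-2",
    "94": "Sodium channel inhibition leading to congenital malformations",
    "104": "Altered ion channel activity leading impaired heart function",
    "138": "Organic anion transporter (OAT1) inhibition leading to renal failure and mortality",
    "150": "Aryl hydrocarbon receptor activation leading to early life stage mortality, via reduced VEGF",
    "177": "Cyclooxygenase 1 (COX1) inhibition leading to renal failure and mortality",
    "261": "L-type calcium channel blockade leading to heart failure via decrease in cardiac contractility",
    "433": "hERG channel blockade leading to sudden cardiac death",
    "448": "ROS, inflammation, and activation of nAChR lead to increased incidence of cardiovascular morbidity and mortality",
    "456": "Aryl hydrocarbon receptor activation leading to early life stage mortality via sox9 repression induced cardiovascular toxicity",
    "479": "Mitochondrial complexes inhibition leading to left ventricular function decrease via increased myocardial oxidative stress",
    "480": "Mitochondrial complexes inhibition leading to heart failure via decreased ATP production",
}


def cardiotox_screening_config() -> ScreeningConfig:
    """The published screening configuration (keywords, exclusions, re-inclusion)."""
    return ScreeningConfig(
        keywords=DEFAULT_KEYWORDS,
        exclusion_rules=list(EXCLUSION_RULES),
        reinclusions=dict(REINCLUSIONS),
    )
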