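"""Screening funnel: from keyword candidates to the included AOP corpus.

Runs the published cardiotoxicity screen: 19 AOPs flagged by cardiac
keywords in key-event titles, 3 more by AOP-title search, five categorised
exclusion rules, and one justified re-inclusion (AOP 448, whose relationships
come from an associated publication).
"""

from aopnet import apply_exclusions
from aopnet.datasets import (
    KEYWORD_CANDIDATES,
    TITLE_CANDIDATES,
    cardiotox_screening_config,
)

report = apply_exclusions(
    KEYWORD_CANDIDATES | TITLE_CANDIDATES,
    cardiotox_screening_config(),
    candidates_keyword=KEYWORD_CANDIDATES,
    candidates_title=TITLE_CANDIDATES,
)

print("screening funnel:")
for step, count in report.funnel_counts().items():
    print(f"  {step:>20}: {count}")
print("excluded, by category:")
for aop_id, category in sorted(report.excluded.items(), key=lambda kv: kv[1]):
    marker = " (re-included)" if aop_id in report.reincluded else ""
    print(f"  AOP {aop_id:>3}: {category}{marker}")
print(f"included corpus: {', '.join(sorted(report.included, key=int))}")
print()
print("Reading: 22 candidates minus 10 categorised exclusions, plus the")
print("re-included AOP 448, leaves the 13 pathways the network is built from.")
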