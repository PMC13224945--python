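"""Annotation layers: evidence recoding, KC mapping, method catalogue.

Joins the non-topological layers onto the reference network and renders the
summary report that collects every headline percentage family.
"""

from aopnet import (
    build_method_catalogue,
    cardiotox_reference_network,
    compute_metrics,
    kc_coverage,
    summary_report,
)

bundle, network = cardiotox_reference_network()
metrics = compute_metrics(network)
kc = kc_coverage(network, {k: set(v) for k, v in bundle.kc_table.items()})
catalogue = build_method_catalogue(network, bundle.measurement_sections)
report = summary_report(network, metrics, kc, catalogue)

print(report.to_markdown())
tagged = [e for e in catalogue if e.modality_tags]
print(f"catalogue entries with modality tags: {len(tagged)}")
example = next(e for e in tagged if "in vitro" in e.modality_tags)
print(f"  e.g. {example.node}: {sorted(example.modality_tags)}")
print()
print("Reading: half the relationships carry high/strong evidence but only")
print("37.2% any quantitative understanding; 50 of 64 events map to key")
print("characteristics of cardiovascular toxicants (KC7, dyslipidaemia, is")
print("absent) and 28 have described detection methods.")
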