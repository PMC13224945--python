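# aopnet

Construction and topological analysis of **adverse outcome pathway (AOP)
networks**, built for the cardiotoxicity domain.

An AOP is a causal chain of measurable biological events — from a molecular
initiating event (MIE) through intermediate key events (KEs) to an adverse
outcome (AO) — connected by evidence-annotated key event relationships
(KERs). AOPs are curated one pathway at a time in the OECD AOP-Wiki, but the
biology they describe is shared: oxidative stress, mitochondrial dysfunction
and decreased contractility recur across many routes to cardiac injury.
`aopnet` pools AOP-Wiki-style exports into a single directed network and asks
which events sit at the crossroads.

The pipeline, for toxicologists and systems biologists assembling such
networks:

1. **Screening** — case-insensitive substring search of cardiac keywords
   ("heart", "cardio", "cardiac", "ventricular", …) over KE/AO titles and AOP
   titles, then categorised expert exclusions with justified re-inclusions,
   with a fully auditable funnel report.
2. **Harmonisation** — an expert merge map collapses duplicate key events
   ("Heart failure" / "Sudden cardiac death") into canonical nodes; titles are
   standardised (leading capital, gene symbols like *hERG* preserved, NA
   entries dropped); roles resolve with precedence AO > MIE > KE.
3. **Network build** — edges point cause → effect and carry adjacency
   (adjacent = consecutive events, non-adjacent = skips intermediate biology),
   recoded evidence and quantitative-understanding categories, and source-AOP
   provenance. Parallel assertions across AOPs merge (adjacent wins,
   strongest evidence wins, all raw labels retained); self-loops are kept.
4. **Topology metrics** — in/out/total degree, shortest-path betweenness
   (raw or pair-normalised), stress centrality, out-eccentricity,
   convergent/divergent flow classes, MIE→AO simple-path occurrence with the
   path-length distribution, and a combined importance score
   (min–max-normalised degree + betweenness + stress).
5. **Annotation & reporting** — evidence recoding (High/Strong → High;
   NA/blank → Not Specified), mapping to the key characteristics of
   cardiovascular toxicants (KC1–KC12), a detection-method catalogue with
   in vivo / in vitro / in silico lexicon tagging, and a summary report of
   every percentage family.
6. **Export** — SIF, GraphML (lossless round trip) and MINERVA-style
   categorical overlay TSVs.

A seeded synthetic-fixture generator (`generate_fixture`) and a
composition-pinned reference fixture (`cardiotox_reference_network`) make the
whole pipeline testable offline; the reference fixture is synthetic but
reproduces the published cardiotoxicity network's aggregate composition
exactly (13 AOPs, 71 raw ids → 64 nodes, 94 edges, …).

## Worked example

```python
from aopnet import cardiotox_reference_network, composition_summary

bundle, network = cardiotox_reference_network()
comp = composition_summary(network)
```

Running `python examples/02_build_and_summarise_network.py` prints:

```
nodes: 64 (11 MIE, 48 KE, 5 AO)
edges: 94, self-loops: 2 (Mitochondrial dysfunction, Oxidative stress)
       adjacent: 81 (86.17%)
   non-adjacent: 13 (13.83%)
sharing (number of AOPs a node appears in -> nodes):
  1 AOP(s): 47 nodes (73.44%)
  2 AOP(s): 10 nodes (15.63%)
  3 AOP(s): 5 nodes (7.81%)
  4 AOP(s): 1 nodes (1.56%)
  8 AOP(s): 1 nodes (1.56%)
```

64 harmonised events joined by 94 directed relationships; most events belong
to a single pathway, while a small shared core (increased mortality in 8
AOPs, oxidative stress in 4) ties the 13 pathways together. The two
self-loops record self-amplifying biology (oxidative stress and mitochondrial
dysfunction reinforcing themselves).

The other scripts in `examples/` each demonstrate one capability: the
screening funnel (22 candidates → 13 included), the metric table and node
ranking, the annotation layers and summary report, and synthetic-fixture
generation with format exports.

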