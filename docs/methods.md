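# Methods

## Model and scope

`aopnet` treats a pooled AOP corpus as a directed graph whose nodes are
*harmonised* biological events and whose edges are key event relationships
pointing cause → effect. The package covers the path from AOP-Wiki-style
exports to a prioritised, annotated, exportable network. It does not attempt
graph layout, interactive hosting, automatic semantic matching of event
titles, or quantitative (dose/time-parameterised) AOP modelling: merging
decisions, exclusion judgements and KC assignments are expert inputs that
enter as data tables.

## Screening

Matching is case-insensitive **substring** matching, not whole-word: the
keyword list only works on this corpus under substring semantics ("cardio"
must hit "Cardiovascular", "atrio" must hit "atrioventricular"). Comparison
uses case-folding only, no accent stripping (titles are English). All roles
are scanned — an AO row can flag its AOP just as a KE row can. Exclusion
rules apply in configuration order with first-match-wins; since curated
category id sets are disjoint, precedence only matters for misconfigured
inputs, which are surfaced as warnings. Re-including an id never named by an
exclusion rule is a hard error (it signals a broken configuration, not a
judgement call).

## Harmonisation

Title standardisation trims whitespace, upper-cases the first *alphabetic*
character (so "(non-alpha) …" capitalises the first letter, not the first
byte) and drops the literal sentinel "NA". Titles whose first token is in a
preserve list (default: hERG, mRNA, miRNA, qPCR) are kept verbatim, because
gene-symbol-initial names must not be mangled. Event ids normalise by
stripping internal whitespace ("KE 1964" ≡ "KE1964").

The merge map is injective by construction (an id in two entries is an
error). Unmapped events become nodes keyed by standardised title; two
unmapped events whose titles collide after standardisation are auto-merged
with a warning, since identical titles denote duplicates. Role resolution
uses the precedence **AO > MIE > KE**: a merged node that contains a
terminal outcome anywhere stays an outcome, and initiating events dominate
intermediates. Relationships whose endpoints merge into one node become
self-loops and are retained — dropping them is a rendering decision, offered
only at export time.

## Network build

Edges deduplicate by (upstream, downstream). On merged parallel assertions:
adjacency resolves adjacent-wins (the more direct mechanistic claim),
evidence and quantitative understanding resolve strongest-wins
(High > Moderate > Low > Not Specified) with every contributing raw label
retained sorted, which both keeps the merge auditable and makes the build
invariant under permutation of input rows.

Evidence recoding is total and case-insensitive: High/Strong → High,
Not Specified/NA/blank → Not Specified; unknown labels fall back to
Not Specified with a warning rather than failing or silently vanishing.

## Topology metrics

All path-based metrics exclude self-loops (a shortest or simple path cannot
repeat a node) and simply skip disconnected ordered pairs — no infinite
distances. Self-loops still contribute 2 to total degree (one in, one out),
so mean total degree is always 2·|E|/|N|.

- **Betweenness** is shortest-path betweenness over ordered pairs
  (s ≠ v ≠ t) with fractional credit across equally short paths. The default
  is the raw (unnormalised) value; `pair_normalised` divides by (N−1)(N−2).
  Both conventions are exposed because published network tables do not
  always state which one they print.
- **Stress** counts (integer) the shortest s→t paths on which a node is
  internal. It is computed by per-source BFS path counting and a
  distance-composition check (σ_sv·σ_vt summed where d(s,v)+d(v,t)=d(s,t)),
  written in-package because no installed library provides directed stress
  centrality.
- **Out-eccentricity** is the maximum shortest-path distance to any
  *reachable* node; sinks score 0 and unreachable nodes are excluded from
  the maximum (again avoiding infinities on weakly connected digraphs).
- **Simple-path occurrence** enumerates every simple directed path from
  every MIE-role node to every AO-role node and counts, per node, the paths
  on which it is internal (endpoints excluded). The histogram is keyed by
  path length in **edges**. Enumeration is capped (default 10⁶ paths) and
  aborts with a clear error beyond the cap: a pathological input should fail
  loudly, not burn CPU.
- **Combined importance** min–max normalises each component (total degree,
  betweenness, stress by default) to [0, 1] over the node set and sums. A
  zero-range component contributes 0 for every node. The score is invariant
  under affine rescaling of any single component. Ranking ties break
  lexicographically by canonical title for reproducibility.
- **Flow classes**: convergent if in-degree > out-degree, divergent if
  out > in, balanced otherwise — a total partition of the node set.

Each path-based metric is property-tested against an independent brute-force
enumeration oracle on random digraphs of ≤ 12 nodes (the oracle shares no
code with the implementation, which uses networkx for betweenness and
simple-path enumeration).

## Annotation layers

A node's KC set is the union over its member event ids; coverage counts
nodes with a non-empty union. The method catalogue concatenates member
sections with per-member provenance, and `has_method` is true iff the
concatenated text is non-empty after whitespace normalisation — making the
coverage count independent of member ordering. Modality tagging (in vivo /
in vitro / in silico) uses a keyword lexicon shipped as editable package
data (`aopnet/data/modality_lexicon.tsv`), not code, because no published
rule set exists for this classification.

Percentages are rounded half-up at the reported precision: 2 decimals
everywhere except the share of relationships with any quantitative
understanding, reported at 1 decimal. Half-up is the convention that
reproduces reported values such as 78.13 (= 50/64) and 15.63 (= 10/64);
note that 4/94 = 4.2553 therefore reports as 4.26.

## Synthetic data

`generate_fixture` emulates the corpus structure the pipeline consumes.
Each AOP is a backbone chain MIE → KE… → AO — mirroring how AOPs are curated
as linear constructs — with middle events drawn from a shared pool with
configurable probability, so cross-cutting hubs emerge. Within every chain,
shared middles are ordered by creation index, which guarantees the pooled
network is acyclic. Non-adjacent relationships are forward skip links within
a chain, added until the adjacent fraction approximates the configured
value. Evidence labels are sampled from the raw vocabulary (High, Strong,
Moderate, Low, Not Specified, NA) so the recoder is genuinely exercised;
categorical tables given as integer counts are hit exactly (a mismatched
total is an error), probabilities are sampled per relationship. Event ids
are minted in a synthetic namespace so they can never collide with real
AOP-Wiki ids. Defaults (8 AOPs of 4–8 events, 25% sharing, 85% adjacent,
evidence ~50/20/5/25, 45% method coverage, 80% KC coverage) follow the
composition observed in curated cardiotoxicity corpora of this kind.

The **reference fixture** (`aopnet.reference`) is a hand-built synthetic
corpus whose *aggregates* are pinned to the published cardiotoxicity
network's composition: 13 AOPs (one lacking formal MIE/AO annotations),
71 raw ids harmonising to 64 nodes (11/48/5 MIE/KE/AO), 94 edges
(81 adjacent / 13 non-adjacent, two self-loops on oxidative stress and
mitochondrial dysfunction), the 47/10/5/1/1 sharing profile, evidence
51/15/4/24, 35 quantitatively characterised relationships, 28 nodes with
described methods and 50 nodes with KC mappings (KC7 absent). The topology
*within* those aggregates is one deliberate deterministic choice — the real
network's full edge list is not published — so node-level results on this
fixture (which node has the highest betweenness, the eccentricity maximum,
the simple-path histogram) characterise the fixture, not the real network.
Passing tests on it demonstrate that the pipeline reproduces every
composition-level statistic; they cannot validate claims about any
particular real node, and real exports will additionally contain header
variants and free-text noise beyond the two dialects emulated here.

## Numerical and degenerate-input choices

- Empty networks report count 0 and percentage `None` (never 0/0).
- Header-only or fully empty input files yield empty collections; a missing
  mapped column is a hard error listing the available headers.
- Invalid rows are collected with their row numbers in the reader's issue
  report; validation never mutates values.
- Problem sizes in tests: property suites use random digraphs of ≤ 12 nodes
  and ≤ 20 edges (where exhaustive enumeration is exact and fast) with 200
  derandomised cases for the acceptance suite; the reference network
  (64 nodes, 94 edges, 1317 MIE→AO simple paths) is computed once per test
  session.

## Known limitations

- The overlay writer targets the generic MINERVA categorical header style
  (`#VERSION=`/`#NAME=`/`#DESCRIPTION=` + name/value/color); platform
  deployments with stricter dialects may need the configurable headers.
- Harmonisation is only as good as the supplied merge map; no ontology
  alignment is attempted.
- The modality lexicon is a starting vocabulary; texts matching no keyword
  simply carry no modality tag.
- Betweenness conventions differ across tools; both provided modes are
  standard, but matching a specific third-party tool's printed numbers may
  require knowing which convention it used.
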