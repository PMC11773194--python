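# Methods

## The document model

An instance map is a directed graph document: nodes (id, kind, label,
descriptive metadata, a free-form `fields` mapping, resource links, an
optional colour override), directed edges with an optional label,
annotation regions (named, possibly overlapping node sets), and cross-map
links whose resolution is deferred until maps meet in a workspace.  Node
ids are caller-supplied stable strings matching `[A-Za-z0-9_.-]+` — never
auto-generated — because diffing across versions requires identity to
survive serialisation and editing.

The `fields` mapping deliberately carries structured study metadata
(e.g. `medium_volume: "900 mL"`) without a per-kind schema.  Community
experience with the format shows that node usage varies legitimately
between groups; freezing a schema per kind would forbid that variation.
The requirement slots of the taxonomy (below) give the mapping just enough
structure to support completeness checking.

Maps are DAG-like but not trees: multiple parents are allowed, since
collaborative workflows converge (several partners' branches feeding one
assessment).  Edge direction encodes workflow order and, along instance
chains, time.  Construction ops (`add_node`, `add_edge`, ...) are
non-mutating and enforce referential integrity; a map parsed with relaxed
reference checking may carry dangling references, which validation reports
as rule R1 rather than crashing — a deliberate split so that broken files
can be loaded, inspected and repaired.

Materials and media may exist unattached to any instance (they occur
independently when first used in a synthesis or exposure protocol);
validation reports them at info severity only.

## Taxonomy and completeness

Twelve node kinds partition into four categories (instance-family,
protocol, property, data) with default colours blue / purple / orange /
red (`#6baed6`, `#9e9ac8`, `#fd8d3c`, `#e34a33`; the hue family is the
format's convention, the exact hex values are this package's constants).
A colour override on a node is purely presentational — planning practice
deliberately "misuses" category colours to flag open points, so validation
and completeness never read colours.

Each kind carries requirement slots derived from the format's per-kind
"information to be covered" descriptions.  Slot ids are stable snake_case
identifiers invented here (the source descriptions are prose); the prose
label is stored verbatim alongside, and a slot lists the field names and
link roles that satisfy it.  A slot is satisfied per node; several nodes
pointing to the same file each satisfy their own slots independently,
since the model stores links opaquely and cannot (and should not) verify
shared content.  Node score is satisfied/required; the map score is the
unweighted mean (1.0 for an empty map, vacuously).  Completeness is
monotone under added fields/links by construction.

The legacy NIKC vocabulary (instance, material, medium, property,
supplementary) maps onto the taxonomy with `property → CuratedProperty` by
default, because the original curation effort extracted all data from
publications; the default is overridable.  A legacy *supplementary* row is
visual support for a property and becomes a `supplementary`-role resource
link on the preceding property node, not a node of its own.

## Validation profiles

The format intentionally avoids hard connection rules, but comparison and
interoperability benefit from a limited rule set.  Both built-in profiles
carry the same adjacency whitelist — material/medium into instance,
instance chains, transformation protocols bridging instances, the
five-stage measurement chain entered from an instance, properties hanging
off instance-family or data nodes, and the chain-before-property variant
(property → sample preparation) — covering the arrangements observed in
practice without declaring any of them wrong.  The profiles differ only in
severity: strict grades off-whitelist edges (R3) and inverted measurement
chains (R4) as warnings, lenient as info.  This makes the lenient report a
severity-wise lower bound of the strict one (a property the tests assert).
Dangling references (R1) and directed cycles (R2) are errors under every
profile, because a cycle contradicts the time semantics of instance order.
Unattached material/medium (R5) is info; an empty map (R6) a warning.
Community profiles can replace adjacency lists per source kind and
re-grade any rule via severity overrides, loaded from YAML/JSON.

Backbone extraction returns maximal paths in the instance subgraph, where
two instances are adjacent if connected directly or through one
transformation protocol.  Branching backbones yield one chain per maximal
path; chains and successors are ordered lexicographically for determinism.
Cycle detection delegates to networkx; its witness is one cycle's node
sequence.

## Serialisation

Canonical form is JSON, format_version "1.0": nodes sorted by id, edges by
(source, target, label), regions by id, fixed key order, empty/None values
omitted, UTF-8, trailing newline.  Serialising equal maps is
byte-identical, so documents diff cleanly in version control — the
intended home of map version history (the document itself stores none).
YAML is accepted on read only.  Map equality is canonical: edge, region
and link order is not semantically meaningful, and round-tripping
preserves equality exactly.

Schema violations raise errors with JSON-pointer-style locations
(`/edges/3/target`).  Export formats: DOT (clusters per region; a node
belongs to the first region claiming it, since DOT clusters cannot
overlap), Mermaid flowchart TD (shape per category — rectangle, hexagon,
rounded, parallelogram — a convention of this package; colours via style
lines; node ids re-mapped to Mermaid-safe identifiers), and GraphML via
networkx with plain data keys (kind, category, label, colour, regions as a
comma-joined attribute, since plain GraphML has no grouping).  In every
format each node yields exactly one node statement and each resolvable
edge one edge statement.

## Worked examples and the random generator

The seven fixture builders encode only what the published use-case
descriptions state; where a figure's full node roster is not enumerated in
text, the fixture is a faithful skeleton and says so in its map
description (the mesocosm map in particular).  Fixed facts encoded:
sulfidation synthesis in three consecutive instances, three sulfidation
transformation protocols differing only in PVP-AgNP concentration, four
tracked nanoparticle variants (three sulfidised + pristine, asserted as
variants = protocols + 1); daphnia culture in 1 L vessels with 900 mL high
hardness medium, 10–15 adults, 20 °C, 16:8 photoperiod, Chlorella ration
7.5 mg C (days 0–7) / 11.25 mg C (day 7+), with the 16-day culture log
shipped as CSV and attached to the raw-data node (attachment data only,
never parsed); the acute test ending in a dose–response processed-data
node; the chronic test holding a cross-map link to it (the exposure
concentration derives from the acute curve); immunotoxicity sections A–E
as regions; and the project-planning map with shipping transformation
protocols and red-overridden planning nodes.  Sulfidation concentrations
(2/5/10 g/L) are plausible placeholders for values the descriptions do not
print; nothing downstream depends on them.

`random_map(seed, n_instances, branch_prob)` emulates the shape of real
maps for property testing: an instance backbone in time order with
material+medium, property, or measurement-chain side branches drawn per
instance with probability `branch_prob` (default 0.5, n_instances 5 — the
scale of the published examples).  All edges point forward, so generated
maps are acyclic and lenient-clean by construction.  What it does *not*
emulate: converging branches, cross-map links, colour misuse, or the
malformed documents real users produce — tests for those construct their
cases explicitly, and passing random-map suites therefore says nothing
about adversarial input beyond what the explicit cases cover.

## Numerical and design choices

* Diff granularity is field-level for nodes (dotted paths,
  `fields.medium_volume`), identity-level for edges and cross-map links
  (their label/relation participates in identity).  Added nodes carry full
  payloads so a changeset is self-contained; `apply_diff` reconstructs the
  target exactly (asserted as a patch property).  Versioning is linear; no
  three-way merge — the use case is documenting deviation from a plan, not
  concurrent editing.  A revision's *reason* is free-text annotation on
  the changeset.
* `merge` with id-prefixing renames nodes to `<map_id>.<node_id>` (legal
  ids, since dots are allowed) and rewrites cross-map links between merged
  maps into ordinary edges labelled by the link relation.
* Oracle scales: acyclicity is checked against an exhaustive DFS cycle
  search on 200 random digraphs of ≤ 8 nodes, the size at which exhaustive
  search is exact and instant; round-trip identity uses all fixtures plus
  100 seeded random maps.  These sizes keep the whole suite under a few
  seconds while exercising every code path the larger examples use.
* Scores and rates are exact rational counts formatted to one decimal;
  no tolerance is involved anywhere in the package.

## Known limitations

Resource links are opaque: content is never fetched, parsed or verified,
so completeness measures *documentation* coverage, not data quality.  The
adjacency whitelist encodes one community's observed practice; profiles
exist precisely because it is not authoritative.  Region rendering loses
overlap in DOT/Mermaid.  No ontology annotation of kinds, no geometric
layout persistence, and no multi-user/web functionality — file-based
exchange replaces shared workspaces.
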