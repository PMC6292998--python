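# Methods

## The knowledge model

The package represents multimodal brain data as a typed property graph.
Every *object type* derives from one of five static kinds — element,
context, experiment, ontology, annotation — and is created dynamically
(`define_object_type`). *Relation classes* are directed and named twice: a
forward label used when traversing source→target and a distinct backward
label for target→source. Relation identity is the (class, source, target)
triple; repeated `relate` calls are idempotent. This rules out parallel
edges of one class, which is the natural reading of connectivity data:
a connection either exists between two coordinates or it does not, and
repeated measurements belong in experiment entries, not extra edges.

Relation *sources* may themselves be relation instances; targets are
always object instances. The asymmetry is deliberate: experiments on
connections need relations as subjects (and occasionally as sources of
provenance links), while nothing in the data model requires a relation as
a target. Identifiers are case-sensitive exact strings; labels are
free-text and matched case-insensitively in queries, because atlas labels
vary in capitalization across sources.

The store is in-memory with JSON export/import (stable key ordering, so
exports diff cleanly). Multi-user access, RDBMS backends and client/server
protocol are out of scope at desk scale.

## Experiments

An experiment method fixes a *subject specification* — an object type
(patient, probe, coordinate) or a relation class (a measured connection) —
and one or more *formats*. Formats carry hard ranges checked on every
write: correlation values in [−1, 1], normalized fiber density and
tracking probability in [0, 1], absolute fiber density ≥ 0, expression
level as a free real plus a {0, 1} PACall validity flag. One data entry
holds one format's values for one subject in one experiment; multi-format
methods store parallel entries, since the formats have disjoint attribute
sets. Missing measurements are **absent entries, not sentinels** — the
cross-modal join must distinguish "no DTI edge" from "zero correlation".
`tabulate` expands a method into a subjects × experiments table; the cell
value is the format's first attribute unless overridden.

## Atlases, ontologies, mapping

Coordinates are MNI millimetre triples with exact-match identity; there is
no spatial tolerance or nearest-neighbour lookup, because all joins run on
atlas-provided coordinate tables, not on geometry. Flat atlases load as
element types (one instance per row); hierarchical atlases load as
ontologies with a child→parent is-a edge list. The is-a graph may be a DAG
(anatomical ontologies are not strictly trees); cycles are rejected at
load, naming a member. `ontology_descendants` is the transitive closure of
is-a children, computed on the stored graph; it is the engine's only
built-in inference. Curated cross-atlas correspondence ("best match") is
consumed as a mapping table and never inferred automatically — label
matching across atlases is an editorial judgement, not an algorithm.

## Query engine

Queries are existential: `Related(label, nested)` holds iff *some*
relation with that label connects the object to an endpoint satisfying
`nested`. Universal quantification is not provided; negation and
disjunction are included as standard logic. Results are deduplicated and
sorted by (type, identifier). Name resolution happens before evaluation,
so a typo raises a query error instead of returning an empty set.
Availability tables cross the per-path bindings of each result instance
(nested-loop join); a path without bindings contributes an empty cell.
There is no query planner beyond hash lookups — knowledge bases here are
thousands of objects, not millions.

## Connectivity import

A symmetric matrix yields one directed relation per unordered pair, with
the canonical direction chosen by ascending coordinate identifier;
traversal works in both directions regardless. Storing one edge rather
than two keeps join counts honest. Asymmetric matrices keep both ordered
directions. Diagonal cells are always dropped; distinct coordinates with
identical region labels are retained (coarse parcellations genuinely
contain such pairs). Exact-zero cells default to *kept* for correlation
formats (zero correlation is information) and *dropped* for fiber density
(zero means no tract), overridable via `zero_policy`. Symmetry is checked
to 1e-9.

Functional classification uses the closed bounds exactly as printed:
correlated ≥ 0.5, anticorrelated < 0.0, uncorrelated in between; no
epsilon. The same convention governs the record filters: structural and
functional minima and the DEG maximum are inclusive (≥, ≤), the DEG
minimum is strict (> 200).

## Cross-modal join

Each measured connection's endpoints resolve through coordinate → atlas
entry → brain structure → ontology term. Both endpoint term sets are
expanded to their is-a descendants (`include_self` defaults to true, so a
structure with a direct DEG link and no sub-regions still joins); DEG
links with one endpoint in each expanded set are collected, each unordered
structure pair once, and the DEG average is their arithmetic mean — the
only aggregation that produces fractional averages from integer counts.
Connections with no matched DEG pair are excluded from the join output
(the joined table requires all three modalities; connectivity-only
records remain available via `extract_fbn`). Endpoints with no mapping
chain are skipped with a logged warning rather than an error, since
partial atlas coverage is the normal case.

## Synthetic data

`generate_kb` builds the whole stack from one seed. Defaults are chosen as
the smallest configuration that exercises every mechanism at the scale the
statistical checks need:

| parameter | default | why |
|---|---|---|
| `n_regions` | 21 | 210 region pairs ≥ 200, the size at which the rank association is recovered reliably |
| `coords_per_region` | 1 | one coordinate per parcel; >1 exercises duplicate-label rows |
| `n_substructures` | 2 | DEG links sit strictly below the mapped terms, so the join requires ontology descent |
| `deg_conn_association` | −0.6 | planted Spearman correlation between functional connectivity and DEG |
| `hub_region` / `exception_region` | 0 / 1 | planted maximal-degree node; planted high-structural + high-DEG outlier |
| `n_exception_targets` | 6 | the exception connects strongly to a handful of regions, like a subcortical hub projecting to frontal/temporal targets |

Structural connectivity is uniform on [0.01, 0.55], with hub edges on
[0.75, 0.95] (guaranteeing strictly maximal weighted degree) and exception
edges on [0.3, 0.7]. Functional connectivity is a noisy monotone transform
of structural, `f = −0.25 + 1.3 s + N(0, 0.15)` clipped to [−1, 1] with
the floor raised above zero where `s > 0.4`, so strong tracts only show
positive correlations. The exception region's planted edges override this
transform with low correlations on [0, 0.33]: high fiber density with
near-zero activity correlation is exactly the signature that makes the
region an outlier.

DEG counts are drawn per sub-structure pair through a Gaussian copula
against the rank of the pair's functional connectivity: latent correlation
`2·sin(π·ρ/6)` gives the target Spearman ρ exactly, and counts are rounded
log-normal `exp(3.5 + 0.8 z)` (median ≈ 33). Non-exception counts are
clamped at 200 so that the exception region is, by construction, the
unique source of counts above the strict >200 threshold; exception counts
are uniform integers on [400, 900]. The clamp touches only the far upper
tail (~1% of draws) and has negligible effect on the rank correlation.

What the generator does **not** emulate: anatomical geometry (coordinates
are uniform in a brain-sized box), BOLD time series, probe-level
measurement noise structure, hemispheric symmetry, or realistic atlas
granularity. Passing tests therefore demonstrate the correctness of the
graph construction, query semantics and join/filter arithmetic under
controlled conditions — not neuroscientific validity on real acquisitions.

`generate_expression_fixture` plants a hotspot: the listed genes exceed
the expression threshold (8, the data's native log-intensity scale) with
PACall 1 only at the hotspot structure, with one above-threshold /
PACall-0 decoy per gene elsewhere, so the localized-expression filter
provably needs both conditions.

## Numerical choices and degenerate inputs

* Thresholds are applied exactly as printed, with no epsilon; ties sort by
  identifier for reproducibility.
* Empty inputs are valid everywhere they can be: empty atlases, empty
  mapping tables, empty record sets (the lattice exporter writes a valid
  empty graph), methods without experiments (zero-column tables).
* Annotation and format ranges are inclusive on both sides.
* Graph exports insert nodes and edges in sorted order, so re-export of
  the same records is byte-identical.
* Seeds: one integer drives the whole generator via
  `numpy.random.default_rng`; identical seeds give identical serialized
  knowledge bases.

## Known limitations

* Expression units are treated as the data's native scale; the >8
  threshold is not rescaled.
* Availability tables enumerate bindings by nested loops; pathological
  fan-out (many bindings per path) grows multiplicatively.
* The query language has no universal quantifier and no aggregation;
  aggregations are done on the exported tables.
* External-data reproductions (full averaged connectome matrices, donor
  microarray data) require third-party downloads and are outside the test
  surface; the synthetic generator stands in for them structurally, not
  numerically.
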