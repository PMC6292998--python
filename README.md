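# semconnectome

A semantic-network knowledge base for annotating the human connectome.

Connectomics usually stores brain connectivity as *n×n* matrices: anonymous
weights between parcel indices. `semconnectome` turns those matrices into an
explicit, typed knowledge graph in which every measured brain coordinate is a
semantic object, every measured connection is a directed semantic relation
("connects to" / "is connected from"), and every modality — DTI fiber
density, resting-state fMRI correlation, gene expression, differential
expression — is a measurement attached to an object *or to a relation*.
Because atlases, anatomical ontologies and transcriptome data live in the
same graph, questions that would otherwise require ad-hoc matrix/table
alignment become path queries, e.g. *"all measured coordinates that belong
to a Craddock200 entry that maps to a brain structure that maps to an
ontology term inferred from 'limbic lobe'"*.

It is a library plus a thin CLI, aimed at researchers integrating
multimodal neuroimaging with molecular data at desk scale.

## The model

* **Object kinds.** Five static kinds — element, context, experiment,
  ontology, annotation — from which dynamic object types (`patient`,
  `measured brain coordinates`, `Craddock200`, `probe`, …) are derived.
  Typed, range-checked annotations attach to any object or relation.
* **Relation classes** carry a forward and a backward traversal label
  (a patient *is assessed by* a scan; the scan *assesses* the patient).
  At most one relation instance exists per (class, source, target);
  a relation may itself be the source of further structure.
* **Experiments** are subject-indexed measurement stores: a method fixes a
  subject specification (an object type, or a relation class — this is how
  connections carry per-modality values) and one or more formats with
  hard ranges (correlations in [−1, 1], normalized fiber densities in
  [0, 1], expression values with a PACall validity flag).
* **Three naming layers** join image space to anatomy: coordinates
  *belong to* atlas entries (image parcellation), atlas entries *map to*
  canonical brain structures, structures *map to* ontology terms. The only
  built-in inference is the is-a transitive closure
  (`ontology_descendants`).
* **Queries** are existential condition trees (`Related`, `InContext`,
  `HasEntry`, `OntologyWithin`, `LabelIs`, `IdIs`, and/or/not) evaluated
  over a start type, with deterministic ordering and availability-table
  expansion.
* **Cross-modal join.** For every measured connection with endpoints
  resolving to ontology terms *O* and *T*, all differential-expression
  (DEG) links between descendants(*O*) × descendants(*T*) are averaged —
  connectivity is measured between coarse parcels, DEG between fine
  structures, so without the ontology descent the join is empty.

## Worked example

The 42 published connection records (strong-connectivity / high-DEG tables)
ship with the package and the headline filter — structurally (≥ 0.5) and
functionally (≥ 0.5) connected with at most 10 differentially expressed
genes — can be reproduced in two commands:

```
$ semconnectome tables-fixture --out tables.tsv
wrote 42 records to tables.tsv
$ semconnectome filter --in tables.tsv --min-struct 0.5 --min-func 0.5 --max-deg 10
9 of 42 records pass
```

The nine surviving rows are short-range pairs such as *right cingulate
anterior → right cingulate posterior* (structural 0.63, functional 0.59,
DEG 1.5): strongly wired structures with near-identical expression.

The full pipeline runs on synthetic data with planted structure — a hub
region, a negative rank association between functional connectivity and
DEG count, and one "putamen-like" exception region that is strongly
connected *and* highly differentially expressed:

```
$ semconnectome simulate --seed 7 --out kb.json
wrote knowledge base with 127 instances, 273 relations to kb.json
$ semconnectome xmodal --kb kb.json --out join.tsv
210 joined records; saved to join.tsv
$ semconnectome filter --in join.tsv --min-struct 0.1 --min-deg 200
6 of 210 records pass
```

All six records passing the high-DEG filter touch the planted exception
region, mirroring the localized-exception pattern the filter is designed
to expose. In Python:

```python
import semconnectome as sc
from semconnectome import synthetic as syn

kb = sc.generate_kb(sc.SynthConfig(seed=7))
records = sc.crossmodal_join(kb, syn.SYNTH_ONTOLOGY, syn.SYNTH_ATLAS)
kept = sc.filter_connections(records, min_struct=0.1, min_deg=200)
print(len(records), len(kept))   # 210 6
```

`export-lattice` writes the styled 3D lattice graph (GraphML or JSON
node-link): node positions are MNI millimetres, edge width is structural
connectivity, edge color is functional connectivity binned as correlated
(≥ 0.5), uncorrelated ([0, 0.5)) or anticorrelated (< 0), or the DEG
average.

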