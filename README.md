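# biograph

Link and query biological metadata from heterogeneous datasets as one
knowledge graph.

Biological databases describe the same entities — genes, proteins, diseases,
antigens, epitopes, organisms — under different schemas, formats, and
identifier systems. A question like *"which tumor-antigen genes are
associated with a disease (association score ≥ 0.5) and transcribed into
proteins with disorder content ≥ 0.9?"* cannot be answered in any single
database: it requires joining gene-disease associations, protein disorder
annotations, gene nomenclature, and antigen/epitope catalogs. `biograph`
builds that join as a property graph and makes it queryable.

## The model

Three addressable object kinds plus relations:

- **Entity objects** — one biological (or contextual) thing, keyed by
  `(entity_type, primary_identifier)`, e.g. `gene CDKN1A`,
  `protein P38936`.
- **Identifier objects** — `(kind ∈ {name, url, id}, title, value)` records
  attached to entities by `HAS_ID` edges; one identifier can be shared by
  several entities.
- **Data objects** — non-identifier metadata (disorder content, chromosome
  location, ...) labeled with the source dataset, attached by `HAS_DATA`
  edges.
- **Relations** — labeled, directed, property-carrying edges. Base
  entity-relation vocabulary: `IS`, `IS_INSTANCE`, `IS_VARIANT`, `FROM`,
  `CONTAINS`, `RELATED_WITH` (extensible by higher-level schemas); e.g.
  *gene A* `RELATED_WITH` *disease B* with `{score: 0.9}`.

Every object and relation id is its **content address**: SHA-256 over a
canonical serialization (kind tag + key-sorted fields, UTF-8). Identical
objects arriving from different datasets therefore collapse onto one node,
and re-importing a dataset is a transactional no-op. Writes go through an
embedded graph store plus a catalog database (entry / identifier /
description / import indexers with prefix-tree keyword search), committed
together in one transaction.

Pattern queries are JSON documents with two segments — `match` (typed
aliases and relations between them) and `params` (attribute and
relation-property conditions). Matching is an injective subgraph search;
each matched, possibly branching, result subgraph is decomposed into
edge-disjoint **linear paths** for display and export (minimal on
tree-shaped matches: `o/2` paths for `o` odd-degree vertices).

## Worked example

No downloads are needed: the fixture generator emulates the five dataset
dialects (DisProt-, HGNC-, DisGeNET-, IEDB-, and Tantigen-style files), and
`worked_example` deterministically reconstructs a small cross-dataset
network around the gene CDKN1A.

```sh
biograph fixture --dialect worked_example --out fixtures
for d in disprot hgnc disgenet tantigen iedb; do
  biograph import --importer $d --input fixtures/$d.* --db db
done
biograph stats --db db
```

```
entities: 5
identifiers: 6
data_objects: 5
relations: 15
  CONTAINS: 1
  FROM: 1
  HAS_DATA: 5
  HAS_ID: 6
  IS: 1
  RELATED_WITH: 1
```

Five entities (gene CDKN1A, protein P38936, disease C0038356, antigen
Ag002102, epitope FAWERVRGL) and six identifiers — the protein carries both
its UniProt and DisProt ids, and the gene node created by the HGNC importer
is the same node the DisGeNET importer linked, because both hash to the same
content address.

The cross-dataset query (`biograph.importers.figure_query()`) asks for
disease–gene pairs with association score ≥ 0.5 where the gene's protein has
disorder content ≥ 0.9, the gene is a tumor antigen, and all epitopes of
that antigen:

```sh
python -c 'import json; from biograph.importers import figure_query; \
           json.dump(figure_query(), open("query.json","w"))'
biograph query --db db --query query.json --out results.csv
cat results.csv
```

```
matches: 1
paths: 2
results written to results.csv (csv)
match_index,path_index,element_1,element_2,element_3,element_4,element_5,element_6,element_7
0,0,FAWERVRGL,CONTAINS,Ag002102,IS,CDKN1A,FROM,P38936
0,1,C0038356,RELATED_WITH,CDKN1A
```

One match binds all five entities; its branching subgraph (the gene has
degree 3) is decomposed into two linear paths: epitope → antigen → gene →
protein, and disease → gene. Keyword search runs on the catalog's prefix
trees:

```sh
biograph search --db db --keyword cdkn1a
# gene    CDKN1A    identifier
```

The same operations are available as library functions (`parse_query`,
`execute`, `decompose_paths`, `export_results`, `keyword_search`, ...); the
CLI is a thin shell over them.

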