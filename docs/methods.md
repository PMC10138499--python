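# Methods

This note documents the model, the algorithms, the defaults, and the design
choices made where the design was genuinely open, plus what the synthetic
fixtures do and do not establish about real data.

## Data model and content addressing

The graph holds three node kinds — entity, identifier, data — and relation
edges. An entity is keyed by `(entity_type, primary_identifier)`;
entity types are lower-cased and fields whitespace-trimmed before anything
else happens, because dataset dialects disagree on casing. The primary
identifier of an entity is the identifier most widely shared across
datasets; the importers elect it per dialect (gene → gene symbol, protein →
UniProt accession, disease → UMLS CUI, antigen → Tantigen accession,
epitope → amino-acid sequence, organism → NCBI taxon id).

Object ids are content addresses. The canonical byte form is the JSON
document `[tag, fields]` — `tag` one of `entity` / `identifier` / `data` /
`relation` — serialized with lexicographically sorted keys, compact
separators, UTF-8, NaN/Infinity forbidden; the id is the SHA-256 hex
digest. Consequences, all tested:

- equal content (regardless of payload key order) ⇒ equal id, so the same
  entity arriving from two datasets is one node and re-imports deduplicate;
- the kind tag participates, so objects of different kinds can never
  collide on field values;
- floats serialize in shortest round-trip decimal form (`0.9` and `0.90`
  hash equally). Integers and integral floats remain distinct values
  (`1` ≠ `1.0`); importers parse numeric columns consistently (TSV scores
  always as float), so this never splits nodes in practice.
- relation labels are normalized (upper-case, whitespace → `_`) before
  hashing, giving one canonical spelling (`HAS ID` → `HAS_ID`).

Relations are a fourth addressable kind: they carry properties and need
deduplication exactly like nodes. Self-relations are rejected for every
label; no label in the base vocabulary admits them and no mechanism is
provided to declare one that does.

## Storage and transactions

The embedded backend is an in-memory adjacency structure implementing a
small `GraphDatabaseAdapter` contract (`Neo4jAdapter` is an explicit
unimplemented stub marking where a server-backed adapter would plug in).
Durability is a JSON-lines snapshot — header, then nodes and edges sorted by
id, so equal stores produce byte-identical files; a `.gz` suffix selects a
gzip variant. Snapshot reading re-validates every record (content address
recomputed, endpoints resolved) and reports corruption with the line
number.

Writes happen only inside a single-writer transaction; reads observe
committed state. The catalog joins the graph transaction, so one
`commit`/`rollback` covers both: sqlite commit/rollback rides along, and
the in-memory tries are updated from a buffer only at commit. A crash
between the graph apply and the catalog commit is not recovered — a real
two-phase protocol is out of scope; within one process the two cannot
drift, which is what the fault-injection tests establish.

The catalog's durable form is sqlite (entry log, token posting tables,
import log). The posting tables are the serialized form of the prefix
trees; the tries are rebuilt from them on open.

## Keyword search

Tokenization: lower-case, split on any non-alphanumeric, tokens of length
≥ 2 indexed; identifier values are additionally indexed verbatim
(lower-cased) so exact id lookup (`C0038356`) works alongside word search
(`pneumonia`). Search modes are `exact` and `prefix` over the trie; infix
search is deliberately out of scope (a prefix tree cannot serve it
directly). Hits from the identifier and description indexes are unioned,
optionally filtered by entity type, and sorted by id. There is no ranking.

String payload values of data objects are description-indexed under their
owning entity, which is how a disease imported with the name
"Pneumonia, Bacterial" becomes findable by the keyword `pneumonia`.

## Query language and matching

The JSON grammar has exactly two top-level keys. `match` entries declare
typed node aliases (`{"alias": "type"}` on first occurrence, plain string
afterwards) and one relation each (`relation` label or `ANY`; `direction`
`out` — the stored direction — or `any`; optional edge `alias`). `params`
attaches conditions: targets `primary_id`, `identifier`,
`data.<source_label>.<key>` on nodes and `prop.<key>` on edges; ops `eq`,
`ne`, `gt`, `gte`, `lt`, `lte`, `contains`. Patterns must be connected,
aliases consistent, ordering ops numeric. Both strict and inclusive
threshold ops exist because both readings of "greater than" appear in
practice; the shipped example query uses `gte`.

Condition semantics: `primary_id` tests the primary identifier only;
`identifier` tests the primary identifier plus all `HAS_ID`-linked values;
`data.*` resolves through `HAS_DATA` objects with the matching source
label. A condition is true if *any* candidate value satisfies it; a missing
attribute is simply false, never an error; an ordering op against a
non-numeric stored value is false with a logged warning. String equality
and `contains` are case-insensitive.

Matching is an injective homomorphism — distinct node aliases bind distinct
entities, distinct pattern edges bind distinct stored relations — because a
drawn query shows distinct boxes for distinct biological entities. (Whether
a non-injective reading is ever wanted is an open modeling question; the
injective one is the documented, tested contract.) The search backtracks
most-constrained-alias-first over pre-filtered candidate sets, pruning on
edge existence; after a complete node binding, edges are assigned to
distinct stored relations. Results are sorted by binding tuple, so repeated
runs produce byte-identical exports. Correctness is established against
exhaustive injective-assignment enumeration on random instances (stores of
up to 40 entities, patterns of up to 5 aliases — sizes chosen so the
brute-force oracle itself stays exact and cheap).

## Linear disjoint path decomposition

Matched subgraphs are often branching; for display and CSV export they are
decomposed into edge-disjoint paths whose union is exactly the matched edge
set. Algorithm: while edges remain, start at the smallest-id odd-degree
vertex (smallest-id positive-degree vertex if none) and walk greedily,
always taking the smallest-id unused incident edge, until stuck; emit the
trail. A maximal trail from an odd vertex ends at another odd vertex, so
each peel removes two odd vertices; in a tree the even-degree remainder is
empty, giving exactly `o/2` paths — the minimum, which the tests confirm
against an exhaustive path-cover search (memoized over edge subsets, trees
up to 12 edges). Cyclic patterns are accepted: remainders peel as closed
trails, preserving coverage and disjointness without the tree-minimality
guarantee. Paths may share vertices; only edges are disjoint.

## Importers and fixtures

Importers drive a five-method contract (`begin_import`, `map_entity`,
`map_identifier`/`map_data`, `map_relation`, `finish_import`) and never
touch storage directly; every mapped object flows through content
addressing, dedup, both databases, and one transaction. Structural input
failures abort (rollback, nothing persisted — including the import-log
row); malformed records are skipped with a logged warning, so
`records mapped + records skipped = records read` always holds. Field and
column names are resolved through per-dialect mapping configs (shipped
defaults, overridable per call), since real releases rename columns.

Edge directions follow the vocabulary's reading: protein `FROM` gene, gene
`FROM` organism (and epitope `FROM` its source organism), antigen
`CONTAINS` epitope, gene `IS` antigen, gene `RELATED_WITH` disease carrying
`{score}`.

The fixture generator stands in for live downloads. `worked_example`
deterministically reconstructs the CDKN1A network: 1 record per dialect,
disorder content 0.9, association score 0.9, yielding 5 entities and 6
identifiers (UniProt + DisProt on the protein, gene name + NCBI id on the
gene, UMLS CUI on the disease, Tantigen id on the antigen; the epitope's
sequence is its primary identifier only, and no organism appears). Random
mode writes `n` records per dialect, reproducible from a seed: entity names
come from shared pools with a configurable cross-dialect overlap rate
(default 0.3, enough that joins occur regularly at fixture sizes) and
disease names cycle round-robin through a 10-disease pool that includes a
bacterial-pneumonia entry, so keyword-search behavior is exercised
deterministically for any seed once `n ≥ 10`.

What the fixtures do **not** emulate: real release schemas (field names are
close but simplified), data volume (the real datasets carry millions of
rows; fixtures are desk-scale, so no performance claims follow), dirty
real-world values (encoding noise, partial duplicates differing only in
formatting), and cross-release identifier drift. Passing tests therefore
establish the correctness of the model, the dedup semantics, and the query
algebra — not throughput or schema coverage for any particular dataset
release.

## Numerical and degenerate-input choices

- Scores and disorder contents are stored as parsed floats; values outside
  [0, 1] are stored as-is with a warning (the model records dataset values,
  it does not repair them).
- All listings, search results, and exports sort by object id; ties in the
  decomposition break by smallest id. There is no other tie-breaking state.
- Empty stores, empty imports (header-only files), empty query results, and
  punctuation-only descriptions are all valid no-ops, not errors.
- Non-finite floats are rejected at validation time (they have no canonical
  JSON form).

## Known limitations

- Single-writer concurrency; no crash recovery between graph and catalog
  commits (documented above).
- No ranking, fuzzy, infix, or semantic search; no query optimizer beyond
  most-constrained-first ordering; no Cypher/SPARQL translation; no natural
  language queries; no ontology alignment (RDF/OBO/Biolink) — the generic
  model is the point, schema semantics belong to higher layers.
- The in-memory backend targets desk-scale graphs (fixture- to
  million-object range depending on RAM); larger deployments would
  implement the adapter contract against a server-backed graph database.
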