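"""Random-instance generators for validating the matcher, indexes and store.

These build small, fully in-memory databases, query patterns, and keyword
corpora from a seeded :class:`random.Random`, mirroring the structure of the
imported datasets (typed entities, shared identifiers, numeric data
attributes, scored relations). They are used by the test suite and the
reproduction script, where their output is compared against brute-force
oracles.
"""

from __future__ import annotations

import random
import string
from typing import Sequence

from .model import make_data, make_entity, make_identifier
from .service import BioGraphDB

ENTITY_TYPES = ("gene", "protein", "disease", "antigen", "epitope", "organism")

#: Typed relation templates (label, source type, target type) mirroring how
#: the dataset importers wire entities together.
RELATION_TEMPLATES = (
    ("RELATED_WITH", "gene", "disease"),
    ("FROM", "protein", "gene"),
    ("FROM", "protein", "organism"),
    ("IS", "gene", "antigen"),
    ("CONTAINS", "antigen", "epitope"),
    ("IS_VARIANT", "protein", "protein"),
)


def _name(rng: random.Random, prefix: str) -> str:
    return prefix + "".join(rng.choice(string.ascii_uppercase + string.digits) for _ in range(6))


def random_store(rng: random.Random, max_entities: int = 40) -> BioGraphDB:
    """A random in-memory database with typed entities, shared identifiers,
    numeric data attributes, and scored typed relations."""
    db = BioGraphDB.open(None)
    service = db.service
    service.begin_import("synthetic")

    n_entities = rng.randint(4, max_entities)
    entities_by_type: dict[str, list] = {t: [] for t in ENTITY_TYPES}
    for i in range(n_entities):
        entity_type = rng.choice(ENTITY_TYPES)
        entity = make_entity(entity_type, _name(rng, entity_type[:2].upper()))
        service.map_entity(entity)
        entities_by_type[entity_type].append(entity)
        if rng.random() < 0.5:
            service.map_identifier(
                make_identifier("id", f"{entity_type} accession", _name(rng, "ID")), entity
            )
        if entity_type == "protein" and rng.random() < 0.7:
            service.map_data(
                make_data("disprot", {"disorder_content": round(rng.uniform(0, 1), 2)}),
                entity,
            )
        elif rng.random() < 0.3:
            service.map_data(
                make_data("synthetic", {"weight": round(rng.uniform(0, 10), 2)}), entity
            )

    # a shared identifier across two entities of the same type, when possible
    for type_entities in entities_by_type.values():
        if len(type_entities) >= 2 and rng.random() < 0.5:
            shared = make_identifier("name", "shared alias", _name(rng, "AL"))
            service.map_identifier(shared, type_entities[0])
            service.map_identifier(shared, type_entities[1])
            break

    n_edges = rng.randint(0, 2 * n_entities)
    for _ in range(n_edges):
        label, source_type, target_type = rng.choice(RELATION_TEMPLATES)
        sources = entities_by_type[source_type]
        targets = entities_by_type[target_type]
        if not sources or not targets:
            continue
        source = rng.choice(sources)
        target = rng.choice(targets)
        if source == target:
            continue
        props = {"score": round(rng.uniform(0, 1), 2)} if rng.random() < 0.6 else {}
        service.map_relation(label, source, target, props)

    service.finish_import()
    return db


def random_pattern(rng: random.Random, db: BioGraphDB, max_nodes: int = 5) -> dict:
    """A random connected query document over ``db``'s schema.

    Biased toward patterns grown from stored edges (so nonempty results are
    common), with occasional label/threshold scrambling to exercise the empty
    and over-constrained cases.
    """
    store = db.store
    stored_edges = [
        (edge_id, relation)
        for edge_id, relation in store.iter_edges()
        if relation.label not in ("HAS_ID", "HAS_DATA")
    ]
    types_present = sorted({obj.entity_type for _, obj in store.iter_nodes("entity")}) or ["gene"]

    aliases: dict[str, str] = {}  # alias -> entity type
    hints: dict[str, str] = {}  # alias -> entity id it was grown from
    match: list[dict] = []
    counter = 0

    def new_alias(entity_type: str, hint: str | None) -> str:
        nonlocal counter
        alias = f"n{counter}"
        counter += 1
        aliases[alias] = entity_type
        if hint is not None:
            hints[alias] = hint
        return alias

    def entity_type_of(object_id: str) -> str:
        return store.get(object_id)[1].entity_type

    if stored_edges and rng.random() < 0.8:
        _, relation = rng.choice(stored_edges)
        a = new_alias(entity_type_of(relation.source_id), relation.source_id)
        b = new_alias(entity_type_of(relation.target_id), relation.target_id)
        match.append(
            {
                "from": {a: aliases[a]},
                "relation": relation.label if rng.random() < 0.7 else "ANY",
                "to": {b: aliases[b]},
                "direction": "out" if rng.random() < 0.7 else "any",
            }
        )
        target_nodes = rng.randint(2, max_nodes)
        while len(aliases) < target_nodes:
            grown = [alias for alias in aliases if alias in hints]
            if not grown:
                break
            base = rng.choice(grown)
            incident = [
                relation
                for _, relation in stored_edges
                if hints[base] in (relation.source_id, relation.target_id)
            ]
            if not incident:
                break
            relation = rng.choice(incident)
            outward = relation.source_id == hints[base]
            other_id = relation.target_id if outward else relation.source_id
            other = new_alias(entity_type_of(other_id), other_id)
            entry = {
                "from": base if outward else other,
                "relation": relation.label if rng.random() < 0.7 else "ANY",
                "to": other if outward else base,
                "direction": "out" if rng.random() < 0.7 else "any",
            }
            for key in ("from", "to"):
                alias = entry[key]
                if alias == other:
                    entry[key] = {other: aliases[other]}
            match.append(entry)
    else:
        a = new_alias(rng.choice(types_present), None)
        b = new_alias(rng.choice(types_present), None)
        match.append(
            {
                "from": {a: aliases[a]},
                "relation": "ANY",
                "to": {b: aliases[b]},
                "direction": "any",
            }
        )

    for index, entry in enumerate(match):
        entry["alias"] = f"e{index}"

    params: dict[str, list] = {}
    for index, entry in enumerate(match):
        if rng.random() < 0.3:
            params[f"e{index}"] = [
                {
                    "target": "prop.score",
                    "op": rng.choice(["gt", "gte", "lt", "lte"]),
                    "value": round(rng.uniform(0, 1), 2),
                }
            ]
    for alias, entity_type in aliases.items():
        roll = rng.random()
        if roll < 0.15 and alias in hints:
            primary = store.get(hints[alias])[1].primary_identifier
            fragment = primary[: rng.randint(2, len(primary))]
            params.setdefault(alias, []).append(
                {"target": "identifier", "op": "contains", "value": fragment}
            )
        elif roll < 0.3 and entity_type == "protein":
            params.setdefault(alias, []).append(
                {
                    "target": "data.disprot.disorder_content",
                    "op": "gte",
                    "value": round(rng.uniform(0, 1), 2),
                }
            )

    return {"match": match, "params": params}


def random_tree_edges(rng: random.Random, max_edges: int = 12) -> list[tuple[str, str, str]]:
    """A random tree as ``(edge_id, source, target)`` triples over synthetic
    64-hex-looking ids (ids only need to be distinct and sortable)."""
    n_edges = rng.randint(1, max_edges)
    node_ids = [f"{rng.getrandbits(256):064x}" for _ in range(n_edges + 1)]
    edges = []
    for index in range(1, n_edges + 1):
        parent = rng.randrange(index)
        edges.append((f"{rng.getrandbits(256):064x}", node_ids[parent], node_ids[index]))
    return edges


def random_corpus(
    rng: random.Random, max_tokens: int = 30
) -> list[tuple[str, str]]:
    """Random (token, object_id) pairs for trie-vs-scan comparisons."""
    alphabet = string.ascii_lowercase[:6] + "0123"
    pairs = []
    for _ in range(rng.randint(0, max_tokens)):
        token = "".join(rng.choice(alphabet) for _ in range(rng.randint(1, 8)))
        object_id = f"{rng.getrandbits(64):016x}"
        pairs.append((token, object_id))
    return pairs


def random_query_terms(rng: random.Random, corpus: Sequence[tuple[str, str]], k: int = 8):
    """Query terms mixing existing tokens, their prefixes, and random noise."""
    alphabet = string.ascii_lowercase[:6] + "0123"
    terms = []
    for _ in range(k):
        roll = rng.random()
        if corpus and roll < 0.4:
            terms.append(rng.choice(corpus)[0])
        elif corpus and roll < 0.7:
            token = rng.choice(corpus)[0]
            terms.append(token[: rng.randint(1, len(token))])
        else:
            terms.append("".join(rng.choice(alphabet) for _ in range(rng.randint(1, 6))))
    return terms
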