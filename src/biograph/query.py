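"""Pattern-query language: parsing, matching, and linear-path decomposition.

A query is a JSON document with exactly two segments:

``match``
    A list of relation entries between typed entity aliases, e.g.::

        {"from": {"gene": "gene"}, "relation": "RELATED_WITH",
         "to": {"disease": "disease"}, "alias": "gd", "direction": "out"}

    ``from``/``to`` either declare an alias (one-pair object
    ``{alias: entity_type}``) or reference one declared elsewhere (plain
    string). ``relation`` is a relation label or ``"ANY"``; ``direction`` is
    ``"out"`` (stored direction, the default) or ``"any"``; ``alias`` names
    the edge for conditions (auto-named ``_e0``, ``_e1``, ... otherwise).

``params``
    Conditions per alias: ``{"target": ..., "op": ..., "value": ...}`` where
    the target is ``primary_id``, ``identifier``,
    ``data.<source_label>.<key>`` (node aliases), or ``prop.<key>`` (edge
    aliases), and op is one of eq, ne, gt, gte, lt, lte, contains.

Matching is an injective homomorphism: distinct node aliases bind distinct
entities (graphical queries draw distinct boxes for distinct biological
entities) and distinct pattern edges bind distinct stored relations. Each
matched, possibly branching, subgraph is decomposed into edge-disjoint linear
paths; on tree-shaped matches the decomposition is minimal (``o/2`` paths for
``o`` odd-degree vertices).
"""

from __future__ import annotations

import csv
import json
import logging
import numbers
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import networkx as nx

from .errors import QueryParseError, ValidationError
from .model import (
    STRUCTURAL_LABELS,
    EntityObject,
    ObjectID,
    Relation,
    Scalar,
    normalize_relation_label,
)
from .store import GraphStore

logger = logging.getLogger(__name__)

ANY_LABEL = "ANY"
CONDITION_OPS = ("eq", "ne", "gt", "gte", "lt", "lte", "contains")
ORDERING_OPS = frozenset({"gt", "gte", "lt", "lte"})
NODE_TARGETS = ("primary_id", "identifier")  # plus data.<source>.<key>


def _is_number(value: Any) -> bool:
    return isinstance(value, numbers.Real) and not isinstance(value, bool)


@dataclass(frozen=True)
class Condition:
    """One attribute filter attached to a node or edge alias."""

    target: str
    op: str
    value: Scalar

    @property
    def target_kind(self) -> str:
        head = self.target.split(".", 1)[0]
        return head  # primary_id | identifier | data | prop

    @property
    def data_source(self) -> str:
        return self.target.split(".", 2)[1]

    @property
    def key(self) -> str:
        parts = self.target.split(".", 2)
        return parts[-1]

    def as_dict(self) -> dict:
        return {"target": self.target, "op": self.op, "value": self.value}


@dataclass(frozen=True)
class EdgeSpec:
    """One ``match`` entry: a relation between two node aliases."""

    from_alias: str
    label: str  # normalized label or ANY
    to_alias: str
    direction: str = "out"  # out | any
    alias: str = ""


@dataclass(frozen=True)
class QueryPattern:
    """A validated, connected query pattern."""

    nodes: tuple[tuple[str, str], ...]  # (alias, entity_type), declaration order
    edges: tuple[EdgeSpec, ...]
    conditions: tuple[tuple[str, tuple[Condition, ...]], ...]

    @property
    def node_types(self) -> dict[str, str]:
        return dict(self.nodes)

    @property
    def conditions_by_alias(self) -> dict[str, tuple[Condition, ...]]:
        return dict(self.conditions)


def _parse_endpoint(
    raw: Any, declared: dict[str, str], entry_index: int
) -> str:
    where = f"match[{entry_index}]"
    if isinstance(raw, str):
        alias = raw.strip()
        if not alias:
            raise QueryParseError(f"{where}: empty alias")
        return alias
    if isinstance(raw, Mapping):
        if len(raw) != 1:
            raise QueryParseError(
                f"{where}: endpoint must be a single {{alias: entity_type}} pair"
            )
        ((alias, entity_type),) = raw.items()
        alias = str(alias).strip()
        entity_type = str(entity_type).strip().lower()
        if not alias or not entity_type:
            raise QueryParseError(f"{where}: alias and entity_type must be non-empty")
        if alias in declared and declared[alias] != entity_type:
            raise QueryParseError(
                f"{where}: alias {alias!r} redeclared as {entity_type!r} "
                f"(was {declared[alias]!r})"
            )
        declared[alias] = entity_type
        return alias
    raise QueryParseError(f"{where}: endpoint must be an alias string or {{alias: type}} object")


def _parse_condition(alias: str, raw: Any, node_aliases: set, edge_aliases: set) -> Condition:
    where = f"params[{alias!r}]"
    if not isinstance(raw, Mapping):
        raise QueryParseError(f"{where}: condition must be an object")
    unknown = set(raw) - {"target", "op", "value"}
    if unknown:
        raise QueryParseError(f"{where}: unknown condition keys {sorted(unknown)}")
    for required in ("target", "op", "value"):
        if required not in raw:
            raise QueryParseError(f"{where}: condition is missing {required!r}")
    target, op, value = str(raw["target"]), str(raw["op"]), raw["value"]
    if op not in CONDITION_OPS:
        raise QueryParseError(
            f"{where}: unknown op {op!r}; allowed ops: {', '.join(CONDITION_OPS)}"
        )
    parts = target.split(".")
    if parts[0] == "prop":
        if len(parts) != 2 or not parts[1]:
            raise QueryParseError(f"{where}: prop target must be prop.<key>")
        if alias not in edge_aliases:
            raise QueryParseError(f"{where}: prop.* conditions apply to edge aliases only")
    elif parts[0] == "data":
        if len(parts) != 3 or not parts[1] or not parts[2]:
            raise QueryParseError(f"{where}: data target must be data.<source_label>.<key>")
        if alias not in node_aliases:
            raise QueryParseError(f"{where}: data.* conditions apply to node aliases only")
    elif target in NODE_TARGETS:
        if alias not in node_aliases:
            raise QueryParseError(f"{where}: {target} conditions apply to node aliases only")
    else:
        raise QueryParseError(
            f"{where}: unknown target {target!r}; expected primary_id, identifier, "
            "data.<source_label>.<key>, or prop.<key>"
        )
    if op in ORDERING_OPS and not _is_number(value):
        raise QueryParseError(f"{where}: op {op!r} requires a numeric value, got {value!r}")
    if op == "contains" and not isinstance(value, str):
        raise QueryParseError(f"{where}: op 'contains' requires a string value")
    if not isinstance(value, (str, int, float, bool)):
        raise QueryParseError(f"{where}: value must be a scalar")
    return Condition(target, op, value)


def parse_query(document: str | Mapping) -> QueryPattern:
    """Parse and validate a query document (JSON text or mapping)."""
    if isinstance(document, str):
        try:
            document = json.loads(document)
        except json.JSONDecodeError as exc:
            raise QueryParseError(
                f"malformed JSON at line {exc.lineno} column {exc.colno}: {exc.msg}"
            ) from exc
    if not isinstance(document, Mapping):
        raise QueryParseError("query document must be a JSON object")
    unknown = set(document) - {"match", "params"}
    if unknown:
        raise QueryParseError(f"unknown top-level keys {sorted(unknown)}; allowed: match, params")
    match = document.get("match")
    if not isinstance(match, list) or not match:
        raise QueryParseError("'match' must be a non-empty list of relation entries")

    declared: dict[str, str] = {}
    edges: list[EdgeSpec] = []
    edge_aliases: set[str] = set()
    for index, entry in enumerate(match):
        where = f"match[{index}]"
        if not isinstance(entry, Mapping):
            raise QueryParseError(f"{where}: entry must be an object")
        unknown = set(entry) - {"from", "relation", "to", "alias", "direction"}
        if unknown:
            raise QueryParseError(f"{where}: unknown keys {sorted(unknown)}")
        if "from" not in entry or "to" not in entry:
            raise QueryParseError(f"{where}: entry requires 'from' and 'to'")
        from_alias = _parse_endpoint(entry["from"], declared, index)
        to_alias = _parse_endpoint(entry["to"], declared, index)
        if from_alias == to_alias:
            raise QueryParseError(f"{where}: self-relation pattern {from_alias!r}->{to_alias!r}")
        raw_label = str(entry.get("relation", ANY_LABEL)).strip()
        label = ANY_LABEL if raw_label.upper() == ANY_LABEL else normalize_relation_label(raw_label)
        if not label:
            raise QueryParseError(f"{where}: empty relation label")
        direction = str(entry.get("direction", "out")).strip().lower()
        if direction not in ("out", "any"):
            raise QueryParseError(f"{where}: direction must be 'out' or 'any'")
        alias = str(entry.get("alias", f"_e{index}")).strip()
        if not alias:
            raise QueryParseError(f"{where}: empty edge alias")
        if alias in edge_aliases:
            raise QueryParseError(f"{where}: duplicate edge alias {alias!r}")
        edge_aliases.add(alias)
        edges.append(EdgeSpec(from_alias, label, to_alias, direction, alias))

    for spec in edges:
        for alias in (spec.from_alias, spec.to_alias):
            if alias not in declared:
                raise QueryParseError(
                    f"alias {alias!r} is referenced but never declared with an entity type"
                )
    clash = set(declared) & edge_aliases
    if clash:
        raise QueryParseError(f"aliases used for both nodes and edges: {sorted(clash)}")

    alias_graph = nx.Graph()
    alias_graph.add_nodes_from(declared)
    alias_graph.add_edges_from((spec.from_alias, spec.to_alias) for spec in edges)
    if len(declared) > 1 and not nx.is_connected(alias_graph):
        raise QueryParseError("pattern must be connected")

    params = document.get("params", {})
    if not isinstance(params, Mapping):
        raise QueryParseError("'params' must be an object mapping alias -> conditions")
    conditions: list[tuple[str, tuple[Condition, ...]]] = []
    node_aliases = set(declared)
    for alias, raw_conditions in params.items():
        if alias not in node_aliases and alias not in edge_aliases:
            raise QueryParseError(f"params references unknown alias {alias!r}")
        if not isinstance(raw_conditions, list):
            raise QueryParseError(f"params[{alias!r}] must be a list of conditions")
        parsed = tuple(
            _parse_condition(alias, raw, node_aliases, edge_aliases) for raw in raw_conditions
        )
        if parsed:
            conditions.append((alias, parsed))
    conditions.sort(key=lambda item: item[0])

    return QueryPattern(tuple(declared.items()), tuple(edges), tuple(conditions))


def serialize_pattern(pattern: QueryPattern) -> dict:
    """The JSON-able document form of a pattern; re-parsing yields an equal
    pattern."""
    types = pattern.node_types
    seen: set[str] = set()

    def endpoint(alias: str):
        if alias in seen:
            return alias
        seen.add(alias)
        return {alias: types[alias]}

    match = []
    for spec in pattern.edges:
        match.append(
            {
                "from": endpoint(spec.from_alias),
                "relation": spec.label,
                "to": endpoint(spec.to_alias),
                "alias": spec.alias,
                "direction": spec.direction,
            }
        )
    params = {
        alias: [condition.as_dict() for condition in conditions]
        for alias, conditions in pattern.conditions
    }
    return {"match": match, "params": params}


def save_query(pattern: QueryPattern, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(serialize_pattern(pattern), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )


def load_query(path: str | Path) -> QueryPattern:
    return parse_query(Path(path).read_text(encoding="utf-8"))


# -- condition evaluation ----------------------------------------------------


def _candidate_values(condition: Condition, subject_id: ObjectID, store: GraphStore) -> list:
    kind, obj = store.get(subject_id)
    target_kind = condition.target_kind
    if target_kind == "prop":
        if kind != "relation":
            return []
        value = obj.props.get(condition.key)
        return [] if value is None else [value]
    if kind != "entity":
        return []
    if target_kind == "primary_id":
        return [obj.primary_identifier]
    if target_kind == "identifier":
        values = [obj.primary_identifier]
        for relation, neighbor in store.neighbors(subject_id, label="HAS_ID", direction="out"):
            values.append(neighbor.value)
        return values
    if target_kind == "data":
        values = []
        for relation, neighbor in store.neighbors(subject_id, label="HAS_DATA", direction="out"):
            if neighbor.source_label == condition.data_source and condition.key in neighbor.payload:
                values.append(neighbor.payload[condition.key])
        return values
    return []


def _compare(op: str, stored: Scalar, wanted: Scalar) -> bool:
    if op in ORDERING_OPS:
        if not _is_number(stored):
            logger.warning(
                "ordering op %r against non-numeric stored value %r evaluates false", op, stored
            )
            return False
        return {
            "gt": stored > wanted,
            "gte": stored >= wanted,
            "lt": stored < wanted,
            "lte": stored <= wanted,
        }[op]
    if op == "contains":
        return isinstance(stored, str) and wanted.casefold() in stored.casefold()
    # eq / ne: strings compare case-insensitively, numbers numerically
    if isinstance(stored, str) and isinstance(wanted, str):
        equal = stored.casefold() == wanted.casefold()
    elif _is_number(stored) and _is_number(wanted):
        equal = stored == wanted
    elif isinstance(stored, bool) and isinstance(wanted, bool):
        equal = stored == wanted
    else:
        equal = False
    return equal if op == "eq" else not equal


def evaluate_condition(
    condition: Condition,
    subject_id: ObjectID,
    store: GraphStore,
    catalog=None,
) -> bool:
    """True if any candidate attribute value satisfies the condition.

    A missing attribute never errors: it simply yields no candidate values and
    the condition evaluates false.
    """
    values = _candidate_values(condition, subject_id, store)
    return any(_compare(condition.op, value, condition.value) for value in values)


# -- pattern matching --------------------------------------------------------


@dataclass
class MatchResult:
    """One injective binding of pattern aliases to stored objects."""

    binding: dict[str, ObjectID]  # node alias -> entity id
    edge_binding: dict[str, ObjectID]  # edge alias -> relation id
    nodes: dict[ObjectID, EntityObject] = field(default_factory=dict)
    edges: dict[ObjectID, Relation] = field(default_factory=dict)

    def sort_key(self) -> tuple:
        return (
            tuple(self.binding[a] for a in sorted(self.binding)),
            tuple(self.edge_binding[a] for a in sorted(self.edge_binding)),
        )


def _edge_candidates(
    spec: EdgeSpec,
    source_id: ObjectID,
    target_id: ObjectID,
    store: GraphStore,
    conditions: Sequence[Condition],
) -> list[ObjectID]:
    """Stored relation ids that can realize a pattern edge between two bound
    entities."""
    out: list[ObjectID] = []
    directed_pairs = [(source_id, target_id)]
    if spec.direction == "any":
        directed_pairs.append((target_id, source_id))
    for src, dst in directed_pairs:
        for edge_id in store._backend.out_edge_ids(src):
            relation = store._backend.edge(edge_id)
            if relation.target_id != dst:
                continue
            if relation.label in STRUCTURAL_LABELS:
                continue
            if spec.label != ANY_LABEL and relation.label != spec.label:
                continue
            if all(evaluate_condition(c, edge_id, store) for c in conditions):
                out.append(edge_id)
    return sorted(set(out))


def execute(pattern: QueryPattern, store: GraphStore, catalog=None) -> list[MatchResult]:
    """All injective matches of the pattern, deterministically ordered.

    Backtracking search binds the most-constrained alias first (fewest
    remaining candidates among aliases adjacent to the bound part); after a
    complete node binding, pattern edges are assigned to distinct stored
    relations.
    """
    types = pattern.node_types
    cond_by_alias = pattern.conditions_by_alias

    candidates: dict[str, list[ObjectID]] = {}
    for alias, entity_type in types.items():
        conds = cond_by_alias.get(alias, ())
        candidates[alias] = [
            object_id
            for object_id, obj in store.iter_nodes("entity")
            if obj.entity_type == entity_type
            and all(evaluate_condition(c, object_id, store) for c in conds)
        ]

    adjacency: dict[str, list[EdgeSpec]] = {alias: [] for alias in types}
    for spec in pattern.edges:
        adjacency[spec.from_alias].append(spec)
        adjacency[spec.to_alias].append(spec)

    results: list[MatchResult] = []
    binding: dict[str, ObjectID] = {}

    def assign_edges(index: int, used: set[ObjectID], edge_binding: dict[str, ObjectID]) -> None:
        if index == len(pattern.edges):
            result = MatchResult(dict(binding), dict(edge_binding))
            for object_id in result.binding.values():
                result.nodes[object_id] = store.get(object_id)[1]
            for object_id in result.edge_binding.values():
                result.edges[object_id] = store.get(object_id)[1]
            results.append(result)
            return
        spec = pattern.edges[index]
        options = _edge_candidates(
            spec,
            binding[spec.from_alias],
            binding[spec.to_alias],
            store,
            cond_by_alias.get(spec.alias, ()),
        )
        for edge_id in options:
            if edge_id in used:
                continue
            edge_binding[spec.alias] = edge_id
            assign_edges(index + 1, used | {edge_id}, edge_binding)
            del edge_binding[spec.alias]

    def extend() -> None:
        if len(binding) == len(types):
            assign_edges(0, set(), {})
            return
        unbound = [alias for alias in types if alias not in binding]
        if binding:
            frontier = [
                alias
                for alias in unbound
                if any(
                    (spec.from_alias in binding or spec.to_alias in binding)
                    for spec in adjacency[alias]
                )
            ] or unbound
        else:
            frontier = unbound
        alias = min(frontier, key=lambda a: (len(candidates[a]), a))
        bound_ids = set(binding.values())
        for object_id in candidates[alias]:
            if object_id in bound_ids:
                continue
            binding[alias] = object_id
            ok = True
            for spec in adjacency[alias]:
                other = spec.to_alias if spec.from_alias == alias else spec.from_alias
                if other not in binding:
                    continue
                if not _edge_candidates(
                    spec,
                    binding[spec.from_alias],
                    binding[spec.to_alias],
                    store,
                    cond_by_alias.get(spec.alias, ()),
                ):
                    ok = False
                    break
            if ok:
                extend()
            del binding[alias]

    extend()
    results.sort(key=MatchResult.sort_key)
    return results


# -- linear disjoint path decomposition --------------------------------------


@dataclass(frozen=True)
class LinearPath:
    """An alternating entity-relation-...-entity walk without repeated edges."""

    node_ids: tuple[ObjectID, ...]
    edge_ids: tuple[ObjectID, ...]

    def __len__(self) -> int:
        return len(self.edge_ids)


def decompose_paths(match: MatchResult) -> list[LinearPath]:
    """Edge-disjoint linear paths exactly covering the matched subgraph.

    Paths are peeled as maximal trails starting at odd-degree vertices (ties
    broken by smallest ObjectID at every choice point); for tree-shaped
    subgraphs this attains the minimum cover size ``o/2`` where ``o`` is the
    number of odd-degree vertices. Cyclic remainders are peeled as closed
    trails (coverage and edge-disjointness hold; tree minimality does not
    apply).
    """
    incident: dict[ObjectID, list[tuple[ObjectID, ObjectID]]] = {}
    for edge_id, relation in match.edges.items():
        incident.setdefault(relation.source_id, []).append((edge_id, relation.target_id))
        incident.setdefault(relation.target_id, []).append((edge_id, relation.source_id))
    remaining = set(match.edges)
    paths: list[LinearPath] = []

    def degree(node_id: ObjectID) -> int:
        return sum(1 for edge_id, _ in incident.get(node_id, ()) if edge_id in remaining)

    while remaining:
        odd = sorted(n for n in incident if degree(n) % 2 == 1)
        if odd:
            start = odd[0]
        else:
            start = min(n for n in incident if degree(n) > 0)
        node_ids = [start]
        edge_ids = []
        current = start
        while True:
            options = sorted(
                (edge_id, other)
                for edge_id, other in incident.get(current, ())
                if edge_id in remaining
            )
            if not options:
                break
            edge_id, other = options[0]
            remaining.discard(edge_id)
            edge_ids.append(edge_id)
            node_ids.append(other)
            current = other
        paths.append(LinearPath(tuple(node_ids), tuple(edge_ids)))
    return paths


# -- result export -----------------------------------------------------------


def export_results(
    matches: Sequence[MatchResult], format: str, path: str | Path
) -> None:
    """Write matches to ``path`` as CSV (one row per match/path) or JSON.

    CSV rows carry ``match_index``, ``path_index``, then the path's
    alternating entity primary identifiers and relation labels. JSON mirrors
    the full binding structure and round-trips via :func:`load_results_json`.
    Output is byte-deterministic for a given result list.
    """
    path = Path(path)
    if format == "csv":
        rows = []
        for match_index, match in enumerate(matches):
            for path_index, linear in enumerate(decompose_paths(match)):
                cells: list[str] = [str(match_index), str(path_index)]
                for position, node_id in enumerate(linear.node_ids):
                    cells.append(match.nodes[node_id].primary_identifier)
                    if position < len(linear.edge_ids):
                        cells.append(match.edges[linear.edge_ids[position]].label)
                rows.append(cells)
        width = max((len(row) - 2 for row in rows), default=0)
        header = ["match_index", "path_index"] + [f"element_{i + 1}" for i in range(width)]
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(header)
            writer.writerows(rows)
    elif format == "json":
        documents = []
        for match_index, match in enumerate(matches):
            alias_of_node = {v: k for k, v in match.binding.items()}
            documents.append(
                {
                    "match_index": match_index,
                    "nodes": {
                        alias: {
                            "id": object_id,
                            "entity_type": match.nodes[object_id].entity_type,
                            "primary_identifier": match.nodes[object_id].primary_identifier,
                        }
                        for alias, object_id in match.binding.items()
                    },
                    "edges": {
                        alias: {
                            "id": object_id,
                            "label": match.edges[object_id].label,
                            "source": alias_of_node.get(match.edges[object_id].source_id),
                            "target": alias_of_node.get(match.edges[object_id].target_id),
                            "props": dict(match.edges[object_id].props),
                        }
                        for alias, object_id in match.edge_binding.items()
                    },
                    "paths": [
                        {"node_ids": list(p.node_ids), "edge_ids": list(p.edge_ids)}
                        for p in decompose_paths(match)
                    ],
                }
            )
        path.write_text(
            json.dumps(documents, indent=2, sort_keys=True, ensure_ascii=False) + "\n",
            encoding="utf-8",
        )
    else:
        raise ValidationError(f"format must be csv|json, got {format!r}")


def load_results_json(path: str | Path) -> list[tuple[dict[str, ObjectID], dict[str, ObjectID]]]:
    """Re-read a JSON export as ``(node binding, edge binding)`` pairs."""
    documents = json.loads(Path(path).read_text(encoding="utf-8"))
    out = []
    for document in documents:
        binding = {alias: node["id"] for alias, node in document["nodes"].items()}
        edge_binding = {alias: edge["id"] for alias, edge in document["edges"].items()}
        out.append((binding, edge_binding))
    return out
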