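"""Independent brute-force oracles used by the test suite.

Everything here deliberately avoids the implementation paths it checks:
condition evaluation re-derives attribute values by scanning all edges,
pattern matching enumerates every injective alias assignment, the path-cover
minimum is found by exhaustive search over all simple paths, and keyword
retrieval is a linear scan over (token, id) pairs.
"""

from __future__ import annotations

import itertools
import operator
from functools import lru_cache

import networkx as nx

from biograph.model import HAS_DATA, HAS_ID
from biograph.query import QueryPattern
from biograph.store import GraphStore

_ORDERING = {"gt": operator.gt, "gte": operator.ge, "lt": operator.lt, "lte": operator.le}


def _is_num(value) -> bool:
    return isinstance(value, (int, float)) and not isinstance(value, bool)


def _compare(op: str, stored, wanted) -> bool:
    if op in _ORDERING:
        return _is_num(stored) and _ORDERING[op](stored, wanted)
    if op == "contains":
        return isinstance(stored, str) and wanted.casefold() in stored.casefold()
    if isinstance(stored, str) and isinstance(wanted, str):
        equal = stored.casefold() == wanted.casefold()
    elif _is_num(stored) and _is_num(wanted):
        equal = stored == wanted
    elif isinstance(stored, bool) and isinstance(wanted, bool):
        equal = stored == wanted
    else:
        equal = False
    return equal if op == "eq" else not equal


def naive_condition(store: GraphStore, condition, subject_id: str) -> bool:
    """Condition evaluation by full edge scan (no adjacency lists)."""
    kind, obj = store.get(subject_id)
    target = condition.target
    values = []
    if target.startswith("prop."):
        if kind == "relation":
            key = target.split(".", 1)[1]
            if key in obj.props:
                values = [obj.props[key]]
    elif target == "primary_id":
        if kind == "entity":
            values = [obj.primary_identifier]
    elif target == "identifier":
        if kind == "entity":
            values = [obj.primary_identifier]
            for _, relation in store.iter_edges():
                if relation.label == HAS_ID and relation.source_id == subject_id:
                    values.append(store.get(relation.target_id)[1].value)
    elif target.startswith("data."):
        _, source_label, key = target.split(".", 2)
        for _, relation in store.iter_edges():
            if relation.label == HAS_DATA and relation.source_id == subject_id:
                data = store.get(relation.target_id)[1]
                if data.source_label == source_label and key in data.payload:
                    values.append(data.payload[key])
    return any(_compare(condition.op, value, condition.value) for value in values)


def brute_force_execute(pattern: QueryPattern, store: GraphStore) -> set:
    """All (node binding, edge binding) pairs by exhaustive injective
    assignment, as frozen sorted item tuples."""
    types = pattern.node_types
    conditions = pattern.conditions_by_alias
    aliases = sorted(types)
    candidates = {
        alias: [
            object_id
            for object_id, obj in store.iter_nodes("entity")
            if obj.entity_type == types[alias]
            and all(naive_condition(store, c, object_id) for c in conditions.get(alias, ()))
        ]
        for alias in aliases
    }
    entity_edges = [
        (edge_id, relation)
        for edge_id, relation in store.iter_edges()
        if relation.label not in (HAS_ID, HAS_DATA)
    ]
    results = set()
    for combo in itertools.product(*(candidates[alias] for alias in aliases)):
        if len(set(combo)) != len(combo):
            continue
        binding = dict(zip(aliases, combo))
        per_edge = []
        feasible = True
        for spec in pattern.edges:
            pairs = [(binding[spec.from_alias], binding[spec.to_alias])]
            if spec.direction == "any":
                pairs.append((binding[spec.to_alias], binding[spec.from_alias]))
            options = [
                edge_id
                for edge_id, relation in entity_edges
                if (relation.source_id, relation.target_id) in pairs
                and (spec.label == "ANY" or relation.label == spec.label)
                and all(
                    naive_condition(store, c, edge_id) for c in conditions.get(spec.alias, ())
                )
            ]
            if not options:
                feasible = False
                break
            per_edge.append(options)
        if not feasible:
            continue

        def assign(index: int, used: frozenset, edge_binding: dict) -> None:
            if index == len(pattern.edges):
                results.add(
                    (tuple(sorted(binding.items())), tuple(sorted(edge_binding.items())))
                )
                return
            spec = pattern.edges[index]
            for edge_id in per_edge[index]:
                if edge_id in used:
                    continue
                edge_binding[spec.alias] = edge_id
                assign(index + 1, used | {edge_id}, edge_binding)
                del edge_binding[spec.alias]

        assign(0, frozenset(), {})
    return results


def match_result_keys(matches) -> set:
    """MatchResults in the same frozen form as :func:`brute_force_execute`."""
    return {
        (tuple(sorted(m.binding.items())), tuple(sorted(m.edge_binding.items())))
        for m in matches
    }


def min_path_cover(edges: list[tuple[str, str, str]]) -> int:
    """Minimum number of edge-disjoint simple paths covering a tree's edges,
    by exhaustive search over all simple paths with memoization."""
    index_of = {edge_id: i for i, (edge_id, _, _) in enumerate(edges)}
    graph = nx.Graph()
    for edge_id, u, v in edges:
        graph.add_edge(u, v, eid=edge_id)
    paths = []
    for a, b in itertools.combinations(sorted(graph.nodes), 2):
        if not nx.has_path(graph, a, b):
            continue
        walk = nx.shortest_path(graph, a, b)
        paths.append(
            frozenset(
                index_of[graph.edges[walk[i], walk[i + 1]]["eid"]]
                for i in range(len(walk) - 1)
            )
        )

    @lru_cache(maxsize=None)
    def solve(remaining: frozenset) -> int:
        if not remaining:
            return 0
        best = len(remaining)  # single-edge paths always suffice
        for path in paths:
            if path <= remaining:
                best = min(best, 1 + solve(remaining - path))
        return best

    return solve(frozenset(range(len(edges))))


def odd_degree_count(edges: list[tuple[str, str, str]]) -> int:
    degree: dict[str, int] = {}
    for _, u, v in edges:
        degree[u] = degree.get(u, 0) + 1
        degree[v] = degree.get(v, 0) + 1
    return sum(1 for d in degree.values() if d % 2 == 1)


def naive_token_scan(pairs, term: str, mode: str) -> list[str]:
    """Linear scan retrieval over (token, object_id) pairs."""
    if mode == "exact":
        hits = {object_id for token, object_id in pairs if token == term}
    else:
        hits = {object_id for token, object_id in pairs if token.startswith(term)}
    return sorted(hits)


class FaultyContract:
    """Import-contract proxy that raises after a fixed number of map calls,
    for atomicity fault-injection tests."""

    def __init__(self, service, fail_after: int) -> None:
        self._service = service
        self._fail_after = fail_after
        self.calls = 0

    def _maybe_fail(self) -> None:
        self.calls += 1
        if self.calls >= self._fail_after:
            raise RuntimeError(f"injected failure at map call {self.calls}")

    def begin_import(self, source_label):
        return self._service.begin_import(source_label)

    def map_entity(self, entity):
        self._maybe_fail()
        return self._service.map_entity(entity)

    def map_identifier(self, identifier, owner):
        self._maybe_fail()
        return self._service.map_identifier(identifier, owner)

    def map_data(self, data, owner):
        self._maybe_fail()
        return self._service.map_data(data, owner)

    def map_relation(self, label, source, target, props=None):
        self._maybe_fail()
        return self._service.map_relation(label, source, target, props)

    def finish_import(self, **kwargs):
        return self._service.finish_import(**kwargs)

    def abort_import(self):
        return self._service.abort_import()
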