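"""Embedded graph database for model objects and relations.

Nodes are entity/identifier/data objects, edges are relations; both are keyed
by their content address. All writes go through a single-writer
:class:`Transaction` with duplicate-skipping upserts, so re-importing the same
dataset is a no-op and a failed import leaves the store untouched.

The storage layer is expressed as a :class:`GraphDatabaseAdapter` contract
(the model is not tied to one DBMS): :class:`InMemoryGraphBackend` is the
reference embedded implementation, persisted via JSON-lines snapshots;
:class:`Neo4jAdapter` marks where a server-backed adapter would plug in.
"""

from __future__ import annotations

import abc
import gzip
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .errors import (
    NotFoundError,
    ReferentialIntegrityError,
    SnapshotError,
    TransactionError,
    ValidationError,
)
from .model import (
    HAS_DATA,
    HAS_ID,
    KIND_DATA,
    KIND_ENTITY,
    KIND_IDENTIFIER,
    ModelObject,
    ObjectID,
    Relation,
    content_address,
    kind_of,
    make_data,
    make_entity,
    make_identifier,
    make_relation,
)

Direction = str  # "out" | "in" | "any"


@dataclass
class StoreStats:
    """Object and relation counts, maintained incrementally."""

    entities: int = 0
    identifiers: int = 0
    data_objects: int = 0
    relations: int = 0
    relations_by_label: dict[str, int] = field(default_factory=dict)

    @property
    def node_total(self) -> int:
        return self.entities + self.identifiers + self.data_objects


class GraphDatabaseAdapter(abc.ABC):
    """Contract a storage backend must satisfy.

    The transactional upsert layer above talks only to these primitives, so a
    different graph DBMS can be swapped in by implementing this interface.
    """

    @abc.abstractmethod
    def install_node(self, object_id: ObjectID, kind: str, obj: ModelObject) -> None: ...

    @abc.abstractmethod
    def install_edge(self, object_id: ObjectID, relation: Relation) -> None: ...

    @abc.abstractmethod
    def has_node(self, object_id: ObjectID) -> bool: ...

    @abc.abstractmethod
    def has_edge(self, object_id: ObjectID) -> bool: ...

    @abc.abstractmethod
    def node(self, object_id: ObjectID) -> tuple[str, ModelObject]: ...

    @abc.abstractmethod
    def edge(self, object_id: ObjectID) -> Relation: ...

    @abc.abstractmethod
    def nodes(self) -> Iterator[tuple[ObjectID, str, ModelObject]]: ...

    @abc.abstractmethod
    def edges(self) -> Iterator[tuple[ObjectID, Relation]]: ...

    @abc.abstractmethod
    def out_edge_ids(self, object_id: ObjectID) -> list[ObjectID]: ...

    @abc.abstractmethod
    def in_edge_ids(self, object_id: ObjectID) -> list[ObjectID]: ...


class InMemoryGraphBackend(GraphDatabaseAdapter):
    """Reference embedded backend: plain dictionaries plus adjacency lists."""

    def __init__(self) -> None:
        self._nodes: dict[ObjectID, tuple[str, ModelObject]] = {}
        self._edges: dict[ObjectID, Relation] = {}
        self._out: dict[ObjectID, list[ObjectID]] = {}
        self._in: dict[ObjectID, list[ObjectID]] = {}

    def install_node(self, object_id: ObjectID, kind: str, obj: ModelObject) -> None:
        self._nodes[object_id] = (kind, obj)

    def install_edge(self, object_id: ObjectID, relation: Relation) -> None:
        self._edges[object_id] = relation
        self._out.setdefault(relation.source_id, []).append(object_id)
        self._in.setdefault(relation.target_id, []).append(object_id)

    def has_node(self, object_id: ObjectID) -> bool:
        return object_id in self._nodes

    def has_edge(self, object_id: ObjectID) -> bool:
        return object_id in self._edges

    def node(self, object_id: ObjectID) -> tuple[str, ModelObject]:
        return self._nodes[object_id]

    def edge(self, object_id: ObjectID) -> Relation:
        return self._edges[object_id]

    def nodes(self) -> Iterator[tuple[ObjectID, str, ModelObject]]:
        for object_id in sorted(self._nodes):
            kind, obj = self._nodes[object_id]
            yield object_id, kind, obj

    def edges(self) -> Iterator[tuple[ObjectID, Relation]]:
        for object_id in sorted(self._edges):
            yield object_id, self._edges[object_id]

    def out_edge_ids(self, object_id: ObjectID) -> list[ObjectID]:
        return self._out.get(object_id, [])

    def in_edge_ids(self, object_id: ObjectID) -> list[ObjectID]:
        return self._in.get(object_id, [])


class Neo4jAdapter(GraphDatabaseAdapter):
    """Unimplemented stub marking the seam for a server-backed graph DBMS.

    A real implementation would translate installs into parameterized Cypher
    ``MERGE`` statements over a driver session.
    """

    def __init__(self, uri: str, auth: tuple[str, str] | None = None) -> None:
        raise NotImplementedError(
            "Neo4jAdapter is an interface stub; use the embedded backend "
            "(InMemoryGraphBackend) or implement GraphDatabaseAdapter."
        )

    # pragma: no cover - abstract satisfaction only
    def install_node(self, object_id, kind, obj):  # noqa: D102
        raise NotImplementedError

    def install_edge(self, object_id, relation):  # noqa: D102
        raise NotImplementedError

    def has_node(self, object_id):  # noqa: D102
        raise NotImplementedError

    def has_edge(self, object_id):  # noqa: D102
        raise NotImplementedError

    def node(self, object_id):  # noqa: D102
        raise NotImplementedError

    def edge(self, object_id):  # noqa: D102
        raise NotImplementedError

    def nodes(self):  # noqa: D102
        raise NotImplementedError

    def edges(self):  # noqa: D102
        raise NotImplementedError

    def out_edge_ids(self, object_id):  # noqa: D102
        raise NotImplementedError

    def in_edge_ids(self, object_id):  # noqa: D102
        raise NotImplementedError


class Transaction:
    """Buffered single-writer transaction over the graph (and any participant).

    Pending writes are invisible to reads until :meth:`commit`; after
    :meth:`rollback` the store is unchanged. Other components (the catalog)
    can :meth:`register` to commit or roll back atomically with the graph.
    """

    def __init__(self, store: "GraphStore") -> None:
        self._store = store
        self.state = "open"
        self.pending_nodes: dict[ObjectID, tuple[str, ModelObject]] = {}
        self.pending_edges: dict[ObjectID, Relation] = {}
        self._participants: list = []

    def register(self, participant) -> None:
        """Join a participant exposing ``_commit_txn``/``_rollback_txn``."""
        self._require_open()
        self._participants.append(participant)

    def _require_open(self) -> None:
        if self.state != "open":
            raise TransactionError(f"transaction is {self.state}, not open")

    def commit(self) -> None:
        """Atomically publish all pending graph and participant writes."""
        self._require_open()
        self._store._apply(self)
        for participant in self._participants:
            participant._commit_txn(self)
        self.state = "committed"
        self._store._txn = None

    def rollback(self) -> None:
        """Discard all pending writes; the store is as before ``begin``."""
        self._require_open()
        for participant in self._participants:
            participant._rollback_txn(self)
        self.pending_nodes.clear()
        self.pending_edges.clear()
        self.state = "rolled_back"
        self._store._txn = None


class GraphStore:
    """Transactional, content-addressed graph of model objects.

    Reads (``get``, ``neighbors``, iteration, ``stats``) observe committed
    state only. All listings are sorted by :data:`ObjectID` so outputs are
    reproducible.
    """

    def __init__(self, backend: GraphDatabaseAdapter | None = None) -> None:
        self._backend = backend if backend is not None else InMemoryGraphBackend()
        self._txn: Transaction | None = None
        self._node_counts: Counter = Counter()
        self._label_counts: Counter = Counter()

    # -- transactions -----------------------------------------------------

    def begin_transaction(self) -> Transaction:
        if self._txn is not None:
            raise TransactionError("another transaction is already open (single-writer)")
        self._txn = Transaction(self)
        return self._txn

    @property
    def in_transaction(self) -> bool:
        return self._txn is not None

    def _require_txn(self) -> Transaction:
        if self._txn is None:
            raise TransactionError("writes require an open transaction")
        return self._txn

    def _apply(self, txn: Transaction) -> None:
        for object_id, (kind, obj) in txn.pending_nodes.items():
            self._backend.install_node(object_id, kind, obj)
            self._node_counts[kind] += 1
        for object_id, relation in txn.pending_edges.items():
            self._backend.install_edge(object_id, relation)
            self._label_counts[relation.label] += 1

    # -- writes ------------------------------------------------------------

    def _exists_any(self, object_id: ObjectID) -> bool:
        txn = self._txn
        if txn is not None and (object_id in txn.pending_nodes or object_id in txn.pending_edges):
            return True
        return self._backend.has_node(object_id) or self._backend.has_edge(object_id)

    def _kind_any(self, object_id: ObjectID) -> str | None:
        txn = self._txn
        if txn is not None:
            if object_id in txn.pending_nodes:
                return txn.pending_nodes[object_id][0]
            if object_id in txn.pending_edges:
                return "relation"
        if self._backend.has_node(object_id):
            return self._backend.node(object_id)[0]
        if self._backend.has_edge(object_id):
            return "relation"
        return None

    def upsert_object(self, obj: ModelObject) -> tuple[ObjectID, bool]:
        """Insert a node unless its content address is already present.

        Returns ``(object_id, inserted)``; duplicates are skipped, leaving the
        store unchanged.
        """
        txn = self._require_txn()
        kind = kind_of(obj)
        if isinstance(obj, Relation):
            raise ValidationError("relations are stored via upsert_relation")
        object_id = content_address(obj)
        if self._exists_any(object_id):
            return object_id, False
        txn.pending_nodes[object_id] = (kind, obj)
        return object_id, True

    _ENDPOINT_RULES = {
        HAS_ID: (KIND_ENTITY, KIND_IDENTIFIER),
        HAS_DATA: (KIND_ENTITY, KIND_DATA),
    }

    def upsert_relation(self, relation: Relation) -> tuple[ObjectID, bool]:
        """Insert an edge with duplicate-skip semantics.

        Both endpoints must already be stored (committed or pending in the
        same transaction) and their kinds must be legal for the label:
        ``HAS_ID`` entity->identifier, ``HAS_DATA`` entity->data, any other
        label entity->entity.
        """
        txn = self._require_txn()
        source_kind = self._kind_any(relation.source_id)
        target_kind = self._kind_any(relation.target_id)
        if source_kind is None or target_kind is None:
            missing = relation.source_id if source_kind is None else relation.target_id
            raise ReferentialIntegrityError(
                f"relation {relation.label} references unknown object {missing}"
            )
        want = self._ENDPOINT_RULES.get(relation.label, (KIND_ENTITY, KIND_ENTITY))
        if (source_kind, target_kind) != want:
            raise ValidationError(
                f"{relation.label} must connect {want[0]}->{want[1]}, "
                f"got {source_kind}->{target_kind}"
            )
        object_id = content_address(relation)
        if self._exists_any(object_id):
            return object_id, False
        txn.pending_edges[object_id] = relation
        return object_id, True

    # -- reads (committed state only) --------------------------------------

    def has(self, object_id: ObjectID) -> bool:
        return self._backend.has_node(object_id) or self._backend.has_edge(object_id)

    def get(self, object_id: ObjectID) -> tuple[str, ModelObject]:
        """Return ``(kind, object)`` for a committed node or edge."""
        if self._backend.has_node(object_id):
            return self._backend.node(object_id)
        if self._backend.has_edge(object_id):
            return "relation", self._backend.edge(object_id)
        raise NotFoundError(f"no object with id {object_id}")

    def iter_nodes(self, kind: str | None = None) -> Iterator[tuple[ObjectID, ModelObject]]:
        for object_id, node_kind, obj in self._backend.nodes():
            if kind is None or node_kind == kind:
                yield object_id, obj

    def iter_edges(self) -> Iterator[tuple[ObjectID, Relation]]:
        yield from self._backend.edges()

    def neighbors(
        self,
        object_id: ObjectID,
        label: str | None = None,
        direction: Direction = "any",
    ) -> list[tuple[Relation, ModelObject]]:
        """Incident edges (with the neighbor object) sorted by edge id."""
        if not self._backend.has_node(object_id):
            raise NotFoundError(f"no node with id {object_id}")
        if direction not in ("out", "in", "any"):
            raise ValidationError(f"direction must be out|in|any, got {direction!r}")
        edge_ids: list[ObjectID] = []
        if direction in ("out", "any"):
            edge_ids += self._backend.out_edge_ids(object_id)
        if direction in ("in", "any"):
            edge_ids += self._backend.in_edge_ids(object_id)
        hits = []
        for edge_id in sorted(edge_ids):
            relation = self._backend.edge(edge_id)
            if label is not None and relation.label != label:
                continue
            other = (
                relation.target_id if relation.source_id == object_id else relation.source_id
            )
            hits.append((relation, self._backend.node(other)[1]))
        return hits

    def stats(self) -> StoreStats:
        return StoreStats(
            entities=self._node_counts.get(KIND_ENTITY, 0),
            identifiers=self._node_counts.get(KIND_IDENTIFIER, 0),
            data_objects=self._node_counts.get(KIND_DATA, 0),
            relations=sum(self._label_counts.values()),
            relations_by_label=dict(sorted(self._label_counts.items())),
        )


# -- snapshots --------------------------------------------------------------

SNAPSHOT_HEADER = {"record": "header", "format": "biograph-snapshot", "version": 1}

_NODE_BUILDERS = {
    KIND_ENTITY: lambda f: make_entity(f["entity_type"], f["primary_identifier"]),
    KIND_IDENTIFIER: lambda f: make_identifier(f["id_type"], f["title"], f["value"]),
    KIND_DATA: lambda f: make_data(f["source_label"], f["payload"]),
}

_NODE_FIELDS = {
    KIND_ENTITY: lambda o: {
        "entity_type": o.entity_type,
        "primary_identifier": o.primary_identifier,
    },
    KIND_IDENTIFIER: lambda o: {"id_type": o.id_type, "title": o.title, "value": o.value},
    KIND_DATA: lambda o: {"source_label": o.source_label, "payload": dict(o.payload)},
}


def _open_snapshot(path: Path, mode: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t", encoding="utf-8")
    return open(path, mode, encoding="utf-8")


def snapshot_write(store: GraphStore, path: str | Path) -> None:
    """Write the committed store as JSON lines (gzip if the path ends ``.gz``).

    One record per line: a header, then nodes and edges sorted by id, so the
    same store always produces byte-identical snapshots.
    """
    path = Path(path)
    with _open_snapshot(path, "w") as fh:
        fh.write(json.dumps(SNAPSHOT_HEADER, sort_keys=True) + "\n")
        for object_id, obj in store.iter_nodes():
            kind = kind_of(obj)
            record = {
                "record": "node",
                "kind": kind,
                "id": object_id,
                "fields": _NODE_FIELDS[kind](obj),
            }
            fh.write(json.dumps(record, sort_keys=True, ensure_ascii=False) + "\n")
        for object_id, relation in store.iter_edges():
            record = {
                "record": "edge",
                "id": object_id,
                "fields": {
                    "label": relation.label,
                    "source_id": relation.source_id,
                    "target_id": relation.target_id,
                    "props": dict(relation.props),
                },
            }
            fh.write(json.dumps(record, sort_keys=True, ensure_ascii=False) + "\n")


def snapshot_read(path: str | Path) -> GraphStore:
    """Rebuild a store from a snapshot, verifying ids and referential integrity.

    Corruption (bad JSON, unknown record shape, id/content mismatch, dangling
    edge endpoint) raises :class:`SnapshotError` naming the line.
    """
    path = Path(path)
    store = GraphStore()
    txn = store.begin_transaction()
    try:
        with _open_snapshot(path, "r") as fh:
            first = fh.readline()
            if not first:
                raise SnapshotError(f"{path}: line 1: empty snapshot")
            try:
                header = json.loads(first)
            except json.JSONDecodeError as exc:
                raise SnapshotError(f"{path}: line 1: {exc.msg}") from exc
            if not isinstance(header, dict) or header.get("format") != "biograph-snapshot":
                raise SnapshotError(f"{path}: line 1: not a biograph snapshot header")
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                try:
                    record = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise SnapshotError(f"{path}: line {lineno}: {exc.msg}") from exc
                try:
                    _load_record(store, record)
                except (KeyError, TypeError, ValidationError, ReferentialIntegrityError) as exc:
                    raise SnapshotError(f"{path}: line {lineno}: {exc}") from exc
    except (OSError, EOFError, gzip.BadGzipFile) as exc:
        txn.rollback()
        raise SnapshotError(f"{path}: unreadable snapshot: {exc}") from exc
    except SnapshotError:
        txn.rollback()
        raise
    txn.commit()
    return store


def _load_record(store: GraphStore, record: dict) -> None:
    record_type = record["record"]
    if record_type == "node":
        obj = _NODE_BUILDERS[record["kind"]](record["fields"])
        object_id, _ = store.upsert_object(obj)
    elif record_type == "edge":
        fields = record["fields"]
        relation = make_relation(
            fields["label"], fields["source_id"], fields["target_id"], fields["props"]
        )
        object_id, _ = store.upsert_relation(relation)
    else:
        raise ValidationError(f"unknown record type {record_type!r}")
    if object_id != record["id"]:
        raise ValidationError(
            f"content address mismatch: stored id {record['id']} != computed {object_id}"
        )
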