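"""Core service: the import contract wiring importers to graph and catalog.

An importer never touches the graph store or catalog directly. It drives the
five-method contract exposed here — :meth:`BioGraphService.begin_import`,
:meth:`~BioGraphService.map_entity`, :meth:`~BioGraphService.map_identifier` /
:meth:`~BioGraphService.map_data`, :meth:`~BioGraphService.map_relation`, and
:meth:`~BioGraphService.finish_import` — and every mapped object flows through
content addressing, duplicate skipping, the graph store, and the catalog
indexers inside one transaction. :meth:`~BioGraphService.abort_import` rolls
the whole import back.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path
from typing import Mapping, Union

from .catalog import CatalogDB, ImportRecord
from .errors import NotFoundError, TransactionError
from .model import (
    HAS_DATA,
    HAS_ID,
    DataObject,
    EntityObject,
    IdentifierObject,
    ObjectID,
    RelationVocabulary,
    Scalar,
    content_address,
    make_relation,
)
from .store import GraphStore, snapshot_read, snapshot_write

EntityRef = Union[EntityObject, ObjectID]

GRAPH_SNAPSHOT = "graph.jsonl"
CATALOG_FILE = "catalog.sqlite"


class BioGraphService:
    """Implements the import contract over one graph store and catalog."""

    def __init__(self, store: GraphStore, catalog: CatalogDB) -> None:
        self.store = store
        self.catalog = catalog
        catalog.graph = store
        self.vocabulary = RelationVocabulary()
        self._txn = None
        self._record: ImportRecord | None = None
        self._inserted: Counter = Counter()
        self._skipped: Counter = Counter()

    # -- contract ----------------------------------------------------------

    def begin_import(self, source_label: str) -> ImportRecord:
        """Open a transaction spanning graph and catalog and log the import."""
        if self._record is not None:
            raise TransactionError("an import is already in progress")
        self._txn = self.store.begin_transaction()
        self.catalog.join(self._txn)
        self._record = self.catalog.log_import(source_label)
        self._inserted = Counter()
        self._skipped = Counter()
        return self._record

    def _require_import(self) -> ImportRecord:
        if self._record is None:
            raise TransactionError("no import in progress; call begin_import first")
        return self._record

    def _account(self, object_id: ObjectID, kind: str, inserted: bool) -> None:
        record = self._require_import()
        if inserted:
            self._inserted[kind] += 1
            self.catalog.index_entry(object_id, kind, record.import_id)
        else:
            self._skipped[kind] += 1
        self.catalog.record_import_object(record.import_id, object_id)
        if object_id not in record.object_ids:
            record.object_ids.append(object_id)

    def _entity_id(self, entity: EntityRef) -> ObjectID:
        if isinstance(entity, EntityObject):
            return content_address(entity)
        return entity

    def map_entity(self, entity: EntityObject) -> ObjectID:
        """Store an entity and index its primary identifier for keyword lookup."""
        self._require_import()
        object_id, inserted = self.store.upsert_object(entity)
        self._account(object_id, "entity", inserted)
        self.catalog.index_identifier_value(entity.primary_identifier, [object_id])
        return object_id

    def map_identifier(self, identifier: IdentifierObject, owner: EntityRef) -> ObjectID:
        """Store an identifier, attach it to its owner with ``HAS_ID``, and
        index its value with the owner as posting.

        The identifier node is shared: mapping the same identifier for a
        second entity adds a second ``HAS_ID`` edge and posting only.
        """
        self._require_import()
        owner_id = self._entity_id(owner)
        object_id, inserted = self.store.upsert_object(identifier)
        self._account(object_id, "identifier", inserted)
        edge = make_relation(HAS_ID, owner_id, object_id)
        edge_id, edge_inserted = self.store.upsert_relation(edge)
        self._account(edge_id, "relation", edge_inserted)
        self.catalog.index_identifier(identifier, [owner_id])
        return object_id

    def map_data(self, data: DataObject, owner: EntityRef) -> ObjectID:
        """Store a data object, attach it via ``HAS_DATA``, and index its
        string payload values as descriptions of the owning entity."""
        self._require_import()
        owner_id = self._entity_id(owner)
        object_id, inserted = self.store.upsert_object(data)
        self._account(object_id, "data", inserted)
        edge = make_relation(HAS_DATA, owner_id, object_id)
        edge_id, edge_inserted = self.store.upsert_relation(edge)
        self._account(edge_id, "relation", edge_inserted)
        for value in data.payload.values():
            if isinstance(value, str):
                self.catalog.index_description(owner_id, value)
        return object_id

    def map_relation(
        self,
        label: str,
        source: EntityRef,
        target: EntityRef,
        props: Mapping[str, Scalar] | None = None,
    ) -> ObjectID:
        """Store an entity-to-entity relation (endpoints must be mapped)."""
        self._require_import()
        self.vocabulary.classify(label)
        relation = make_relation(label, self._entity_id(source), self._entity_id(target), props)
        object_id, inserted = self.store.upsert_relation(relation)
        self._account(object_id, "relation", inserted)
        return object_id

    def finish_import(self, records_read: int = 0, records_skipped: int = 0) -> ImportRecord:
        """Close the import: persist counters and commit graph + catalog."""
        record = self._require_import()
        finished = self.catalog.finish_import(
            record,
            inserted=sum(self._inserted.values()),
            skipped=sum(self._skipped.values()),
            records_read=records_read,
            records_skipped=records_skipped,
            inserted_by_kind=dict(self._inserted),
            skipped_by_kind=dict(self._skipped),
        )
        self._txn.commit()
        self._txn = None
        self._record = None
        return finished

    def abort_import(self) -> None:
        """Roll back the whole import; graph and catalog are as before."""
        self._require_import()
        self._txn.rollback()
        self._txn = None
        self._record = None


class BioGraphDB:
    """A graph store + catalog pair behind one service, optionally on disk.

    On disk, ``<path>/graph.jsonl`` holds the graph snapshot (written by
    :meth:`save`) and ``<path>/catalog.sqlite`` the catalog (durable at each
    commit).
    """

    def __init__(self, store: GraphStore, catalog: CatalogDB, path: Path | None = None) -> None:
        self.store = store
        self.catalog = catalog
        self.path = path
        self.service = BioGraphService(store, catalog)

    @classmethod
    def open(cls, path: str | Path | None = None, must_exist: bool = False) -> "BioGraphDB":
        """Open (or create) a database directory; ``None`` opens in memory."""
        if path is None:
            return cls(GraphStore(), CatalogDB())
        path = Path(path)
        if must_exist and not path.is_dir():
            raise NotFoundError(f"no database at {path}")
        path.mkdir(parents=True, exist_ok=True)
        snapshot = path / GRAPH_SNAPSHOT
        store = snapshot_read(snapshot) if snapshot.exists() else GraphStore()
        catalog = CatalogDB(path / CATALOG_FILE, graph=store)
        return cls(store, catalog, path)

    def save(self) -> None:
        """Write the graph snapshot (catalog commits are already durable)."""
        if self.path is not None:
            snapshot_write(self.store, self.path / GRAPH_SNAPSHOT)

    def close(self) -> None:
        self.catalog.close()
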