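"""Catalog database: entry, identifier, description, and import indexers.

The catalog is the secondary index kept transactionally in sync with the
graph store. It answers keyword queries (identifier values and free-text
descriptions) through in-memory prefix trees, while its durable form is a
small embedded relational database (sqlite): ``entries``, token posting
tables (the serialized form of the tries, rebuilt on open), and the import
log. Joining a graph :class:`~biograph.store.Transaction` makes sqlite
commit/rollback ride along with the graph commit, so graph and catalog can
never drift apart across an aborted import.
"""

from __future__ import annotations

import datetime
import json
import re
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import TransactionError, ValidationError
from .model import IdentifierObject, ObjectID

_TOKEN_SPLIT = re.compile(r"[^0-9a-z]+")
#: Minimum length of an indexed word token; the full identifier value is
#: always indexed verbatim as well, so short ids remain findable.
MIN_TOKEN_LEN = 2


def tokenize(text: str) -> list[str]:
    """Lowercase word tokens of length >= 2 (split on non-alphanumerics)."""
    tokens = []
    seen = set()
    for token in _TOKEN_SPLIT.split(text.strip().lower()):
        if len(token) >= MIN_TOKEN_LEN and token not in seen:
            seen.add(token)
            tokens.append(token)
    return tokens


def identifier_tokens(value: str) -> list[str]:
    """Tokens indexed for an identifier value: word tokens plus the whole
    value verbatim (lowercased), so both ``pneumonia`` and ``C0038356``-style
    lookups work."""
    tokens = tokenize(value)
    verbatim = value.strip().lower()
    if verbatim and verbatim not in tokens:
        tokens.append(verbatim)
    return tokens


class PrefixTree:
    """Character trie mapping tokens to posting lists of object ids."""

    __slots__ = ("_root", "_size")

    def __init__(self) -> None:
        self._root: dict = {"children": {}, "postings": None}
        self._size = 0

    def insert(self, token: str, object_id: ObjectID) -> None:
        node = self._root
        for char in token:
            node = node["children"].setdefault(char, {"children": {}, "postings": None})
        if node["postings"] is None:
            node["postings"] = set()
            self._size += 1
        node["postings"].add(object_id)

    def _find(self, token: str) -> dict | None:
        node = self._root
        for char in token:
            node = node["children"].get(char)
            if node is None:
                return None
        return node

    def lookup(self, token: str) -> list[ObjectID]:
        """Postings inserted under exactly this token, sorted."""
        node = self._find(token)
        if node is None or node["postings"] is None:
            return []
        return sorted(node["postings"])

    def with_prefix(self, prefix: str) -> list[ObjectID]:
        """Union of postings over all tokens starting with ``prefix``, sorted."""
        node = self._find(prefix)
        if node is None:
            return []
        out: set[ObjectID] = set()
        stack = [node]
        while stack:
            current = stack.pop()
            if current["postings"] is not None:
                out |= current["postings"]
            stack.extend(current["children"].values())
        return sorted(out)

    def __len__(self) -> int:
        return self._size


@dataclass
class ImportRecord:
    """One logged import: provenance, timing, and bookkeeping counters.

    ``inserted + skipped`` equals the number of objects/relations submitted;
    ``records_read``/``records_skipped`` count input records (rows) so every
    record is accounted for either by mapped objects or by a logged skip.
    """

    import_id: str
    source_label: str
    started: str
    finished: str | None = None
    inserted: int = 0
    skipped: int = 0
    records_read: int = 0
    records_skipped: int = 0
    inserted_by_kind: dict[str, int] = field(default_factory=dict)
    skipped_by_kind: dict[str, int] = field(default_factory=dict)
    object_ids: list[ObjectID] = field(default_factory=list)

    @property
    def submitted(self) -> int:
        return self.inserted + self.skipped


_SCHEMA = """
CREATE TABLE IF NOT EXISTS entries (
    object_id TEXT NOT NULL,
    kind TEXT NOT NULL,
    import_id TEXT NOT NULL,
    PRIMARY KEY (object_id, import_id)
);
CREATE TABLE IF NOT EXISTS identifier_tokens (
    token TEXT NOT NULL,
    object_id TEXT NOT NULL,
    PRIMARY KEY (token, object_id)
);
CREATE TABLE IF NOT EXISTS description_tokens (
    token TEXT NOT NULL,
    object_id TEXT NOT NULL,
    PRIMARY KEY (token, object_id)
);
CREATE TABLE IF NOT EXISTS imports (
    import_id TEXT PRIMARY KEY,
    source_label TEXT NOT NULL,
    started TEXT NOT NULL,
    finished TEXT,
    inserted INTEGER NOT NULL DEFAULT 0,
    skipped INTEGER NOT NULL DEFAULT 0,
    records_read INTEGER NOT NULL DEFAULT 0,
    records_skipped INTEGER NOT NULL DEFAULT 0,
    by_kind TEXT NOT NULL DEFAULT '{}'
);
CREATE TABLE IF NOT EXISTS import_objects (
    import_id TEXT NOT NULL,
    object_id TEXT NOT NULL,
    PRIMARY KEY (import_id, object_id)
);
"""


def _now() -> str:
    return datetime.datetime.now(datetime.timezone.utc).isoformat(timespec="seconds")


class CatalogDB:
    """The four indexers over one embedded relational database.

    ``graph`` (optional backref to the :class:`~biograph.store.GraphStore`)
    enables entity-type filtering in :meth:`keyword_search`; the core service
    wires it automatically.
    """

    def __init__(self, path: str | Path | None = None, graph=None) -> None:
        self._conn = sqlite3.connect(str(path) if path is not None else ":memory:")
        self._conn.executescript(_SCHEMA)
        self._conn.commit()
        self.graph = graph
        self._txn = None
        self._pending_identifier_tokens: list[tuple[str, ObjectID]] = []
        self._pending_description_tokens: list[tuple[str, ObjectID]] = []
        self._identifier_trie = PrefixTree()
        self._description_trie = PrefixTree()
        self._rebuild_tries()

    def close(self) -> None:
        self._conn.close()

    def _rebuild_tries(self) -> None:
        for table, trie in (
            ("identifier_tokens", self._identifier_trie),
            ("description_tokens", self._description_trie),
        ):
            for token, object_id in self._conn.execute(f"SELECT token, object_id FROM {table}"):
                trie.insert(token, object_id)

    # -- transaction participation ---------------------------------------

    def join(self, txn) -> None:
        """Participate in a graph transaction: catalog writes commit or roll
        back together with the graph."""
        if self._txn is not None:
            raise TransactionError("catalog already joined to an open transaction")
        txn.register(self)
        self._txn = txn

    def _require_txn(self) -> None:
        if self._txn is None or self._txn.state != "open":
            raise TransactionError("catalog writes require an open, joined transaction")

    def _commit_txn(self, txn) -> None:
        self._conn.commit()
        for token, object_id in self._pending_identifier_tokens:
            self._identifier_trie.insert(token, object_id)
        for token, object_id in self._pending_description_tokens:
            self._description_trie.insert(token, object_id)
        self._pending_identifier_tokens.clear()
        self._pending_description_tokens.clear()
        self._txn = None

    def _rollback_txn(self, txn) -> None:
        self._conn.rollback()
        self._pending_identifier_tokens.clear()
        self._pending_description_tokens.clear()
        self._txn = None

    # -- entry indexer -----------------------------------------------------

    def index_entry(self, object_id: ObjectID, kind: str, import_id: str) -> None:
        """Log one stored object or relation under the import that created it."""
        self._require_txn()
        self._conn.execute(
            "INSERT OR IGNORE INTO entries (object_id, kind, import_id) VALUES (?, ?, ?)",
            (object_id, kind, import_id),
        )

    def entries_for_import(self, import_id: str) -> list[tuple[ObjectID, str]]:
        rows = self._conn.execute(
            "SELECT object_id, kind FROM entries WHERE import_id = ? ORDER BY object_id",
            (import_id,),
        )
        return list(rows)

    def entry_count(self, kind: str | None = None) -> int:
        if kind is None:
            (n,) = self._conn.execute("SELECT COUNT(*) FROM entries").fetchone()
        else:
            (n,) = self._conn.execute(
                "SELECT COUNT(*) FROM entries WHERE kind = ?", (kind,)
            ).fetchone()
        return n

    # -- identifier indexer ------------------------------------------------

    def index_identifier(
        self, identifier: IdentifierObject, entity_ids: Sequence[ObjectID]
    ) -> None:
        """Index an identifier's value with the owning entities as postings."""
        self.index_identifier_value(identifier.value, entity_ids)

    def index_identifier_value(self, value: str, entity_ids: Sequence[ObjectID]) -> None:
        self._require_txn()
        if not entity_ids:
            raise ValidationError("entity_ids must be non-empty")
        for token in identifier_tokens(value):
            for entity_id in entity_ids:
                self._conn.execute(
                    "INSERT OR IGNORE INTO identifier_tokens (token, object_id) VALUES (?, ?)",
                    (token, entity_id),
                )
                self._pending_identifier_tokens.append((token, entity_id))

    # -- description indexer -----------------------------------------------

    def index_description(self, object_id: ObjectID, text: str) -> None:
        """Index free-text description words with ``object_id`` as posting."""
        self._require_txn()
        for token in tokenize(text):
            self._conn.execute(
                "INSERT OR IGNORE INTO description_tokens (token, object_id) VALUES (?, ?)",
                (token, object_id),
            )
            self._pending_description_tokens.append((token, object_id))

    # -- keyword search -----------------------------------------------------

    def keyword_search(
        self,
        term: str,
        entity_type: str | None = None,
        mode: str = "exact",
    ) -> list[ObjectID]:
        """Case-insensitive token search over both indexes, sorted by id."""
        return [object_id for object_id, _ in self.keyword_search_detailed(term, entity_type, mode)]

    def keyword_search_detailed(
        self,
        term: str,
        entity_type: str | None = None,
        mode: str = "exact",
    ) -> list[tuple[ObjectID, tuple[str, ...]]]:
        """Like :meth:`keyword_search` but each hit carries the index source
        (``identifier`` and/or ``description``) that matched."""
        term = term.strip().lower()
        if not term:
            raise ValidationError("search term must be non-empty")
        if mode not in ("exact", "prefix"):
            raise ValidationError(f"mode must be exact|prefix, got {mode!r}")
        sources: dict[ObjectID, set[str]] = {}
        for name, trie in (
            ("identifier", self._identifier_trie),
            ("description", self._description_trie),
        ):
            hits = trie.lookup(term) if mode == "exact" else trie.with_prefix(term)
            for object_id in hits:
                sources.setdefault(object_id, set()).add(name)
        out = []
        for object_id in sorted(sources):
            if entity_type is not None:
                if self.graph is None:
                    raise ValidationError("entity_type filtering requires an attached graph store")
                if not self.graph.has(object_id):
                    continue
                kind, obj = self.graph.get(object_id)
                if kind != "entity" or obj.entity_type != entity_type.strip().lower():
                    continue
            out.append((object_id, tuple(sorted(sources[object_id]))))
        return out

    # -- import indexer ------------------------------------------------------

    def log_import(self, source_label: str) -> ImportRecord:
        """Open a new import record (persisted with the joined transaction)."""
        self._require_txn()
        (n,) = self._conn.execute("SELECT COUNT(*) FROM imports").fetchone()
        record = ImportRecord(
            import_id=f"imp-{n + 1:06d}",
            source_label=source_label,
            started=_now(),
        )
        self._conn.execute(
            "INSERT INTO imports (import_id, source_label, started) VALUES (?, ?, ?)",
            (record.import_id, record.source_label, record.started),
        )
        return record

    def record_import_object(self, import_id: str, object_id: ObjectID) -> None:
        self._require_txn()
        self._conn.execute(
            "INSERT OR IGNORE INTO import_objects (import_id, object_id) VALUES (?, ?)",
            (import_id, object_id),
        )

    def finish_import(
        self,
        record: ImportRecord,
        inserted: int,
        skipped: int,
        records_read: int = 0,
        records_skipped: int = 0,
        inserted_by_kind: dict[str, int] | None = None,
        skipped_by_kind: dict[str, int] | None = None,
    ) -> ImportRecord:
        """Close an import record with its final counters."""
        self._require_txn()
        if record.finished is not None:
            raise TransactionError(f"import {record.import_id} is already finished")
        record.finished = _now()
        record.inserted = inserted
        record.skipped = skipped
        record.records_read = records_read
        record.records_skipped = records_skipped
        record.inserted_by_kind = dict(inserted_by_kind or {})
        record.skipped_by_kind = dict(skipped_by_kind or {})
        by_kind = json.dumps(
            {"inserted": record.inserted_by_kind, "skipped": record.skipped_by_kind},
            sort_keys=True,
        )
        self._conn.execute(
            "UPDATE imports SET finished = ?, inserted = ?, skipped = ?, "
            "records_read = ?, records_skipped = ?, by_kind = ? WHERE import_id = ?",
            (
                record.finished,
                inserted,
                skipped,
                records_read,
                records_skipped,
                by_kind,
                record.import_id,
            ),
        )
        return record

    def imports(self) -> list[ImportRecord]:
        """All committed import records, oldest first."""
        rows = self._conn.execute(
            "SELECT import_id, source_label, started, finished, inserted, skipped, "
            "records_read, records_skipped, by_kind FROM imports ORDER BY import_id"
        ).fetchall()
        records = []
        for row in rows:
            by_kind = json.loads(row[8])
            object_ids = [
                object_id
                for (object_id,) in self._conn.execute(
                    "SELECT object_id FROM import_objects WHERE import_id = ? ORDER BY object_id",
                    (row[0],),
                )
            ]
            records.append(
                ImportRecord(
                    import_id=row[0],
                    source_label=row[1],
                    started=row[2],
                    finished=row[3],
                    inserted=row[4],
                    skipped=row[5],
                    records_read=row[6],
                    records_skipped=row[7],
                    inserted_by_kind=by_kind.get("inserted", {}),
                    skipped_by_kind=by_kind.get("skipped", {}),
                    object_ids=object_ids,
                )
            )
        return records

    def posting_ids(self) -> set[ObjectID]:
        """All object ids appearing in any committed posting list."""
        out = set()
        for table in ("identifier_tokens", "description_tokens"):
            out |= {oid for (oid,) in self._conn.execute(f"SELECT object_id FROM {table}")}
        return out
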