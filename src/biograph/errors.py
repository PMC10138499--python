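"""Exception hierarchy shared across the package."""


class BioGraphError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(BioGraphError, ValueError):
    """An object, relation, or query fragment violates a model invariant."""


class NotFoundError(BioGraphError, KeyError):
    """A requested object id does not resolve in the store."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it readable
        return self.args[0] if self.args else ""


class ReferentialIntegrityError(BioGraphError):
    """A relation references an endpoint that is not stored."""


class TransactionError(BioGraphError):
    """Transactional API misuse (nested begin, commit of a closed txn, ...)."""


class SnapshotError(BioGraphError):
    """A snapshot file is corrupt; the message carries the line position."""


class QueryParseError(ValidationError):
    """A query document is malformed or violates the query-language schema."""


class ImportAbortedError(BioGraphError):
    """An import was rolled back due to a structural input failure."""
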