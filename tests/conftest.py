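import pytest

from biograph import BioGraphDB, content_address, make_entity
from biograph.importers import import_worked_example


@pytest.fixture
def mem_db():
    db = BioGraphDB.open(None)
    yield db
    db.close()


@pytest.fixture
def worked_db(tmp_path):
    """In-memory database loaded with the five worked-example fixture files."""
    db = BioGraphDB.open(None)
    import_worked_example(db.service, tmp_path / "fixtures")
    yield db
    db.close()


def entity_id(entity_type: str, primary_identifier: str) -> str:
    return content_address(make_entity(entity_type, primary_identifier))
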