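"""Dialect-specific importers: DisProt, HGNC, DisGeNET, IEDB, Tantigen.

Each importer reads a local file in its dialect (JSON records or TSV with a
header row), maps records to model objects through the import contract, and
returns the resulting :class:`~biograph.catalog.ImportRecord`. Structural
failures (missing required column, non-list JSON) abort the import — the
transaction is rolled back and :class:`~biograph.errors.ImportAbortedError`
raised. Record-level problems (missing key field, unparsable score) skip the
record with a logged warning, so ``records mapped + records skipped`` always
equals records read.

Primary-identifier elections per dialect: gene -> gene symbol, protein ->
UniProt accession, disease -> UMLS-style CUI, antigen -> Tantigen accession,
epitope -> amino-acid sequence, organism -> NCBI taxon id.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Any, Callable, Iterable, Mapping

from ..catalog import ImportRecord
from ..errors import ImportAbortedError
from ..model import make_data, make_entity, make_identifier
from .configs import resolve_config

logger = logging.getLogger(__name__)


def _read_json_records(path: Path) -> list[dict]:
    try:
        document = json.loads(path.read_text(encoding="utf-8"))
    except (OSError, json.JSONDecodeError) as exc:
        raise ImportAbortedError(f"{path}: unreadable JSON input: {exc}") from exc
    if isinstance(document, dict) and isinstance(document.get("data"), list):
        document = document["data"]
    if not isinstance(document, list):
        raise ImportAbortedError(f"{path}: expected a JSON array of records")
    return document


def _read_tsv_rows(path: Path, required: Iterable[str]) -> list[dict]:
    try:
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            header = reader.fieldnames or []
            missing = [column for column in required if column not in header]
            if missing:
                raise ImportAbortedError(f"{path}: missing required column(s) {missing}")
            return list(reader)
    except OSError as exc:
        raise ImportAbortedError(f"{path}: unreadable TSV input: {exc}") from exc
    except csv.Error as exc:
        raise ImportAbortedError(f"{path}: malformed TSV input: {exc}") from exc


def _run(
    contract,
    source_label: str,
    records: list,
    map_record: Callable[[Any], bool],
) -> ImportRecord:
    """Drive the import contract over records; abort on any failure."""
    contract.begin_import(source_label)
    skipped = 0
    try:
        for record in records:
            if not map_record(record):
                skipped += 1
        return contract.finish_import(records_read=len(records), records_skipped=skipped)
    except BaseException:
        contract.abort_import()
        raise


def _clean(value: Any) -> str:
    return str(value).strip() if value is not None else ""


def import_disgenet(
    path: str | Path, contract, config: Mapping | str | Path | None = None
) -> ImportRecord:
    """Gene-disease association rows -> gene/disease entities linked by
    ``RELATED_WITH`` edges carrying the association score."""
    cfg = resolve_config("disgenet", config)
    path = Path(path)
    rows = _read_tsv_rows(path, cfg["required"])
    mapped_columns = {cfg["gene_symbol"], cfg["disease_id"], cfg["score"]}

    def map_row(row: dict) -> bool:
        symbol = _clean(row.get(cfg["gene_symbol"]))
        disease_id = _clean(row.get(cfg["disease_id"]))
        if not symbol or not disease_id:
            logger.warning("disgenet: skipping row with missing gene/disease id: %r", row)
            return False
        try:
            score = float(row.get(cfg["score"], ""))
        except (TypeError, ValueError):
            logger.warning("disgenet: skipping row with unparsable score: %r", row)
            return False
        gene = make_entity("gene", symbol)
        disease = make_entity("disease", disease_id)
        contract.map_entity(gene)
        contract.map_entity(disease)
        contract.map_identifier(make_identifier("name", "gene name", symbol), gene)
        contract.map_identifier(make_identifier("id", "UMLS CUI", disease_id), disease)
        payload = {}
        for column, value in row.items():
            if column in mapped_columns or column is None:
                continue
            value = _clean(value)
            if value:
                key = "disease_name" if column == cfg["disease_name"] else column
                payload[key] = value
        if payload:
            contract.map_data(make_data("disgenet", payload), disease)
        contract.map_relation("RELATED_WITH", gene, disease, {"score": score})
        return True

    return _run(contract, "disgenet", rows, map_row)


def import_hgnc(
    path: str | Path, contract, config: Mapping | str | Path | None = None
) -> ImportRecord:
    """Gene nomenclature records -> gene entities with identifiers, chromosome
    location data, and ``FROM`` edges from their protein products."""
    cfg = resolve_config("hgnc", config)
    records = _read_json_records(Path(path))

    def map_record(record: Any) -> bool:
        if not isinstance(record, Mapping):
            logger.warning("hgnc: skipping non-object record: %r", record)
            return False
        symbol = _clean(record.get(cfg["symbol"]))
        if not symbol:
            logger.warning("hgnc: skipping record without gene symbol: %r", record)
            return False
        gene = make_entity("gene", symbol)
        contract.map_entity(gene)
        contract.map_identifier(make_identifier("name", "gene name", symbol), gene)
        entrez = _clean(record.get(cfg["entrez_id"]))
        if entrez:
            contract.map_identifier(make_identifier("id", "NCBI ID", entrez), gene)
        payload = {}
        location = _clean(record.get(cfg["location"]))
        if location:
            payload["location"] = location
        name = _clean(record.get(cfg["name"]))
        if name:
            payload["name"] = name
        if payload:
            contract.map_data(make_data("hgnc", payload), gene)
        uniprot_ids = record.get(cfg["uniprot_ids"]) or []
        if isinstance(uniprot_ids, str):
            uniprot_ids = [uniprot_ids]
        for accession in uniprot_ids:
            accession = _clean(accession)
            if not accession:
                continue
            protein = make_entity("protein", accession)
            contract.map_entity(protein)
            contract.map_relation("FROM", protein, gene)  # a protein comes FROM its gene
        return True

    return _run(contract, "hgnc", records, map_record)


def import_disprot(
    path: str | Path, contract, config: Mapping | str | Path | None = None
) -> ImportRecord:
    """Disordered-protein records -> protein entities with UniProt/DisProt
    identifiers, disorder-content data, and organism ``FROM`` edges."""
    cfg = resolve_config("disprot", config)
    records = _read_json_records(Path(path))

    def map_record(record: Any) -> bool:
        if not isinstance(record, Mapping):
            logger.warning("disprot: skipping non-object record: %r", record)
            return False
        accession = _clean(record.get(cfg["accession"]))
        if not accession:
            logger.warning("disprot: skipping record without accession: %r", record)
            return False
        protein = make_entity("protein", accession)
        contract.map_entity(protein)
        contract.map_identifier(make_identifier("id", "UniProt ID", accession), protein)
        disprot_id = _clean(record.get(cfg["disprot_id"]))
        if disprot_id:
            contract.map_identifier(make_identifier("id", "DisProt ID", disprot_id), protein)
        payload = {}
        disorder = record.get(cfg["disorder_content"])
        if disorder is not None:
            try:
                disorder = float(disorder)
            except (TypeError, ValueError):
                logger.warning("disprot: skipping record with unparsable disorder: %r", record)
                return False
            if not 0.0 <= disorder <= 1.0:
                # stored as-is: the model records dataset values, it does not repair them
                logger.warning(
                    "disprot: disorder_content %r outside [0, 1] for %s", disorder, accession
                )
            payload["disorder_content"] = disorder
        name = _clean(record.get(cfg["name"]))
        if name:
            payload["name"] = name
        if payload:
            contract.map_data(make_data("disprot", payload), protein)
        taxon = _clean(record.get(cfg["taxon_id"]))
        if taxon:
            organism = make_entity("organism", taxon)
            contract.map_entity(organism)
            organism_name = _clean(record.get(cfg["organism_name"]))
            if organism_name:
                contract.map_identifier(
                    make_identifier("name", "organism name", organism_name), organism
                )
            contract.map_relation("FROM", protein, organism)
        return True

    return _run(contract, "disprot", records, map_record)


def import_tantigen(
    path: str | Path, contract, config: Mapping | str | Path | None = None
) -> ImportRecord:
    """Tumor-antigen records -> antigen entities, ``IS`` edges from their
    genes, and ``CONTAINS`` edges to their epitopes."""
    cfg = resolve_config("tantigen", config)
    records = _read_json_records(Path(path))

    def map_record(record: Any) -> bool:
        if not isinstance(record, Mapping):
            logger.warning("tantigen: skipping non-object record: %r", record)
            return False
        accession = _clean(record.get(cfg["accession"]))
        if not accession:
            logger.warning("tantigen: skipping record without accession: %r", record)
            return False
        antigen = make_entity("antigen", accession)
        contract.map_entity(antigen)
        contract.map_identifier(make_identifier("id", "Tantigen ID", accession), antigen)
        full_name = _clean(record.get(cfg["full_name"]))
        if full_name:
            contract.map_data(make_data("tantigen", {"full_name": full_name}), antigen)
        gene_symbol = _clean(record.get(cfg["gene_symbol"]))
        if gene_symbol:
            gene = make_entity("gene", gene_symbol)
            contract.map_entity(gene)
            contract.map_relation("IS", gene, antigen)  # the gene IS a tumor antigen
        for sequence in record.get(cfg["epitopes"]) or []:
            sequence = _clean(sequence)
            if not sequence:
                continue
            epitope = make_entity("epitope", sequence)
            contract.map_entity(epitope)
            contract.map_relation("CONTAINS", antigen, epitope)
        return True

    return _run(contract, "tantigen", records, map_record)


def import_iedb(
    path: str | Path, contract, config: Mapping | str | Path | None = None
) -> ImportRecord:
    """Epitope rows -> epitope entities linked to their source antigens
    (``CONTAINS``) and source organisms (``FROM``)."""
    cfg = resolve_config("iedb", config)
    rows = _read_tsv_rows(Path(path), cfg["required"])

    def map_row(row: dict) -> bool:
        sequence = _clean(row.get(cfg["epitope_seq"]))
        antigen_ref = _clean(row.get(cfg["antigen_ref"]))
        if not sequence or not antigen_ref:
            logger.warning("iedb: skipping row with missing epitope/antigen: %r", row)
            return False
        epitope = make_entity("epitope", sequence)
        antigen = make_entity("antigen", antigen_ref)
        contract.map_entity(epitope)
        contract.map_entity(antigen)
        contract.map_relation("CONTAINS", antigen, epitope)
        epitope_type = _clean(row.get(cfg["epitope_type"]))
        if epitope_type:
            contract.map_data(make_data("iedb", {"epitope_type": epitope_type}), epitope)
        taxon = _clean(row.get(cfg["taxon_id"]))
        if taxon:
            organism = make_entity("organism", taxon)
            contract.map_entity(organism)
            organism_name = _clean(row.get(cfg["organism_name"]))
            if organism_name:
                contract.map_identifier(
                    make_identifier("name", "organism name", organism_name), organism
                )
            contract.map_relation("FROM", epitope, organism)
        return True

    return _run(contract, "iedb", rows, map_row)


IMPORTERS: dict[str, Callable] = {
    "disgenet": import_disgenet,
    "hgnc": import_hgnc,
    "disprot": import_disprot,
    "tantigen": import_tantigen,
    "iedb": import_iedb,
}


def run_importer(
    name: str, path: str | Path, contract, config: Mapping | str | Path | None = None
) -> ImportRecord:
    """Dispatch to a dialect importer by name."""
    try:
        importer = IMPORTERS[name]
    except KeyError:
        available = ", ".join(sorted(IMPORTERS))
        raise ImportAbortedError(f"unknown importer {name!r}; available: {available}") from None
    return importer(path, contract, config)
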