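"""Deterministic fixture generator for the five dataset dialects.

Live downloads are out of scope: these generators write syntactically valid
files in each dialect so the whole import/query pipeline is exercisable
offline. Two modes:

* ``worked_example`` — reconstructs, byte-for-byte reproducibly, the small
  cross-dataset network used throughout the documentation: gene ``CDKN1A``
  (HGNC) transcribed into protein ``P38936``/``DP00016`` (DisProt, disorder
  content 0.9), associated with disease ``C0038356`` (DisGeNET, score 0.9),
  and acting as tumor antigen ``Ag002102`` containing epitope ``FAWERVRGL``
  (Tantigen/IEDB). Importing all five files yields exactly 5 entity and 6
  identifier objects.
* randomized records per dialect, reproducible from a seed. Entity names are
  drawn from shared pools with a configurable cross-dialect ``overlap`` rate
  (default 0.3) so joins across datasets are exercised; the remainder are
  dialect-unique synthetic names. Disease names cycle round-robin through a
  fixed pool (which includes a pneumonia entry), so every pool disease is
  guaranteed to appear once ``n_records`` reaches the pool size.
"""

from __future__ import annotations

import json
import random
from pathlib import Path

from ..errors import ValidationError

DIALECTS = ("disprot", "hgnc", "disgenet", "iedb", "tantigen", "worked_example")

#: (gene symbol, UniProt accession, Entrez/NCBI gene id) — shared across
#: dialects so random fixtures join on genes and proteins.
GENE_POOL: tuple[tuple[str, str, str], ...] = (
    ("CDKN1A", "P38936", "1026"),
    ("TP53", "P04637", "7157"),
    ("BRCA1", "P38398", "672"),
    ("EGFR", "P00533", "1956"),
    ("MYC", "P01106", "4609"),
    ("KRAS", "P01116", "3845"),
    ("PTEN", "P60484", "5728"),
    ("RB1", "P06400", "5925"),
    ("CDK2", "P24941", "1017"),
    ("MDM2", "Q00987", "4193"),
    ("ERBB2", "P04626", "2064"),
    ("VEGFA", "P15692", "7422"),
    ("CTNNB1", "P35222", "1499"),
    ("AKT1", "P31749", "207"),
    ("STAT3", "P40763", "6774"),
    ("NRAS", "P01111", "4893"),
)

#: (UMLS CUI, disease name); cycled round-robin by the DisGeNET generator.
DISEASE_POOL: tuple[tuple[str, str], ...] = (
    ("C0032285", "Pneumonia, Bacterial"),
    ("C0038356", "Stomach Neoplasms"),
    ("C0006142", "Malignant neoplasm of breast"),
    ("C0023893", "Liver Cirrhosis"),
    ("C0011849", "Diabetes Mellitus"),
    ("C0004096", "Asthma"),
    ("C0002395", "Alzheimer Disease"),
    ("C0007222", "Cardiovascular Diseases"),
    ("C0036341", "Schizophrenia"),
    ("C0027651", "Neoplasms"),
)

EPITOPE_POOL: tuple[str, ...] = (
    "FAWERVRGL",
    "SLYNTVATL",
    "GILGFVFTL",
    "NLVPMVATV",
    "LLFGYPVYV",
    "KTWGQYWQV",
    "YMDGTMSQV",
    "ELAGIGILTV",
    "RMFPNAPYL",
    "VLQELNVTV",
)

ORGANISM_POOL: tuple[tuple[str, str], ...] = (
    ("9606", "Homo sapiens"),
    ("10090", "Mus musculus"),
    ("10116", "Rattus norvegicus"),
    ("7227", "Drosophila melanogaster"),
)

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

FIXTURE_FILES = {
    "disprot": "disprot.json",
    "hgnc": "hgnc.json",
    "disgenet": "disgenet.tsv",
    "iedb": "iedb.tsv",
    "tantigen": "tantigen.json",
}


def _write_json(path: Path, records: list) -> None:
    path.write_text(
        json.dumps(records, indent=2, sort_keys=True, ensure_ascii=False) + "\n",
        encoding="utf-8",
    )


def _write_tsv(path: Path, header: list[str], rows: list[list[str]]) -> None:
    lines = ["\t".join(header)] + ["\t".join(row) for row in rows]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _rng(dialect: str, seed: int) -> random.Random:
    return random.Random(f"{dialect}:{seed}")


def _random_peptide(rng: random.Random) -> str:
    return "".join(rng.choice(_AMINO_ACIDS) for _ in range(9))


def _gene(rng: random.Random, overlap: float, index: int) -> tuple[str, str, str]:
    if rng.random() < overlap:
        return rng.choice(GENE_POOL)
    return (f"GENE{index:04d}", f"X{index:05d}", str(90000 + index))


def generate_fixture(
    dialect: str,
    n_records: int = 0,
    seed: int = 0,
    out_path: str | Path = ".",
    overlap: float = 0.3,
) -> list[Path]:
    """Write fixture file(s) for ``dialect`` into directory ``out_path``.

    Returns the written paths. ``worked_example`` ignores ``n_records``/
    ``seed`` and writes all five files deterministically; every other dialect
    writes ``n_records`` pseudo-random records reproducible from ``seed``.
    """
    if dialect not in DIALECTS:
        raise ValidationError(f"unknown dialect {dialect!r}; known: {', '.join(DIALECTS)}")
    if n_records < 0:
        raise ValidationError("n_records must be >= 0")
    out_dir = Path(out_path)
    out_dir.mkdir(parents=True, exist_ok=True)

    if dialect == "worked_example":
        return _write_worked_example(out_dir)

    rng = _rng(dialect, seed)
    path = out_dir / FIXTURE_FILES[dialect]

    if dialect == "disgenet":
        rows = []
        for i in range(n_records):
            symbol, _, _ = _gene(rng, overlap, i)
            cui, name = DISEASE_POOL[i % len(DISEASE_POOL)]
            score = f"{rng.uniform(0.0, 1.0):.2f}"
            rows.append([symbol, cui, name, score])
        _write_tsv(path, ["geneSymbol", "diseaseId", "diseaseName", "score"], rows)
    elif dialect == "hgnc":
        records = []
        for i in range(n_records):
            symbol, uniprot, entrez = _gene(rng, overlap, i)
            location = f"{rng.randint(1, 22)}{rng.choice('pq')}{rng.randint(11, 25)}.{rng.randint(1, 3)}"
            records.append(
                {
                    "symbol": symbol,
                    "name": f"{symbol.lower()} gene",
                    "location": location,
                    "entrez_id": entrez,
                    "uniprot_ids": [uniprot] if rng.random() < 0.9 else [],
                }
            )
        _write_json(path, records)
    elif dialect == "disprot":
        records = []
        for i in range(n_records):
            _, uniprot, _ = _gene(rng, overlap, i)
            taxon, organism = (
                rng.choice(ORGANISM_POOL) if rng.random() < 0.8 else (None, None)
            )
            record = {
                "acc": uniprot,
                "disprot_id": f"DP{rng.randint(0, 99999):05d}",
                "name": f"protein {uniprot}",
                "disorder_content": round(rng.uniform(0.0, 1.0), 2),
            }
            if taxon:
                record["taxon_id"] = taxon
                record["organism"] = organism
            records.append(record)
        _write_json(path, records)
    elif dialect == "tantigen":
        records = []
        for i in range(n_records):
            symbol, _, _ = _gene(rng, overlap, i)
            n_epitopes = rng.randint(1, 3)
            epitopes = sorted(
                {
                    rng.choice(EPITOPE_POOL) if rng.random() < overlap else _random_peptide(rng)
                    for _ in range(n_epitopes)
                }
            )
            records.append(
                {
                    "agid": f"Ag{rng.randint(0, 999999):06d}",
                    "full_name": f"{symbol} tumor antigen",
                    "gene_symbol": symbol,
                    "epitopes": epitopes,
                }
            )
        _write_json(path, records)
    elif dialect == "iedb":
        rows = []
        for i in range(n_records):
            sequence = (
                rng.choice(EPITOPE_POOL) if rng.random() < overlap else _random_peptide(rng)
            )
            antigen_ref = f"Ag{rng.randint(0, 999999):06d}"
            taxon, organism = (
                rng.choice(ORGANISM_POOL) if rng.random() < 0.8 else ("", "")
            )
            rows.append([sequence, "Linear peptide", antigen_ref, taxon, organism])
        _write_tsv(
            path,
            ["epitope_seq", "epitope_type", "antigen_ref", "organism_taxon", "organism_name"],
            rows,
        )
    return [path]


def _write_worked_example(out_dir: Path) -> list[Path]:
    paths = []

    path = out_dir / FIXTURE_FILES["disprot"]
    _write_json(
        path,
        [
            {
                "acc": "P38936",
                "disprot_id": "DP00016",
                "name": "Cyclin-dependent kinase inhibitor 1",
                "disorder_content": 0.9,
            }
        ],
    )
    paths.append(path)

    path = out_dir / FIXTURE_FILES["hgnc"]
    _write_json(
        path,
        [
            {
                "symbol": "CDKN1A",
                "name": "cyclin dependent kinase inhibitor 1A",
                "location": "6p21.2",
                "entrez_id": "1026",
                "uniprot_ids": ["P38936"],
            }
        ],
    )
    paths.append(path)

    path = out_dir / FIXTURE_FILES["disgenet"]
    _write_tsv(
        path,
        ["geneSymbol", "diseaseId", "diseaseName", "score"],
        [["CDKN1A", "C0038356", "Stomach Neoplasms", "0.9"]],
    )
    paths.append(path)

    path = out_dir / FIXTURE_FILES["tantigen"]
    _write_json(
        path,
        [
            {
                "agid": "Ag002102",
                "full_name": "Cyclin-dependent kinase inhibitor 1",
                "gene_symbol": "CDKN1A",
                "epitopes": ["FAWERVRGL"],
            }
        ],
    )
    paths.append(path)

    path = out_dir / FIXTURE_FILES["iedb"]
    _write_tsv(
        path,
        ["epitope_seq", "epitope_type", "antigen_ref", "organism_taxon", "organism_name"],
        [["FAWERVRGL", "Linear peptide", "Ag002102", "", ""]],
    )
    paths.append(path)
    return paths


def import_worked_example(contract, out_dir: str | Path):
    """Generate the worked-example fixtures into ``out_dir`` and import all
    five files; returns the list of import records."""
    from .dialects import IMPORTERS

    generate_fixture("worked_example", out_path=out_dir)
    records = []
    for dialect, filename in FIXTURE_FILES.items():
        records.append(IMPORTERS[dialect](Path(out_dir) / filename, contract))
    return records


def figure_query() -> dict:
    """The cross-dataset pattern query used as the worked example: diseases
    related to genes (score >= 0.5) whose proteins are highly disordered
    (disorder content >= 0.9), where the gene is a tumor antigen; all epitopes
    of the antigen are fetched."""
    return {
        "match": [
            {
                "from": {"gene": "gene"},
                "relation": "RELATED_WITH",
                "to": {"disease": "disease"},
                "alias": "gd",
            },
            {"from": {"protein": "protein"}, "relation": "FROM", "to": "gene"},
            {"from": "gene", "relation": "IS", "to": {"antigen": "antigen"}},
            {"from": "antigen", "relation": "CONTAINS", "to": {"epitope": "epitope"}},
        ],
        "params": {
            "gd": [{"target": "prop.score", "op": "gte", "value": 0.5}],
            "protein": [
                {"target": "data.disprot.disorder_content", "op": "gte", "value": 0.9}
            ],
        },
    }
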