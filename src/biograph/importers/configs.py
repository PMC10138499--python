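"""Default field/column mapping configs per dataset dialect.

Real releases of these datasets rename columns between versions, so every
mapper resolves its record fields through a config mapping instead of
hard-coding names. These shipped defaults match the fixture dialects written
by :mod:`biograph.importers.fixtures`; pass a ``config`` dict (or a JSON file
path via the CLI) to remap fields for a different release.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

DISGENET_CONFIG: dict = {
    "format": "tsv",
    "gene_symbol": "geneSymbol",
    "disease_id": "diseaseId",
    "disease_name": "diseaseName",
    "score": "score",
    # columns that must be present for the import to proceed at all
    "required": ["geneSymbol", "diseaseId", "score"],
}

HGNC_CONFIG: dict = {
    "format": "json",
    "symbol": "symbol",
    "name": "name",
    "location": "location",
    "entrez_id": "entrez_id",
    "uniprot_ids": "uniprot_ids",
}

DISPROT_CONFIG: dict = {
    "format": "json",
    "accession": "acc",
    "disprot_id": "disprot_id",
    "name": "name",
    "disorder_content": "disorder_content",
    "taxon_id": "taxon_id",
    "organism_name": "organism",
}

TANTIGEN_CONFIG: dict = {
    "format": "json",
    "accession": "agid",
    "full_name": "full_name",
    "gene_symbol": "gene_symbol",
    "epitopes": "epitopes",
}

IEDB_CONFIG: dict = {
    "format": "tsv",
    "epitope_seq": "epitope_seq",
    "epitope_type": "epitope_type",
    "antigen_ref": "antigen_ref",
    "taxon_id": "organism_taxon",
    "organism_name": "organism_name",
    "required": ["epitope_seq", "antigen_ref"],
}

DEFAULT_CONFIGS: dict[str, dict] = {
    "disgenet": DISGENET_CONFIG,
    "hgnc": HGNC_CONFIG,
    "disprot": DISPROT_CONFIG,
    "tantigen": TANTIGEN_CONFIG,
    "iedb": IEDB_CONFIG,
}


def resolve_config(dialect: str, override: Mapping | str | Path | None = None) -> dict:
    """Shipped defaults for a dialect, shallow-merged with an override mapping
    or JSON config file."""
    config = dict(DEFAULT_CONFIGS[dialect])
    if override is None:
        return config
    if isinstance(override, (str, Path)):
        override = json.loads(Path(override).read_text(encoding="utf-8"))
    config.update(override)
    return config
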