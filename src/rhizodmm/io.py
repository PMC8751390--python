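"""Readers and writers for the standard on-disk formats.

Count tables travel as wide TSV (header row, first column = identifier,
orientation declared explicitly — never guessed) or as BIOM 1.0 JSON.
Taxonomy and metadata travel as TSV/CSV.  Every writer can drop a JSON
provenance sidecar recording the operations that produced the table.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .tables import CompositionTable, CountTable, SampleMetadata, TaxonomyTable, ValidationError

#: TSV orientations for count tables
TAXA_AS_ROWS = "taxa_as_rows"
SAMPLES_AS_ROWS = "samples_as_rows"


def _read_delim(path, sep) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # pragma: no cover - message wrapper
        raise ValidationError(f"could not parse {path}: {exc}") from exc


def read_count_table(path, format: str = "tsv", orientation: str = TAXA_AS_ROWS) -> CountTable:
    """Read a count table from TSV or BIOM 1.0 JSON.

    Parameters
    ----------
    format : {"tsv", "biom"}
    orientation : {"taxa_as_rows", "samples_as_rows"}
        How the TSV is laid out.  Ignored for BIOM (whose axes are
        explicit).  The returned table is always samples x taxa.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        df = _read_delim(path, "\t")
        if orientation == TAXA_AS_ROWS:
            df = df.T
        elif orientation != SAMPLES_AS_ROWS:
            raise ValueError(f"unknown orientation {orientation!r}")
        try:
            numeric = df.astype(float)
        except ValueError as exc:
            raise ValidationError(f"non-numeric count in {path}: {exc}") from exc
        return CountTable(numeric)
    if format == "biom":
        return _read_biom(path)
    raise ValueError(f"unknown count-table format {format!r}")


def write_count_table(ct: CountTable, path, format: str = "tsv",
                      orientation: str = TAXA_AS_ROWS, provenance: bool = True) -> None:
    path = Path(path)
    if format == "tsv":
        df = ct.data.T if orientation == TAXA_AS_ROWS else ct.data
        df.to_csv(path, sep="\t")
    elif format == "biom":
        _write_biom(ct, path)
    else:
        raise ValueError(f"unknown count-table format {format!r}")
    if provenance and ct.provenance:
        write_provenance(ct.provenance, path.with_suffix(path.suffix + ".provenance.json"))


def _read_biom(path: Path) -> CountTable:
    """Minimal BIOM 1.0 (JSON dialect) reader, sparse or dense."""
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("rows", "columns", "shape", "data", "matrix_type"):
        if key not in doc:
            raise ValidationError(f"BIOM file {path} missing field {key!r}")
    n_rows, n_cols = doc["shape"]
    mat = np.zeros((n_rows, n_cols))
    if doc["matrix_type"] == "sparse":
        for r, c, v in doc["data"]:
            mat[r, c] = v
    elif doc["matrix_type"] == "dense":
        mat = np.asarray(doc["data"], dtype=float)
    else:
        raise ValidationError(f"unknown BIOM matrix_type {doc['matrix_type']!r}")
    taxon_ids = [row["id"] for row in doc["rows"]]
    sample_ids = [col["id"] for col in doc["columns"]]
    # BIOM convention: rows are observations (taxa), columns are samples
    df = pd.DataFrame(mat.T, index=sample_ids, columns=taxon_ids)
    return CountTable(df)


def _write_biom(ct: CountTable, path: Path) -> None:
    mat = ct.counts.T  # observations x samples
    rows_idx, cols_idx = np.nonzero(mat)
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "rhizodmm",
        "date": "",
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": [int(mat.shape[0]), int(mat.shape[1])],
        "rows": [{"id": str(t), "metadata": None} for t in ct.taxon_ids],
        "columns": [{"id": str(s), "metadata": None} for s in ct.sample_ids],
        "data": [[int(r), int(c), int(mat[r, c])] for r, c in zip(rows_idx, cols_idx)],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_taxonomy(path, sep: str = "\t") -> TaxonomyTable:
    """Read a taxonomy table (taxon id + ranked lineage columns).

    Accepts either one column per rank or a single semicolon-delimited
    ``lineage`` column.
    """
    df = _read_delim(path, sep)
    df.columns = [c.lower() for c in df.columns]
    if "lineage" in df.columns:
        from .tables import RANKS

        parts = df["lineage"].str.split(";", expand=True)
        parts.columns = list(RANKS)[: parts.shape[1]]
        df = parts
    return TaxonomyTable(df)


def write_taxonomy(tax: TaxonomyTable, path, sep: str = "\t") -> None:
    tax.data.to_csv(path, sep=sep)


def read_metadata(path) -> SampleMetadata:
    """Read sample metadata from CSV or TSV (sniffed from the suffix)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = _read_delim(path, sep)
    for col in ("genotype", "ploidy"):
        if col in df.columns:
            df[col] = df[col].replace({"": None, "NA": None, "nan": None})
    return SampleMetadata(df)


def write_metadata(md: SampleMetadata, path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    md.data.to_csv(path, sep=sep)


def read_phenotypes(path) -> pd.DataFrame:
    """Read the inoculation-experiment phenotype table (CSV)."""
    df = pd.read_csv(path)
    required = {"genotype", "inoculum", "block"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"phenotype table missing columns {sorted(missing)}")
    return df


def write_composition(comp: CompositionTable, path, sep: str = "\t") -> None:
    comp.data.to_csv(path, sep=sep)


def write_provenance(entries: list, path) -> None:
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=2, default=str)
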