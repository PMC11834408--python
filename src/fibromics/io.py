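"""Validated TSV readers/writers shared across the pipeline.

All tables are UTF-8 TSV with a single header line and '.' decimal
separator, for bit-exact cross-language interchange.  Readers validate a
declared schema (required columns, dtypes, unique key) and raise
:class:`~fibromics.errors.SchemaError` naming the offending column/row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError
from .tables import AbundanceTable, validate_catalog

logger = logging.getLogger("fibromics")


@dataclass(frozen=True)
class TableSchema:
    """Declarative TSV schema: required columns, numeric columns, key."""

    name: str
    required: tuple[str, ...]
    numeric: tuple[str, ...] = ()
    unique_key: str | None = None


METADATA_SCHEMA = TableSchema(
    "metadata", ("sample_id", "breed", "diet", "level"), ("level",), "sample_id"
)
CATALOG_SCHEMA = TableSchema(
    "gene_catalog", ("gene_id", "species"), (), "gene_id"
)
DIGESTIBILITY_SCHEMA = TableSchema(
    "digestibility",
    ("pig_id", "nutrient", "dc_d", "dc_f", "aia_d", "aia_f"),
    ("dc_d", "dc_f", "aia_d", "aia_f"),
)
SCFA_SCHEMA = TableSchema("scfa", ("sample_id",), (), "sample_id")
FIELDS_SCHEMA = TableSchema(
    "field_areas",
    ("sample_id", "field_id", "area_residual", "area_damaged", "area_total"),
    ("area_residual", "area_damaged", "area_total"),
)
CRYPTS_SCHEMA = TableSchema(
    "crypts",
    ("sample_id", "crypt_id", "goblet_count", "crypt_depth_um"),
    ("goblet_count", "crypt_depth_um"),
)
CELLS_SCHEMA = TableSchema(
    "cell_counts",
    ("sample_id", "region_id", "positive", "total"),
    ("positive", "total"),
)


def read_table(path, schema: TableSchema) -> pd.DataFrame:
    """Read and validate one TSV against ``schema``.

    Row order is preserved; a row-count and NA report is logged at INFO.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{schema.name}: file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in schema.required if c not in df.columns]
    if missing:
        raise SchemaError(f"{schema.name}: missing columns {missing} in {path}")
    for col in schema.numeric:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise SchemaError(
                f"{schema.name}: non-numeric value in column {col!r}, row {bad + 2}"
            ) from None
    if schema.unique_key is not None and df[schema.unique_key].duplicated().any():
        dup = df.loc[df[schema.unique_key].duplicated(), schema.unique_key].iloc[0]
        raise SchemaError(f"{schema.name}: duplicate {schema.unique_key} {dup!r}")
    n_na = int((df == "").sum().sum())
    logger.info("%s: read %d rows from %s (%d empty cells)", schema.name, len(df), path, n_na)
    return df


def write_table(df: pd.DataFrame, path, *, index: bool = False) -> None:
    """Write a DataFrame as the package's canonical TSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, lineterminator="\n")


# ----------------------------------------------------------------------
# Composite objects
# ----------------------------------------------------------------------

def read_abundance_table(matrix_path, metadata_path) -> AbundanceTable:
    """Abundance/count matrix (features × samples TSV) plus metadata TSV."""
    meta = read_table(metadata_path, METADATA_SCHEMA).set_index("sample_id")
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if not mat.index.is_unique:
        raise SchemaError(f"duplicate feature IDs in {matrix_path}")
    try:
        mat = mat.astype(float)
    except ValueError as exc:
        raise SchemaError(f"non-numeric cell in {matrix_path}: {exc}") from None
    return AbundanceTable(mat, meta)


def write_abundance_table(table: AbundanceTable, matrix_path, metadata_path) -> None:
    write_table(table.values.rename_axis("feature_id"), matrix_path, index=True)
    write_table(table.metadata.rename_axis("sample_id").reset_index(), metadata_path)


def read_gene_catalog(path) -> pd.DataFrame:
    return validate_catalog(read_table(path, CATALOG_SCHEMA))


def write_cohort(cohort, outdir) -> dict[str, str]:
    """Write a :class:`~fibromics.simulate.SyntheticCohort` as TSV files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def _w(name: str, df: pd.DataFrame, index: bool = False) -> None:
        p = outdir / f"{name}.tsv"
        write_table(df, p, index=index)
        paths[name] = str(p)

    _w("abundance", cohort.abundances.values.rename_axis("feature_id"), index=True)
    _w("metadata", cohort.abundances.metadata.rename_axis("sample_id").reset_index())
    _w("species_truth", cohort.species_truth.reset_index())
    _w("gene_catalog", cohort.catalog)
    _w("expression", cohort.host.expression.values.rename_axis("gene_id"), index=True)
    _w("gene_truth", cohort.host.gene_truth.reset_index())
    _w("scfa", cohort.host.scfa.rename_axis("sample_id").reset_index())
    _w("digestibility", cohort.host.digestibility)
    _w("field_areas", cohort.host.fields)
    _w("crypts", cohort.host.crypts)
    _w("cell_counts", cohort.host.cells)
    return paths
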