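"""In-memory containers for the pipeline's tabular substrates.

The central object is :class:`AbundanceTable`: a features × samples matrix
(species relative abundances, or gene counts) paired with per-sample
metadata (breed, diet, numeric wheat-bran level).  It is a thin, validated
wrapper around two :class:`pandas.DataFrame` objects rather than a new
container type, so everything interoperates with the pandas ecosystem.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError, DesignError

#: metadata columns every sample must carry
META_COLUMNS = ("breed", "diet", "level")


@dataclass
class AbundanceTable:
    """Features × samples matrix with breed/diet sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by feature ID with one column per sample ID.
        Non-negative; relative abundances or raw counts.
    metadata
        DataFrame indexed by sample ID with columns ``breed``, ``diet``
        and numeric ``level`` (wheat-bran inclusion, % of diet).
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.metadata.index.is_unique:
            raise SchemaError("duplicate sample IDs in metadata")
        if not self.values.columns.is_unique:
            raise SchemaError("duplicate sample IDs in value matrix")
        if not self.values.index.is_unique:
            raise SchemaError("duplicate feature IDs")
        missing = set(self.values.columns) - set(self.metadata.index)
        if missing:
            raise SchemaError(f"samples without metadata: {sorted(missing)[:5]}")
        for col in META_COLUMNS:
            if col not in self.metadata.columns:
                raise SchemaError(f"metadata missing required column {col!r}")
        if (self.values.to_numpy() < 0).any():
            raise SchemaError("negative values in abundance/count matrix")
        # keep metadata aligned and restricted to the matrix samples
        self.metadata = self.metadata.loc[list(self.values.columns)]

    # ------------------------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_of(self, breed: str, diet: str | None = None) -> list[str]:
        """Sample IDs of one breed, optionally restricted to one diet."""
        mask = self.metadata["breed"] == breed
        if diet is not None:
            mask &= self.metadata["diet"] == diet
        ids = list(self.metadata.index[mask])
        if not ids:
            raise DesignError(f"no samples for breed={breed!r}, diet={diet!r}")
        return ids

    def group(self, breed: str, diet: str) -> pd.DataFrame:
        """Submatrix (features × samples) of one breed × diet cell."""
        return self.values[self.samples_of(breed, diet)]

    def closed(self) -> "AbundanceTable":
        """Return a copy with each sample renormalised to sum to 1."""
        totals = self.values.sum(axis=0)
        if (totals <= 0).any():
            raise SchemaError("cannot close a sample with zero total")
        return AbundanceTable(self.values / totals, self.metadata.copy())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"AbundanceTable({self.values.shape[0]} features × "
            f"{self.values.shape[1]} samples)"
        )


# canonical CAZyme classes in display order
CAZY_CLASSES = ("GH", "GT", "CE", "CBM", "AA", "PL")

#: gene catalog column schema: gene → source species → CAZyme annotation → KO
CATALOG_COLUMNS = ("gene_id", "species", "cazy_class", "cazy_family", "ko")


def validate_catalog(catalog: pd.DataFrame) -> pd.DataFrame:
    """Validate a gene-catalog DataFrame and return it with a clean schema.

    Required columns: ``gene_id``, ``species``; optional ``cazy_class``,
    ``cazy_family``, ``ko`` (empty string or NaN = unannotated).  When both
    class and family are present the family's alphabetic prefix must equal
    the class (e.g. family GH9 ⇒ class GH).
    """
    for col in ("gene_id", "species"):
        if col not in catalog.columns:
            raise SchemaError(f"gene catalog missing column {col!r}")
    catalog = catalog.copy()
    for col in ("cazy_class", "cazy_family", "ko"):
        if col not in catalog.columns:
            catalog[col] = ""
        catalog[col] = catalog[col].fillna("").astype(str)
    if catalog["gene_id"].duplicated().any():
        dup = catalog.loc[catalog["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise SchemaError(f"duplicate gene_id {dup!r} in catalog")
    has_class = catalog["cazy_class"] != ""
    bad_class = has_class & ~catalog["cazy_class"].isin(CAZY_CLASSES)
    if bad_class.any():
        raise SchemaError(
            f"unknown CAZyme class {catalog.loc[bad_class, 'cazy_class'].iloc[0]!r}"
        )
    both = has_class & (catalog["cazy_family"] != "")
    prefix = catalog.loc[both, "cazy_family"].str.extract(r"^([A-Za-z]+)", expand=False)
    mismatch = prefix != catalog.loc[both, "cazy_class"]
    if mismatch.any():
        row = catalog.loc[both].loc[mismatch].iloc[0]
        raise SchemaError(
            f"family {row['cazy_family']!r} does not match class {row['cazy_class']!r}"
        )
    return catalog[list(CATALOG_COLUMNS)]
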