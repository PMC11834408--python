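"""Specific-gene-set (SGS) construction and CAZyme contribution profiling.

The SGS is the pooled gene catalog of the screened candidate species.
Restricting a metagenomic gene catalog to those species and tabulating
CAZyme annotations attributes carbohydrate-degradation capacity to
individual taxa: per-species gene counts by CAZyme class (GH, GT, CE,
CBM, AA, PL) and family (e.g. GH9), each species' share of the set, the
cumulative share of the top-k contributors, and per-enzyme (KO) species
proportions for pathway reconstruction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, ParameterError
from .screen import CandidateSet
from .tables import AbundanceTable, CAZY_CLASSES, validate_catalog

__all__ = [
    "SGSProfile",
    "build_sgs",
    "class_composition",
    "top_contributor_fraction",
    "enzyme_contribution_profile",
    "fold_change_flag",
]


@dataclass
class SGSProfile:
    """CAZyme tabulation of a specific gene set.

    class_counts
        species × class integer gene counts (columns = the six classes).
    family_counts
        species × family integer gene counts.
    missing_species
        candidate species absent from the catalog (reported, not fatal).
    """

    class_counts: pd.DataFrame
    family_counts: pd.DataFrame
    missing_species: list[str]

    @property
    def species_totals(self) -> pd.Series:
        """Total CAZyme-encoding genes per species (sum over classes)."""
        return self.class_counts.sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.species_totals.sum())

    def species_share(self) -> pd.Series:
        """Each species' fraction of all CAZyme-encoding genes in the SGS."""
        tot = self.total
        if tot == 0:
            return self.species_totals.astype(float)
        return self.species_totals / tot


def _candidate_species(candidates: CandidateSet | Sequence[str]) -> list[str]:
    if isinstance(candidates, CandidateSet):
        return candidates.passed
    return list(candidates)


def build_sgs(
    candidates: CandidateSet | Sequence[str], catalog: pd.DataFrame
) -> SGSProfile:
    """Restrict a gene catalog to candidate species and tabulate CAZymes.

    Genes without a CAZyme class are kept out of the counts (they belong
    to the SGS but not to its CAZyme profile).  Each gene counts once in
    its class and once in its family.  Candidate species not found in the
    catalog are reported in ``missing_species`` with a warning.
    """
    catalog = validate_catalog(catalog)
    species = _candidate_species(candidates)
    if not species:
        warnings.warn("empty candidate set: returning empty profile")
    present = set(catalog["species"])
    missing = sorted(set(species) - present)
    if missing:
        warnings.warn(f"{len(missing)} candidate species absent from catalog")
    sub = catalog[catalog["species"].isin(species) & (catalog["cazy_class"] != "")]
    class_counts = (
        sub.groupby(["species", "cazy_class"], sort=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=list(CAZY_CLASSES), fill_value=0)
        .reindex(index=sorted(set(species) & present), fill_value=0)
        .astype(int)
    )
    with_family = sub[sub["cazy_family"] != ""]
    family_counts = (
        with_family.groupby(["species", "cazy_family"], sort=True)
        .size()
        .unstack(fill_value=0)
        .reindex(index=class_counts.index, fill_value=0)
        .astype(int)
    )
    return SGSProfile(class_counts, family_counts, missing)


def class_composition(source: SGSProfile | pd.DataFrame) -> pd.Series:
    """Gene-count fractions over the six CAZyme classes (sum to 1).

    Accepts an :class:`SGSProfile` or a whole gene-catalog DataFrame.
    """
    if isinstance(source, SGSProfile):
        totals = source.class_counts.sum(axis=0)
    else:
        catalog = validate_catalog(source)
        annotated = catalog[catalog["cazy_class"] != ""]
        totals = (
            annotated.groupby("cazy_class").size().reindex(list(CAZY_CLASSES), fill_value=0)
        )
    grand = totals.sum()
    if grand == 0:
        raise DomainError("no CAZyme-annotated genes: composition undefined")
    return (totals / grand).reindex(list(CAZY_CLASSES))


def top_contributor_fraction(
    profile: SGSProfile,
    k: int,
    class_filter: str | None = None,
) -> float:
    """Cumulative share (percent) of the k species with most genes.

    ``class_filter`` restricts counting to one CAZyme class (e.g. "GH");
    ties in the ranking break lexicographically by species label for
    determinism.  Monotone non-decreasing in k and equal to 100% once k
    reaches the number of contributing species.
    """
    if k < 1:
        raise ParameterError("k must be ≥ 1")
    if class_filter is not None:
        if class_filter not in CAZY_CLASSES:
            raise ParameterError(f"unknown CAZyme class {class_filter!r}")
        counts = profile.class_counts[class_filter]
    else:
        counts = profile.species_totals
    total = counts.sum()
    if total == 0:
        raise DomainError("no genes in the selected class")
    ordered = counts.sort_index().sort_values(ascending=False, kind="mergesort")
    return float(100.0 * ordered.iloc[:k].sum() / total)


def enzyme_contribution_profile(
    candidates: CandidateSet | Sequence[str],
    catalog: pd.DataFrame,
    enzyme_list: Sequence[str],
) -> tuple[pd.DataFrame, int]:
    """Per-enzyme species proportions among candidate species.

    For each KO in ``enzyme_list``, counts the genes of each candidate
    species carrying that KO and normalises to proportions (rows sum to 1,
    or stay all-zero when no candidate encodes the enzyme).  Also returns
    the number of listed enzymes with ≥ 1 encoding gene.
    """
    if len(enzyme_list) == 0:
        raise ParameterError("enzyme_list must be non-empty")
    catalog = validate_catalog(catalog)
    if (catalog["ko"] == "").all():
        raise ParameterError("catalog has no KO annotations")
    species = sorted(set(_candidate_species(candidates)) & set(catalog["species"]))
    sub = catalog[catalog["species"].isin(species)]
    counts = (
        sub[sub["ko"].isin(enzyme_list)]
        .groupby(["ko", "species"], sort=True)
        .size()
        .unstack(fill_value=0)
        .reindex(index=list(enzyme_list), columns=species, fill_value=0)
        .astype(float)
    )
    totals = counts.sum(axis=1)
    annotated = int((totals > 0).sum())
    nonzero = totals > 0
    counts.loc[nonzero] = counts.loc[nonzero].div(totals[nonzero], axis=0)
    return counts, annotated


def fold_change_flag(
    abundances: AbundanceTable,
    species: str,
    *,
    breeds: tuple[str, str] = ("MS", "LW"),
    diets: Sequence[str] | None = None,
    pseudocount: float = 0.0,
) -> tuple[float, bool]:
    """Breed fold change of one species' mean relative abundance.

    Ratio of mean abundance in the first breed (MS) to the second (LW),
    pooled across diets by default (``diets`` restricts the pooling).
    The flag is True when the ratio strictly exceeds 1.
    """
    if species not in abundances.values.index:
        raise ParameterError(f"unknown species {species!r}")
    meta = abundances.metadata
    means = []
    for breed in breeds:
        mask = meta["breed"] == breed
        if diets is not None:
            mask &= meta["diet"].isin(diets)
        ids = list(meta.index[mask])
        if not ids:
            raise DomainError(f"no samples for breed {breed!r}")
        means.append(float(abundances.values.loc[species, ids].mean()))
    ms_mean, lw_mean = means
    if lw_mean + pseudocount == 0:
        raise DomainError("zero denominator mean with zero pseudocount")
    ratio = (ms_mean + pseudocount) / (lw_mean + pseudocount)
    return ratio, bool(ratio > 1.0)
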