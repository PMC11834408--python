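"""Fiber-microstructure and mucosal-morphometry metrics.

Two electron-micrograph area ratios quantify how completely dietary fiber
was degraded in feces:

* CRMP — completeness rate of matrix polysaccharide: area of residual
  matrix polysaccharide / area of the total fecal particle.
* DRCM — damage rate of cellulose microfibrils: area of damaged cellulose
  microfibrils / area of the total fecal particle.

Both are computed per microscopic field and averaged across the fields of
one sample (six random fields is the conventional protocol).  Mucosal
morphology is summarised as goblet-cell density per 100 µm of crypt depth
and as positive-cell percentages (Ki-67 proliferation, TUNEL apoptosis),
again ratio-first then averaged across crypts/regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DomainError, InsufficientDataError


@dataclass(frozen=True)
class FieldAreaMeasurement:
    """Measured areas for one microscopic field (any consistent unit)."""

    sample_id: str
    field_id: str
    area_residual_matrix_polysaccharide: float
    area_damaged_cellulose_microfibrils: float
    area_total_fecal_particle: float

    def __post_init__(self) -> None:
        a_r = self.area_residual_matrix_polysaccharide
        a_d = self.area_damaged_cellulose_microfibrils
        a_t = self.area_total_fecal_particle
        if a_r < 0 or a_d < 0:
            raise DomainError(f"{self.sample_id}/{self.field_id}: negative area")
        if a_t <= 0:
            raise DomainError(f"{self.sample_id}/{self.field_id}: total area must be > 0")
        if a_r > a_t or a_d > a_t:
            raise DomainError(
                f"{self.sample_id}/{self.field_id}: component area exceeds total"
            )


@dataclass(frozen=True)
class CryptMeasurement:
    """Goblet-cell count and depth of one well-oriented crypt."""

    sample_id: str
    crypt_id: str
    goblet_count: int
    crypt_depth_um: float

    def __post_init__(self) -> None:
        if self.goblet_count < 0:
            raise DomainError(f"{self.sample_id}/{self.crypt_id}: negative count")
        if self.crypt_depth_um <= 0:
            raise DomainError(f"{self.sample_id}/{self.crypt_id}: depth must be > 0")


@dataclass(frozen=True)
class PositiveCellCount:
    """Positively stained cells out of total counted in one region."""

    sample_id: str
    region_id: str
    positive: int
    total: int

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise DomainError(f"{self.sample_id}/{self.region_id}: total must be > 0")
        if not 0 <= self.positive <= self.total:
            raise DomainError(
                f"{self.sample_id}/{self.region_id}: positive outside [0, total]"
            )


def _require(fields: Sequence, what: str) -> None:
    if len(fields) == 0:
        raise InsufficientDataError(f"need ≥ 1 {what}")


def crmp(
    fields: Sequence[FieldAreaMeasurement], *, assert_disjoint: bool = False
) -> float:
    """Completeness rate of matrix polysaccharide for one sample, in [0, 1].

    Per-field ratios averaged across fields (ratio-then-mean).  With
    ``assert_disjoint`` the residual-polysaccharide and damaged-microfibril
    annotations are checked not to jointly exceed the particle area.
    """
    _require(fields, "field measurement")
    ratios = []
    for f in fields:
        if assert_disjoint and (
            f.area_residual_matrix_polysaccharide
            + f.area_damaged_cellulose_microfibrils
            > f.area_total_fecal_particle
        ):
            raise DomainError(
                f"{f.sample_id}/{f.field_id}: overlapping annotations "
                "(residual + damaged > total) with disjointness asserted"
            )
        ratios.append(
            f.area_residual_matrix_polysaccharide / f.area_total_fecal_particle
        )
    return float(np.mean(ratios))


def drcm(
    fields: Sequence[FieldAreaMeasurement], *, assert_disjoint: bool = False
) -> float:
    """Damage rate of cellulose microfibrils for one sample, in [0, 1]."""
    _require(fields, "field measurement")
    if assert_disjoint:
        crmp(fields, assert_disjoint=True)  # runs the joint check
    ratios = [
        f.area_damaged_cellulose_microfibrils / f.area_total_fecal_particle
        for f in fields
    ]
    return float(np.mean(ratios))


def goblet_density(crypts: Sequence[CryptMeasurement]) -> float:
    """Mean goblet-cell density, cells per 100 µm of crypt depth."""
    _require(crypts, "crypt measurement")
    dens = [100.0 * c.goblet_count / c.crypt_depth_um for c in crypts]
    return float(np.mean(dens))


def positive_fraction(counts: Sequence[PositiveCellCount]) -> float:
    """Mean positively-stained-cell percentage across regions."""
    _require(counts, "region count")
    pct = [100.0 * c.positive / c.total for c in counts]
    return float(np.mean(pct))


def areas_from_mask(
    mask: np.ndarray,
    *,
    sample_id: str = "sample",
    field_id: str = "field",
    residual_label: int = 1,
    damaged_label: int = 2,
) -> FieldAreaMeasurement:
    """Pixel-count areas from an integer label mask (0 = background).

    Any nonzero label counts toward the total fecal particle; the two
    annotation labels give the component areas.  Useful when segmentations
    are available as label images instead of an area table.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2 or not np.issubdtype(mask.dtype, np.integer):
        raise DomainError("mask must be a 2-D integer label array")
    total = int((mask != 0).sum())
    if total == 0:
        raise DomainError("mask contains no foreground pixels")
    return FieldAreaMeasurement(
        sample_id=sample_id,
        field_id=field_id,
        area_residual_matrix_polysaccharide=int((mask == residual_label).sum()),
        area_damaged_cellulose_microfibrils=int((mask == damaged_label).sum()),
        area_total_fecal_particle=total,
    )
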