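"""Marker-based apparent total-tract digestibility (ATTD) and growth metrics.

Acid-insoluble ash (AIA) is an indigestible marker occurring naturally in
feed.  Because the marker passes through the gut unabsorbed, the ratio of
marker concentration in diet to feces calibrates how much of a nutrient
disappeared in transit:

    ATTD(%) = 100 × [1 − (DC_F × AIA_D) / (DC_D × AIA_F)]

where DC_D / DC_F are the nutrient concentrations in diet and feces and
AIA_D / AIA_F the marker concentrations, all in shared units (the formula
is scale-invariant).  The module also computes standard growth summaries
(ADFI, ADG, F/G) and the linear polynomial contrast of an outcome against
numeric dietary-fiber inclusion levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DesignError, DomainError, InsufficientDataError


@dataclass(frozen=True)
class DigestibilityRecord:
    """One pig × nutrient marker-ratio measurement.

    All four concentrations share units (e.g. % of dry matter); ``dc_f``
    may be zero (complete digestion) but the denominator terms must be
    strictly positive.
    """

    pig_id: str
    nutrient: str  # e.g. IDF / SDF / TDF
    dc_d: float  # nutrient concentration in diet
    dc_f: float  # nutrient concentration in feces
    aia_d: float  # acid-insoluble ash in diet
    aia_f: float  # acid-insoluble ash in feces

    def __post_init__(self) -> None:
        if self.dc_d <= 0 or self.aia_d <= 0 or self.aia_f <= 0:
            raise DomainError(
                f"{self.pig_id}/{self.nutrient}: dc_d, aia_d and aia_f must be > 0"
            )
        if self.dc_f < 0:
            raise DomainError(f"{self.pig_id}/{self.nutrient}: dc_f must be ≥ 0")


@dataclass(frozen=True)
class GrowthRecord:
    """Daily intake series plus a body-weight series with day indices."""

    pig_id: str
    daily_intake_kg: Sequence[float]
    weight_kg: Sequence[float]
    weight_days: Sequence[int]

    def __post_init__(self) -> None:
        w = np.asarray(self.weight_kg, float)
        d = np.asarray(self.weight_days, float)
        if (w <= 0).any():
            raise DomainError(f"{self.pig_id}: weights must be positive")
        if len(d) != len(w):
            raise DomainError(f"{self.pig_id}: weight/day series length mismatch")
        if len(d) >= 2 and not (np.diff(d) > 0).all():
            raise DomainError(f"{self.pig_id}: day indices must strictly increase")


class NegativeDigestibilityWarning(UserWarning):
    """ATTD came out negative — usually a marker or sampling problem."""


def attd(record: DigestibilityRecord) -> float:
    """Apparent total-tract digestibility of one record, in percent.

    Returns 100 when nothing of the nutrient was excreted and 0 at the
    marker-ratio identity DC_F·AIA_D = DC_D·AIA_F.  A negative value is
    possible (more nutrient per unit marker in feces than in feed); it is
    preserved but flagged with :class:`NegativeDigestibilityWarning`
    because it diagnoses marker or sampling error.
    """
    value = 100.0 * (1.0 - (record.dc_f * record.aia_d) / (record.dc_d * record.aia_f))
    if value < 0:
        warnings.warn(
            f"negative ATTD ({value:.2f}%) for {record.pig_id}/{record.nutrient}",
            NegativeDigestibilityWarning,
            stacklevel=2,
        )
    return value


def growth_summary(record: GrowthRecord) -> dict:
    """ADFI, ADG and feed-to-gain ratio over the test period.

    ADFI = total intake / days on test; ADG = (final − initial weight) /
    days between first and last weighing; F/G = ADFI / ADG, flagged
    undefined when ADG ≤ 0.
    """
    if len(record.weight_kg) < 2:
        raise InsufficientDataError(
            f"{record.pig_id}: need ≥ 2 weight points to compute gain"
        )
    days = record.weight_days[-1] - record.weight_days[0]
    if days <= 0:
        raise InsufficientDataError(f"{record.pig_id}: zero-length test period")
    adfi = float(np.sum(record.daily_intake_kg)) / len(record.daily_intake_kg)
    adg = (record.weight_kg[-1] - record.weight_kg[0]) / days
    defined = adg > 0
    return {
        "ADFI": adfi,
        "ADG": adg,
        "F_over_G": adfi / adg if defined else float("nan"),
        "fg_defined": bool(defined),
    }


def linear_trend(values: Sequence[float], levels: Sequence[float]) -> dict:
    """Linear polynomial contrast of an outcome on numeric diet levels.

    Regresses the per-animal outcome on the actual numeric inclusion
    levels (the levels 0 / 7 / 10.5 / 14 are unequally spaced, so metric
    regression rather than equal-spacing orthogonal coefficients is the
    appropriate linear contrast) and returns the slope with its two-sided
    p-value.
    """
    y = np.asarray(values, float)
    x = np.asarray(levels, float)
    if len(y) != len(x):
        raise DesignError("values and levels must have equal length")
    if len(np.unique(x)) < 2:
        raise DesignError("all observations at a single diet level")
    if len(y) < 3:
        raise InsufficientDataError("need ≥ 3 observations for a trend test")
    res = stats.linregress(x, y)
    p = res.pvalue
    if np.isnan(p):  # perfectly constant outcome → zero slope, no evidence
        p = 1.0
    return {"slope": float(res.slope), "p_linear": float(p)}


def summarize_groups(
    records: pd.DataFrame,
    group_cols: Sequence[str] = ("breed", "diet"),
    trend_within: str | None = "breed",
) -> pd.DataFrame:
    """Per-group ATTD means ± SE plus, optionally, within-breed linear trends.

    ``records`` needs columns pig_id, nutrient, dc_d, dc_f, aia_d, aia_f
    plus the grouping columns (and ``level`` when ``trend_within`` is set).
    """
    df = records.copy()
    df["attd"] = [
        attd(
            DigestibilityRecord(
                str(r.pig_id), str(r.nutrient), r.dc_d, r.dc_f, r.aia_d, r.aia_f
            )
        )
        for r in df.itertuples()
    ]
    keys = ["nutrient", *group_cols]
    out = (
        df.groupby(keys, sort=True)["attd"]
        .agg(mean="mean", se=lambda v: v.std(ddof=1) / np.sqrt(len(v)), n="count")
        .reset_index()
    )
    if trend_within is not None and "level" in df.columns:
        trends = []
        for (nut, grp), sub in df.groupby(["nutrient", trend_within], sort=True):
            if sub["level"].nunique() >= 2 and len(sub) >= 3:
                t = linear_trend(sub["attd"], sub["level"])
                trends.append(
                    {"nutrient": nut, trend_within: grp, **t}
                )
        out = out.merge(pd.DataFrame(trends), on=["nutrient", trend_within], how="left") \
            if trends else out
    return out
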