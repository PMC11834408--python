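"""Dual-contrast candidate-biomarker screening.

The screening rule contrasts a fiber-tolerant breed (Meishan, MS) with a
fiber-intolerant one (Large White, LW) on a control and a high-fiber diet.
A feature is a candidate biomarker when it is *stable* within MS (no
significant control vs high-fiber difference) yet *depleted/changed* within
LW on the high-fiber diet:

* species mode — present in every MS sample, Mann-Whitney MS contrast
  two-sided p ≥ alpha_ms, and one-sided (lower in LW-high-fiber) p <
  alpha_lw (default 0.01);
* gene mode — LW contrast BH-FDR < 0.05 and |log2 fold change| > 1 on
  normalized counts, with MS contrast two-sided p ≥ alpha_ms; candidates
  are partitioned into up- and down-regulated sets.

The Mann-Whitney U test is implemented here with an exact null
distribution (dynamic programming over the classic lattice recurrence)
whenever both groups have ≤ 12 observations and the pooled data are
tie-free; otherwise the midrank normal approximation with tie-corrected
variance and continuity correction is used.  At the study's n = 7 per
group the exact path is always taken for continuous data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DesignError, DomainError, ParameterError
from .tables import AbundanceTable

__all__ = [
    "MannWhitneyResult",
    "ScreenCriteria",
    "CandidateSet",
    "mann_whitney",
    "bh_fdr",
    "log2_fold_change",
    "screen_species",
    "screen_genes",
]


# ----------------------------------------------------------------------
# Mann-Whitney U
# ----------------------------------------------------------------------

class MannWhitneyResult(NamedTuple):
    u: float  #: U statistic of the first group
    p: float
    exact: bool  #: whether the exact null distribution was used


@lru_cache(maxsize=None)
def _u_counts(n1: int, n2: int) -> tuple:
    """Number of orderings with each U value, for group sizes (n1, n2).

    Uses the lattice-path recurrence
    ``c(n1, n2)[u] = c(n1-1, n2)[u - n2] + c(n1, n2-1)[u]``; the total is
    C(n1+n2, n1).  Returned as a tuple so the cache stays immutable.
    """
    if n1 == 0 or n2 == 0:
        return (1.0,)
    size = n1 * n2 + 1
    a = np.zeros(size)
    prev = np.asarray(_u_counts(n1 - 1, n2))
    a[n2 : n2 + len(prev)] += prev
    prev = np.asarray(_u_counts(n1, n2 - 1))
    a[: len(prev)] += prev
    return tuple(a)


def exact_u_sf_cdf(u: int, n1: int, n2: int) -> tuple[float, float]:
    """(P(U ≤ u), P(U ≥ u)) under the exact tie-free null."""
    counts = np.asarray(_u_counts(n1, n2))
    total = counts.sum()
    return float(counts[: u + 1].sum() / total), float(counts[u:].sum() / total)


def mann_whitney(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alternative: str = "two-sided",
    *,
    exact_max_n: int = 12,
) -> MannWhitneyResult:
    """Mann-Whitney U rank-sum test of ``group_a`` against ``group_b``.

    ``alternative`` is one of ``two-sided``, ``less`` (values in *a* tend
    lower) or ``greater``.  Exact p when both groups have ≤ ``exact_max_n``
    observations and no tied values; tie-corrected normal approximation
    with continuity correction otherwise.  Degenerate all-tied data give
    p = 1.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both groups must be non-empty")
    if a.size < 2 or b.size < 2:
        raise ParameterError("each group needs ≥ 2 observations")
    if alternative not in ("two-sided", "less", "greater"):
        raise ParameterError(f"unknown alternative {alternative!r}")

    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = (tie_counts > 1).any()

    if not has_ties and n1 <= exact_max_n and n2 <= exact_max_n:
        cdf, sf = exact_u_sf_cdf(int(round(u1)), n1, n2)
        if alternative == "two-sided":
            p = min(1.0, 2.0 * min(cdf, sf))
        elif alternative == "less":
            p = cdf
        else:
            p = sf
        return MannWhitneyResult(u1, p, True)

    n = n1 + n2
    mu = n1 * n2 / 2.0
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:  # all observations identical
        return MannWhitneyResult(u1, 1.0, False)
    sd = np.sqrt(var)
    if alternative == "two-sided":
        z = (abs(u1 - mu) - 0.5) / sd
        p = 2.0 * stats.norm.sf(max(z, 0.0))
    elif alternative == "less":
        z = (u1 - mu + 0.5) / sd
        p = stats.norm.cdf(z)
    else:
        z = (u1 - mu - 0.5) / sd
        p = stats.norm.sf(z)
    return MannWhitneyResult(u1, min(1.0, float(p)), False)


# ----------------------------------------------------------------------
# FDR and fold change
# ----------------------------------------------------------------------

def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values (q-values).

    q_(i) = min over j ≥ i of p_(j)·m/j after sorting ascending, clipped
    to 1; elementwise q ≥ p.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ParameterError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def log2_fold_change(
    group_a: Sequence[float],
    group_b: Sequence[float],
    pseudocount: float = 0.5,
) -> float:
    """log2((mean_a + pseudocount) / (mean_b + pseudocount)).

    The pseudocount guards zero means; it must be positive whenever either
    mean is zero.
    """
    ma = float(np.mean(group_a))
    mb = float(np.mean(group_b))
    if pseudocount < 0:
        raise ParameterError("pseudocount must be ≥ 0")
    if pseudocount == 0 and (ma == 0 or mb == 0):
        raise DomainError("zero mean with zero pseudocount")
    return float(np.log2((ma + pseudocount) / (mb + pseudocount)))


# ----------------------------------------------------------------------
# Screen configuration and result containers
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenCriteria:
    """Thresholds of the dual-contrast screen.

    alpha_lw
        Significance level of the LW (high-fiber vs control) contrast;
        species default 0.01 (raw p, one-sided lower).
    alpha_ms
        Non-significance threshold of the MS contrast: the feature must
        have two-sided p ≥ alpha_ms to count as "stable in MS".
    require_prevalence / detection_floor
        Species mode demands a value > detection_floor in *every* MS
        sample of both diets.
    fdr_threshold / log2fc_threshold / pseudocount
        Gene-mode gates: BH-FDR < fdr_threshold and |log2FC| >
        log2fc_threshold on normalized counts.
    lw_two_sided
        Use a two-sided LW species contrast instead of the default
        one-sided (lower in LW high-fiber).
    correct_species_p
        Apply BH across species to the LW contrast p before gating
        (default off: raw per-feature p).
    """

    alpha_lw: float = 0.01
    alpha_ms: float = 0.05
    require_prevalence: bool = True
    detection_floor: float = 0.0
    fdr_threshold: float = 0.05
    log2fc_threshold: float = 1.0
    pseudocount: float = 0.5
    lw_two_sided: bool = False
    correct_species_p: bool = False
    normalize: bool = True

    def __post_init__(self) -> None:
        for name in ("alpha_lw", "alpha_ms", "fdr_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ParameterError(f"{name} must lie in (0, 1), got {v}")
        if self.log2fc_threshold < 0:
            raise ParameterError("log2fc_threshold must be ≥ 0")
        if self.detection_floor < 0:
            raise ParameterError("detection_floor must be ≥ 0")


@dataclass
class CandidateSet:
    """Audit-complete result of one screen.

    ``table`` holds one row per feature with every per-criterion statistic
    and boolean gate; ``passed`` lists feature IDs whose overall ``pass``
    flag is true.  Gene mode adds ``up`` / ``down`` partitions by the sign
    of the LW log2 fold change.
    """

    table: pd.DataFrame
    criteria: ScreenCriteria
    mode: str  # "species" | "genes"

    @property
    def passed(self) -> list[str]:
        return list(self.table.index[self.table["pass"]])

    @property
    def up(self) -> list[str]:
        self._require_genes()
        return list(self.table.index[self.table["pass"] & (self.table["log2fc_lw"] > 0)])

    @property
    def down(self) -> list[str]:
        self._require_genes()
        return list(self.table.index[self.table["pass"] & (self.table["log2fc_lw"] < 0)])

    def _require_genes(self) -> None:
        if self.mode != "genes":
            raise ParameterError("up/down partitions exist only in gene mode")

    def __len__(self) -> int:
        return int(self.table["pass"].sum())


_GROUPS = (("MS", "CON"), ("MS", "WB-10.5"), ("LW", "CON"), ("LW", "WB-10.5"))


def _group_arrays(
    table: AbundanceTable,
    *,
    breeds: tuple[str, str] = ("MS", "LW"),
    diets: tuple[str, str] = ("CON", "WB-10.5"),
) -> dict[tuple[str, str], np.ndarray]:
    """Feature × sample submatrices of the four screen cells."""
    out = {}
    for breed in breeds:
        for diet in diets:
            try:
                out[(breed, diet)] = table.group(breed, diet).to_numpy(float)
            except DesignError as exc:
                raise DesignError(
                    f"screen requires group {breed}-{diet} to be present"
                ) from exc
    return out


def screen_species(
    table: AbundanceTable,
    criteria: ScreenCriteria | None = None,
    *,
    breeds: tuple[str, str] = ("MS", "LW"),
    diets: tuple[str, str] = ("CON", "WB-10.5"),
) -> CandidateSet:
    """Species-mode dual-contrast screen.

    A species passes iff (i) its value exceeds the detection floor in every
    sample of both stable-breed (MS) diets, (ii) the MS contrast is
    non-significant (two-sided p ≥ alpha_ms), and (iii) the LW contrast is
    significant in the depletion direction (one-sided lower p < alpha_lw
    by default).  Tables of counts are closed to relative abundance per
    sample first.
    """
    criteria = criteria or ScreenCriteria()
    work = table.closed() if criteria.normalize else table
    cells = _group_arrays(work, breeds=breeds, diets=diets)
    ms_con, ms_hi = cells[(breeds[0], diets[0])], cells[(breeds[0], diets[1])]
    lw_con, lw_hi = cells[(breeds[1], diets[0])], cells[(breeds[1], diets[1])]

    n_feat = work.values.shape[0]
    rows = {
        "prevalent": np.empty(n_feat, bool),
        "p_ms": np.empty(n_feat),
        "p_lw": np.empty(n_feat),
        "u_ms": np.empty(n_feat),
        "u_lw": np.empty(n_feat),
        "direction_lw": np.empty(n_feat, object),
    }
    lw_alt = "two-sided" if criteria.lw_two_sided else "less"
    for i in range(n_feat):
        rows["prevalent"][i] = bool(
            (ms_con[i] > criteria.detection_floor).all()
            and (ms_hi[i] > criteria.detection_floor).all()
        )
        ms = mann_whitney(ms_hi[i], ms_con[i], "two-sided")
        lw = mann_whitney(lw_hi[i], lw_con[i], lw_alt)
        rows["p_ms"][i], rows["u_ms"][i] = ms.p, ms.u
        rows["p_lw"][i], rows["u_lw"][i] = lw.p, lw.u
        diff = lw_hi[i].mean() - lw_con[i].mean()
        rows["direction_lw"][i] = "down" if diff < 0 else ("up" if diff > 0 else "none")

    df = pd.DataFrame(rows, index=work.values.index)
    p_lw_gate = bh_fdr(df["p_lw"]) if criteria.correct_species_p else df["p_lw"]
    df["ms_stable"] = df["p_ms"] >= criteria.alpha_ms
    df["lw_significant"] = np.asarray(p_lw_gate) < criteria.alpha_lw
    gates = df["ms_stable"] & df["lw_significant"]
    if criteria.require_prevalence:
        gates &= df["prevalent"]
    df["pass"] = gates
    return CandidateSet(df, criteria, "species")


def screen_genes(
    counts: AbundanceTable,
    criteria: ScreenCriteria | None = None,
    *,
    breeds: tuple[str, str] = ("MS", "LW"),
    diets: tuple[str, str] = ("CON", "WB-10.5"),
) -> CandidateSet:
    """Gene-mode dual-contrast screen on a count matrix.

    Counts are normalized to per-sample relative totals (CPM-like) before
    testing.  A gene passes iff the LW contrast BH-FDR < fdr_threshold,
    |log2FC| > log2fc_threshold (pseudocount-guarded, on normalized
    means), and the MS contrast two-sided p ≥ alpha_ms.  The candidate set
    is the union of the up- and down-regulated partitions.
    """
    criteria = criteria or ScreenCriteria()
    work = counts.closed() if criteria.normalize else counts
    cells = _group_arrays(work, breeds=breeds, diets=diets)
    ms_con, ms_hi = cells[(breeds[0], diets[0])], cells[(breeds[0], diets[1])]
    lw_con, lw_hi = cells[(breeds[1], diets[0])], cells[(breeds[1], diets[1])]

    # normalized means are tiny fractions; scale to CPM so the default
    # pseudocount of 0.5 acts on counts-per-million, not on raw fractions
    scale = 1e6 if criteria.normalize else 1.0

    n_feat = work.values.shape[0]
    p_ms = np.empty(n_feat)
    p_lw = np.empty(n_feat)
    l2fc = np.empty(n_feat)
    for i in range(n_feat):
        p_ms[i] = mann_whitney(ms_hi[i], ms_con[i], "two-sided").p
        p_lw[i] = mann_whitney(lw_hi[i], lw_con[i], "two-sided").p
        l2fc[i] = log2_fold_change(
            lw_hi[i] * scale, lw_con[i] * scale, criteria.pseudocount
        )
    fdr = bh_fdr(p_lw)
    df = pd.DataFrame(
        {
            "p_ms": p_ms,
            "p_lw": p_lw,
            "fdr_lw": fdr,
            "log2fc_lw": l2fc,
            "ms_stable": p_ms >= criteria.alpha_ms,
            "lw_significant": fdr < criteria.fdr_threshold,
            "effect_size": np.abs(l2fc) > criteria.log2fc_threshold,
        },
        index=work.values.index,
    )
    df["pass"] = df["ms_stable"] & df["lw_significant"] & df["effect_size"]
    return CandidateSet(df, criteria, "genes")
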