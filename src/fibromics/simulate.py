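"""Seeded synthetic cohorts with planted breed-contrast signals.

The generator emulates the two-breed (Meishan MS, Large White LW) ×
wheat-bran-level feeding design and every post-annotation table the
pipeline consumes, so the whole analysis chain is testable without any
sequencing data:

* species relative abundances — log-normal per-feature baselines closed
  to compositions, with a planted class of "MS-stable, LW-depleted"
  species whose mean drops by a configurable fold in LW high-fiber
  samples, optional zero-inflation of null species (uniform across groups,
  hence exchangeable), and an optional latent-factor clique of
  co-occurring degrader species in MS;
* a gene catalog assigning genes to species with CAZyme class/family and
  KO annotations, GH-enriched in designated degrader species;
* host gene-expression counts (negative-binomial with log-normal library
  sizes) carrying a log2 fold-change effect on planted genes in the LW
  contrast only;
* SCFA concentrations, marker-based digestibility records and
  morphometry measurement tables with configurable group shifts.

All randomness flows from a single root seed through
``numpy.random.SeedSequence`` spawning, in a fixed documented order
(abundances, catalog, host tables), so a fixed seed reproduces the full
bundle byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .tables import AbundanceTable, CAZY_CLASSES

__all__ = [
    "CohortDesign",
    "PlantedSignal",
    "SyntheticHostTables",
    "SyntheticCohort",
    "simulate_abundances",
    "simulate_gene_catalog",
    "simulate_host_tables",
    "simulate_cohort",
]

#: seven measured short-chain fatty acids
SCFA_ACIDS = (
    "acetate",
    "propionate",
    "butyrate",
    "isobutyrate",
    "valerate",
    "isovalerate",
    "caproate",
)

_FAMILIES = {
    "GH": ("GH2", "GH3", "GH5", "GH9", "GH10", "GH13", "GH43", "GH51", "GH94"),
    "GT": ("GT2", "GT4", "GT35"),
    "CE": ("CE1", "CE4", "CE10"),
    "CBM": ("CBM6", "CBM13", "CBM50"),
    "AA": ("AA3", "AA6"),
    "PL": ("PL1", "PL9", "PL11"),
}

#: pathway-enzyme KO pool (cellulose/pectin degradation and glycolysis)
KO_POOL = (
    "K05350",  # bglB, beta-glucosidase
    "K01179",  # endoglucanase
    "K00702",  # cellobiose phosphorylase
    "K00850",  # PFK
    "K01006",  # ppdK
    "K01834",  # gpmI
    "K01051",  # pectinesterase
    "K01730",  # pectate lyase
    "K00041",  # uxaB
    "K01815",  # kduI
    "K00874",  # kdgK
)


@dataclass(frozen=True)
class CohortDesign:
    """Breed × diet × replicate layout of a feeding trial.

    ``diets`` is an ordered tuple of (label, numeric wheat-bran level in %)
    with strictly increasing levels; ``n_per_group`` animals populate each
    breed × diet cell (seven in the conventional pen design).
    """

    breeds: tuple[str, ...] = ("MS", "LW")
    diets: tuple[tuple[str, float], ...] = (
        ("CON", 0.0),
        ("WB-7", 7.0),
        ("WB-10.5", 10.5),
        ("WB-14", 14.0),
    )
    n_per_group: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ParameterError("n_per_group must be ≥ 2")
        if len(self.breeds) < 1 or len(self.diets) < 1:
            raise ParameterError("need at least one breed and one diet")
        levels = [lv for _, lv in self.diets]
        if not all(b > a for a, b in zip(levels, levels[1:])):
            raise ParameterError("diet levels must be strictly increasing")

    @classmethod
    def screen_design(cls, n_per_group: int = 7, seed: int = 0) -> "CohortDesign":
        """Two-diet (control vs 10.5% wheat bran) design used by the screen."""
        return cls(
            diets=(("CON", 0.0), ("WB-10.5", 10.5)),
            n_per_group=n_per_group,
            seed=seed,
        )

    def metadata(self) -> pd.DataFrame:
        """Sample metadata table (sample_id → breed, diet, level)."""
        rows = []
        for breed in self.breeds:
            for diet, level in self.diets:
                for i in range(1, self.n_per_group + 1):
                    rows.append(
                        {
                            "sample_id": f"{breed}-{diet}-{i}",
                            "breed": breed,
                            "diet": diet,
                            "level": level,
                        }
                    )
        return pd.DataFrame(rows).set_index("sample_id")


@dataclass(frozen=True)
class PlantedSignal:
    """Effect sizes and noise parameters of the planted signals.

    lw_depletion_fold
        Factor (≥ 1) by which planted species' mean abundance drops in LW
        high-fiber samples; 1 means no effect.
    gene_log2fc
        |log2 fold change| planted on candidate genes in the LW contrast
        (sign randomised per gene); 0 means no effect.
    dispersion
        Negative-binomial overdispersion of expression counts
        (variance = μ + dispersion·μ²).
    scfa_effects
        Per-acid log2 shift applied in LW high-fiber samples.
    abundance_sigma / mean_log_sigma
        Within-group log-scale noise and spread of per-feature baseline
        log-means of the abundance model.
    sparsity
        Zero-inflation probability of null species, identical in every
        group (keeps the null exchangeable while making the prevalence
        gate informative).
    clique_size / clique_strength
        Number of planted species sharing a latent log-normal factor in
        MS samples, and the factor's log-scale loading.
    high_fiber_min_level
        Wheat-bran level (%) at and above which a diet counts as
        high-fiber for the planted effects.
    """

    n_planted_species: int = 30
    n_null_species: int = 470
    lw_depletion_fold: float = 4.0
    n_planted_genes: int = 40
    n_null_genes: int = 1960
    gene_log2fc: float = 2.0
    dispersion: float = 0.1
    scfa_effects: Mapping[str, float] = field(
        default_factory=lambda: {"propionate": 0.4, "butyrate": 0.4}
    )
    abundance_sigma: float = 0.45
    mean_log_sigma: float = 1.5
    sparsity: float = 0.1
    clique_size: int = 0
    clique_strength: float = 1.2
    digestibility_drop: float = 10.0
    high_fiber_min_level: float = 10.5

    def __post_init__(self) -> None:
        for name in (
            "n_planted_species",
            "n_null_species",
            "n_planted_genes",
            "n_null_genes",
            "clique_size",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be ≥ 0")
        if self.lw_depletion_fold < 1:
            raise ParameterError("lw_depletion_fold must be ≥ 1 (1 = no effect)")
        if self.dispersion <= 0:
            raise ParameterError("dispersion must be > 0")
        if not 0 <= self.sparsity < 1:
            raise ParameterError("sparsity must lie in [0, 1)")
        if self.clique_size > self.n_planted_species:
            raise ParameterError("clique_size cannot exceed n_planted_species")


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    """Independent child generators from one root seed, fixed order."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _root_streams(design: CohortDesign) -> dict[str, np.random.Generator]:
    abundance, catalog, host = _spawn(design.seed, 3)
    return {"abundance": abundance, "catalog": catalog, "host": host}


# ----------------------------------------------------------------------
# Abundances
# ----------------------------------------------------------------------

def simulate_abundances(
    design: CohortDesign,
    signal: PlantedSignal,
    rng: np.random.Generator | None = None,
) -> tuple[AbundanceTable, pd.DataFrame]:
    """Species relative-abundance matrix plus a planted/null truth table.

    Every sample's abundances are non-negative and closed to sum 1.
    Planted species share one generating mean in all MS diets and have
    that mean divided by ``lw_depletion_fold`` in LW diets at or above the
    high-fiber level; they are strictly positive in every MS sample.
    Null species are exchangeable across all groups.
    """
    rng = rng if rng is not None else _root_streams(design)["abundance"]
    meta = design.metadata()
    n_s = len(meta)
    n_planted, n_null = signal.n_planted_species, signal.n_null_species
    n_f = n_planted + n_null
    if n_f == 0:
        raise ParameterError("no features requested")

    feature_ids = [f"sp{i:04d}" for i in range(1, n_f + 1)]
    planted = np.zeros(n_f, bool)
    planted[:n_planted] = True
    clique = np.zeros(n_f, bool)
    clique[: signal.clique_size] = True

    base_log_mean = rng.normal(0.0, signal.mean_log_sigma, size=n_f)
    log_vals = (
        base_log_mean[:, None]
        + rng.normal(0.0, signal.abundance_sigma, size=(n_f, n_s))
    )

    is_lw_hifib = (
        (meta["breed"].to_numpy() == "LW")
        & (meta["level"].to_numpy() >= signal.high_fiber_min_level)
    )
    log_vals[np.ix_(planted, is_lw_hifib)] -= np.log(signal.lw_depletion_fold)

    is_ms = meta["breed"].to_numpy() == "MS"
    if signal.clique_size:
        latent = rng.normal(0.0, 1.0, size=n_s)
        log_vals[np.ix_(clique, is_ms)] += (
            signal.clique_strength * latent[is_ms][None, :]
        )

    vals = np.exp(log_vals)
    if signal.sparsity > 0 and n_null:
        null_rows = ~planted
        zeros = rng.random(size=(n_null, n_s)) < signal.sparsity
        vals[null_rows] = np.where(zeros, 0.0, vals[null_rows])

    # detection floor: planted species stay strictly positive in MS samples
    vals[np.ix_(planted, is_ms)] = np.maximum(vals[np.ix_(planted, is_ms)], 1e-6)
    totals = vals.sum(axis=0)
    vals = vals / totals

    table = AbundanceTable(
        pd.DataFrame(vals, index=feature_ids, columns=meta.index), meta
    )
    truth = pd.DataFrame(
        {"planted": planted, "clique": clique},
        index=pd.Index(feature_ids, name="feature_id"),
    )
    return table, truth


# ----------------------------------------------------------------------
# Gene catalog
# ----------------------------------------------------------------------

def simulate_gene_catalog(
    species_labels: Sequence[str],
    signal: PlantedSignal,
    *,
    degraders: Sequence[str] = (),
    genes_per_species: float = 30.0,
    gh_enrichment: float = 5.0,
    class_weights: Mapping[str, float] | None = None,
    ko_fraction: float = 0.3,
    ko_pool: Sequence[str] = KO_POOL,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Gene catalog (gene → species, CAZyme class/family, KO).

    Per-species class gene counts are Poisson with expectation
    ``genes_per_species × class weight``; species listed in ``degraders``
    have their expected GH count multiplied by ``gh_enrichment``.
    Families are drawn uniformly within each class's family list and a
    ``ko_fraction`` share of genes receives a pathway KO.
    """
    if len(species_labels) == 0:
        raise ParameterError("species_labels must be non-empty")
    if gh_enrichment <= 0:
        raise ParameterError("gh_enrichment must be > 0")
    unknown = set(degraders) - set(species_labels)
    if unknown:
        raise ParameterError(f"degraders not among species: {sorted(unknown)[:5]}")
    rng = rng if rng is not None else np.random.default_rng(seed)
    weights = dict(class_weights) if class_weights is not None else {
        "GH": 0.43,
        "GT": 0.36,
        "CE": 0.14,
        "CBM": 0.032,
        "AA": 0.024,
        "PL": 0.014,
    }
    degrader_set = set(degraders)
    rows = []
    gene_no = 0
    for species in species_labels:
        for cls in CAZY_CLASSES:
            lam = genes_per_species * weights.get(cls, 0.0)
            if cls == "GH" and species in degrader_set:
                lam *= gh_enrichment
            count = int(rng.poisson(lam))
            if count == 0:
                continue
            fams = rng.choice(_FAMILIES[cls], size=count)
            for fam in fams:
                gene_no += 1
                ko = (
                    str(rng.choice(ko_pool))
                    if len(ko_pool) and rng.random() < ko_fraction
                    else ""
                )
                rows.append(
                    {
                        "gene_id": f"gene{gene_no:07d}",
                        "species": species,
                        "cazy_class": cls,
                        "cazy_family": str(fam),
                        "ko": ko,
                    }
                )
    return pd.DataFrame(
        rows, columns=["gene_id", "species", "cazy_class", "cazy_family", "ko"]
    )


# ----------------------------------------------------------------------
# Host tables
# ----------------------------------------------------------------------

@dataclass
class SyntheticHostTables:
    """Bundle of simulated host-side measurement tables."""

    expression: AbundanceTable  # gene counts × samples
    gene_truth: pd.DataFrame  # planted flag and planted sign per gene
    scfa: pd.DataFrame  # samples × acids (µmol/g)
    digestibility: pd.DataFrame  # pig × nutrient marker-ratio records
    fields: pd.DataFrame  # SEM field area measurements
    crypts: pd.DataFrame  # goblet counts and crypt depths
    cells: pd.DataFrame  # positive/total cell counts (ki67, tunel)


def simulate_host_tables(
    design: CohortDesign,
    signal: PlantedSignal,
    rng: np.random.Generator | None = None,
) -> SyntheticHostTables:
    """Expression counts, SCFA, digestibility and morphometry tables.

    Expression counts are negative-binomial (variance μ + dispersion·μ²)
    with log-normal library-size variation; planted genes carry
    ``gene_log2fc`` in LW high-fiber samples and no effect in MS.  SCFA,
    digestibility and morphometry tables carry the configured group
    shifts.  Baseline means of planted genes are drawn from the
    moderately-expressed range so the planted contrast concerns genes a
    count-based test can see.
    """
    rng = rng if rng is not None else _root_streams(design)["host"]
    meta = design.metadata()
    n_s = len(meta)
    is_lw_hifib = (
        (meta["breed"].to_numpy() == "LW")
        & (meta["level"].to_numpy() >= signal.high_fiber_min_level)
    ).astype(float)
    is_hifib = (meta["level"].to_numpy() >= signal.high_fiber_min_level)
    is_ms = meta["breed"].to_numpy() == "MS"

    # --- expression -------------------------------------------------
    n_p, n_0 = signal.n_planted_genes, signal.n_null_genes
    n_g = n_p + n_0
    gene_ids = [f"g{i:05d}" for i in range(1, n_g + 1)]
    planted = np.zeros(n_g, bool)
    planted[:n_p] = True
    mu = np.empty(n_g)
    mu[planted] = rng.lognormal(np.log(200.0), 0.5, size=n_p)
    mu[~planted] = rng.lognormal(np.log(100.0), 1.0, size=n_0)
    sign = np.where(rng.random(n_g) < 0.5, -1.0, 1.0)
    sign[~planted] = 0.0
    lib = rng.lognormal(0.0, 0.25, size=n_s)
    effect = 2.0 ** (sign[:, None] * signal.gene_log2fc * is_lw_hifib[None, :])
    mean_matrix = mu[:, None] * effect * lib[None, :]
    r = 1.0 / signal.dispersion
    counts = rng.negative_binomial(r, r / (r + mean_matrix))
    expression = AbundanceTable(
        pd.DataFrame(counts.astype(np.int64), index=gene_ids, columns=meta.index),
        meta,
    )
    gene_truth = pd.DataFrame(
        {"planted": planted, "sign": sign},
        index=pd.Index(gene_ids, name="gene_id"),
    )

    # --- SCFA -------------------------------------------------------
    base = {
        "acetate": 60.0,
        "propionate": 25.0,
        "butyrate": 15.0,
        "isobutyrate": 2.0,
        "valerate": 3.0,
        "isovalerate": 2.0,
        "caproate": 1.0,
    }
    scfa = {}
    for acid in SCFA_ACIDS:
        shift = 2.0 ** (float(signal.scfa_effects.get(acid, 0.0)) * is_lw_hifib)
        scfa[acid] = base[acid] * shift * rng.lognormal(0.0, 0.2, size=n_s)
    scfa_df = pd.DataFrame(scfa, index=meta.index)

    # --- digestibility ----------------------------------------------
    dc_d_base = {"IDF": 12.0, "SDF": 2.5, "TDF": 15.0}
    attd_base = {"IDF": 40.0, "SDF": 70.0, "TDF": 45.0}
    dig_rows = []
    for s_idx, (sample_id, row) in enumerate(meta.iterrows()):
        for nutrient in ("IDF", "SDF", "TDF"):
            dc_d = dc_d_base[nutrient] * (1.0 + 0.04 * row["level"])
            aia_d = 1.2
            aia_f = rng.lognormal(np.log(4.0), 0.1)
            target = attd_base[nutrient]
            if is_lw_hifib[s_idx]:
                target -= signal.digestibility_drop
            elif is_ms[s_idx] and row["level"] >= 14.0:
                target -= signal.digestibility_drop / 2.0
            attd_true = rng.normal(target, 3.0)
            dc_f = dc_d * aia_f / aia_d * (1.0 - attd_true / 100.0)
            dig_rows.append(
                {
                    "pig_id": sample_id,
                    "breed": row["breed"],
                    "diet": row["diet"],
                    "level": row["level"],
                    "nutrient": nutrient,
                    "dc_d": dc_d,
                    "dc_f": max(dc_f, 0.0),
                    "aia_d": aia_d,
                    "aia_f": aia_f,
                }
            )
    digestibility = pd.DataFrame(dig_rows)

    # --- morphometry -------------------------------------------------
    field_rows, crypt_rows, cell_rows = [], [], []
    conc = 50.0  # beta concentration of area fractions
    for s_idx, (sample_id, row) in enumerate(meta.iterrows()):
        crmp_mean = 0.30
        drcm_mean = 0.25
        if is_hifib[s_idx]:
            # MS degrades matrix polysaccharide more completely (lower
            # residual) and damages more microfibrils than LW
            crmp_mean += -0.05 if is_ms[s_idx] else 0.10
            drcm_mean += 0.10 if is_ms[s_idx] else -0.05
        for f in range(1, 7):
            total = rng.lognormal(np.log(5.0e4), 0.2)
            frac_r = rng.beta(crmp_mean * conc, (1 - crmp_mean) * conc)
            frac_d = rng.beta(drcm_mean * conc, (1 - drcm_mean) * conc)
            field_rows.append(
                {
                    "sample_id": sample_id,
                    "field_id": f"f{f}",
                    "area_residual": frac_r * total,
                    "area_damaged": frac_d * total,
                    "area_total": total,
                }
            )
        goblet_density = 8.0 + (1.0 if is_ms[s_idx] else 0.0)
        for c in range(1, 13):
            depth = max(rng.normal(350.0, 30.0), 50.0)
            crypt_rows.append(
                {
                    "sample_id": sample_id,
                    "crypt_id": f"c{c}",
                    "goblet_count": int(rng.poisson(goblet_density * depth / 100.0)),
                    "crypt_depth_um": depth,
                }
            )
        p_ki = 0.35 + (0.03 if is_ms[s_idx] else 0.0)
        for reg in range(1, 13):
            total_cells = 20 + int(rng.poisson(80.0))
            cell_rows.append(
                {
                    "sample_id": sample_id,
                    "assay": "ki67",
                    "region_id": f"r{reg}",
                    "positive": int(rng.binomial(total_cells, p_ki)),
                    "total": total_cells,
                }
            )
        p_tunel = 0.05 + (0.0 if is_ms[s_idx] else 0.01)
        for reg in range(1, 8):
            cell_rows.append(
                {
                    "sample_id": sample_id,
                    "assay": "tunel",
                    "region_id": f"r{reg}",
                    "positive": int(rng.binomial(200, p_tunel)),
                    "total": 200,
                }
            )

    return SyntheticHostTables(
        expression=expression,
        gene_truth=gene_truth,
        scfa=scfa_df,
        digestibility=digestibility,
        fields=pd.DataFrame(field_rows),
        crypts=pd.DataFrame(crypt_rows),
        cells=pd.DataFrame(cell_rows),
    )


# ----------------------------------------------------------------------
# Full cohort bundle
# ----------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """Everything one simulated feeding trial produces."""

    design: CohortDesign
    signal: PlantedSignal
    abundances: AbundanceTable
    species_truth: pd.DataFrame
    catalog: pd.DataFrame
    host: SyntheticHostTables

    def write(self, outdir) -> dict[str, str]:
        """Write every table as TSV; returns {name: path} (sorted keys)."""
        from . import io as _io

        return _io.write_cohort(self, outdir)


def simulate_cohort(
    design: CohortDesign,
    signal: PlantedSignal | None = None,
    *,
    n_degraders: int = 8,
) -> SyntheticCohort:
    """Simulate the full multi-table bundle from one root seed.

    The first ``n_degraders`` planted species double as GH-enriched
    degraders in the gene catalog (mirroring the handful of key
    fiber-degrading taxa a breed-contrast study highlights).
    """
    signal = signal or PlantedSignal()
    streams = _root_streams(design)
    abundances, truth = simulate_abundances(design, signal, rng=streams["abundance"])
    planted_species = list(truth.index[truth["planted"]])
    degraders = planted_species[: min(n_degraders, len(planted_species))]
    catalog = simulate_gene_catalog(
        list(truth.index), signal, degraders=degraders, rng=streams["catalog"]
    )
    host = simulate_host_tables(design, signal, rng=streams["host"])
    return SyntheticCohort(design, signal, abundances, truth, catalog, host)
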