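"""End-to-end pipeline driver: simulate/load → screen → SGS → networks → report.

:func:`run_pipeline` executes the stages in dependency order, writes every
intermediate as canonical TSV, and emits a machine-readable run manifest
(package and library versions, seed, every threshold actually applied,
and the feature counts surviving each filter).  Rerunning with the same
configuration is byte-identical: all randomness flows from the configured
seed and no timestamps enter any output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from . import io as _io
from .cazyme import (
    build_sgs,
    class_composition,
    enzyme_contribution_profile,
    top_contributor_fraction,
)
from .digestibility import summarize_groups
from .errors import FibromicsError, ParameterError, SchemaError
from .morphometrics import (
    CryptMeasurement,
    FieldAreaMeasurement,
    PositiveCellCount,
    crmp,
    drcm,
    goblet_density,
    positive_fraction,
)
from .networks import cooccurrence_network, integration_network
from .screen import ScreenCriteria, screen_genes, screen_species
from .simulate import CohortDesign, PlantedSignal, simulate_cohort, KO_POOL
from .tables import AbundanceTable

logger = logging.getLogger("fibromics")


class StageError(FibromicsError):
    """A pipeline stage failed; partial outputs are left on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything one pipeline run depends on.

    With ``simulate=True`` the input bundle is generated from ``design`` /
    ``signal``; otherwise ``inputs`` must map the table names
    (abundance, metadata, gene_catalog, expression, scfa, digestibility,
    field_areas, crypts, cell_counts) to existing TSV paths.
    """

    outdir: str
    simulate: bool = True
    seed: int = 0
    design: CohortDesign | None = None
    signal: PlantedSignal | None = None
    inputs: Mapping[str, str] = field(default_factory=dict)
    criteria: ScreenCriteria = field(default_factory=ScreenCriteria)
    cooccurrence_alpha: float = 0.05
    integration_alpha: float = 0.01
    prevalence_min: float = 0.5
    breeds: tuple[str, str] = ("MS", "LW")
    diets: tuple[str, str] = ("CON", "WB-10.5")
    max_network_species: int = 50
    enzyme_list: tuple[str, ...] = tuple(KO_POOL)

    def validate(self) -> None:
        if self.simulate:
            return
        required = ("abundance", "metadata")
        missing = [k for k in required if k not in self.inputs]
        if missing:
            raise ParameterError(f"inputs missing required tables: {missing}")
        for name, path in self.inputs.items():
            if not Path(path).exists():
                raise SchemaError(f"input table {name!r} not found: {path}")


def _records_from_df(df: pd.DataFrame, cls, cols: dict):
    return [cls(**{k: r[v] for k, v in cols.items()}) for _, r in df.iterrows()]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest dictionary.

    Outputs land in ``config.outdir``.  A failing stage raises
    :class:`StageError` naming the stage; files written by earlier stages
    are preserved for inspection.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "fibromics",
        "version": __version__,
        "libraries": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "seed": config.seed,
        "thresholds": {
            "alpha_lw": config.criteria.alpha_lw,
            "alpha_ms": config.criteria.alpha_ms,
            "fdr_threshold": config.criteria.fdr_threshold,
            "log2fc_threshold": config.criteria.log2fc_threshold,
            "detection_floor": config.criteria.detection_floor,
            "require_prevalence": config.criteria.require_prevalence,
            "cooccurrence_alpha": config.cooccurrence_alpha,
            "integration_alpha": config.integration_alpha,
            "prevalence_min": config.prevalence_min,
        },
        "stages": [],
        "counts": {},
    }

    stage = "inputs"
    try:
        if config.simulate:
            design = config.design or CohortDesign.screen_design(seed=config.seed)
            if design.seed != config.seed:
                design = CohortDesign(
                    design.breeds, design.diets, design.n_per_group, config.seed
                )
            signal = config.signal or PlantedSignal()
            cohort = simulate_cohort(design, signal)
            cohort.write(outdir / "inputs")
            abundances = cohort.abundances
            catalog = cohort.catalog
            expression = cohort.host.expression
            scfa = cohort.host.scfa
            digestibility = cohort.host.digestibility
            fields_df = cohort.host.fields
            crypts_df = cohort.host.crypts
            cells_df = cohort.host.cells
            species_truth = cohort.species_truth
            gene_truth = cohort.host.gene_truth
        else:
            abundances = _io.read_abundance_table(
                config.inputs["abundance"], config.inputs["metadata"]
            )
            catalog = (
                _io.read_gene_catalog(config.inputs["gene_catalog"])
                if "gene_catalog" in config.inputs
                else None
            )
            expression = (
                _io.read_abundance_table(
                    config.inputs["expression"], config.inputs["metadata"]
                )
                if "expression" in config.inputs
                else None
            )
            scfa = (
                _io.read_table(config.inputs["scfa"], _io.SCFA_SCHEMA)
                .set_index("sample_id")
                .astype(float)
                if "scfa" in config.inputs
                else None
            )
            digestibility = (
                _io.read_table(config.inputs["digestibility"], _io.DIGESTIBILITY_SCHEMA)
                if "digestibility" in config.inputs
                else None
            )
            fields_df = (
                _io.read_table(config.inputs["field_areas"], _io.FIELDS_SCHEMA)
                if "field_areas" in config.inputs
                else None
            )
            crypts_df = (
                _io.read_table(config.inputs["crypts"], _io.CRYPTS_SCHEMA)
                if "crypts" in config.inputs
                else None
            )
            cells_df = (
                _io.read_table(config.inputs["cell_counts"], _io.CELLS_SCHEMA)
                if "cell_counts" in config.inputs
                else None
            )
            species_truth = gene_truth = None
        manifest["stages"].append(stage)
    except FibromicsError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError(stage, exc) from exc

    # --- digestibility & morphometrics ------------------------------
    stage = "digestibility"
    try:
        if digestibility is not None:
            summary = summarize_groups(digestibility)
            _io.write_table(summary, outdir / "attd_summary.tsv")
            manifest["counts"]["digestibility_records"] = int(len(digestibility))
        manifest["stages"].append(stage)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "morphometrics"
    try:
        rows = []
        if fields_df is not None:
            for sid, sub in fields_df.groupby("sample_id", sort=True):
                fm = _records_from_df(
                    sub,
                    FieldAreaMeasurement,
                    {
                        "sample_id": "sample_id",
                        "field_id": "field_id",
                        "area_residual_matrix_polysaccharide": "area_residual",
                        "area_damaged_cellulose_microfibrils": "area_damaged",
                        "area_total_fecal_particle": "area_total",
                    },
                )
                rows.append(
                    {"sample_id": sid, "metric": "crmp", "value": crmp(fm)}
                )
                rows.append(
                    {"sample_id": sid, "metric": "drcm", "value": drcm(fm)}
                )
        if crypts_df is not None:
            for sid, sub in crypts_df.groupby("sample_id", sort=True):
                cm = _records_from_df(
                    sub,
                    CryptMeasurement,
                    {
                        "sample_id": "sample_id",
                        "crypt_id": "crypt_id",
                        "goblet_count": "goblet_count",
                        "crypt_depth_um": "crypt_depth_um",
                    },
                )
                rows.append(
                    {
                        "sample_id": sid,
                        "metric": "goblet_per_100um",
                        "value": goblet_density(cm),
                    }
                )
        if cells_df is not None:
            assay_col = "assay" if "assay" in cells_df.columns else None
            groups = (
                cells_df.groupby(["sample_id", assay_col], sort=True)
                if assay_col
                else cells_df.groupby("sample_id", sort=True)
            )
            for key, sub in groups:
                sid, assay = key if assay_col else (key, "positive")
                pc = _records_from_df(
                    sub,
                    PositiveCellCount,
                    {
                        "sample_id": "sample_id",
                        "region_id": "region_id",
                        "positive": "positive",
                        "total": "total",
                    },
                )
                rows.append(
                    {
                        "sample_id": sid,
                        "metric": f"{assay}_pct",
                        "value": positive_fraction(pc),
                    }
                )
        if rows:
            _io.write_table(pd.DataFrame(rows), outdir / "morphometrics.tsv")
        manifest["stages"].append(stage)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- screens -----------------------------------------------------
    stage = "screen_species"
    try:
        species_set = screen_species(
            abundances, config.criteria, breeds=config.breeds, diets=config.diets
        )
        _io.write_table(
            species_set.table.rename_axis("feature_id").reset_index(),
            outdir / "species_candidates.tsv",
        )
        t = species_set.table
        manifest["counts"]["species_total"] = int(len(t))
        manifest["counts"]["species_prevalent"] = int(t["prevalent"].sum())
        manifest["counts"]["species_ms_stable"] = int(t["ms_stable"].sum())
        manifest["counts"]["species_lw_significant"] = int(t["lw_significant"].sum())
        manifest["counts"]["species_candidates"] = len(species_set)
        logger.info(
            "species screen: %d/%d features pass",
            len(species_set),
            len(t),
        )
        manifest["stages"].append(stage)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    gene_set = None
    stage = "screen_genes"
    try:
        if expression is not None:
            gene_set = screen_genes(
                expression, config.criteria, breeds=config.breeds, diets=config.diets
            )
            _io.write_table(
                gene_set.table.rename_axis("gene_id").reset_index(),
                outdir / "gene_candidates.tsv",
            )
            manifest["counts"]["gene_total"] = int(len(gene_set.table))
            manifest["counts"]["gene_candidates"] = len(gene_set)
            manifest["counts"]["gene_up"] = len(gene_set.up)
            manifest["counts"]["gene_down"] = len(gene_set.down)
        manifest["stages"].append(stage)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- CAZyme profile ---------------------------------------------
    stage = "cazyme"
    try:
        if catalog is not None and len(catalog):
            profile = build_sgs(species_set, catalog)
            _io.write_table(
                profile.class_counts.rename_axis("species").reset_index(),
                outdir / "sgs_class_counts.tsv",
            )
            _io.write_table(
                profile.family_counts.rename_axis("species").reset_index(),
                outdir / "sgs_family_counts.tsv",
            )
            if profile.total > 0:
                comp = class_composition(profile)
                _io.write_table(
                    comp.rename("fraction").rename_axis("cazy_class").reset_index(),
                    outdir / "class_composition.tsv",
                )
                k = min(8, int((profile.species_totals > 0).sum()))
                if k >= 1:
                    manifest["counts"]["sgs_top8_share_pct"] = top_contributor_fraction(
                        profile, k
                    )
                    if profile.class_counts["GH"].sum() > 0:
                        manifest["counts"]["sgs_top8_gh_share_pct"] = (
                            top_contributor_fraction(profile, k, class_filter="GH")
                        )
            if (catalog["ko"] != "").any() and len(species_set):
                props, n_enzymes = enzyme_contribution_profile(
                    species_set, catalog, list(config.enzyme_list)
                )
                _io.write_table(
                    props.rename_axis("ko").reset_index(),
                    outdir / "enzyme_proportions.tsv",
                )
                manifest["counts"]["annotated_enzymes"] = n_enzymes
        manifest["stages"].append(stage)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- networks ----------------------------------------------------
    stage = "networks"
    try:
        candidates = species_set.passed
        for breed in config.breeds:
            keep = candidates or list(abundances.values.index)
            sub = abundances.values.loc[keep]
            # cap network size at the most abundant candidates for tractability
            order = sub.mean(axis=1).sort_values(ascending=False, kind="mergesort")
            keep = sorted(order.index[: config.max_network_species])
            net_table = AbundanceTable(
                abundances.values.loc[keep], abundances.metadata.copy()
            )
            net = cooccurrence_network(
                net_table,
                breed,
                alpha=config.cooccurrence_alpha,
                prevalence_min=config.prevalence_min,
            )
            _io.write_table(net.edges, outdir / f"cooccurrence_{breed}_edges.tsv")
            _io.write_table(net.node_table, outdir / f"cooccurrence_{breed}_nodes.tsv")
            manifest["counts"][f"cooccurrence_{breed}_edges"] = int(
                net.graph.number_of_edges()
            )

        if expression is not None and scfa is not None:
            expr_cpm = expression.closed().values * 1e6
            gene_table = gene_set.table if gene_set is not None else None
            if gene_table is not None and len(gene_set):
                top_genes = (
                    gene_table[gene_table["pass"]]
                    .sort_values("fdr_lw", kind="mergesort")
                    .index[:8]
                )
            else:
                top_genes = expr_cpm.index[:8]
            top_microbes = candidates[:4] if candidates else list(
                abundances.values.index[:4]
            )
            for breed in config.breeds:
                ids = abundances.samples_of(breed)
                ids = [s for s in ids if s in expr_cpm.columns and s in scfa.index]
                if len(ids) < 4:
                    continue
                layers = {
                    "host_gene": expr_cpm.loc[sorted(top_genes), ids],
                    "microbe": abundances.values.loc[sorted(top_microbes), ids],
                    "scfa": scfa.loc[ids].T,
                }
                net = integration_network(layers, alpha=config.integration_alpha)
                _io.write_table(net.edges, outdir / f"integration_{breed}_edges.tsv")
                manifest["counts"][f"integration_{breed}_edges"] = int(
                    net.graph.number_of_edges()
                )
        manifest["stages"].append(stage)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- planted-recovery report ------------------------------------
    stage = "report"
    try:
        if species_truth is not None:
            truth = species_truth["planted"]
            passed = species_set.table["pass"]
            planted_idx = truth[truth].index
            null_idx = truth[~truth].index
            recovery = {
                "species_sensitivity": float(passed.loc[planted_idx].mean())
                if len(planted_idx)
                else float("nan"),
                "species_null_admission": float(passed.loc[null_idx].mean())
                if len(null_idx)
                else float("nan"),
            }
            if gene_set is not None and gene_truth is not None:
                gpass = gene_set.table["pass"]
                gp = gene_truth["planted"]
                recovery["gene_sensitivity"] = (
                    float(gpass.loc[gp[gp].index].mean()) if gp.any() else float("nan")
                )
                recovery["gene_null_admission"] = (
                    float(gpass.loc[gp[~gp].index].mean())
                    if (~gp).any()
                    else float("nan")
                )
            manifest["recovery"] = recovery
        manifest["stages"].append(stage)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
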