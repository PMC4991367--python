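"""End-to-end analysis: simulate -> QC -> call -> deconvolve -> concordance.

Mirrors the structure of a multi-cohort whole-blood study: a panel of
purified leukocyte subtypes anchors both the myeloid/lymphoid differential
list and the deconvolution reference; bulk cohorts supply per-dataset age
associations (integrated across datasets) and an AD case/control rank-product
comparison; the concordance framework then separates composition-driven from
intrinsic calls and tests the filtered age/AD lists for overlap and
directional agreement.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    age_associations,
    concordance,
    deconvolution,
    differential,
    enrichment,
    preprocessing,
    synth,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineReport", "run_full_pipeline"]

DEFAULT_THRESHOLDS = (0.0, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40)


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and study-condition settings for a full synthetic run."""

    sim: synth.SimulationConfig = field(default_factory=synth.SimulationConfig)
    fdr: float = 0.05
    nominal_p: float = 0.05
    max_missing_rate: float = 0.10
    outlier_sd: float = 2.0
    outlier_iterations: int = 3
    n_markers: int = 500
    n_permutations: int = 100
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    covariates: tuple[str, ...] = ("sex",)
    #: AD case/control cohort: sizes and the elderly age range mirror a small
    #: clinical methylation cohort (48 cases vs 9 controls, ages 65-96)
    ad_n_samples: int = 57
    ad_fraction: float = 48 / 57
    ad_age_range: tuple[float, float] = (65.0, 96.0)
    seed: int = 0

    def __post_init__(self):
        for name in ("fdr", "nominal_p", "max_missing_rate"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.outlier_sd <= 0 or self.outlier_iterations < 0:
            raise ValueError("invalid outlier-removal settings")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", {})
        if "subtype_names" in sim_raw:
            sim_raw["subtype_names"] = tuple(tuple(x) for x in sim_raw["subtype_names"])
        for key in ("age_range", "age_slope_range", "ad_effect_range", "ml_diff_range"):
            if key in sim_raw:
                sim_raw[key] = tuple(sim_raw[key])
        if "thresholds" in raw:
            raw["thresholds"] = tuple(raw["thresholds"])
        if "ad_age_range" in raw:
            raw["ad_age_range"] = tuple(raw["ad_age_range"])
        if "covariates" in raw:
            raw["covariates"] = tuple(raw["covariates"])
        return cls(sim=synth.SimulationConfig(**sim_raw), **raw)

    def with_seed(self, seed: int) -> "PipelineConfig":
        return dataclasses.replace(self, seed=seed, sim=self.sim.replace(seed=seed))


@dataclass
class PipelineReport:
    """All stage outputs of one pipeline run, JSON-serializable via summary()."""

    config: PipelineConfig
    qc_age: preprocessing.QCReport
    qc_ad: preprocessing.QCReport
    universe: list[str]
    age_tables: dict[str, pd.DataFrame]
    age_cpgs: pd.Series
    ad_table: pd.DataFrame
    ad_cpgs: pd.Series
    ml_table: pd.DataFrame
    proportions: pd.DataFrame
    age_correlations: pd.DataFrame
    concordance_age_ml: concordance.ConcordanceResult
    concordance_ad_ml: concordance.ConcordanceResult
    age_threshold_curve: pd.DataFrame
    ad_threshold_curve: pd.DataFrame
    age_cpgs_filtered: pd.Series
    ad_cpgs_filtered: pd.Series
    overlap: concordance.OverlapResult
    concordance_ad_age: concordance.ConcordanceResult
    ad_age_cpgs: pd.Series
    enrichment_table: pd.DataFrame
    truth: synth.GroundTruth
    panel: synth.ReferencePanel

    def summary(self) -> dict:
        def conc(r: concordance.ConcordanceResult) -> dict:
            return {"k": r.k, "s": r.s, "rate": r.rate, "p_value": r.p_value, "mode": r.mode}

        return {
            "seed": self.config.seed,
            "n_universe_probes": len(self.universe),
            "qc_age": self.qc_age.to_dict(),
            "qc_ad": self.qc_ad.to_dict(),
            "n_age_cpgs_per_dataset": {k: int((t["q"] < self.config.fdr).sum())
                                       for k, t in self.age_tables.items()},
            "n_age_cpgs_integrated": int(len(self.age_cpgs)),
            "n_ad_cpgs": int(len(self.ad_cpgs)),
            "n_ml_cpgs": int(len(self.ml_table)),
            "age_correlations": self.age_correlations.round(6).to_dict(),
            "concordance_age_ml": conc(self.concordance_age_ml),
            "concordance_ad_ml": conc(self.concordance_ad_ml),
            "n_age_cpgs_filtered": int(len(self.age_cpgs_filtered)),
            "n_ad_cpgs_filtered": int(len(self.ad_cpgs_filtered)),
            "overlap": dataclasses.asdict(self.overlap),
            "concordance_ad_age": conc(self.concordance_ad_age),
            "n_ad_age_cpgs": int(len(self.ad_age_cpgs)),
            "n_enriched_terms": int(self.enrichment_table["called"].sum())
            if not self.enrichment_table.empty else 0,
        }

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, t in self.age_tables.items():
            t.to_csv(outdir / f"age_associations_{name}.tsv", sep="\t")
        self.age_cpgs.rename("direction").to_csv(outdir / "age_cpgs.tsv", sep="\t")
        self.ad_table.to_csv(outdir / "ad_rank_product.tsv", sep="\t")
        self.ad_cpgs.rename("direction").to_csv(outdir / "ad_cpgs.tsv", sep="\t")
        self.ml_table.to_csv(outdir / "ml_cpgs.tsv", sep="\t")
        self.proportions.to_csv(outdir / "proportions.tsv", sep="\t")
        self.age_threshold_curve.to_csv(outdir / "age_threshold_curve.tsv", sep="\t", index=False)
        self.ad_threshold_curve.to_csv(outdir / "ad_threshold_curve.tsv", sep="\t", index=False)
        self.ad_age_cpgs.rename("direction").to_csv(outdir / "ad_age_cpgs.tsv", sep="\t")
        if not self.enrichment_table.empty:
            self.enrichment_table.to_csv(outdir / "enrichment.tsv", sep="\t")
        (outdir / "report.json").write_text(json.dumps(self.summary(), indent=1, default=float))


def _signed_calls(table: pd.DataFrame, fdr: float) -> pd.Series:
    called = table[table["fdr"] < fdr]
    return called["direction"].astype(int)


def run_full_pipeline(config: PipelineConfig) -> PipelineReport:
    """Run every stage on freshly simulated data; see module docstring."""
    sim = config.sim
    logger.info("simulating reference panel and cohorts (seed=%d)", sim.seed)
    panel = synth.generate_reference_panel(sim)
    annotation = synth.generate_probe_annotation(sim)
    beta_age, ann_age, truth = synth.generate_mixture_cohort(panel, sim)
    ad_sim = sim.replace(
        n_samples=config.ad_n_samples,
        ad_fraction=config.ad_fraction,
        age_range=config.ad_age_range,
        n_datasets=1,
        n_outliers=0,
        seed=sim.seed + 1000,
        # same planted biology as the age cohort, fresh samples
        effects_seed=sim.effects_seed if sim.effects_seed is not None else sim.seed,
    )
    beta_ad, ann_ad, _ = synth.generate_mixture_cohort(panel, ad_sim)

    logger.info("preprocessing bulk cohorts")
    beta_age, qc_age = preprocessing.preprocess(
        beta_age, annotation,
        max_missing_rate=config.max_missing_rate,
        outlier_sd=config.outlier_sd,
        outlier_iterations=config.outlier_iterations,
    )
    # the case/control cohort skips outlier removal (QC step reserved for the
    # age cohorts); probe filtering still applies
    beta_ad, qc_ad = preprocessing.preprocess(
        beta_ad, annotation,
        max_missing_rate=config.max_missing_rate,
        outlier_iterations=0,
    )
    universe = beta_age.index.intersection(beta_ad.index).tolist()
    beta_age, beta_ad = beta_age.loc[universe], beta_ad.loc[universe]
    ann_age = ann_age.loc[beta_age.columns]
    ann_ad = ann_ad.loc[beta_ad.columns]

    logger.info("age associations per dataset + integration")
    age_tables = {}
    for ds, ann_ds in ann_age.groupby("dataset"):
        age_tables[ds] = age_associations.fit_age_models(
            beta_age[ann_ds.index], ann_ds, list(config.covariates), dataset_id=ds
        )
    age_cpgs = age_associations.integrate_age_cpgs(
        list(age_tables.values()), fdr=config.fdr, nominal_p=config.nominal_p
    )

    logger.info("AD rank-product test (%d permutations)", config.n_permutations)
    ad_table = differential.rank_product_test(
        beta_ad, ann_ad["group"], n_permutations=config.n_permutations,
        seed=config.seed + 7, class1="AD",
    )
    ad_cpgs = _signed_calls(ad_table, config.fdr)

    logger.info("myeloid/lymphoid differential probes from the reference panel")
    panel_u = synth.ReferencePanel(
        profiles=panel.profiles.loc[universe],
        subtype_of=panel.subtype_of,
        lineage_of=panel.lineage_of,
        ml_truth=panel.ml_truth,
    )
    ml_table = differential.call_ml_cpgs(panel_u, fdr=config.fdr)

    logger.info("deconvolution of the age cohort")
    proportions = deconvolution.estimate_proportions_cohort(
        beta_age, panel_u, n_markers=min(config.n_markers, len(universe))
    )
    age_correlations = deconvolution.correlate_proportions_age(proportions, ann_age)

    logger.info("concordance framework")
    ml_dirs = ml_table["direction"].astype(int)
    conc_age_ml = concordance.classify_concordance(age_cpgs, ml_dirs, mode="age-ml")
    conc_ad_ml = concordance.classify_concordance(ad_cpgs, ml_dirs, mode="ad-ml")
    age_curve = concordance.concordance_by_difference_threshold(
        age_cpgs, ml_table, list(config.thresholds), mode="age-ml"
    )
    ad_curve = concordance.concordance_by_difference_threshold(
        ad_cpgs, ml_table, list(config.thresholds), mode="ad-ml"
    )

    age_filtered = concordance.filter_composition_concordant(age_cpgs, ml_dirs)
    ad_filtered = concordance.filter_composition_concordant(ad_cpgs, ml_dirs)
    shared = age_filtered.index.intersection(ad_filtered.index)
    overlap = concordance.hypergeometric_overlap(
        N=len(universe), K=len(age_filtered), n=len(ad_filtered), k=len(shared)
    )
    conc_ad_age = concordance.classify_concordance(ad_filtered, age_filtered, mode="ad-age")
    ad_age_cpgs = age_filtered[shared[(age_filtered[shared] == ad_filtered[shared])]]

    if len(ad_age_cpgs):
        terms = synth.generate_term_map(annotation, truth, seed=sim.seed)
        enrich = enrichment.fisher_term_enrichment(
            list(ad_age_cpgs.index), universe, annotation, terms, alpha=config.fdr
        )
    else:
        enrich = pd.DataFrame()

    return PipelineReport(
        config=config, qc_age=qc_age, qc_ad=qc_ad, universe=universe,
        age_tables=age_tables, age_cpgs=age_cpgs,
        ad_table=ad_table, ad_cpgs=ad_cpgs, ml_table=ml_table,
        proportions=proportions, age_correlations=age_correlations,
        concordance_age_ml=conc_age_ml, concordance_ad_ml=conc_ad_ml,
        age_threshold_curve=age_curve, ad_threshold_curve=ad_curve,
        age_cpgs_filtered=age_filtered, ad_cpgs_filtered=ad_filtered,
        overlap=overlap, concordance_ad_age=conc_ad_age, ad_age_cpgs=ad_age_cpgs,
        enrichment_table=enrich, truth=truth, panel=panel,
    )
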