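"""End-to-end pipeline: score panel in, index and hypothesis tables out."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import evaluate, indices, pca, reliability
from .io import AnalysisConfig, FEATURES


@dataclass
class PipelineResult:
    feature_table: pd.DataFrame  # rescaled rater means + sigma columns
    reliability: pd.DataFrame
    pca_result: pca.PCAResult
    stopping_rules: pd.DataFrame
    reduction_trace: pca.ReductionTrace
    index_table: pd.DataFrame
    classification: pd.DataFrame
    species_summary: pd.DataFrame | None
    tests: pd.DataFrame | None
    musical_summary: dict


def run_pipeline(
    panel: pd.DataFrame,
    metadata: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    config: AnalysisConfig | None = None,
    compute_reliability: bool = True,
) -> PipelineResult:
    """Run aggregation, PCA reduction, indexing and the hypothesis battery.

    Mirrors the study design: average raters, rescale to probabilities,
    standardize all six features for the correlation-matrix PCA, run the
    retention battery and the backward variable elimination, compute ARDI and
    the approximate song complexity per call, attach PC1 scores, classify
    call names, and (when covariates are given) test the species-level
    maxima against the socioecological covariates.
    """
    cfg = config or AnalysisConfig()
    averaged = reliability.average_raters(panel)
    table = reliability.rescale_probabilities(averaged)
    rel = reliability.reliability_report(panel) if compute_reliability else pd.DataFrame()

    standardized = reliability.standardize(table, FEATURES)
    pca_res = pca.run_pca(standardized)
    rules = pca.stopping_rule_report(
        pca_res,
        kaiser_threshold=cfg.kaiser_threshold,
        jolliffe_cutoff=cfg.jolliffe_cutoff,
        cumvar_threshold=cfg.cumvar_threshold,
        pa_replicates=cfg.pa_replicates,
        pa_criterion=cfg.pa_criterion,
        rng=cfg.rng_seed,
    )
    trace = pca.jolliffe_b2_eliminate(standardized, cutoff=cfg.jolliffe_cutoff)

    index_table = indices.build_index_table(
        table, metadata, clamp=cfg.clamp_reappearance
    )
    index_table = pca.attach_pc1_scores(pca_res, index_table)
    classification = evaluate.classify_call_names(metadata, cfg.musical_keywords)
    index_table["musical_flag"] = classification["musical_flag"].reindex(index_table.index)
    musical_summary = indices.summarize_putative_musical(table, index_table)

    species_summary = None
    tests = None
    if covariates is not None:
        species_summary = indices.species_max_index(index_table, metadata, covariates)
        results = evaluate.run_hypothesis_battery(species_summary)
        tests = evaluate.tests_table(results)

    return PipelineResult(
        feature_table=table,
        reliability=rel,
        pca_result=pca_res,
        stopping_rules=rules,
        reduction_trace=trace,
        index_table=index_table,
        classification=classification,
        species_summary=species_summary,
        tests=tests,
        musical_summary=musical_summary,
    )
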