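"""End-to-end orchestration of the cfRNA analysis stages.

A single :class:`RunConfig` (flat keys, YAML-serializable) drives the run;
one global seed expands into per-stage seeds by fixed offsets so identical
configs give byte-identical metrics. Each stage logs its inputs and the
row/gene counts surviving each filter, and writes its tables and metrics
under the run directory.
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

from . import clock, correction, genesets, pe, simulate
from .containers import ExpressionMatrix, Space
from .io import write_annotation, write_counts_tsv, write_gmt, write_json

logger = logging.getLogger(__name__)

# fixed per-stage seed offsets from the global seed
SEED_OFFSETS = {"simulate": 0, "correct": 101, "ga_clock": 202,
                "trends": 303, "pe": 404}


class DependencyError(RuntimeError):
    """A stage's upstream artifact is missing; message names the stage."""


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "run"
    # stage toggles
    run_simulate: bool = True
    run_correct: bool = True
    run_ga_clock: bool = True
    run_trends: bool = True
    run_pe: bool = True
    # simulation scale
    n_cohorts: int = 8
    samples_per_cohort: int = 100
    n_genes: int = 1200
    trend_frac: float = 0.1
    slope_scale: float = 0.05
    cohort_offset_sd: float = 0.3
    pe_effect: float = 1.0
    pe_prevalence: float = 0.137
    longitudinal_subjects: int = 93
    # stage parameters (defaults mirror the analysis conventions)
    qc_k_sd: float = 3.0
    cv_folds: int = 10
    n_alphas: int = 40
    trend_alpha: float = 0.01
    confirm_alpha: float = 0.05
    min_confirm_cohorts: int = 2
    screen_alpha: float = 0.05
    sensitivity_target: float = 0.75
    bootstrap_B: int = 1000

    def stage_seed(self, stage: str) -> int:
        return self.seed * 1000 + SEED_OFFSETS[stage]

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sim_config(cfg: RunConfig) -> simulate.SimConfig:
    return simulate.SimConfig(
        n_cohorts=cfg.n_cohorts,
        samples_per_cohort=[cfg.samples_per_cohort] * cfg.n_cohorts,
        ga_window_per_cohort=simulate.DEFAULT_GA_WINDOWS[: cfg.n_cohorts],
        n_genes=cfg.n_genes,
        trend_frac=cfg.trend_frac,
        slope_scale=cfg.slope_scale,
        cohort_offset_sd=cfg.cohort_offset_sd,
        pe_effect=cfg.pe_effect,
        pe_prevalence=cfg.pe_prevalence,
        longitudinal_cohort=simulate.LongitudinalSpec(n_subjects=cfg.longitudinal_subjects),
        seed=cfg.stage_seed("simulate"),
    )


def run_all(config: RunConfig) -> dict:
    """Run every enabled stage; returns the metrics dict written to
    ``<out_dir>/metrics.json``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    metrics: dict = {"seed": config.seed}
    state: dict = {}

    if config.run_simulate:
        _stage_simulate(config, state, metrics, out)
    if config.run_correct:
        _require(state, "matrix", "correct")
        _stage_correct(config, state, metrics)
    if config.run_ga_clock:
        _require(state, "corrected_train", "ga_clock")
        _stage_ga_clock(config, state, metrics)
    if config.run_trends:
        _require(state, "longitudinal", "trends")
        _stage_trends(config, state, metrics)
    if config.run_pe:
        _require(state, "matrix", "pe")
        _stage_pe(config, state, metrics)

    write_json(metrics, out / "metrics.json")
    return metrics


def _require(state: dict, key: str, stage: str) -> None:
    if key not in state:
        raise DependencyError(
            f"stage {stage!r} requires upstream artifact {key!r}; "
            "enable the producing stage or supply it on disk"
        )


def _stage_simulate(cfg: RunConfig, state: dict, metrics: dict, out: Path) -> None:
    sim = _sim_config(cfg)
    matrix, ann, gene_ann, sets, truth = simulate.simulate_cohorts(sim)
    lmatrix, lann, lgene_ann, lsets, ltruth = simulate.simulate_multi_longitudinal(sim)
    state.update(matrix=matrix, ann=ann, gene_ann=gene_ann, sets=sets, truth=truth,
                 longitudinal=(lmatrix, lann, lsets, ltruth))
    write_counts_tsv(matrix, out / "counts.tsv")
    write_annotation(ann, out / "samples.tsv")
    write_annotation(gene_ann, out / "genes.tsv")
    write_gmt(sets, out / "gene_sets.gmt")
    write_json(truth.to_dict(), out / "truth.json")
    metrics["simulate"] = {"n_samples": int(matrix.n_samples),
                           "n_genes": int(matrix.n_genes),
                           "n_longitudinal_samples": int(lmatrix.n_samples)}
    logger.info("simulate: %d samples x %d genes", matrix.n_samples, matrix.n_genes)


def _stage_correct(cfg: RunConfig, state: dict, metrics: dict) -> None:
    matrix, ann = state["matrix"], state["ann"]
    qc = ann.set_index("sample_id")[["qc_total_reads", "qc_dup_rate", "qc_actb_ct"]]
    flags = correction.flag_outliers(qc, k=cfg.qc_k_sd)
    keep = flags.flagged.index[~flags.flagged]
    logger.info("correct: QC kept %d/%d samples", len(keep), len(ann))
    ann = ann[ann["sample_id"].isin(keep)].reset_index(drop=True)
    matrix = matrix.subset_samples(ann["sample_id"])

    healthy = ann[ann["outcome"] == "normotensive"]
    spec = clock.SplitSpec(seed=cfg.stage_seed("correct"))
    train_ids, test_ids = clock.split_stratified(healthy, spec)

    log_m = correction.log_transform(correction.compute_cpm(matrix))
    totals = ann.set_index("sample_id")["qc_total_reads"].astype(float)
    ga = ann.set_index("sample_id")["ga_collect_weeks"].astype(float)
    cohort = ann.set_index("sample_id")["cohort"]
    model = correction.fit_cohort_correction(
        log_m.subset_samples(train_ids), ga, cohort, totals=totals)
    corrected = correction.apply_correction(model, log_m, cohort, totals)
    state.update(ann=ann, log_m=log_m, corrected=corrected, corr_model=model,
                 corrected_train=train_ids, corrected_test=test_ids,
                 totals=totals, ga=ga, cohort=cohort)
    metrics["correct"] = {"n_flagged": int(flags.flagged.sum()),
                          "flagged_fraction": flags.flagged_fraction,
                          "n_train": len(train_ids), "n_test": len(test_ids)}


def _stage_ga_clock(cfg: RunConfig, state: dict, metrics: dict) -> None:
    corrected, ann = state["corrected"], state["ann"]
    train_ids, test_ids = state["corrected_train"], state["corrected_test"]
    features = clock.filter_features(corrected, state["gene_ann"], sample_ids=train_ids)
    logger.info("ga_clock: %d/%d genes pass the feature filter",
                len(features), corrected.n_genes)
    X = corrected.data.loc[features].T
    y = state["ga"]
    curve = clock.fit_lasso_cv(X.loc[train_ids], y.loc[train_ids],
                               folds=cfg.cv_folds, seed=cfg.stage_seed("ga_clock"),
                               n_alphas=cfg.n_alphas)
    alpha = clock.select_one_se(curve)
    model = clock.fit_final(X.loc[train_ids], y.loc[train_ids], alpha)
    pred = clock.predict(model, X.loc[test_ids])
    mae = clock.evaluate_mae(pred, y)
    cov = ann.set_index("sample_id").loc[test_ids, ["bmi", "maternal_age", "race"]]
    decomp = clock.anova_variance(y.loc[test_ids], pred, cov)
    state.update(ga_model=model, ga_pred=pred)
    metrics["ga_clock"] = {
        "alpha": alpha,
        "n_features_used": model.n_features_used,
        "test_mae_days": mae,
        "variance_fractions": decomp.fractions.to_dict(),
    }


def _stage_trends(cfg: RunConfig, state: dict, metrics: dict) -> None:
    lmatrix, lann, lsets, _ = state["longitudinal"]
    cpm = correction.compute_cpm(lmatrix)
    scores = genesets.partition_scores(cpm, lsets, lann)
    fits = genesets.fit_trends_by_cohort(scores)
    confirmed = genesets.confirm_across_cohorts(
        fits, discovery="H", alpha_discovery=cfg.trend_alpha,
        alpha_confirm=cfg.confirm_alpha, min_other=cfg.min_confirm_cohorts)
    mono = genesets.monotonicity_test(
        scores[(scores["cohort"] == "H")
               & (scores["set_name"] == scores["set_name"].iloc[0])])
    state.update(scores=scores, trend_fits=fits, confirmed=confirmed)
    metrics["trends"] = {
        "n_sets_tested": int(fits["set_name"].nunique()) if len(fits) else 0,
        "n_confirmed": int(confirmed["confirmed"].sum()) if len(confirmed) else 0,
        "monotonicity": mono.to_dict(),
    }


def _stage_pe(cfg: RunConfig, state: dict, metrics: dict) -> None:
    ann = state["ann"]
    # case-control design from two cohorts, second-trimester style
    cc_cohorts = [c for c in ("A", "E") if c in set(ann["cohort"])] or \
        sorted(ann["cohort"].unique())[:2]
    design = ann[ann["cohort"].isin(cc_cohorts)].set_index("sample_id")
    y = (design["outcome"] == "PE").astype(int)
    X = state["corrected"].data.loc[:, design.index].T
    rep = pe.full_report(X, y, alpha=cfg.screen_alpha,
                         sens_target=cfg.sensitivity_target,
                         B=cfg.bootstrap_B, seed=cfg.stage_seed("pe"))
    positive = rep.oof_prob >= rep.threshold
    sptb = design["outcome"] == "sPTB"
    surv = pe.km_logrank(design["ga_delivery_weeks"], positive, exclude=sptb)
    metrics["pe"] = {
        "n_cases": int(y.sum()), "n_noncases": int((1 - y).sum()),
        "prevalence_percent": 100.0 * float(y.mean()),
        "auc": rep.auc, "auc_ci": list(rep.auc_ci),
        "sensitivity": rep.sensitivity, "specificity": rep.specificity,
        "ppv_percent": 100.0 * rep.ppv,
        "consensus_features": rep.consensus_features,
        "km_logrank_p": surv.p_value,
    }
    state["pe_report"] = rep
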