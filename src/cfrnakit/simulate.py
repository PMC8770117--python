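"""Multi-cohort cell-free RNA count simulator with known ground truth.

Emulates the structure of a multi-site plasma cfRNA study: several cohorts
sampled over distinct gestational-age (GA) windows, per-gene linear GA
trends in log2-CPM space, additive per-(gene, cohort) offsets that are
partially confounded with GA because cohorts occupy different GA windows,
negative-binomial counts around CPM-implied means scaled by lognormal
library sizes, a small gene panel perturbed in pre-eclampsia (PE) cases,
and clinical covariates drawn independently of the transcriptome.

Every generated dataset is accompanied by a :class:`TruthRecord` so that
downstream correction, regression and classification stages can be tested
for parameter recovery rather than against inaccessible real data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneSetCollection, Space

#: Default per-cohort GA windows (weeks), one per cohort A..H, spanning the
#: range a multi-site pregnancy study covers; cohorts deliberately occupy
#: different windows so cohort offsets are partially confounded with GA.
DEFAULT_GA_WINDOWS = [
    (12.0, 27.9),
    (5.6, 38.2),
    (8.9, 28.1),
    (12.2, 23.8),
    (16.9, 26.8),
    (4.9, 40.2),
    (8.0, 38.7),
    (11.4, 34.8),
]

#: The four longitudinal draw windows (weeks).
DEFAULT_DRAW_WINDOWS = [(11.4, 14.0), (18.0, 21.0), (22.8, 27.8), (29.2, 34.8)]

RACES = ("asian", "black", "hispanic", "white", "other")


class SimConfigError(ValueError):
    """Invalid simulation configuration; message names the offending field."""


@dataclass
class LongitudinalSpec:
    """Serial-sampling design: each subject drawn once per window."""

    n_subjects: int = 93
    draw_windows: Sequence[tuple] = field(default_factory=lambda: list(DEFAULT_DRAW_WINDOWS))


@dataclass
class SimConfig:
    """Parameters of the generating model.

    Units: GA in weeks; baselines, slopes, offsets and PE effects in
    log2-CPM; library sizes in raw read counts (lognormal); dispersion is
    the negative-binomial overdispersion (variance = mu + dispersion*mu^2).
    """

    n_cohorts: int = 8
    samples_per_cohort: Sequence[int] = field(default_factory=lambda: [150] * 8)
    ga_window_per_cohort: Sequence[tuple] = field(
        default_factory=lambda: list(DEFAULT_GA_WINDOWS)
    )
    n_genes: int = 2000
    frac_coding: float = 0.7
    trend_frac: float = 0.1
    slope_scale: float = 0.05
    cohort_offset_sd: float = 0.3
    libsize_meanlog: float = 14.5
    libsize_sdlog: float = 0.4
    nb_dispersion: float = 0.1
    pe_prevalence: float = 0.137
    pe_panel_size: int = 7
    pe_effect: float = 1.0
    n_gene_sets: int = 20
    gene_set_size_range: tuple = (10, 50)
    longitudinal_cohort: Optional[LongitudinalSpec] = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_cohorts < 1:
            raise SimConfigError("n_cohorts must be >= 1")
        if len(self.samples_per_cohort) != self.n_cohorts:
            raise SimConfigError("samples_per_cohort length must equal n_cohorts")
        if len(self.ga_window_per_cohort) != self.n_cohorts:
            raise SimConfigError("ga_window_per_cohort length must equal n_cohorts")
        for lo, hi in self.ga_window_per_cohort:
            if not (4.0 < lo < hi < 42.0):
                raise SimConfigError(
                    f"ga_window_per_cohort window ({lo}, {hi}) outside (4, 42) weeks"
                )
        if not 0.0 <= self.frac_coding <= 1.0:
            raise SimConfigError("frac_coding must be in [0, 1]")
        if not 0.0 <= self.trend_frac <= 1.0:
            raise SimConfigError("trend_frac must be in [0, 1]")
        if not 0.0 <= self.pe_prevalence <= 1.0:
            raise SimConfigError("pe_prevalence must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise SimConfigError("nb_dispersion must be > 0")
        if self.longitudinal_cohort is not None:
            windows = list(self.longitudinal_cohort.draw_windows)
            if len(windows) != 4:
                raise SimConfigError("longitudinal_cohort.draw_windows must have 4 windows")
            for (lo, hi) in windows:
                if not (4.0 < lo < hi < 42.0):
                    raise SimConfigError(
                        f"longitudinal draw window ({lo}, {hi}) outside (4, 42) weeks"
                    )
            for (_, prev_hi), (lo, _) in zip(windows[:-1], windows[1:]):
                if lo <= prev_hi:
                    raise SimConfigError(
                        "longitudinal draw windows must be strictly increasing and non-overlapping"
                    )


@dataclass
class TruthRecord:
    """Ground truth of a simulated dataset, for parameter-recovery tests."""

    gene_baseline: pd.Series  # log2-CPM intercept per gene
    gene_slope: pd.Series  # log2-CPM per week, 0 for non-trending genes
    cohort_offset: pd.DataFrame  # genes x cohorts, log2-CPM
    pe_panel: list  # gene ids perturbed in PE cases
    pe_effect: float
    libsize_factor: pd.Series  # per-sample total-count draw
    biotype: pd.Series  # per-gene biotype label
    set_membership: dict  # set name -> member gene ids
    set_slope: pd.Series  # per-set mean true member slope (log2-CPM/week)

    def to_dict(self) -> dict:
        return {
            "gene_baseline": self.gene_baseline.to_dict(),
            "gene_slope": self.gene_slope.to_dict(),
            "cohort_offset": {c: self.cohort_offset[c].to_dict() for c in self.cohort_offset},
            "pe_panel": list(self.pe_panel),
            "pe_effect": self.pe_effect,
            "libsize_factor": self.libsize_factor.to_dict(),
            "biotype": self.biotype.to_dict(),
            "set_membership": {k: list(v) for k, v in self.set_membership.items()},
            "set_slope": self.set_slope.to_dict(),
        }


def _gene_universe(cfg: SimConfig, rng: np.random.Generator):
    """Draw per-gene biotypes, baselines and GA slopes."""
    genes = pd.Index([f"G{i:05d}" for i in range(cfg.n_genes)], name="gene_id")
    n_coding = int(round(cfg.frac_coding * cfg.n_genes))
    biotype = np.array(["protein_coding"] * n_coding + [""] * (cfg.n_genes - n_coding), dtype=object)
    other = rng.choice(["pseudogene", "non_coding"], size=cfg.n_genes - n_coding)
    biotype[n_coding:] = other
    baseline = rng.normal(4.0, 2.0, size=cfg.n_genes).clip(min=0.0)

    slope = np.zeros(cfg.n_genes)
    n_trend = int(round(cfg.trend_frac * cfg.n_genes))
    trend_idx = rng.choice(cfg.n_genes, size=n_trend, replace=False)
    # every trending gene gets a sign and a magnitude bounded away from zero
    # so TruthRecord signs are meaningful for recovery tests
    mags = np.abs(rng.normal(cfg.slope_scale, cfg.slope_scale / 2, size=n_trend))
    mags = np.maximum(mags, cfg.slope_scale / 4)
    signs = rng.choice([-1.0, 1.0], size=n_trend)
    slope[trend_idx] = signs * mags
    return genes, pd.Series(biotype, index=genes), pd.Series(baseline, index=genes), pd.Series(
        slope, index=genes
    )


def _build_gene_sets(cfg, genes, slope, rng) -> tuple:
    """Sample co-trending gene sets so set-level slopes are known.

    Half the sets draw from positively trending genes, half from negatively
    trending genes, topped up with flat genes when a pool is small; the set
    slope recorded in TruthRecord is the mean member slope.
    """
    pos_pool = list(genes[slope > 0])
    neg_pool = list(genes[slope < 0])
    flat_pool = list(genes[slope == 0])
    membership: dict = {}
    lo, hi = cfg.gene_set_size_range
    for i in range(cfg.n_gene_sets):
        size = int(rng.integers(lo, hi + 1))
        pool = pos_pool if i % 2 == 0 else neg_pool
        take = min(size, len(pool))
        members = list(rng.choice(pool, size=take, replace=False)) if take else []
        if take < size:
            top_up = min(size - take, len(flat_pool))
            members += list(rng.choice(flat_pool, size=top_up, replace=False))
        membership[f"SET{i:02d}"] = members
    set_slope = pd.Series(
        {name: float(slope.loc[m].mean()) for name, m in membership.items()}, name="set_slope"
    )
    collection = GeneSetCollection(
        {name: (f"synthetic co-trending set {name}", m) for name, m in membership.items()}
    )
    return collection, membership, set_slope


def _draw_counts(mu_log2cpm: np.ndarray, libsizes: np.ndarray, dispersion: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Negative-binomial counts around CPM-implied means.

    mu_log2cpm is genes x samples; CPM weights are renormalized per sample
    so expected counts sum to the sample's library size.
    """
    cpm = np.maximum(np.exp2(mu_log2cpm) - 1.0, 0.0)
    colsum = cpm.sum(axis=0)
    colsum[colsum == 0] = 1.0
    frac = cpm / colsum
    mean = frac * libsizes[None, :]
    size = 1.0 / dispersion  # NB shape: var = mu + mu^2/size
    p = size / (size + mean)
    return rng.negative_binomial(size, p).astype(np.int64)


def _clinical_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Clinical covariates drawn independently of expression."""
    return pd.DataFrame(
        {
            "bmi": rng.normal(27.5, 6.5, size=n).clip(15, 55).round(1),
            "maternal_age": rng.normal(30.0, 5.3, size=n).clip(16, 48).round(1),
            "race": rng.choice(RACES, size=n, p=[0.05, 0.25, 0.1, 0.5, 0.1]),
        }
    )


def _delivery_ga(outcome: np.ndarray, ga_collect: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """Delivery GA as 40 - Exp(rate) weeks truncated to [24, 42]; PE earlier."""
    n = len(outcome)
    delivery = 40.0 - rng.exponential(1.5, size=n)
    delivery[outcome == "PE"] -= rng.exponential(2.5, size=int((outcome == "PE").sum()))
    delivery[outcome == "sPTB"] = rng.uniform(28.0, 36.9, size=int((outcome == "sPTB").sum()))
    delivery = np.clip(delivery, 24.0, 42.0)
    return np.maximum(delivery, ga_collect + 0.5)


def _assign_outcomes(n: int, prevalence: float, rng: np.random.Generator) -> np.ndarray:
    """Case/non-case labels with non-case substrata (HTN variants, sPTB)."""
    outcome = np.full(n, "normotensive", dtype=object)
    u = rng.random(n)
    outcome[u < prevalence] = "PE"
    noncase = outcome != "PE"
    v = rng.random(n)
    outcome[noncase & (v < 0.06)] = "chronic_htn"
    outcome[noncase & (v >= 0.06) & (v < 0.10)] = "gestational_htn"
    outcome[noncase & (v >= 0.10) & (v < 0.16)] = "sPTB"
    return outcome


def simulate_cohorts(config: SimConfig):
    """Generate the full multi-cohort dataset.

    Returns
    -------
    (ExpressionMatrix, sample annotation DataFrame, gene annotation
    DataFrame, GeneSetCollection, TruthRecord)
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes, biotype, baseline, slope = _gene_universe(config, rng)
    sets, membership, set_slope = _build_gene_sets(config, genes, slope, rng)

    cohort_names = [chr(ord("A") + i) for i in range(config.n_cohorts)]
    offsets = pd.DataFrame(
        rng.normal(0.0, config.cohort_offset_sd, size=(config.n_genes, config.n_cohorts)),
        index=genes,
        columns=cohort_names,
    )

    coding = genes[biotype == "protein_coding"]
    panel = list(rng.choice(coding, size=config.pe_panel_size, replace=False))
    panel_mask = genes.isin(panel).astype(float)

    rows = []
    mu_blocks = []
    sample_counter = 0
    for ci, cname in enumerate(cohort_names):
        n_s = config.samples_per_cohort[ci]
        lo, hi = config.ga_window_per_cohort[ci]
        ga = rng.uniform(lo, hi, size=n_s)
        outcome = _assign_outcomes(n_s, config.pe_prevalence, rng)
        cov = _clinical_covariates(n_s, rng)
        delivery = _delivery_ga(outcome, ga, rng)
        for j in range(n_s):
            rows.append(
                {
                    "sample_id": f"S{sample_counter:05d}",
                    "subject_id": f"P{sample_counter:05d}",
                    "cohort": cname,
                    "draw_index": 1,
                    "ga_collect_weeks": round(float(ga[j]), 2),
                    "ga_delivery_weeks": round(float(delivery[j]), 2),
                    "outcome": outcome[j],
                    "bmi": cov.loc[j, "bmi"],
                    "maternal_age": cov.loc[j, "maternal_age"],
                    "race": cov.loc[j, "race"],
                }
            )
            sample_counter += 1
        mu = (
            baseline.values[:, None]
            + slope.values[:, None] * ga[None, :]
            + offsets[cname].values[:, None]
        )
        mu = mu + config.pe_effect * panel_mask[:, None] * (outcome == "PE")[None, :]
        mu_blocks.append(mu)

    ann = pd.DataFrame(rows)
    mu_all = np.concatenate(mu_blocks, axis=1)
    libsizes = rng.lognormal(config.libsize_meanlog, config.libsize_sdlog, size=len(ann))
    counts = _draw_counts(mu_all, libsizes, config.nb_dispersion, rng)
    ann["qc_total_reads"] = counts.sum(axis=0)
    ann["qc_dup_rate"] = rng.beta(8, 30, size=len(ann)).round(4)
    ann["qc_actb_ct"] = rng.normal(24.0, 1.2, size=len(ann)).round(2)

    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=genes, columns=ann["sample_id"].tolist()),
        Space.raw_counts,
    )
    gene_ann = pd.DataFrame({"gene_id": genes, "biotype": biotype.values})
    truth = TruthRecord(
        gene_baseline=baseline,
        gene_slope=slope,
        cohort_offset=offsets,
        pe_panel=panel,
        pe_effect=config.pe_effect,
        libsize_factor=pd.Series(libsizes, index=ann["sample_id"].tolist()),
        biotype=biotype,
        set_membership=membership,
        set_slope=set_slope,
    )
    return matrix, ann, gene_ann, sets, truth


def simulate_longitudinal(config: SimConfig):
    """Generate a serial-sampling cohort: each subject drawn once per window.

    Returns the same tuple as :func:`simulate_cohorts`; the annotation has
    ``n_subjects x 4`` rows with subject identity and draw index recorded.
    """
    if config.longitudinal_cohort is None:
        raise SimConfigError("longitudinal_cohort must be set for simulate_longitudinal")
    config.validate()
    spec = config.longitudinal_cohort
    rng = np.random.default_rng(config.seed + 1)
    genes, biotype, baseline, slope = _gene_universe(config, rng)
    sets, membership, set_slope = _build_gene_sets(config, genes, slope, rng)

    cohort = "H"
    offsets = pd.DataFrame(0.0, index=genes, columns=[cohort])

    windows = list(spec.draw_windows)
    rows = []
    ga_cols = []
    for s in range(spec.n_subjects):
        cov = _clinical_covariates(1, rng).iloc[0]
        delivery = float(np.clip(40.0 - rng.exponential(1.5), 24.0, 42.0))
        for d, (lo, hi) in enumerate(windows, start=1):
            ga = float(rng.uniform(lo, hi))
            ga_cols.append(ga)
            rows.append(
                {
                    "sample_id": f"H{s:03d}_d{d}",
                    "subject_id": f"HP{s:03d}",
                    "cohort": cohort,
                    "draw_index": d,
                    "ga_collect_weeks": round(ga, 2),
                    "ga_delivery_weeks": round(delivery, 2),
                    "outcome": "normotensive",
                    "bmi": cov["bmi"],
                    "maternal_age": cov["maternal_age"],
                    "race": cov["race"],
                }
            )
    ann = pd.DataFrame(rows)
    ga_arr = np.array(ga_cols)
    mu = baseline.values[:, None] + slope.values[:, None] * ga_arr[None, :]
    libsizes = rng.lognormal(config.libsize_meanlog, config.libsize_sdlog, size=len(ann))
    counts = _draw_counts(mu, libsizes, config.nb_dispersion, rng)
    ann["qc_total_reads"] = counts.sum(axis=0)
    ann["qc_dup_rate"] = rng.beta(8, 30, size=len(ann)).round(4)
    ann["qc_actb_ct"] = rng.normal(24.0, 1.2, size=len(ann)).round(2)

    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=genes, columns=ann["sample_id"].tolist()),
        Space.raw_counts,
    )
    gene_ann = pd.DataFrame({"gene_id": genes, "biotype": biotype.values})
    truth = TruthRecord(
        gene_baseline=baseline,
        gene_slope=slope,
        cohort_offset=offsets,
        pe_panel=[],
        pe_effect=0.0,
        libsize_factor=pd.Series(libsizes, index=ann["sample_id"].tolist()),
        biotype=biotype,
        set_membership=membership,
        set_slope=set_slope,
    )
    return matrix, ann, gene_ann, sets, truth


def simulate_multi_longitudinal(config: SimConfig, n_cohorts: int = 4,
                                subjects_per_cohort: Sequence[int] | None = None):
    """Several longitudinal cohorts sharing one gene universe.

    Used for the cross-cohort confirmation analysis: the first cohort plays
    the discovery role and the rest are confirmation cohorts. Cohort names
    are H, A, B, G (discovery first) then numbered.
    """
    if config.longitudinal_cohort is None:
        raise SimConfigError("longitudinal_cohort must be set")
    config.validate()
    spec = config.longitudinal_cohort
    if subjects_per_cohort is None:
        subjects_per_cohort = [spec.n_subjects] * n_cohorts
    rng = np.random.default_rng(config.seed + 2)
    genes, biotype, baseline, slope = _gene_universe(config, rng)
    sets, membership, set_slope = _build_gene_sets(config, genes, slope, rng)
    names = (["H", "A", "B", "G"] + [f"L{i}" for i in range(4, n_cohorts)])[:n_cohorts]
    offsets = pd.DataFrame(
        rng.normal(0.0, config.cohort_offset_sd, size=(config.n_genes, n_cohorts)),
        index=genes, columns=names,
    )
    offsets["H"] = 0.0

    rows, mu_cols = [], []
    for cname, n_sub in zip(names, subjects_per_cohort):
        for s in range(n_sub):
            delivery = float(np.clip(40.0 - rng.exponential(1.5), 24.0, 42.0))
            for d, (lo, hi) in enumerate(spec.draw_windows, start=1):
                ga = float(rng.uniform(lo, hi))
                rows.append(
                    {
                        "sample_id": f"{cname}{s:03d}_d{d}",
                        "subject_id": f"{cname}P{s:03d}",
                        "cohort": cname,
                        "draw_index": d,
                        "ga_collect_weeks": round(ga, 2),
                        "ga_delivery_weeks": round(delivery, 2),
                        "outcome": "normotensive",
                        "bmi": 27.0,
                        "maternal_age": 30.0,
                        "race": "white",
                    }
                )
                mu_cols.append(
                    baseline.values + slope.values * ga + offsets[cname].values
                )
    ann = pd.DataFrame(rows)
    mu = np.stack(mu_cols, axis=1)
    libsizes = rng.lognormal(config.libsize_meanlog, config.libsize_sdlog, size=len(ann))
    counts = _draw_counts(mu, libsizes, config.nb_dispersion, rng)
    ann["qc_total_reads"] = counts.sum(axis=0)
    ann["qc_dup_rate"] = 0.2
    ann["qc_actb_ct"] = 24.0
    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=genes, columns=ann["sample_id"].tolist()),
        Space.raw_counts,
    )
    gene_ann = pd.DataFrame({"gene_id": genes, "biotype": biotype.values})
    truth = TruthRecord(
        gene_baseline=baseline, gene_slope=slope, cohort_offset=offsets,
        pe_panel=[], pe_effect=0.0,
        libsize_factor=pd.Series(libsizes, index=ann["sample_id"].tolist()),
        biotype=biotype, set_membership=membership, set_slope=set_slope,
    )
    return matrix, ann, gene_ann, sets, truth
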