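"""Normalization, QC outlier removal, and depth + cohort correction.

The correction removes two nuisance structures from log2(CPM+1) data:

1. *Depth*: each gene's linear relationship to the sample's total read
   count, removed as linear-model residuals (the per-gene training mean is
   re-added so values stay on the log2-CPM scale).
2. *Cohort*: additive per-(gene, cohort) offsets. Because cohorts occupy
   different parts of the gestational-age (GA) spectrum, a naive per-cohort
   mean correction would also remove genuine GA signal. The fit therefore
   first residualizes training expression on the variable of interest
   (GA), then estimates cohort offsets from those residuals — only cohort
   structure *orthogonal* to GA is corrected.

Applying a fitted model needs only cohort labels and total counts, never
the variable of interest of the target samples, so leakage of held-out GA
(or outcome) into corrected test data is impossible by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import DegenerateSampleError, ExpressionMatrix, Space

logger = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    pass


def compute_cpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Counts-per-million normalization: each sample scaled to sum 1e6."""
    m.require_space(Space.raw_counts)
    totals = m.data.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise DegenerateSampleError(
            f"all-zero sample(s): {', '.join(map(str, zero.index[:5]))}"
        )
    cpm = m.data.div(totals, axis=1) * 1e6
    return ExpressionMatrix(cpm, Space.cpm)


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2(CPM + 1)."""
    m.require_space(Space.cpm)
    return ExpressionMatrix(np.log2(m.data + 1.0), Space.log2cpm1)


@dataclass
class QcFlags:
    metrics: pd.DataFrame
    flagged: pd.Series  # bool per sample
    metric_list: list
    k: float

    @property
    def flagged_fraction(self) -> float:
        return float(self.flagged.mean())


def flag_outliers(qc: pd.DataFrame, k: float = 3.0,
                  metrics: Optional[Sequence[str]] = None) -> QcFlags:
    """Flag samples whose QC metrics deviate more than ``k`` s.d. from the mean.

    A sample is flagged iff *any* of the used metrics deviates by more than
    ``k`` sample standard deviations (ddof=1). Zero-variance metrics are
    skipped with a warning.
    """
    if len(qc) < 3:
        raise InsufficientDataError("need at least 3 samples to flag outliers")
    if metrics is None:
        metrics = [c for c in qc.columns if pd.api.types.is_numeric_dtype(qc[c])]
    used = []
    flagged = pd.Series(False, index=qc.index)
    for col in metrics:
        vals = qc[col].astype(float)
        sd = vals.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            logger.warning("QC metric %r has zero variance; skipped", col)
            continue
        z = (vals - vals.mean()).abs() / sd
        flagged |= z > k
        used.append(col)
    result = QcFlags(qc[used].copy() if used else qc.iloc[:, :0].copy(),
                     flagged, used, k)
    logger.info("flag_outliers: %d/%d samples flagged (%.1f%%)",
                int(flagged.sum()), len(flagged), 100 * result.flagged_fraction)
    return result


@dataclass
class CorrectionModel:
    """Learned depth slopes and cohort offsets, plus the training-only
    variable-of-interest coefficients that define orthogonality."""

    depth_intercept: pd.Series  # per gene
    depth_slope: pd.Series  # per gene, log2CPM per read of total counts
    gene_mean: pd.Series  # per-gene training mean (re-added after residualization)
    voi_slope: Optional[pd.Series] = None  # training-only; never used at apply time
    cohort_offsets: Optional[pd.DataFrame] = None  # genes x training cohorts
    training_cohorts: list = field(default_factory=list)
    fitted_space: Space = Space.log2cpm1

    def to_dict(self) -> dict:
        return {
            "depth_intercept": self.depth_intercept.to_dict(),
            "depth_slope": self.depth_slope.to_dict(),
            "gene_mean": self.gene_mean.to_dict(),
            "voi_slope": None if self.voi_slope is None else self.voi_slope.to_dict(),
            "cohort_offsets": None if self.cohort_offsets is None else
                {c: self.cohort_offsets[c].to_dict() for c in self.cohort_offsets},
            "training_cohorts": list(self.training_cohorts),
            "fitted_space": self.fitted_space.value,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CorrectionModel":
        return cls(
            depth_intercept=pd.Series(d["depth_intercept"]),
            depth_slope=pd.Series(d["depth_slope"]),
            gene_mean=pd.Series(d["gene_mean"]),
            voi_slope=None if d.get("voi_slope") is None else pd.Series(d["voi_slope"]),
            cohort_offsets=None if d.get("cohort_offsets") is None
                else pd.DataFrame(d["cohort_offsets"]),
            training_cohorts=d.get("training_cohorts", []),
            fitted_space=Space(d.get("fitted_space", "log2cpm1")),
        )


def _colwise_ols(X: np.ndarray, t: np.ndarray):
    """Per-row simple OLS of X (genes x samples) on covariate t.

    Returns (intercept, slope) arrays per gene; constant t gives slope 0.
    """
    tc = t - t.mean()
    denom = float((tc ** 2).sum())
    if denom == 0:
        slope = np.zeros(X.shape[0])
    else:
        slope = (X @ tc) / denom
    intercept = X.mean(axis=1) - slope * t.mean()
    return intercept, slope


def fit_depth_correction(train: ExpressionMatrix, totals: pd.Series) -> CorrectionModel:
    """Per-gene linear fit of log2(CPM+1) expression on total counts."""
    train.require_space(Space.log2cpm1)
    if train.n_samples < 3:
        raise InsufficientDataError("depth correction needs >= 3 training samples")
    t = totals.loc[train.sample_ids].astype(float).values
    X = train.data.values
    intercept, slope = _colwise_ols(X, t)
    return CorrectionModel(
        depth_intercept=pd.Series(intercept, index=train.gene_ids),
        depth_slope=pd.Series(slope, index=train.gene_ids),
        gene_mean=pd.Series(X.mean(axis=1), index=train.gene_ids),
    )


def _depth_correct_values(model: CorrectionModel, m: ExpressionMatrix,
                          totals: pd.Series) -> pd.DataFrame:
    t = totals.loc[m.sample_ids].astype(float).values
    fitted = (model.depth_intercept.values[:, None]
              + model.depth_slope.values[:, None] * t[None, :])
    resid = m.data.values - fitted
    return pd.DataFrame(resid + model.gene_mean.values[:, None],
                        index=m.gene_ids, columns=m.sample_ids)


def fit_cohort_correction(train: ExpressionMatrix, voi: pd.Series,
                          cohort: pd.Series,
                          totals: Optional[pd.Series] = None) -> CorrectionModel:
    """Learn cohort offsets orthogonal to the variable of interest.

    Steps, all on training data only: (1) depth-correct if ``totals`` given;
    (2) residualize each gene on ``voi`` (e.g. GA in weeks); (3) cohort
    offsets = per-cohort means of those residuals. The voi fit is retained
    in the model only to document orthogonality — it is never applied to
    target data.
    """
    train.require_space(Space.log2cpm1)
    cohort = cohort.loc[train.sample_ids]
    if cohort.nunique() < 2:
        raise InsufficientDataError("cohort correction needs >= 2 training cohorts")
    voi = voi.loc[train.sample_ids]
    if voi.isna().any():
        missing = voi.index[voi.isna()][:5].tolist()
        raise ValueError(f"variable of interest missing for training samples: {missing}")

    if totals is not None:
        model = fit_depth_correction(train, totals)
        X = _depth_correct_values(model, train, totals).values
    else:
        X = train.data.values
        zeros = pd.Series(0.0, index=train.gene_ids)
        model = CorrectionModel(
            depth_intercept=pd.Series(X.mean(axis=1), index=train.gene_ids),
            depth_slope=zeros.copy(),
            gene_mean=pd.Series(X.mean(axis=1), index=train.gene_ids),
        )

    v = voi.astype(float).values
    intercept, slope = _colwise_ols(X, v)
    resid = X - (intercept[:, None] + slope[:, None] * v[None, :])

    cohorts = sorted(cohort.unique())
    offsets = pd.DataFrame(0.0, index=train.gene_ids, columns=cohorts)
    for c in cohorts:
        mask = (cohort == c).values
        if mask.sum() < 2:
            logger.warning("cohort %r has <2 training samples; offset set to 0", c)
            continue
        offsets[c] = resid[:, mask].mean(axis=1)

    model.voi_slope = pd.Series(slope, index=train.gene_ids)
    model.cohort_offsets = offsets
    model.training_cohorts = cohorts
    return model


def apply_correction(model: CorrectionModel, m: ExpressionMatrix,
                     cohort: Optional[pd.Series] = None,
                     totals: Optional[pd.Series] = None) -> ExpressionMatrix:
    """Apply a fitted correction to any data, train or test.

    Signature deliberately takes no variable-of-interest argument: applying
    the correction uses only cohort labels and total counts. Samples from
    cohorts unseen in training are left uncorrected (offset 0) with a warning.
    """
    m.require_space(Space.log2cpm1)
    if not model.depth_intercept.index.equals(m.gene_ids):
        if set(model.depth_intercept.index) != set(m.gene_ids):
            raise ValueError("gene ids of model and matrix do not match")
        m = m.subset_genes(model.depth_intercept.index)
    if totals is not None:
        values = _depth_correct_values(model, m, totals)
    else:
        values = m.data.copy()

    if model.cohort_offsets is not None and cohort is not None:
        cohort = cohort.loc[m.sample_ids]
        offs = np.zeros((m.n_genes, m.n_samples))
        for c in cohort.unique():
            mask = (cohort == c).values
            if c in model.cohort_offsets.columns:
                offs[:, mask] = model.cohort_offsets[c].values[:, None]
            else:
                logger.warning("cohort %r unseen in training; samples left uncorrected", c)
        values = values - offs
    return ExpressionMatrix(values, Space.corrected)


def correct_pipeline(train: ExpressionMatrix, apply_to: ExpressionMatrix,
                     voi: pd.Series, cohort: pd.Series, totals: pd.Series):
    """Convenience wrapper: fit depth + cohort correction on train, apply to
    both. Returns (model, corrected_train, corrected_apply)."""
    model = fit_cohort_correction(train, voi, cohort, totals=totals)
    ctrain = apply_correction(model, train, cohort, totals)
    capply = apply_correction(model, apply_to, cohort, totals)
    return model, ctrain, capply
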