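"""Gestational-age (GA) molecular clock.

L1-penalized linear regression of GA (weeks) on corrected log2-CPM
expression: coding genes with positive median expression are the feature
space, features are centred and scaled on training statistics, the penalty
is chosen by 10-fold cross-validation with mean-absolute-error loss and
the one-standard-error (Breiman) rule — the most regularized model whose
CV error is within one SE of the minimum. Utilities cover stratified
splitting, learning curves over shrinking training fractions, a top-k
refit, a sequential ANOVA variance decomposition over clinical covariates,
and a paired-bootstrap model comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, lasso_path
from sklearn.model_selection import KFold

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)


class EmptyFeatureSetError(ValueError):
    pass


def filter_features(m: ExpressionMatrix, gene_ann: pd.DataFrame,
                    sample_ids: Optional[Sequence[str]] = None) -> list:
    """Retain protein-coding genes with median expression > 0.

    Medians are computed over ``sample_ids`` (the training samples) when
    given, else over all samples.
    """
    ann = gene_ann.set_index("gene_id")
    missing = m.gene_ids.difference(ann.index)
    if len(missing):
        raise ValueError(f"annotation missing for {len(missing)} genes")
    data = m.data if sample_ids is None else m.data.loc[:, list(sample_ids)]
    coding = ann.loc[m.gene_ids, "biotype"] == "protein_coding"
    medians = data.median(axis=1)
    keep = m.gene_ids[coding.values & (medians > 0).values]
    if len(keep) == 0:
        raise EmptyFeatureSetError(
            "no protein-coding genes with positive median expression; "
            "review the expression threshold or annotation"
        )
    return list(keep)


@dataclass
class SplitSpec:
    train_fraction: float = 0.8
    n_strata: int = 8
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


def split_stratified(ann: pd.DataFrame, spec: SplitSpec,
                     ga_column: str = "ga_collect_weeks"):
    """Train/test split stratified by GA so all age strata are represented
    proportionally. Strata are equal-width bins of the observed GA range;
    per-stratum test counts are rounded to the nearest sample. Singleton
    strata go to train with a warning. Returns (train_ids, test_ids)."""
    rng = np.random.default_rng(spec.seed)
    ga = ann[ga_column].astype(float)
    if ga.isna().any():
        raise ValueError("GA missing for some samples")
    edges = np.linspace(ga.min(), ga.max(), spec.n_strata + 1)
    strata = np.clip(np.digitize(ga, edges[1:-1]), 0, spec.n_strata - 1)
    test_frac = 1.0 - spec.train_fraction
    train_ids, test_ids = [], []
    for s in np.unique(strata):
        ids = ann.loc[strata == s, "sample_id"].tolist()
        if len(ids) == 1:
            logger.warning("GA stratum %d has a single sample; assigned to train", s)
            train_ids += ids
            continue
        perm = rng.permutation(len(ids))
        n_test = int(round(test_frac * len(ids)))
        n_test = min(max(n_test, 0), len(ids) - 1)
        test_ids += [ids[i] for i in perm[:n_test]]
        train_ids += [ids[i] for i in perm[n_test:]]
    return sorted(train_ids), sorted(test_ids)


@dataclass
class CvCurve:
    """Cross-validation error profile over a descending penalty grid."""

    alphas: np.ndarray  # strictly decreasing
    mean_mae_days: np.ndarray
    se_mae_days: np.ndarray
    n_folds: int

    def __post_init__(self):
        if not np.all(np.diff(self.alphas) < 0):
            raise ValueError("penalty grid must be strictly decreasing")
        if (self.se_mae_days < 0).any():
            raise ValueError("SE must be >= 0")


@dataclass
class GaModel:
    alpha: float
    intercept: float
    coef: pd.Series  # per feature, on the standardized scale
    feature_means: pd.Series
    feature_scales: pd.Series
    feature_filter: str = "protein_coding, median>0"

    @property
    def nonzero_features(self) -> pd.Series:
        return self.coef[self.coef != 0.0]

    @property
    def n_features_used(self) -> int:
        return int((self.coef != 0.0).sum())

    def to_dict(self) -> dict:
        nz = self.nonzero_features
        return {
            "alpha": self.alpha,
            "intercept": self.intercept,
            "weights": nz.to_dict(),
            "feature_means": self.feature_means.loc[nz.index].to_dict(),
            "feature_scales": self.feature_scales.loc[nz.index].to_dict(),
            "feature_filter": self.feature_filter,
        }


def _standardize(X: pd.DataFrame, means=None, scales=None):
    if means is None:
        means = X.mean(axis=0)
        scales = X.std(axis=0, ddof=0).replace(0.0, 1.0)
    return (X - means) / scales, means, scales


def _alpha_grid(Xs: np.ndarray, y: np.ndarray, n_alphas: int, eps: float = 1e-3):
    n = Xs.shape[0]
    alpha_max = np.abs(Xs.T @ (y - y.mean())).max() / n
    alpha_max = max(alpha_max, 1e-12)
    return np.logspace(np.log10(alpha_max), np.log10(alpha_max * eps), n_alphas)


def fit_lasso_cv(X: pd.DataFrame, y: pd.Series, folds: int = 10, seed: int = 0,
                 n_alphas: int = 100) -> CvCurve:
    """K-fold CV error (MAE, days) over a shared log-spaced penalty grid.

    Features are centred/scaled on each fold's training statistics; ``y``
    is GA in weeks, errors are reported in days (weeks x 7).
    """
    n = len(y)
    if folds > n:
        raise ValueError(f"folds={folds} exceeds n={n}")
    yv = y.values.astype(float)
    Xs_full, _, _ = _standardize(X)
    alphas = _alpha_grid(Xs_full.values, yv, n_alphas)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_mae = np.empty((folds, len(alphas)))
    for k, (tr, te) in enumerate(kf.split(X)):
        Xtr, means, scales = _standardize(X.iloc[tr])
        Xte = (X.iloc[te] - means) / scales
        ytr = yv[tr]
        _, coefs, _ = lasso_path(Xtr.values, ytr - ytr.mean(), alphas=alphas)
        preds = Xte.values @ coefs + ytr.mean()  # samples x alphas
        fold_mae[k] = np.mean(np.abs(preds - yv[te][:, None]), axis=0) * 7.0
    return CvCurve(
        alphas=alphas,
        mean_mae_days=fold_mae.mean(axis=0),
        se_mae_days=fold_mae.std(axis=0, ddof=1) / np.sqrt(folds),
        n_folds=folds,
    )


def select_one_se(curve: CvCurve) -> float:
    """One-SE (Breiman) rule: the largest penalty whose mean CV error is
    within one standard error of the best mean CV error."""
    i_best = int(np.argmin(curve.mean_mae_days))
    threshold = curve.mean_mae_days[i_best] + curve.se_mae_days[i_best]
    ok = np.flatnonzero(curve.mean_mae_days <= threshold)
    return float(curve.alphas[ok[0]])  # grid is descending: first = largest


def fit_final(X: pd.DataFrame, y: pd.Series, alpha: float,
              feature_filter: str = "protein_coding, median>0") -> GaModel:
    """Fit the final L1 model at the selected penalty on all training data."""
    Xs, means, scales = _standardize(X)
    lasso = Lasso(alpha=alpha, max_iter=50000)
    lasso.fit(Xs.values, y.values.astype(float))
    return GaModel(
        alpha=float(alpha),
        intercept=float(lasso.intercept_),
        coef=pd.Series(lasso.coef_, index=X.columns),
        feature_means=means,
        feature_scales=scales,
        feature_filter=feature_filter,
    )


def predict(model: GaModel, X: pd.DataFrame) -> pd.Series:
    missing = model.coef.index.difference(X.columns)
    if len(missing):
        raise ValueError(f"features missing from input: {list(missing[:10])}")
    Xs = (X[model.coef.index] - model.feature_means) / model.feature_scales
    return pd.Series(Xs.values @ model.coef.values + model.intercept, index=X.index)


def evaluate_mae(pred: pd.Series, truth: pd.Series) -> float:
    """Mean absolute error in days (GA is carried in weeks)."""
    return float(np.mean(np.abs(pred.values - truth.loc[pred.index].values)) * 7.0)


def refit_top_k(model: GaModel, X: pd.DataFrame, y: pd.Series, k: int = 50) -> GaModel:
    """Refit restricted to the k largest-|weight| features of ``model``."""
    nz = model.nonzero_features.abs().sort_values(ascending=False)
    if len(nz) < k:
        logger.warning("model has %d nonzero features < k=%d; using all", len(nz), k)
        k = len(nz)
    top = nz.index[:k]
    return fit_final(X[list(top)], y, model.alpha,
                     feature_filter=model.feature_filter + f", top-{k} refit")


def learning_curve(X: pd.DataFrame, y: pd.Series, ann: pd.DataFrame,
                   fractions: Sequence[float] = (0.6, 0.7, 0.8),
                   repeats: int = 3, seed: int = 0, folds: int = 10,
                   n_alphas: int = 50) -> pd.DataFrame:
    """MAE as a function of training-set size.

    For each train fraction, repeatedly: stratified split, CV penalty
    selection on train, final fit, test MAE. Returns a table of
    (train_fraction, n_train, mae_mean_days, mae_sd_days).
    """
    if repeats < 2:
        raise ValueError("repeats must be >= 2")
    rows = []
    for frac in fractions:
        maes, n_train = [], 0
        for r in range(repeats):
            spec = SplitSpec(train_fraction=frac, seed=seed * 1000 + r)
            train_ids, test_ids = split_stratified(ann, spec)
            if len(train_ids) < folds:
                logger.warning("fraction %.2f leaves < folds training samples; skipped", frac)
                break
            n_train = len(train_ids)
            curve = fit_lasso_cv(X.loc[train_ids], y.loc[train_ids], folds=folds,
                                 seed=seed + r, n_alphas=n_alphas)
            model = fit_final(X.loc[train_ids], y.loc[train_ids], select_one_se(curve))
            maes.append(evaluate_mae(predict(model, X.loc[test_ids]), y))
        if maes:
            rows.append({"train_fraction": frac, "n_train": n_train,
                         "mae_mean_days": float(np.mean(maes)),
                         "mae_sd_days": float(np.std(maes, ddof=1))})
    return pd.DataFrame(rows)


@dataclass
class VarianceDecomposition:
    terms: list  # ordered term names
    fractions: pd.Series  # SS fraction per term, plus 'residual'

    def __post_init__(self):
        total = float(self.fractions.sum())
        if not np.isclose(total, 1.0, atol=1e-8):
            raise ValueError(f"fractions must sum to 1, got {total}")
        if (self.fractions < -1e-12).any():
            raise ValueError("fractions must be non-negative")


def anova_variance(truth: pd.Series, prediction: pd.Series,
                   covariates: pd.DataFrame,
                   order: Sequence[str] = ("prediction", "bmi", "maternal_age", "race"),
                   ) -> VarianceDecomposition:
    """Sequential (type-I) ANOVA of true GA on the cfRNA prediction and
    clinical covariates, in the given order. Fractions of total sum of
    squares per term; 'residual' completes the unit sum."""
    df = covariates.copy()
    df["prediction"] = prediction
    yv = truth.loc[df.index].astype(float).values
    ss_total = float(((yv - yv.mean()) ** 2).sum())

    # term -> design columns; race expands to indicator contrasts with the
    # most frequent category as reference
    blocks = {}
    for t in order:
        if t == "race":
            if df["race"].nunique() <= 1:
                logger.warning("race is constant; it will explain 0 variance")
                blocks[t] = np.empty((len(df), 0))
            else:
                ref = df["race"].mode().iloc[0]
                dummies = pd.get_dummies(df["race"], dtype=float)
                blocks[t] = dummies.drop(columns=[ref]).values
        else:
            col = df[t].astype(float)
            if col.nunique() <= 1:
                logger.warning("covariate %r is constant; it will explain 0 variance", t)
            blocks[t] = col.values[:, None]

    # sequential (type-I) sums of squares by incremental least squares,
    # guaranteeing the stated entry order regardless of term type
    design = np.ones((len(df), 1))
    rss_prev = ss_total
    names, fracs = [], []
    for t in order:
        design = np.hstack([design, blocks[t]])
        resid = yv - design @ np.linalg.lstsq(design, yv, rcond=None)[0]
        rss = float((resid ** 2).sum())
        names.append(t)
        fracs.append(max(rss_prev - rss, 0.0) / ss_total)
        rss_prev = rss
    names.append("residual")
    fracs.append(rss_prev / ss_total)
    fracs = np.array(fracs) / np.sum(fracs)
    return VarianceDecomposition(terms=list(order),
                                 fractions=pd.Series(fracs, index=names))


def compare_models(pred_a: pd.Series, pred_b: pd.Series, truth: pd.Series,
                   B: int = 1000, seed: int = 0) -> dict:
    """Paired bootstrap over test samples of the MAE difference (days)
    between two prediction vectors. Returns the point difference, a 95%
    percentile CI, and a two-sided bootstrap p-value for zero difference."""
    idx = pred_a.index
    ea = np.abs(pred_a.values - truth.loc[idx].values) * 7.0
    eb = np.abs(pred_b.loc[idx].values - truth.loc[idx].values) * 7.0
    diff = ea - eb
    rng = np.random.default_rng(seed)
    n = len(diff)
    boots = np.array([diff[rng.integers(0, n, n)].mean() for _ in range(B)])
    point = float(diff.mean())
    lo, hi = np.percentile(boots, [2.5, 97.5])
    p = 2.0 * min((boots <= 0).mean(), (boots >= 0).mean())
    return {"mae_diff_days": point, "ci_low": float(lo), "ci_high": float(hi),
            "p_value": float(min(p, 1.0))}
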