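"""Pre-eclampsia (PE) risk classification from corrected cfRNA expression.

Design: a case–control cohort sampled in the second trimester, months
before symptom onset. Inside every cross-validation fold, genes are
screened by a two-sided Spearman correlation against the case label with
Benjamini–Hochberg control (adjusted p < 0.05), and an unpenalized
logistic regression on the retained genes — standardized on the fold's
training statistics — emits the held-out probability. Genes retained in
every fold form the consensus signature. Out-of-fold probabilities yield
the ROC/AUC, an operating threshold at a target sensitivity, and the
positive predictive value

    PPV = (sens x prev) / (sens x prev + (1 - spec) x (1 - prev)),

with bootstrap confidence intervals throughout. Side analyses: a k-fold
learning curve (k = 2..9 plus leave-one-out), Kaplan–Meier delivery-timing
comparison between test-positive and test-negative pregnancies, a
hypertensive-subtype specificity check, and robustness to excluding
spontaneous preterm (sPTB) non-cases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
import scipy.stats as st
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class ScreenResult:
    table: pd.DataFrame  # gene_id, rho, p_value, adjusted_p
    retained: list  # gene ids with adjusted p < alpha
    alpha: float


def _spearman_vs_label(X: np.ndarray, y: np.ndarray):
    """Vectorized average-rank Spearman rho of each column of X against y,
    with two-sided p from the t approximation. Constant columns get nan."""
    n = len(y)
    rx = st.rankdata(X, axis=0)
    ry = st.rankdata(y)
    rxc = rx - rx.mean(axis=0)
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc ** 2).sum(axis=0) * (ryc ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (rxc.T @ ryc) / denom
    rho = np.where(denom == 0, np.nan, rho)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * st.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    return rho, p


def spearman_screen(X: pd.DataFrame, y: pd.Series, alpha: float = 0.05) -> ScreenResult:
    """Two-sided Spearman screen of every gene against the binary label,
    BH-adjusted across genes; genes with adjusted p < alpha are retained.
    Constant genes are skipped with a log entry."""
    yv = y.loc[X.index].astype(float).values
    if len(np.unique(yv)) < 2 or min((yv == v).sum() for v in np.unique(yv)) < 2:
        raise ValueError("need >= 2 samples per class")
    rho, p = _spearman_vs_label(X.values, yv)
    table = pd.DataFrame({"gene_id": X.columns, "rho": rho, "p_value": p})
    n_const = int(table["rho"].isna().sum())
    if n_const:
        logger.info("spearman_screen: %d constant gene(s) skipped", n_const)
    valid = table.dropna(subset=["rho"]).copy()
    if len(valid):
        _, adj, _, _ = multipletests(valid["p_value"].values, method="fdr_bh")
        valid["adjusted_p"] = adj
    else:
        valid["adjusted_p"] = []
    retained = valid.loc[valid["adjusted_p"] < alpha, "gene_id"].tolist()
    return ScreenResult(table=valid.reset_index(drop=True), retained=retained, alpha=alpha)


#: Optional per-fold nuisance correction. Called with the training sample
#: ids and the full (samples x genes) frame; must return the corrected
#: frame for all samples, using only training-side information.
FoldCorrector = Callable[[list, pd.DataFrame], pd.DataFrame]


@dataclass
class ClassifierReport:
    oof_prob: pd.Series  # out-of-fold probability per sample
    labels: pd.Series
    fold_features: list  # retained gene list per fold
    consensus_features: list  # genes selected in every fold
    auc: float
    auc_ci: tuple = (float("nan"), float("nan"))
    roc_points: Optional[pd.DataFrame] = None
    threshold: float = float("nan")
    sensitivity: float = float("nan")
    specificity: float = float("nan")
    ppv: float = float("nan")
    prevalence: float = float("nan")
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "oof_prob": self.oof_prob.to_dict(),
            "labels": self.labels.astype(int).to_dict(),
            "consensus_features": list(self.consensus_features),
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "threshold": self.threshold,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "prevalence": self.prevalence,
            **self.extras,
        }


def _fit_fold(Xtr: pd.DataFrame, ytr: pd.Series, Xte: pd.DataFrame,
              alpha: float):
    """Screen on the fold's training part, fit logistic regression on the
    retained genes, return held-out probabilities and the retained list."""
    screen = spearman_screen(Xtr, ytr, alpha=alpha)
    feats = screen.retained
    if not feats:
        # no gene survives screening: emit an uninformative constant. The
        # constant must not depend on the fold's label composition — a
        # fold-varying constant (e.g. training prevalence) anti-predicts
        # the held-out label under LOOCV and biases the null AUC to 0.
        return np.full(len(Xte), 0.5), feats
    mu = Xtr[feats].mean(axis=0)
    sd = Xtr[feats].std(axis=0, ddof=0).replace(0.0, 1.0)
    clf = LogisticRegression(C=np.inf, max_iter=2000)
    clf.fit(((Xtr[feats] - mu) / sd).values, ytr.values.astype(int))
    prob = clf.predict_proba(((Xte[feats] - mu) / sd).values)[:, 1]
    return prob, feats


def loocv_fit(X: pd.DataFrame, y: pd.Series, alpha: float = 0.05,
              fold_corrector: Optional[FoldCorrector] = None) -> ClassifierReport:
    """Leave-one-out CV with the screen-then-logistic pipeline in each fold.

    ``X`` is samples x genes; ``y`` binary (1 = case). Feature screening —
    and, when ``fold_corrector`` is given, the nuisance correction — is
    re-learned on each fold's n-1 training samples so the held-out sample
    never influences its own probability.
    """
    y = y.loc[X.index].astype(int)
    if len(y) < 10:
        raise ValueError("need n >= 10 for leave-one-out CV")
    if y.nunique() < 2 or y.value_counts().min() < 2:
        raise ValueError("both classes must appear at least twice")
    probs = pd.Series(np.nan, index=X.index)
    fold_features = []
    for i, sid in enumerate(X.index):
        tr_ids = [s for s in X.index if s != sid]
        Xf = fold_corrector(tr_ids, X) if fold_corrector is not None else X
        prob, feats = _fit_fold(Xf.loc[tr_ids], y.loc[tr_ids],
                                Xf.loc[[sid]], alpha)
        probs.loc[sid] = prob[0]
        fold_features.append(feats)
    consensus = sorted(set.intersection(*(set(f) for f in fold_features)))
    curve, auc_val = roc_auc(probs, y)
    return ClassifierReport(oof_prob=probs, labels=y, fold_features=fold_features,
                            consensus_features=consensus, auc=auc_val,
                            roc_points=curve)


def roc_auc(probs: pd.Series, y: pd.Series):
    """ROC curve over all thresholds and the AUC (equivalent to the
    normalized Mann–Whitney U statistic)."""
    yv = y.loc[probs.index].astype(int).values
    if len(np.unique(yv)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thr = roc_curve(yv, probs.values)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}), float(sk_auc(fpr, tpr))


def threshold_at_sensitivity(probs: pd.Series, y: pd.Series,
                             target: float = 0.75):
    """Largest threshold whose sensitivity on the out-of-fold probabilities
    reaches the target (prob >= threshold calls positive). Returns
    (threshold, sensitivity, specificity)."""
    yv = y.loc[probs.index].astype(int).values
    pv = probs.values
    case_probs = np.sort(pv[yv == 1])[::-1]
    if target <= 0:
        thr = pv.max() + 1.0
    else:
        n_needed = int(np.ceil(target * len(case_probs)))
        thr = case_probs[n_needed - 1]
        if len(np.unique(pv)) == 1 and target > 0:
            logger.warning("all probabilities tied; threshold at the minimum")
    pos = pv >= thr
    sens = float(pos[yv == 1].mean()) if (yv == 1).any() else 0.0
    spec = float((~pos)[yv == 0].mean()) if (yv == 0).any() else 0.0
    return float(thr), sens, spec


def ppv(sensitivity: float, specificity: float, prevalence: float) -> float:
    """Positive predictive value from sensitivity, specificity, prevalence."""
    for name, v in [("sensitivity", sensitivity), ("specificity", specificity),
                    ("prevalence", prevalence)]:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    num = sensitivity * prevalence
    den = num + (1.0 - specificity) * (1.0 - prevalence)
    if den == 0:
        raise ZeroDivisionError("PPV undefined: no positive calls (sens=0, spec=1)")
    return num / den


def bootstrap_ci(metric: Callable[[pd.Series, pd.Series], float],
                 probs: pd.Series, y: pd.Series, B: int = 1000, seed: int = 0):
    """Percentile 95% CI and s.d. of a metric over B class-stratified
    bootstrap resamples of (probs, labels)."""
    if B < 100:
        raise ValueError("B must be >= 100")
    rng = np.random.default_rng(seed)
    y = y.loc[probs.index].astype(int)
    idx_case = probs.index[y.values == 1]
    idx_ctrl = probs.index[y.values == 0]
    vals = np.empty(B)
    for b in range(B):
        take = list(rng.choice(idx_case, size=len(idx_case), replace=True)) + \
               list(rng.choice(idx_ctrl, size=len(idx_ctrl), replace=True))
        p_b = pd.Series(probs.loc[take].values,
                        index=pd.RangeIndex(len(take)))
        y_b = pd.Series(y.loc[take].values, index=p_b.index)
        vals[b] = metric(p_b, y_b)
    point = metric(probs, y)
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return {"point": float(point), "ci_low": float(lo), "ci_high": float(hi),
            "sd": float(vals.std(ddof=1))}


def auc_metric(probs: pd.Series, y: pd.Series) -> float:
    return roc_auc(probs, y)[1]


def learning_curve_kfold(X: pd.DataFrame, y: pd.Series, ks=range(2, 10),
                         alpha: float = 0.05, seed: int = 0,
                         include_loocv: bool = True) -> pd.DataFrame:
    """AUC as the training set grows: k-fold CV for k = 2..9 with the same
    screen-then-logistic pipeline per fold, LOOCV appended as the terminal
    point. Folds are stratified so every training part sees both classes."""
    y = y.loc[X.index].astype(int)
    rows = []
    for k in ks:
        if k > len(y) // 2:
            raise ValueError(f"k={k} too large for n={len(y)}")
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        probs = pd.Series(np.nan, index=X.index)
        for tr, te in skf.split(X, y):
            prob, _ = _fit_fold(X.iloc[tr], y.iloc[tr], X.iloc[te], alpha)
            probs.iloc[te] = prob
        rows.append({"k": int(k), "auc": roc_auc(probs, y)[1]})
    if include_loocv:
        rep = loocv_fit(X, y, alpha=alpha)
        rows.append({"k": len(y), "auc": rep.auc})
    return pd.DataFrame(rows)


@dataclass
class SurvivalComparison:
    groups: pd.Series  # 'positive' / 'negative' per sample
    km_positive: pd.DataFrame  # timeline, survival
    km_negative: pd.DataFrame
    logrank_stat: float
    p_value: float
    n: int

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "logrank_stat": self.logrank_stat,
            "p_value": self.p_value,
            "km_positive": self.km_positive.to_dict(orient="list"),
            "km_negative": self.km_negative.to_dict(orient="list"),
        }


def km_logrank(delivery_ga: pd.Series, positive: pd.Series,
               exclude: Optional[pd.Series] = None,
               event_observed: Optional[pd.Series] = None) -> SurvivalComparison:
    """Kaplan–Meier curves of delivery timing for test-positive vs
    test-negative pregnancies, with a two-group log-rank test.

    ``delivery_ga`` in weeks; ``positive`` boolean; ``exclude`` (e.g. the
    sPTB flag) drops samples before the comparison. All deliveries are
    treated as observed events unless ``event_observed`` is supplied.
    """
    idx = delivery_ga.index
    keep = pd.Series(True, index=idx) if exclude is None else ~exclude.loc[idx].astype(bool)
    t = delivery_ga[keep].astype(float)
    g = positive.loc[t.index].astype(bool)
    if g.sum() < 2 or (~g).sum() < 2:
        raise ValueError("need >= 2 samples per group after exclusion")
    e = (pd.Series(1, index=t.index) if event_observed is None
         else event_observed.loc[t.index].astype(int))

    def _fit(mask):
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], event_observed=e[mask])
        sf = kmf.survival_function_
        return pd.DataFrame({"week": sf.index.values,
                             "survival": sf.iloc[:, 0].values})

    res = logrank_test(t[g], t[~g], event_observed_A=e[g], event_observed_B=e[~g])
    groups = pd.Series(np.where(g, "positive", "negative"), index=t.index)
    return SurvivalComparison(groups=groups, km_positive=_fit(g.values),
                              km_negative=_fit((~g).values),
                              logrank_stat=float(res.test_statistic),
                              p_value=float(res.p_value), n=int(len(t)))


def subtype_specificity(X: pd.DataFrame, outcome: pd.Series,
                        pe_retained: list, alpha: float = 0.05) -> dict:
    """Hypertensive-subtype specificity check.

    Spearman-screens chronic-hypertension vs normotensive and gestational-
    hypertension vs normotensive contrasts (unadjusted p < alpha, matching
    the looser criterion used for these secondary contrasts) and reports
    the overlap of each gene list with the PE-retained genes.
    """
    outcome = outcome.loc[X.index]
    report: dict = {"applicable": True, "contrasts": {}}
    norm_ids = X.index[outcome == "normotensive"]
    for substratum in ("chronic_htn", "gestational_htn"):
        ids = X.index[outcome == substratum]
        if len(ids) < 5:
            logger.warning("substratum %r has %d samples (<5); contrast skipped",
                           substratum, len(ids))
            report["contrasts"][substratum] = {"skipped": True}
            continue
        sub_idx = list(norm_ids) + list(ids)
        lab = pd.Series(0, index=sub_idx, dtype=int)
        lab.loc[list(ids)] = 1
        screen = spearman_screen(X.loc[sub_idx], lab, alpha=1.0)
        sig = screen.table.loc[screen.table["p_value"] < alpha, "gene_id"].tolist()
        overlap = sorted(set(sig) & set(pe_retained))
        report["contrasts"][substratum] = {
            "skipped": False, "n_significant": len(sig), "overlap": overlap,
        }
    if not report["contrasts"]:
        report["applicable"] = False
    return report


def robustness_exclude_sptb(X: pd.DataFrame, y: pd.Series, sptb: pd.Series,
                            alpha: float = 0.05,
                            fold_corrector: Optional[FoldCorrector] = None
                            ) -> ClassifierReport:
    """Re-run the full LOOCV pipeline after dropping sPTB non-cases."""
    sptb = sptb.loc[X.index].astype(bool)
    keep = X.index[~(sptb & (y.loc[X.index].astype(int) == 0))]
    if (y.loc[keep] == 0).sum() == 0:
        raise ValueError("no non-cases left after sPTB exclusion")
    return loocv_fit(X.loc[keep], y.loc[keep], alpha=alpha,
                     fold_corrector=fold_corrector)


def qq_expected_uniform(n: int) -> np.ndarray:
    """Expected uniform order statistics i/(n+1), for Q–Q plots of ranked
    screening p-values against the null."""
    return np.arange(1, n + 1) / (n + 1.0)


def full_report(X: pd.DataFrame, y: pd.Series, alpha: float = 0.05,
                sens_target: float = 0.75, B: int = 1000, seed: int = 0,
                prevalence: Optional[float] = None,
                fold_corrector: Optional[FoldCorrector] = None) -> ClassifierReport:
    """LOOCV fit plus operating point, PPV, and bootstrap CIs in one call."""
    rep = loocv_fit(X, y, alpha=alpha, fold_corrector=fold_corrector)
    thr, sens, spec = threshold_at_sensitivity(rep.oof_prob, rep.labels, sens_target)
    prev = float(rep.labels.mean()) if prevalence is None else prevalence
    rep.threshold, rep.sensitivity, rep.specificity = thr, sens, spec
    rep.prevalence = prev
    rep.ppv = ppv(sens, spec, prev)
    boot = bootstrap_ci(auc_metric, rep.oof_prob, rep.labels, B=B, seed=seed)
    rep.auc_ci = (boot["ci_low"], boot["ci_high"])
    rep.extras["auc_sd"] = boot["sd"]

    def ppv_metric(p, yy):
        t, s, sp = threshold_at_sensitivity(p, yy, sens_target)
        return ppv(s, sp, prev)

    boot_ppv = bootstrap_ci(ppv_metric, rep.oof_prob, rep.labels, B=B, seed=seed + 1)
    rep.extras["ppv_sd"] = boot_ppv["sd"]
    rep.extras["ppv_ci"] = [boot_ppv["ci_low"], boot_ppv["ci_high"]]
    return rep
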