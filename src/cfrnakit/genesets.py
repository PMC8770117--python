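"""Plasma transcriptome partitioning by gene sets.

The plasma transcriptome is viewed as partitioned into characteristic gene
sets. Each sample's *cumulative CPM score* for a set is the sum of CPM
over member genes — a relative abundance of that set in the transcriptome
(bounded by 1e6). Scores are regressed on gestational age (weeks) with
ordinary least squares; sets with a Benjamini–Hochberg-adjusted slope
p-value < 0.01 in the discovery cohort are called trending, verified by a
label-scrambling permutation control, and confirmed when the slope is
significant with matching sign in at least two other longitudinal cohorts.

A per-subject monotonicity analysis over four ordered draws uses the exact
combinatorial null: of the 24 orderings of four values, exactly one is
strictly increasing (and one strictly decreasing), so the expected number
of monotone subjects under exchangeability is n/24 per direction.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, GeneSetCollection, Space

logger = logging.getLogger(__name__)


def partition_scores(m: ExpressionMatrix, sets: GeneSetCollection,
                     ann: pd.DataFrame) -> pd.DataFrame:
    """Cumulative CPM score per (sample, set).

    Member genes absent from the matrix contribute 0 and are logged; a set
    with no resolvable members is excluded with a warning. Returns a long
    table with sample metadata attached.
    """
    m.require_space(Space.cpm)
    gene_index = {g: i for i, g in enumerate(m.gene_ids)}
    meta = ann.set_index("sample_id")
    records = []
    values = m.data.values
    for name in sets.names():
        members = sets.members(name)
        idx = [gene_index[g] for g in members if g in gene_index]
        n_missing = len(members) - len(idx)
        if n_missing:
            logger.info("set %r: %d member gene(s) not in matrix, contribute 0",
                        name, n_missing)
        if not idx:
            logger.warning("set %r has no resolvable members; excluded", name)
            continue
        scores = values[idx, :].sum(axis=0)
        for sid, score in zip(m.sample_ids, scores):
            row = {"sample_id": sid, "set_name": name, "score": float(score)}
            if sid in meta.index:
                row.update(
                    ga_collect_weeks=float(meta.loc[sid, "ga_collect_weeks"]),
                    subject_id=meta.loc[sid, "subject_id"],
                    cohort=meta.loc[sid, "cohort"],
                    draw_index=int(meta.loc[sid, "draw_index"]),
                )
            records.append(row)
    return pd.DataFrame(records)


@dataclass
class TrendFit:
    set_name: str
    cohort: str
    slope: float  # CPM per week
    intercept: float
    p_value: float
    n: int
    ci_low: float
    ci_high: float
    adjusted_p: float = float("nan")


def fit_trend(scores: pd.DataFrame, set_name: str | None = None,
              cohort: str | None = None) -> TrendFit:
    """OLS of cumulative CPM score on GA (weeks) for one set in one cohort.

    Returns the slope (CPM/week), its two-sided p-value and 95% CI.
    """
    if len(scores) < 3:
        raise ValueError("trend fit needs >= 3 samples")
    ga = scores["ga_collect_weeks"].astype(float).values
    y = scores["score"].astype(float).values
    if np.ptp(ga) == 0:
        raise ValueError("GA is constant; slope undefined")
    res = st.linregress(ga, y)
    n = len(y)
    tcrit = st.t.ppf(0.975, n - 2)
    if set_name is None:
        set_name = str(scores["set_name"].iloc[0]) if "set_name" in scores else ""
    if cohort is None:
        cohort = str(scores["cohort"].iloc[0]) if "cohort" in scores else ""
    return TrendFit(
        set_name=set_name, cohort=cohort,
        slope=float(res.slope), intercept=float(res.intercept),
        p_value=float(res.pvalue), n=n,
        ci_low=float(res.slope - tcrit * res.stderr),
        ci_high=float(res.slope + tcrit * res.stderr),
    )


def fit_trends_by_cohort(scores: pd.DataFrame) -> pd.DataFrame:
    """One TrendFit per (set, cohort), as a table."""
    rows = []
    for (name, cohort), grp in scores.groupby(["set_name", "cohort"], sort=True):
        if len(grp) < 3 or grp["ga_collect_weeks"].nunique() < 2:
            continue
        fit = fit_trend(grp, set_name=name, cohort=cohort)
        rows.append(vars(fit))
    return pd.DataFrame(rows)


def select_trending(fits: pd.DataFrame, alpha: float = 0.01) -> pd.DataFrame:
    """BH-adjust slope p-values across sets (one discovery cohort) and
    retain adjusted p < alpha; the slope sign is recorded."""
    if len(fits) == 0:
        return fits.assign(adjusted_p=[], direction=[]) if "set_name" in fits else pd.DataFrame(
            columns=["set_name", "adjusted_p", "direction"])
    fits = fits.copy()
    _, adj, _, _ = multipletests(fits["p_value"].values, method="fdr_bh")
    fits["adjusted_p"] = adj
    selected = fits[fits["adjusted_p"] < alpha].copy()
    selected["direction"] = np.sign(selected["slope"]).astype(int)
    return selected


def _perm_slopes(y: np.ndarray, ga: np.ndarray, n_perm: int,
                 rng: np.random.Generator) -> np.ndarray:
    gc = ga - ga.mean()
    denom = float((gc ** 2).sum())
    out = np.empty(n_perm)
    for i in range(n_perm):
        out[i] = float((y[rng.permutation(len(y))] @ gc) / denom)
    return out


def scramble_control(scores: pd.DataFrame, n_perm: int = 999,
                     seed: int = 0) -> pd.DataFrame:
    """Permutation p-value per set: scramble the GA (temporal) labels and
    compare |slope| of the scrambled fits to the observed |slope|, with
    add-one correction: p = (1 + #{|slope_perm| >= |slope_obs|}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = np.random.default_rng(seed)
    rows = []
    for name, grp in scores.groupby("set_name", sort=True):
        ga = grp["ga_collect_weeks"].astype(float).values
        y = grp["score"].astype(float).values
        gc = ga - ga.mean()
        obs = float((y @ gc) / (gc ** 2).sum())
        perm = _perm_slopes(y, ga, n_perm, rng)
        p = (1 + int((np.abs(perm) >= abs(obs)).sum())) / (n_perm + 1)
        rows.append({"set_name": name, "slope": obs, "perm_p": p})
    return pd.DataFrame(rows)


def confirm_across_cohorts(fits: pd.DataFrame, discovery: str,
                           alpha_discovery: float = 0.01,
                           alpha_confirm: float = 0.05,
                           min_other: int = 2) -> pd.DataFrame:
    """Cross-cohort confirmation of discovery-cohort trends.

    A set is confirmed iff it is BH-selected in the discovery cohort and
    its slope is significant (unadjusted p < alpha_confirm) with matching
    sign in at least ``min_other`` non-discovery cohorts. The returned
    table reports the number of cohorts with significant same-sign signal
    including the discovery cohort.
    """
    if discovery not in set(fits["cohort"]):
        raise ValueError(f"discovery cohort {discovery!r} absent from fits")
    disc = select_trending(fits[fits["cohort"] == discovery], alpha=alpha_discovery)
    rows = []
    others = fits[fits["cohort"] != discovery]
    for _, d in disc.iterrows():
        sub = others[others["set_name"] == d["set_name"]]
        ok = sub[(sub["p_value"] < alpha_confirm)
                 & (np.sign(sub["slope"]) == d["direction"])]
        rows.append({
            "set_name": d["set_name"],
            "slope_cpm_per_week": d["slope"],
            "adjusted_p_discovery": d["adjusted_p"],
            "direction": int(d["direction"]),
            "n_cohorts_significant": int(len(ok)) + 1,  # including discovery
            "confirmed": bool(len(ok) >= min_other),
        })
    return pd.DataFrame(rows)


def enumerate_orderings(k: int = 4):
    """Exact permutation null for monotone trends over k ordered draws.

    Returns (n_orderings, n_monotone_up, n_monotone_down) by exhaustive
    enumeration of the k! orderings of distinct values.
    """
    vals = tuple(range(k))
    n_up = n_down = 0
    for perm in itertools.permutations(vals):
        if all(a < b for a, b in zip(perm, perm[1:])):
            n_up += 1
        if all(a > b for a, b in zip(perm, perm[1:])):
            n_down += 1
    return math.factorial(k), n_up, n_down


@dataclass
class MonotonicityResult:
    n_subjects: int
    n_monotone_up: int
    n_monotone_down: int
    expected_per_direction: float  # n / 24
    chi2_up: float
    p_up: float
    chi2_down: float
    p_down: float
    binom_p_up: float
    binom_p_down: float

    def to_dict(self) -> dict:
        return dict(vars(self))


def monotonicity_test(scores: pd.DataFrame) -> MonotonicityResult:
    """Per-subject monotone-trend test over four ordered draws.

    A subject is monotone-up iff their four cumulative-CPM scores strictly
    increase along the draw order (ties count as non-monotone and are
    logged). The observed monotone count per direction is tested against
    the exact null expectation n/24 with a 1-df chi-squared goodness-of-fit
    (monotone vs not); an exact binomial p-value is reported alongside.
    Subjects without exactly 4 draws are excluded with a warning.
    """
    n_total, n_up_perm, _ = enumerate_orderings(4)
    p_null = n_up_perm / n_total  # 1/24
    n_up = n_down = n_subj = 0
    for subj, grp in scores.groupby("subject_id", sort=True):
        if len(grp) != 4:
            logger.warning("subject %r has %d draws (expected 4); excluded", subj, len(grp))
            continue
        grp = grp.sort_values("draw_index")
        ga = grp["ga_collect_weeks"].values
        if not np.all(np.diff(ga) > 0):
            raise ValueError(f"subject {subj!r}: GA not strictly increasing across draws")
        y = grp["score"].values
        d = np.diff(y)
        if np.any(d == 0):
            logger.info("subject %r has tied adjacent scores; counted non-monotone", subj)
        n_subj += 1
        if np.all(d > 0):
            n_up += 1
        elif np.all(d < 0):
            n_down += 1
    expected = n_subj * p_null

    def _chi2(observed):
        exp = np.array([expected, n_subj - expected])
        obs = np.array([observed, n_subj - observed])
        chi2, p = st.chisquare(obs, exp)
        return float(chi2), float(p)

    chi2_up, p_up = _chi2(n_up)
    chi2_down, p_down = _chi2(n_down)
    return MonotonicityResult(
        n_subjects=n_subj, n_monotone_up=n_up, n_monotone_down=n_down,
        expected_per_direction=float(expected),
        chi2_up=chi2_up, p_up=p_up, chi2_down=chi2_down, p_down=p_down,
        binom_p_up=float(st.binomtest(n_up, n_subj, p_null).pvalue) if n_subj else 1.0,
        binom_p_down=float(st.binomtest(n_down, n_subj, p_null).pvalue) if n_subj else 1.0,
    )


def window_means(scores: pd.DataFrame) -> pd.DataFrame:
    """Mean cumulative CPM per (set, draw window) with a 95% CI of the mean
    (mean ± 1.96·SE) — the per-window summary used for trend figures."""
    rows = []
    for (name, draw), grp in scores.groupby(["set_name", "draw_index"], sort=True):
        m = grp["score"].mean()
        se = grp["score"].std(ddof=1) / np.sqrt(len(grp))
        rows.append({"set_name": name, "draw_index": draw, "mean_score": m,
                     "ci_low": m - 1.96 * se, "ci_high": m + 1.96 * se,
                     "n": len(grp)})
    return pd.DataFrame(rows)
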