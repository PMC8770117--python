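"""Pre-eclampsia classifier: screening arithmetic, LOOCV leakage guards,
AUC/PPV oracles, bootstrap behaviour, survival comparison, and the
specificity/robustness side analyses."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cfrnakit import pe
from cfrnakit.simulate import SimConfig, simulate_cohorts


def _frame(arr, index=None, columns=None):
    arr = np.asarray(arr, dtype=float)
    index = index or [f"s{j}" for j in range(arr.shape[0])]
    columns = columns or [f"g{i}" for i in range(arr.shape[1])]
    return pd.DataFrame(arr, index=index, columns=columns)


class TestSpearmanScreen:
    def test_perfect_separator_retained(self):
        y = pd.Series([0, 0, 0, 1, 1, 1, 0, 1, 0, 1],
                      index=[f"s{j}" for j in range(10)])
        X = _frame(np.column_stack([y.values,
                                    np.random.default_rng(0).normal(size=10)]))
        res = pe.spearman_screen(X, y)
        row = res.table.set_index("gene_id").loc["g0"]
        assert abs(row["rho"]) == pytest.approx(1.0)
        assert "g0" in res.retained

    def test_hand_rank_example(self):
        # values {1,2,3,4}, labels {0,0,1,1}: rho = 0.894 by direct rank formula
        y = pd.Series([0, 0, 1, 1], index=list("abcd"))
        X = _frame([[1.0], [2.0], [3.0], [4.0]], index=list("abcd"))
        res = pe.spearman_screen(X, y, alpha=1.0)
        assert res.table["rho"].iloc[0] == pytest.approx(0.894, abs=5e-4)

    def test_matches_scipy_per_gene(self):
        import scipy.stats as st
        rng = np.random.default_rng(1)
        X = _frame(rng.normal(size=(30, 8)))
        y = pd.Series(rng.integers(0, 2, 30), index=X.index)
        while y.value_counts().min() < 2:
            y = pd.Series(rng.integers(0, 2, 30), index=X.index)
        res = pe.spearman_screen(X, y, alpha=1.0).table.set_index("gene_id")
        for g in X.columns:
            ref = st.spearmanr(X[g].values, y.values)
            assert res.loc[g, "rho"] == pytest.approx(ref.statistic, abs=1e-10)
            assert res.loc[g, "p_value"] == pytest.approx(ref.pvalue, rel=1e-6)

    def test_null_genes_yield_no_discoveries(self):
        rng = np.random.default_rng(2)
        X = _frame(rng.normal(size=(60, 1000)))
        y = pd.Series(rng.integers(0, 2, 60), index=X.index)
        res = pe.spearman_screen(X, y, alpha=0.05)
        assert len(res.retained) <= 2  # ~0 expected under BH

    def test_constant_gene_skipped(self):
        y = pd.Series([0, 0, 1, 1, 0, 1], index=[f"s{j}" for j in range(6)])
        X = _frame(np.column_stack([np.ones(6), y.values]))
        res = pe.spearman_screen(X, y, alpha=1.0)
        assert "g0" not in set(res.table["gene_id"])


def _pe_dataset(n=160, n_genes=300, effect=1.0, prevalence=0.2, seed=0):
    cfg = SimConfig(n_cohorts=2, samples_per_cohort=[n // 2, n - n // 2],
                    ga_window_per_cohort=[(16.0, 27.0), (16.0, 27.0)],
                    n_genes=n_genes, trend_frac=0.05, cohort_offset_sd=0.0,
                    pe_effect=effect, pe_prevalence=prevalence, seed=seed)
    m, ann, _, _, truth = simulate_cohorts(cfg)
    from cfrnakit.correction import compute_cpm, log_transform
    X = log_transform(compute_cpm(m)).data.T
    X.index = ann["sample_id"].tolist()
    y = pd.Series((ann["outcome"] == "PE").astype(int).values, index=X.index)
    return X, y, ann, truth


class TestLoocv:
    def test_single_fold_matches_manual_refit(self):
        X, y, _, _ = _pe_dataset(n=40, n_genes=60, effect=2.0,
                                 prevalence=0.35, seed=3)
        rep = pe.loocv_fit(X, y)
        sid = X.index[0]
        prob, feats = pe._fit_fold(X.drop(index=sid), y.drop(index=sid),
                                   X.loc[[sid]], 0.05)
        assert rep.oof_prob.loc[sid] == pytest.approx(prob[0])
        assert rep.fold_features[0] == feats

    def test_consensus_subset_of_every_fold(self):
        X, y, _, _ = _pe_dataset(n=40, n_genes=60, effect=2.0,
                                 prevalence=0.35, seed=4)
        rep = pe.loocv_fit(X, y)
        for feats in rep.fold_features:
            assert set(rep.consensus_features) <= set(feats)

    def test_shuffled_labels_auc_near_half(self):
        """Label-permutation null: AUC in [0.4, 0.6] for 19/20 seeds."""
        X, y, _, _ = _pe_dataset(n=60, n_genes=100, effect=1.0,
                                 prevalence=0.3, seed=5)
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(s)
            y_perm = pd.Series(rng.permutation(y.values), index=y.index)
            rep = pe.loocv_fit(X, y_perm)
            hits += 0.4 <= rep.auc <= 0.6
        assert hits >= 15  # 95% band with binomial slack at 20 runs

    def test_planted_heldout_gene_cannot_inflate_auc(self):
        """Leakage guard: a gene encoding the labels only outside each
        sample's own fold cannot lift out-of-fold AUC above the null band.

        Construction: the gene equals the label everywhere except that each
        sample's own value is flipped — in-fold training data look perfectly
        informative, but the held-out value anti-predicts.
        """
        rng = np.random.default_rng(6)
        n = 60
        idx = [f"s{j}" for j in range(n)]
        y = pd.Series(([0] * 40 + [1] * 20), index=idx)
        X = _frame(rng.normal(size=(n, 30)), index=idx)
        planted = y.astype(float).copy()
        planted[:] = y.values
        X["planted"] = 1.0 - planted  # held-out value flipped relative to label
        # inside every training fold, make the planted gene equal the label
        def corrector(train_ids, full):
            out = full.copy()
            out.loc[train_ids, "planted"] = y.loc[train_ids].astype(float)
            return out
        rep = pe.loocv_fit(X, y, fold_corrector=corrector)
        assert rep.auc <= 0.6

    def test_requires_both_classes(self):
        X, y, _, _ = _pe_dataset(n=30, n_genes=40, seed=7)
        with pytest.raises(ValueError):
            pe.loocv_fit(X, pd.Series(0, index=X.index))


class TestRocAuc:
    def test_perfect_and_reversed(self):
        y = pd.Series([1, 1, 0, 0], index=list("abcd"))
        perfect = pd.Series([0.9, 0.8, 0.2, 0.1], index=list("abcd"))
        reverse = pd.Series([0.1, 0.2, 0.8, 0.9], index=list("abcd"))
        assert pe.roc_auc(perfect, y)[1] == 1.0
        assert pe.roc_auc(reverse, y)[1] == 0.0

    def test_worked_example_three_quarters(self):
        y = pd.Series([1, 0, 1, 0], index=list("abcd"))
        probs = pd.Series([0.9, 0.8, 0.4, 0.3], index=list("abcd"))
        assert pe.roc_auc(probs, y)[1] == pytest.approx(0.75)

    def test_equals_concordant_pair_enumeration(self):
        """AUC == exhaustive concordant-pair counting for random n <= 50."""
        rng = np.random.default_rng(8)
        for trial in range(30):
            n = int(rng.integers(4, 51))
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            probs = np.round(rng.random(n), 2)  # ties likely
            idx = [f"s{j}" for j in range(n)]
            auc = pe.roc_auc(pd.Series(probs, index=idx), pd.Series(y, index=idx))[1]
            num = tot = 0.0
            for i, j in itertools.product(range(n), range(n)):
                if y[i] == 1 and y[j] == 0:
                    tot += 1
                    num += 1.0 if probs[i] > probs[j] else (0.5 if probs[i] == probs[j] else 0.0)
            assert auc == pytest.approx(num / tot, abs=1e-12)

    def test_single_class_rejected(self):
        y = pd.Series([1, 1], index=list("ab"))
        with pytest.raises(ValueError):
            pe.roc_auc(pd.Series([0.5, 0.6], index=list("ab")), y)


class TestThreshold:
    def test_retains_three_of_four_cases(self):
        idx = list("abcdefgh")
        y = pd.Series([1, 1, 1, 1, 0, 0, 0, 0], index=idx)
        probs = pd.Series([0.9, 0.8, 0.7, 0.1, 0.6, 0.5, 0.2, 0.05], index=idx)
        thr, sens, spec = pe.threshold_at_sensitivity(probs, y, target=0.75)
        assert sens >= 0.75
        assert thr == pytest.approx(0.7)

    def test_target_one_captures_all_cases(self):
        idx = list("abcd")
        y = pd.Series([1, 1, 0, 0], index=idx)
        probs = pd.Series([0.9, 0.3, 0.5, 0.1], index=idx)
        thr, sens, _ = pe.threshold_at_sensitivity(probs, y, target=1.0)
        assert thr <= 0.3
        assert sens == 1.0

    def test_target_zero_allows_no_positives(self):
        idx = list("abcd")
        y = pd.Series([1, 1, 0, 0], index=idx)
        probs = pd.Series([0.9, 0.3, 0.5, 0.1], index=idx)
        thr, sens, spec = pe.threshold_at_sensitivity(probs, y, target=0.0)
        assert sens == 0.0 and spec == 1.0


class TestPpv:
    def test_perfect_test(self):
        assert pe.ppv(1.0, 1.0, 0.1) == 1.0

    def test_printed_formula_arithmetic(self):
        assert pe.ppv(0.75, 0.9, 0.137) == pytest.approx(0.10275 / 0.18905)
        assert pe.ppv(0.75, 0.9, 0.137) == pytest.approx(0.5435, abs=5e-5)

    def test_identity_with_confusion_matrix(self):
        """Formula PPV equals TP/(TP+FP) when sens/spec/prev come from the
        same confusion matrix — over random matrices."""
        rng = np.random.default_rng(9)
        for _ in range(200):
            tp, fn, fp, tn = rng.integers(1, 50, 4)
            n = tp + fn + fp + tn
            sens = tp / (tp + fn)
            spec = tn / (tn + fp)
            prev = (tp + fn) / n
            assert pe.ppv(sens, spec, prev) == pytest.approx(tp / (tp + fp), abs=1e-12)

    def test_undefined_denominator(self):
        with pytest.raises(ZeroDivisionError):
            pe.ppv(0.0, 1.0, 0.1)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            pe.ppv(1.2, 0.5, 0.1)


class TestBootstrap:
    def test_degenerate_perfect_auc(self):
        idx = [f"s{j}" for j in range(20)]
        y = pd.Series([1] * 10 + [0] * 10, index=idx)
        probs = pd.Series([0.9] * 10 + [0.1] * 10, index=idx)
        out = pe.bootstrap_ci(pe.auc_metric, probs, y, B=200, seed=0)
        assert out["ci_low"] == out["ci_high"] == 1.0
        assert out["sd"] == 0.0

    def test_same_seed_identical(self):
        rng = np.random.default_rng(10)
        idx = [f"s{j}" for j in range(40)]
        y = pd.Series([1] * 15 + [0] * 25, index=idx)
        probs = pd.Series(rng.random(40), index=idx)
        a = pe.bootstrap_ci(pe.auc_metric, probs, y, B=200, seed=5)
        b = pe.bootstrap_ci(pe.auc_metric, probs, y, B=200, seed=5)
        assert a == b

    def test_coverage_of_true_auc(self):
        """95% CI covers the data-generating AUC in 90-99% of 200 synthetic
        datasets (binormal model with known AUC)."""
        import scipy.stats as st

        def rank_auc(p, yy):  # Mann-Whitney AUC; equals pe.auc_metric
            n1 = int(yy.sum())
            n0 = len(yy) - n1
            r = st.rankdata(p.values)
            return (r[yy.values == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)

        delta = 1.0
        true_auc = st.norm.cdf(delta / np.sqrt(2))
        rng = np.random.default_rng(11)
        covered = 0
        reps = 200
        for r in range(reps):
            n1, n0 = 40, 60
            probs = np.concatenate([rng.normal(delta, 1, n1), rng.normal(0, 1, n0)])
            idx = [f"s{j}" for j in range(n1 + n0)]
            y = pd.Series([1] * n1 + [0] * n0, index=idx)
            ps = pd.Series(probs, index=idx)
            if r == 0:  # the rank formulation matches the package AUC
                assert rank_auc(ps, y) == pytest.approx(pe.auc_metric(ps, y))
            out = pe.bootstrap_ci(rank_auc, ps, y, B=200, seed=r)
            covered += out["ci_low"] <= true_auc <= out["ci_high"]
        assert 0.90 * reps <= covered <= 0.99 * reps


class TestLearningCurveKfold:
    def test_strong_signal_auc_high_and_loocv_consistent(self):
        X, y, _, _ = _pe_dataset(n=60, n_genes=80, effect=2.0,
                                 prevalence=0.3, seed=12)
        table = pe.learning_curve_kfold(X, y, ks=(2, 5, 9), seed=0)
        assert table["auc"].iloc[-1] > 0.8  # LOOCV terminal point
        # terminal point equals loocv_fit output
        assert table["auc"].iloc[-1] == pytest.approx(pe.loocv_fit(X, y).auc)
        # within Monte-Carlo error the curve does not collapse with more folds
        assert table["auc"].iloc[1] >= table["auc"].iloc[0] - 0.15

    def test_null_signal_flat_near_half(self):
        rng = np.random.default_rng(13)
        idx = [f"s{j}" for j in range(80)]
        X = _frame(rng.normal(size=(80, 50)), index=idx)
        y = pd.Series([1] * 25 + [0] * 55, index=idx)
        table = pe.learning_curve_kfold(X, y, ks=(2, 5), include_loocv=False, seed=0)
        assert np.all(np.abs(table["auc"] - 0.5) < 0.2)


class TestSurvival:
    def test_identical_groups_coincide(self):
        rng = np.random.default_rng(14)
        times = np.concatenate([rng.uniform(37, 41, 50)] * 2)
        idx = [f"s{j}" for j in range(100)]
        delivery = pd.Series(times, index=idx)
        positive = pd.Series([True] * 50 + [False] * 50, index=idx)
        delivery[positive.values] = delivery[~positive.values].values  # same times
        out = pe.km_logrank(delivery, positive)
        assert out.p_value > 0.9

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(15)
        idx = [f"s{j}" for j in range(400)]
        delivery = pd.Series(np.concatenate([rng.normal(36, 1.5, 200),
                                             rng.normal(39, 1.5, 200)]), index=idx)
        positive = pd.Series([True] * 200 + [False] * 200, index=idx)
        out = pe.km_logrank(delivery, positive)
        assert out.p_value < 0.01
        # positive curve drops earlier: lower survival at week 38
        def surv_at(df, t):
            vals = df[df["week"] <= t]
            return vals["survival"].iloc[-1] if len(vals) else 1.0
        assert surv_at(out.km_positive, 38.0) < surv_at(out.km_negative, 38.0)

    def test_single_event_time_single_step(self):
        idx = list("abcdef")
        delivery = pd.Series([38.0] * 3 + [40.0] * 3, index=idx)
        positive = pd.Series([True] * 3 + [False] * 3, index=idx)
        out = pe.km_logrank(delivery, positive)
        assert (out.km_positive["survival"].iloc[-1]) == 0.0
        assert set(out.km_positive["week"]) <= {0.0, 38.0}

    def test_exclusion_flag_drops_samples(self):
        idx = [f"s{j}" for j in range(40)]
        rng = np.random.default_rng(16)
        delivery = pd.Series(rng.uniform(30, 41, 40), index=idx)
        positive = pd.Series([True] * 20 + [False] * 20, index=idx)
        sptb = pd.Series([False] * 30 + [True] * 10, index=idx)
        out = pe.km_logrank(delivery, positive, exclude=sptb)
        assert out.n == 30


class TestSideAnalyses:
    def test_pe_only_effect_no_subtype_overlap(self):
        X, y, ann, truth = _pe_dataset(n=200, n_genes=150, effect=1.5,
                                       prevalence=0.2, seed=17)
        outcome = pd.Series(ann["outcome"].values, index=X.index)
        screen = pe.spearman_screen(X, y)
        rep = pe.subtype_specificity(X, outcome, screen.retained)
        for c, r in rep["contrasts"].items():
            if not r.get("skipped"):
                # chance overlap only: PE signal absent from HTN contrasts
                assert len(r["overlap"]) <= max(1, len(screen.retained) // 10)

    def test_injected_shared_gene_appears_in_overlap(self):
        X, y, ann, truth = _pe_dataset(n=240, n_genes=100, effect=2.0,
                                       prevalence=0.2, seed=18)
        outcome = pd.Series(ann["outcome"].values, index=X.index)
        shared = truth.pe_panel[0]
        chronic = outcome == "chronic_htn"
        if chronic.sum() >= 5:
            X = X.copy()
            X.loc[chronic.values, shared] += 3.0  # inject into chronic HTN too
        screen = pe.spearman_screen(X, y)
        rep = pe.subtype_specificity(X, outcome, screen.retained)
        r = rep["contrasts"].get("chronic_htn", {})
        if not r.get("skipped") and shared in screen.retained:
            assert shared in r["overlap"]

    def test_no_substrata_contrast_skipped(self):
        X, y, _, _ = _pe_dataset(n=40, n_genes=50, seed=19)
        outcome = pd.Series("normotensive", index=X.index)
        outcome.iloc[:8] = "PE"
        rep = pe.subtype_specificity(X, outcome, [])
        assert all(r.get("skipped") for r in rep["contrasts"].values())

    def test_sptb_exclusion_noop_when_absent(self):
        X, y, _, _ = _pe_dataset(n=40, n_genes=60, effect=2.0,
                                 prevalence=0.35, seed=20)
        sptb = pd.Series(False, index=X.index)
        full = pe.loocv_fit(X, y)
        reduced = pe.robustness_exclude_sptb(X, y, sptb)
        assert reduced.auc == pytest.approx(full.auc)

    def test_sptb_null_exclusion_small_auc_shift(self):
        X, y, ann, _ = _pe_dataset(n=160, n_genes=120, effect=1.5,
                                   prevalence=0.2, seed=21)
        sptb = pd.Series((ann["outcome"] == "sPTB").values, index=X.index)
        full = pe.loocv_fit(X, y)
        reduced = pe.robustness_exclude_sptb(X, y, sptb)
        assert abs(full.auc - reduced.auc) < 0.1

    def test_all_noncases_sptb_rejected(self):
        X, y, _, _ = _pe_dataset(n=40, n_genes=50, prevalence=0.3, seed=22)
        sptb = pd.Series(True, index=X.index)
        with pytest.raises(ValueError):
            pe.robustness_exclude_sptb(X, y, sptb)


def test_full_report_consistency():
    X, y, _, _ = _pe_dataset(n=60, n_genes=80, effect=2.0, prevalence=0.3, seed=23)
    rep = pe.full_report(X, y, B=200, seed=0)
    assert 0.0 <= rep.oof_prob.min() and rep.oof_prob.max() <= 1.0
    assert rep.sensitivity >= 0.75
    assert rep.ppv == pytest.approx(pe.ppv(rep.sensitivity, rep.specificity,
                                           rep.prevalence))
    assert rep.auc_ci[0] <= rep.auc <= rep.auc_ci[1] + 1e-9
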