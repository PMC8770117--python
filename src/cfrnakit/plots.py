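"""Figure helpers (matplotlib, Agg backend; SVG/PNG by file extension)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_learning_curve(table: pd.DataFrame, path, ylabel="MAE (days)") -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    x = table["n_train"] if "n_train" in table else table["k"]
    y = table["mae_mean_days"] if "mae_mean_days" in table else table["auc"]
    ax.plot(x, y, "o-")
    if "mae_sd_days" in table:
        ax.errorbar(x, y, yerr=table["mae_sd_days"], fmt="none", capsize=3)
    ax.set_xlabel("training samples" if "n_train" in table else "CV folds (k)")
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_roc(curve: pd.DataFrame, auc: float, path) -> None:
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(curve["fpr"], curve["tpr"], label=f"AUC = {auc:.2f}")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_km(surv, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for df, label in ((surv.km_positive, "test-positive"),
                      (surv.km_negative, "test-negative")):
        ax.step(df["week"], df["survival"], where="post", label=label)
    ax.set_xlabel("gestational age at delivery (weeks)")
    ax.set_ylabel("fraction undelivered")
    ax.legend(title=f"log-rank p = {surv.p_value:.2g}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_qq_pvalues(p_values: np.ndarray, path, highlight: dict | None = None) -> None:
    """Q-Q plot of ranked screening p-values against uniform expectation."""
    p = np.sort(np.asarray(p_values))
    n = len(p)
    expected = np.arange(1, n + 1) / (n + 1.0)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(-np.log10(expected), -np.log10(np.maximum(p, 1e-300)), ".", ms=3)
    lim = -np.log10(1.0 / (n + 1))
    ax.plot([0, lim], [0, lim], "k:", lw=0.8)
    ax.set_xlabel("expected -log10 p")
    ax.set_ylabel("observed -log10 p")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_trend(scores: pd.DataFrame, set_name: str, path) -> None:
    sub = scores[scores["set_name"] == set_name]
    fig, ax = plt.subplots(figsize=(5, 4))
    for cohort, grp in sub.groupby("cohort"):
        ax.plot(grp["ga_collect_weeks"], grp["score"], ".", ms=3, label=cohort)
    ax.set_xlabel("gestational age at collection (weeks)")
    ax.set_ylabel("cumulative CPM")
    ax.set_title(set_name)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
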