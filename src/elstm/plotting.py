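"""Line charts for the repeated-split experiment tables."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_daily_curve", "plot_sweep", "save_figure"]

_LABELS = {"auroc": "AUROC", "auprc": "AUPRC",
           "n_learners": "number of base LSTM classifiers (P)",
           "subset_size": "variable subset size (m)"}


def plot_daily_curve(results: pd.DataFrame, metric: str = "auroc"):
    """Mean metric vs. prediction day, one line per model."""
    daily = results[results["phase"] == "daily"]
    fig, ax = plt.subplots(figsize=(6, 4))
    for model, grp in daily.groupby("model"):
        curve = grp.groupby("day")[metric].agg(["mean", "std"])
        ax.errorbar(curve.index, curve["mean"], yerr=curve["std"],
                    marker="o", capsize=3, label=model)
    ax.set_xlabel("day of prediction")
    ax.set_ylabel(_LABELS.get(metric, metric))
    ax.set_title("dynamic prediction with daily data updating")
    ax.legend()
    fig.tight_layout()
    return fig


def plot_sweep(results: pd.DataFrame, by: str = "n_learners",
               metric: str = "auroc"):
    """Mean metric vs. an ensemble hyperparameter (P or m) sweep."""
    static = results[(results["phase"] == "static")
                     & (results["model"] == "elstm")]
    curve = static.groupby(by)[metric].agg(["mean", "std"])
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.errorbar(curve.index, curve["mean"], yerr=curve["std"],
                marker="o", capsize=3)
    ax.set_xlabel(_LABELS.get(by, by))
    ax.set_ylabel(_LABELS.get(metric, metric))
    fig.tight_layout()
    return fig


def save_figure(fig, path: str, dpi: int = 150) -> None:
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
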