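"""Optional figure output: volcano, PLS-DA scores, ROC bands, KM curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["volcano_plot", "plsda_score_plot", "roc_band_plot", "km_plot"]


def volcano_plot(dap: pd.DataFrame, path, p_cut=0.05, fc_cut=2.0) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    up = dap["up_in_pcr"] | dap["up_in_nonpcr"]
    ax.scatter(dap.loc[~up, "log2fc"], dap.loc[~up, "neg_log10_p"],
               s=8, c="0.6", alpha=0.6)
    ax.scatter(dap.loc[dap["up_in_pcr"], "log2fc"],
               dap.loc[dap["up_in_pcr"], "neg_log10_p"], s=14, c="green",
               label="up in pCR")
    ax.scatter(dap.loc[dap["up_in_nonpcr"], "log2fc"],
               dap.loc[dap["up_in_nonpcr"], "neg_log10_p"], s=14, c="red",
               label="up in non-pCR")
    ax.axhline(-np.log10(p_cut), ls="--", lw=0.7, c="k")
    for s in (-1, 1):
        ax.axvline(s * np.log2(fc_cut), ls="--", lw=0.7, c="k")
    ax.set_xlabel("log2 fold-change (pCR / non-pCR)")
    ax.set_ylabel("-log10 p")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plsda_score_plot(model, groups, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    g = np.asarray(groups)
    t = model.scores
    for lv, color in zip(np.unique(g), ("red", "green")):
        m = g == lv
        ax.scatter(t.iloc[m.nonzero()[0], 0], t.iloc[m.nonzero()[0], 1],
                   c=color, label=str(lv), s=20)
    ev = 100 * model.explained_x_variance
    ax.set_xlabel(f"component 1 ({ev[0]:.0f}%)")
    ax.set_ylabel(f"component 2 ({ev[1]:.0f}%)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def roc_band_plot(evaluation, path) -> None:
    fig, axes = plt.subplots(1, len(evaluation.roc_bands),
                             figsize=(4.5 * len(evaluation.roc_bands), 4))
    axes = np.atleast_1d(axes)
    for ax, (name, band) in zip(axes, evaluation.roc_bands.items()):
        x = band["one_minus_specificity"]
        ax.fill_between(x, band["q25"], band["q75"], alpha=0.3)
        ax.plot(x, band["q50"], lw=1.5)
        ax.plot([0, 1], [0, 1], "k--", lw=0.7)
        ax.set_title(f"{name}: median AUC {evaluation.median_auc[name]:.3f}")
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def km_plot(curves: dict, path, title="") -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for lv, curve in curves.items():
        ax.step(curve["time"], curve["survival"], where="post", label=str(lv))
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
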