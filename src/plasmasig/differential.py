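"""Differential abundance between response groups, PLS-DA with VIP scores,
and a subtype-confounding check.

Differentially abundant proteins (DAPs) are called by a two-sample
Student's t-test on log2 abundances combined with a fold-change threshold
on the ratio of group geometric means, i.e. the classic volcano-plot
criterion p < 0.05 and |fold-change| > 2.  No multiplicity correction is
applied to the call itself; Benjamini-Hochberg q-values are reported
alongside for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from statsmodels.stats.multitest import multipletests

from .matrix import QuantMatrix

__all__ = ["dap_test", "plsda_fit", "confounder_check", "PLSDAModel"]


def _as_binary(groups) -> np.ndarray:
    g = np.asarray(groups)
    if g.dtype == bool:
        return g.astype(int)
    levels = np.unique(g)
    if len(levels) != 2:
        raise ValueError("groups must be binary")
    return (g == levels[1]).astype(int)


def dap_test(qm: QuantMatrix, groups, p_cut: float = 0.05,
             fc_cut: float = 2.0, equal_var: bool = True) -> pd.DataFrame:
    """Two-sample t-test on log2 abundances with a fold-change call.

    `groups` is binary with 1 = pCR.  log2 fold-change is oriented pCR
    minus non-pCR (positive = up in pCR) and equals the log2 ratio of
    group geometric means on the linear scale.  `equal_var=False` switches
    to the Welch test.

    Returns a per-protein DataFrame with group means, log2fc, t, p, BH q,
    volcano coordinates, and the up_in_pcr / up_in_nonpcr flags.
    """
    g = _as_binary(groups)
    if g.sum() < 2 or (1 - g).sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    if qm.n_missing:
        raise ValueError("dap_test requires a complete matrix")
    Y = np.log2(qm.values.to_numpy())
    Y1, Y0 = Y[g == 1], Y[g == 0]
    t, p = stats.ttest_ind(Y1, Y0, axis=0, equal_var=equal_var)
    m1, m0 = Y1.mean(axis=0), Y0.mean(axis=0)
    log2fc = m1 - m0
    # zero-variance proteins: identical groups mean no evidence, not NaN
    t = np.where(np.isnan(t), 0.0, t)
    p = np.where(np.isnan(p), 1.0, p)
    q = multipletests(p, method="fdr_bh")[1]
    lfc_cut = np.log2(fc_cut)
    sig = p < p_cut
    out = pd.DataFrame({
        "protein_id": qm.protein_ids,
        "mean_log2_pcr": m1, "mean_log2_nonpcr": m0,
        "log2fc": log2fc, "t": t, "p": p, "q": q,
        "neg_log10_p": -np.log10(np.maximum(p, 1e-300)),
        "up_in_pcr": sig & (log2fc > lfc_cut),
        "up_in_nonpcr": sig & (log2fc < -lfc_cut),
    })
    out["dap"] = out["up_in_pcr"] | out["up_in_nonpcr"]
    return out


@dataclass
class PLSDAModel:
    """Fitted PLS-DA decomposition plus per-protein VIP scores."""

    n_components: int
    protein_ids: list[str]
    scores: pd.DataFrame            # samples x components (T)
    weights: np.ndarray             # proteins x components (W, unit norm)
    loadings: np.ndarray            # proteins x components (P)
    explained_x_variance: np.ndarray  # per component, fraction of X variance
    vip: pd.Series                  # per protein

    def top_vip(self, cut: float = 1.5) -> pd.Series:
        v = self.vip.sort_values(ascending=False)
        return v[v > cut]


def plsda_fit(qm: QuantMatrix, groups, ncomp: int = 2) -> PLSDAModel:
    """PLS-DA on the (centered, unit-variance) abundance matrix.

    The response is the dummy-coded group label; VIP for protein j is
    sqrt(p * sum_a(w_aj^2 SSY_a) / sum_a SSY_a) with SSY_a the Y variance
    explained by component a, so that sum_j VIP_j^2 = p exactly.
    """
    g = _as_binary(groups)
    if qm.n_missing:
        raise ValueError("plsda_fit requires a complete matrix")
    X = np.log2(qm.values.to_numpy())
    if ncomp > np.linalg.matrix_rank(X - X.mean(axis=0)):
        raise ValueError("ncomp exceeds the rank of the centered matrix")
    pls = PLSRegression(n_components=ncomp, scale=True)
    pls.fit(X, g.astype(float))

    T = pls.x_scores_              # n x A
    W = pls.x_weights_             # p x A (columns unit norm)
    P = pls.x_loadings_
    q = pls.y_loadings_.ravel()    # A
    p_prot = X.shape[1]

    ssy = (q ** 2) * (T ** 2).sum(axis=0)          # Y variance per component
    w2 = (W / np.linalg.norm(W, axis=0)) ** 2
    vip = np.sqrt(p_prot * (w2 @ ssy) / ssy.sum())

    Xc = (X - X.mean(0)) / np.where(X.std(0, ddof=1) == 0, 1, X.std(0, ddof=1))
    total_ssx = (Xc ** 2).sum()
    expl = (T ** 2).sum(axis=0) * (P ** 2).sum(axis=0) / total_ssx

    return PLSDAModel(
        n_components=ncomp,
        protein_ids=qm.protein_ids,
        scores=pd.DataFrame(T, index=qm.values.index,
                            columns=[f"comp{a + 1}" for a in range(ncomp)]),
        weights=W, loadings=P,
        explained_x_variance=expl,
        vip=pd.Series(vip, index=qm.protein_ids, name="vip"),
    )


def confounder_check(qm: QuantMatrix, groups, hr_status, her2_status,
                     proteins, alpha: float = 0.05) -> pd.DataFrame:
    """Within each response stratum, test candidate-marker abundance across
    HR and HER2 status.

    A marker is "not confounded" by subtype when, within both the pCR and
    non-pCR strata, neither receptor status shows a difference at `alpha`.
    Comparisons with fewer than 2 samples on either side, or with a
    constant factor in the stratum, are skipped and flagged degenerate.
    """
    g = _as_binary(groups)
    factors = {"HR": np.asarray(hr_status), "HER2": np.asarray(her2_status)}
    rows = []
    Y = np.log2(qm.values.loc[:, list(proteins)].to_numpy())
    for ip, prot in enumerate(proteins):
        verdict_ok = True
        for stratum, label in ((1, "pCR"), (0, "non-pCR")):
            in_s = g == stratum
            for fname, fvals in factors.items():
                f = fvals[in_s]
                y = Y[in_s, ip]
                a, b = y[f == 1], y[f == 0]
                if len(a) < 2 or len(b) < 2:
                    rows.append((prot, label, fname, np.nan, True, ""))
                    continue
                t, p = stats.ttest_ind(a, b, equal_var=True)
                ok = p > alpha
                verdict_ok &= ok
                rows.append((prot, label, fname, p, False,
                             "" if ok else "differs"))
        rows.append((prot, "all", "verdict", np.nan, False,
                     "pass" if verdict_ok else "fail"))
    return pd.DataFrame(rows, columns=["protein_id", "stratum", "factor",
                                       "p", "degenerate", "note"])
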