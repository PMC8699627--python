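"""Presence filtering, local least squares imputation, stability-based
selection of endogenous normalization proteins, and NSF normalization.

The normalization strategy uses a small set of endogenous plasma proteins
whose abundance is stable across samples and, crucially, differs least
between the response groups.  Each stable protein is scaled by its
cross-sample median; the geometric mean of those ratios within a sample is
that sample's normalization scaling factor (NSF), and every other protein
in the sample is divided by it.  This removes per-sample multiplicative
bias (loading, depletion, and instrument drift) exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import QuantMatrix

__all__ = [
    "filter_by_presence", "lls_impute", "rank_stability", "fit_nsf",
    "apply_nsf", "reference_correlation_qc", "NormalizationModel",
    "ImputationModel", "preprocess_pipeline",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# presence filter
# ---------------------------------------------------------------------------

def filter_by_presence(qm: QuantMatrix, threshold: float = 0.80) -> QuantMatrix:
    """Keep proteins quantified in at least `threshold` of samples."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    frac = qm.presence_fraction()
    keep = list(frac.index[frac >= threshold])
    log.info("presence filter at %.0f%%: retained %d / %d proteins",
             100 * threshold, len(keep), qm.n_proteins)
    return qm.subset_proteins(keep)


# ---------------------------------------------------------------------------
# local least squares imputation
# ---------------------------------------------------------------------------

@dataclass
class ImputationModel:
    """Record of how each incomplete protein was filled."""

    k: int
    donors: dict[str, list[str]] = field(default_factory=dict)
    coefficients: dict[str, np.ndarray] = field(default_factory=dict)
    imputed_cells: list[tuple[str, str]] = field(default_factory=list)
    fallback_proteins: list[str] = field(default_factory=list)


def lls_impute(qm: QuantMatrix, k: int = 10) -> tuple[QuantMatrix,
                                                      ImputationModel]:
    """Fill missing cells by local least squares regression.

    For each incomplete protein, the `k` fully-observed proteins with the
    highest absolute Pearson correlation (computed on raw abundances over
    the target's observed samples) serve as donors; an affine least-squares
    fit of the target on the donors over its observed samples predicts the
    missing cells.  Negative predictions are floored at the target's
    smallest observed value.  Observed cells are never altered.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    vals = qm.values.to_numpy().copy()
    obs = ~np.isnan(vals)
    complete = obs.all(axis=0)
    model = ImputationModel(k=k)
    incomplete_idx = np.nonzero(~complete)[0]
    if len(incomplete_idx) == 0:
        return qm.with_values(qm.values.copy(), scale_tag="imputed"), model

    n_complete = int(complete.sum())
    if n_complete == 0:
        raise ValueError("no fully-observed proteins available as donors")
    if n_complete < k:
        warnings.warn(f"only {n_complete} complete proteins; reducing k from "
                      f"{k} to {n_complete}", stacklevel=2)
        k = n_complete
    donors_all = np.nonzero(complete)[0]
    D = vals[:, donors_all]  # complete columns, no NaNs
    proteins = qm.protein_ids
    samples = qm.sample_ids

    for j in incomplete_idx:
        y = vals[:, j]
        seen = obs[:, j]
        miss = ~seen
        if seen.sum() < k + 1:
            mu = float(np.nanmean(y)) if seen.any() else 0.0
            warnings.warn(f"protein {proteins[j]}: only {int(seen.sum())} "
                          "observed samples; falling back to observed mean",
                          stacklevel=2)
            vals[miss, j] = mu
            model.fallback_proteins.append(proteins[j])
        else:
            ys = y[seen]
            Ds = D[seen]
            sd = Ds.std(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                corr = np.abs((Ds - Ds.mean(0)).T @ (ys - ys.mean())
                              / (len(ys) * sd * ys.std() + 1e-300))
            corr[~np.isfinite(corr)] = 0.0
            top = np.argsort(-corr)[:k]
            A = np.column_stack([np.ones(seen.sum()), Ds[:, top]])
            coef, *_ = np.linalg.lstsq(A, ys, rcond=None)
            pred = np.column_stack([np.ones(miss.sum()),
                                    D[miss][:, top]]) @ coef
            floor = float(ys.min())
            pred = np.where(pred > 0, pred, floor)
            vals[miss, j] = pred
            model.donors[proteins[j]] = [proteins[i] for i in donors_all[top]]
            model.coefficients[proteins[j]] = coef
        model.imputed_cells.extend(
            (samples[i], proteins[j]) for i in np.nonzero(miss)[0])

    out = qm.with_values(pd.DataFrame(vals, index=qm.values.index,
                                      columns=qm.values.columns),
                         scale_tag="imputed")
    return out, model


# ---------------------------------------------------------------------------
# stability ranking (NormFinder-style variance decomposition)
# ---------------------------------------------------------------------------

def rank_stability(qm: QuantMatrix, groups, method: str = "normfinder",
                   top_k: int = 4) -> pd.DataFrame:
    """Rank proteins by expression stability across the two response groups.

    ``method="normfinder"`` applies the two-group variance-decomposition
    approach on natural-log abundances: within each group, sample effects
    (column means of gene-centered data) are removed, per-protein residual
    variances are estimated, and the inter-group difference of each protein
    is shrunk toward zero in proportion to its sampling variance.  The
    stability value averages, over groups, the absolute shrunken difference
    plus the standard error of the group mean; smaller is more stable.

    ``method="simple"`` ranks by |group mean difference| + pooled SD, a
    transparent fallback that rewards only a small between-group difference
    and low overall variability.

    Returns a DataFrame sorted by rank with columns: group means, within
    variances, inter-group difference, stability, rank, selected (top_k).
    """
    groups = np.asarray(groups)
    if qm.n_missing:
        raise ValueError("rank_stability requires a complete matrix")
    levels = np.unique(groups)
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    for lv in levels:
        if (groups == lv).sum() < 2:
            raise ValueError(f"group {lv!r} has fewer than 2 samples")
    Y = np.log(qm.values.to_numpy())
    p = Y.shape[1]

    means, variances, ses = [], [], []
    for lv in levels:
        Z = Y[groups == lv]
        ng = Z.shape[0]
        gene_mean = Z.mean(axis=0)
        if method == "normfinder":
            centered = Z - gene_mean[None, :]
            sample_eff = centered.mean(axis=1, keepdims=True)
            resid = centered - sample_eff
            var = resid.var(axis=0, ddof=1) * p / max(p - 1, 1)
        elif method == "simple":
            var = Z.var(axis=0, ddof=1)
        else:
            raise ValueError(f"unknown method {method!r}")
        means.append(gene_mean)
        variances.append(var)
        ses.append(var / ng)
    m0, m1 = means
    v0, v1 = variances

    if method == "normfinder":
        d = m1 - m0
        d = d - d.mean()  # difference relative to the protein-average shift
        samp_var = ses[0] + ses[1]
        gamma = max(d.var(ddof=1) - samp_var.mean(), 0.0)
        shrink = gamma / (gamma + samp_var) if gamma > 0 else np.zeros(p)
        d_tilde = d * shrink
        stability = 0.5 * ((np.abs(d_tilde) + np.sqrt(ses[0]))
                           + (np.abs(d_tilde) + np.sqrt(ses[1])))
        diff = d_tilde
    else:
        diff = m1 - m0
        pooled_sd = np.sqrt((v0 + v1) / 2.0)
        stability = np.abs(diff) + pooled_sd

    out = pd.DataFrame({
        "protein_id": qm.protein_ids,
        f"mean_{levels[0]}": m0, f"mean_{levels[1]}": m1,
        f"var_{levels[0]}": v0, f"var_{levels[1]}": v1,
        "difference": diff,
        "stability": stability,
    })
    out["rank"] = out["stability"].rank(method="first").astype(int)
    out = out.sort_values("rank").reset_index(drop=True)
    out["selected"] = out["rank"] <= top_k
    return out


# ---------------------------------------------------------------------------
# NSF normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizationModel:
    """Stable-protein medians and the per-sample normalization scaling
    factors (NSF) derived from them."""

    norm_protein_ids: tuple[str, ...]
    medians: pd.Series          # per stable protein, cross-sample median
    nsf: pd.Series              # per sample, geometric mean of scaled ratios


def fit_nsf(qm: QuantMatrix, norm_protein_ids,
            medians: pd.Series | None = None) -> NormalizationModel:
    """Fit per-sample normalization scaling factors from stable proteins.

    Each stable protein k is scaled by its cross-sample median m_k; the NSF
    of sample s is the geometric mean over k of x_ks / m_k.  Passing
    `medians` freezes the reference medians of a previously fitted model
    (e.g. to normalize a later cohort against the discovery cohort, or to
    verify that a normalized matrix carries no residual per-sample bias).
    """
    ids = tuple(norm_protein_ids)
    sub = qm.values.loc[:, list(ids)]
    if sub.isna().any().any():
        raise ValueError("normalization proteins must be complete")
    arr = sub.to_numpy()
    if (arr <= 0).any():
        raise ValueError("normalization-protein abundances must be positive")
    med = np.median(arr, axis=0) if medians is None \
        else medians.loc[list(ids)].to_numpy(float)
    if (med <= 0).any():
        raise ValueError("normalization-protein medians must be positive")
    ratios = arr / med[None, :]
    nsf = np.exp(np.mean(np.log(ratios), axis=1))
    return NormalizationModel(
        norm_protein_ids=ids,
        medians=pd.Series(med, index=list(ids)),
        nsf=pd.Series(nsf, index=qm.values.index),
    )


def apply_nsf(qm: QuantMatrix, nm: NormalizationModel,
              norm_proteins: str = "carry") -> QuantMatrix:
    """Divide every non-stable protein by its sample's NSF.

    With ``norm_proteins="carry"`` (the discovery convention) the stable
    proteins pass through unscaled and are flagged in ``norm_protein_ids``;
    with ``"scale"`` they are divided too, after which refitting against
    the model's stored medians yields NSF identically 1 — the idempotence
    check that one normalization pass removes all per-sample bias.
    """
    if norm_proteins not in ("carry", "scale"):
        raise ValueError("norm_proteins must be 'carry' or 'scale'")
    if qm.n_missing:
        raise ValueError("apply_nsf requires a complete matrix")
    if list(nm.nsf.index) != qm.sample_ids:
        raise ValueError("sample mismatch between matrix and model")
    vals = qm.values.copy()
    if norm_proteins == "scale":
        cols = list(qm.protein_ids)
    else:
        cols = [pid for pid in qm.protein_ids
                if pid not in nm.norm_protein_ids]
    vals.loc[:, cols] = vals.loc[:, cols].div(nm.nsf, axis=0)
    return qm.with_values(vals, scale_tag="normalized",
                          norm_protein_ids=nm.norm_protein_ids)


# ---------------------------------------------------------------------------
# reference-concentration QC
# ---------------------------------------------------------------------------

def reference_correlation_qc(qm: QuantMatrix, reference: dict[str, float],
                             n_perm: int = 999, seed: int = 0
                             ) -> tuple[float, float, int]:
    """Pearson correlation of per-protein median abundance (log scale)
    against log reference concentrations, with a one-sided permutation p.

    Returns (rho, p, n_shared).  Used as a sanity check of normalized plasma
    abundances against an external concentration compendium.
    """
    shared = [pid for pid in qm.protein_ids if pid in reference]
    if len(shared) < 3:
        raise ValueError("need at least 3 proteins shared with the reference")
    med = np.log(qm.values.loc[:, shared].median(axis=0).to_numpy())
    ref = np.log(np.asarray([reference[pid] for pid in shared], float))
    rho = float(stats.pearsonr(med, ref).statistic)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        r = float(stats.pearsonr(med, rng.permutation(ref)).statistic)
        if r >= rho:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return rho, p, len(shared)


# ---------------------------------------------------------------------------
# pipeline convenience
# ---------------------------------------------------------------------------

def preprocess_pipeline(qm: QuantMatrix, groups, *, presence_threshold=0.80,
                        lls_k=10, n_norm_proteins=4,
                        stability_method="normfinder",
                        exclude_norm_downstream=True):
    """filter -> impute -> rank stability -> fit/apply NSF.

    Returns (normalized QuantMatrix, stability table, NormalizationModel,
    ImputationModel).  When `exclude_norm_downstream` is True the stable
    proteins are dropped from the returned matrix (they are recoverable
    from the model).
    """
    filtered = filter_by_presence(qm, presence_threshold)
    imputed, imp_model = lls_impute(filtered, k=lls_k)
    stab = rank_stability(imputed, groups, method=stability_method,
                          top_k=n_norm_proteins)
    norm_ids = list(stab.loc[stab["selected"], "protein_id"])
    nm = fit_nsf(imputed, norm_ids)
    normalized = apply_nsf(imputed, nm)
    if exclude_norm_downstream:
        keep = [pid for pid in normalized.protein_ids if pid not in norm_ids]
        normalized = normalized.subset_proteins(keep)
    return normalized, stab, nm, imp_model
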