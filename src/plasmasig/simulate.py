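"""Synthetic plasma-proteome study generator.

Emulates the post-search product of a label-free LC-MS/MS plasma study of
neoadjuvant chemotherapy: a quantification matrix (~51 samples x ~548
proteins) with abundance-dependent (MNAR) missingness, a handful of planted
stable "housekeeping" proteins suitable for endogenous normalization, a
minority of group-differential proteins, and a clinical table whose three
survival endpoints follow an exponential proportional-hazards model linked
to designated protein log-abundances.

Model
-----
log abundance of protein *i* in sample *s*::

    log x_is = b_i + delta_i * g_s + u_s + eps_is

with protein baseline ``b_i ~ N(mu, tau^2)``, group effect ``delta_i`` on
the natural-log scale (specified as a log2 effect size), per-sample
multiplicative bias ``u_s ~ N(0, sample_scale_sd^2)`` shared by every
protein (what NSF normalization must remove), and measurement noise
``eps_is``.  Housekeeping proteins are high-abundance, low-noise, and have
zero group effect.  A cell is missing with probability
``sigmoid(miss_intercept + miss_slope * z_is)`` where ``z_is`` is the
standardized log abundance, so low-abundance cells go missing more often.

Survival: latent distant-metastasis, local-recurrence, and post-metastasis
death times are exponential with rates multiplied by ``exp(eta)``, where
``eta`` is linear in standardized log abundances of the linked proteins;
administrative censoring is uniform over a follow-up window.  DFS events
are any recurrence (local or distant), DMFS events are distant metastases,
and deaths occur only after metastasis, so a DMFS event always implies a
DFS event.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .clinical import ClinicalTable, SUBTYPES
from .matrix import QuantMatrix

__all__ = ["SimSpec", "SimTruth", "simulate_study", "mask_entries"]

# study-like subtype mix and per-subtype pCR weights (HR+/HER2-, HR+/HER2+,
# HER2+, TN); at the default 51/15 these reproduce the 20/5/5/21 split with
# 2/3/2/8 pCR
_SUBTYPE_WEIGHTS = (20, 5, 5, 21)
_PCR_WEIGHTS = (2, 3, 2, 8)
_GRADE3_PROB = {"HR+/HER2-": 0.05, "HR+/HER2+": 0.05, "HER2+": 0.20, "TN": 0.57}


@dataclass
class SimSpec:
    """Parameters of the synthetic study; defaults are the study conditions."""

    n_samples: int = 51
    n_proteins: int = 548
    n_pcr: int = 15
    n_housekeeping: int = 4
    n_differential: int = 4
    log2_effect_size: float = 1.2
    protein_mean_log_abundance: float = 18.0
    protein_log_sd: float = 1.5
    noise_log_sd: float = 0.35
    hk_noise_log_sd: float = 0.05
    sample_scale_sd: float = 0.3
    miss_intercept: float = -1.80
    miss_slope: float = -2.0
    #: (differential-protein index, beta_DFS, beta_OS, beta_DMFS) per linked
    #: protein; betas are log-hazard coefficients on standardized log abundance
    surv_link_proteins: tuple[tuple[int, float, float, float], ...] = (
        (1, 0.9, 0.5, 1.0),
        (2, 0.6, 0.9, 0.3),
    )
    censor_rate: float = 0.70
    followup_months: tuple[float, float] = (24.0, 84.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pcr >= self.n_samples or self.n_pcr <= 0:
            raise ValueError("need 0 < n_pcr < n_samples")
        if self.n_housekeeping + self.n_differential > self.n_proteins:
            raise ValueError("housekeeping + differential exceed n_proteins")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must lie in [0, 1)")
        if self.miss_slope > 0:
            raise ValueError("miss_slope must be <= 0 (low abundance -> missing)")
        if self.followup_months[0] <= 0 or \
                self.followup_months[1] <= self.followup_months[0]:
            raise ValueError("followup window must be 0 < lo < hi")
        for idx, *_ in self.surv_link_proteins:
            if not 0 <= idx < max(self.n_differential, 1):
                raise ValueError("surv_link index out of differential range")

    def replace(self, **kwargs) -> "SimSpec":
        return replace(self, **kwargs)

    def null(self, **kwargs) -> "SimSpec":
        """Spec with all planted effects removed (for calibration checks)."""
        return self.replace(log2_effect_size=0.0, surv_link_proteins=(),
                            **kwargs)


@dataclass
class SimTruth:
    """Ground truth of one simulated study."""

    differential_proteins: dict[str, float]  # accession -> ln group effect,
    #                                          positive = up in pCR
    housekeeping_proteins: list[str]
    hazard_coefficients: dict[str, dict[str, float]]  # accession -> endpoint
    sample_bias: pd.Series  # per-sample ln multiplicative bias
    surv_covariates: pd.DataFrame  # standardized log abundances of linked prots
    true_log_abundance: pd.DataFrame  # samples x proteins, pre-masking
    event_counts: dict[str, int]
    seed: int


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of `total` proportional to `weights`."""
    ideal = weights / weights.sum() * total
    base = np.floor(ideal).astype(int)
    short = total - base.sum()
    order = np.argsort(-(ideal - base))
    base[order[:short]] += 1
    return base


def _event_probability(lam: float, sigma_eta: float,
                       window: tuple[float, float]) -> float:
    """P(exponential PH event before uniform censoring), eta ~ N(0, sigma^2)."""
    z, w = np.polynomial.hermite_e.hermegauss(41)
    rates = lam * np.exp(sigma_eta * z)
    c0, c1 = window
    with np.errstate(over="ignore"):
        surv = (np.exp(-rates * c0) - np.exp(-rates * c1)) / (rates * (c1 - c0))
    p = 1.0 - surv
    return float(np.sum(w * p) / np.sum(w))


def _calibrate_rate(target_event_frac: float, sigma_eta: float,
                    window: tuple[float, float]) -> float:
    if target_event_frac <= 0:
        return 1e-12
    f = lambda loglam: (_event_probability(math.exp(loglam), sigma_eta, window)
                        - target_event_frac)
    return math.exp(brentq(f, -25, 10))


def simulate_study(spec: SimSpec) -> tuple[QuantMatrix, ClinicalTable, SimTruth]:
    """Draw one complete synthetic study from `spec` (seeded, reproducible)."""
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_samples, spec.n_proteins

    sample_ids = [f"S{i + 1:03d}" for i in range(n)]

    # --- protein identities ------------------------------------------------
    accessions = [f"SP{i + 1:04d}" for i in range(p)]
    hk_idx = np.arange(spec.n_housekeeping)
    diff_idx = np.arange(spec.n_housekeeping,
                         spec.n_housekeeping + spec.n_differential)
    genes = {}
    for j, i in enumerate(hk_idx):
        genes[accessions[i]] = f"HK{j + 1}"
    for j, i in enumerate(diff_idx):
        genes[accessions[i]] = f"DIF{j + 1}"
    for i in range(p):
        genes.setdefault(accessions[i], f"G{i + 1:04d}")

    # --- clinical table ----------------------------------------------------
    subtype_n = _largest_remainder(np.array(_SUBTYPE_WEIGHTS, float), n)
    subtypes = np.repeat(SUBTYPES, subtype_n)
    pcr_n = np.minimum(
        _largest_remainder(np.array(_PCR_WEIGHTS, float), spec.n_pcr), subtype_n)
    # if capping by group size left pCR cases unallocated, spill them over
    while pcr_n.sum() < spec.n_pcr:
        room = subtype_n - pcr_n
        pcr_n[np.argmax(room)] += 1
    pcr = np.zeros(n, dtype=int)
    start = 0
    for size, k in zip(subtype_n, pcr_n):
        block = start + rng.choice(size, size=k, replace=False)
        pcr[block] = 1
        start += size
    perm = rng.permutation(n)
    subtypes, pcr = subtypes[perm], pcr[perm]

    hr = np.isin(subtypes, ["HR+/HER2-", "HR+/HER2+"]).astype(int)
    her2 = np.isin(subtypes, ["HR+/HER2+", "HER2+"]).astype(int)
    age = np.clip(rng.normal(46, 9, size=n), 25, 75).round(1)
    tumor_gt5 = rng.binomial(1, 0.35, size=n)
    node_pos = rng.binomial(1, 0.75, size=n)
    grade3 = rng.binomial(1, [_GRADE3_PROB[s] for s in subtypes])

    # --- abundances ----------------------------------------------------
    mu, tau = spec.protein_mean_log_abundance, spec.protein_log_sd
    baseline = rng.normal(mu, tau, size=p)
    # planted proteins sit comfortably above the presence-filter boundary
    baseline[hk_idx] = mu + 2.0 * tau + rng.normal(0, 0.1, size=len(hk_idx))
    baseline[diff_idx] = mu + 0.8 * tau + rng.normal(0, 0.1, size=len(diff_idx))

    eff = spec.log2_effect_size * math.log(2.0)
    delta = np.zeros(p)  # positive = up in pCR
    for j, i in enumerate(diff_idx):
        delta[i] = eff if j == 0 else -eff  # one up in pCR, rest up in non-pCR

    bias = rng.normal(0, spec.sample_scale_sd, size=n)
    noise_sd = np.full(p, spec.noise_log_sd)
    noise_sd[hk_idx] = spec.hk_noise_log_sd
    eps = rng.normal(0, 1, size=(n, p)) * noise_sd[None, :]

    log_x = baseline[None, :] + np.outer(pcr, delta) + bias[:, None] + eps
    true_log = pd.DataFrame(log_x, index=sample_ids, columns=accessions)

    # --- MNAR missingness ----------------------------------------------
    z = (log_x - mu) / tau
    p_miss = expit(spec.miss_intercept + spec.miss_slope * z)
    missing = rng.random(size=(n, p)) < p_miss
    values = np.exp(log_x)
    values[missing] = np.nan
    qm = QuantMatrix(values=pd.DataFrame(values, index=sample_ids,
                                         columns=accessions),
                     gene_symbols=genes, scale_tag="raw")

    # --- survival --------------------------------------------------------
    link_acc: dict[str, dict[str, float]] = {}
    eta = {ep: np.zeros(n) for ep in ("DFS", "OS", "DMFS")}
    cov_cols = {}
    for idx, b_dfs, b_os, b_dmfs in spec.surv_link_proteins:
        acc = accessions[diff_idx[idx]] if len(diff_idx) else accessions[idx]
        col = log_x[:, list(accessions).index(acc)]
        zcol = (col - col.mean()) / col.std(ddof=0)
        cov_cols[acc] = zcol
        link_acc[acc] = {"DFS": b_dfs, "OS": b_os, "DMFS": b_dmfs}
        eta["DFS"] += b_dfs * zcol
        eta["OS"] += b_os * zcol
        eta["DMFS"] += b_dmfs * zcol

    sig_dmfs = math.sqrt(sum(b[3] ** 2 for b in spec.surv_link_proteins)) \
        if spec.surv_link_proteins else 0.0
    target = 1.0 - spec.censor_rate
    lam_m = _calibrate_rate(target, sig_dmfs, spec.followup_months)
    lam_l = lam_m / 2.0  # extra local recurrences on top of metastases
    lam_g = 1.0 / 12.0   # mean 12 months from metastasis to death

    M = rng.exponential(1.0, size=n) / (lam_m * np.exp(eta["DMFS"]))
    L = rng.exponential(1.0, size=n) / (lam_l * np.exp(eta["DFS"]))
    G = rng.exponential(1.0, size=n) / (lam_g * np.exp(eta["OS"]))
    D = M + G
    C = rng.uniform(*spec.followup_months, size=n)
    R = np.minimum(M, L)

    def _observe(t):
        e = (t <= C).astype(int)
        return np.maximum(np.minimum(t, C).round(2), 0.01), e

    dfs_t, dfs_e = _observe(R)
    dmfs_t, dmfs_e = _observe(M)
    os_t, os_e = _observe(D)

    ct = ClinicalTable(pd.DataFrame({
        "sample_id": sample_ids,
        "pcr": pcr, "hr_status": hr, "her2_status": her2,
        "age_years": age, "tumor_size_gt5cm": tumor_gt5,
        "node_positive": node_pos, "grade3": grade3,
        "dfs_months": dfs_t, "dfs_event": dfs_e,
        "os_months": os_t, "os_event": os_e,
        "dmfs_months": dmfs_t, "dmfs_event": dmfs_e,
    }))

    truth = SimTruth(
        differential_proteins={accessions[i]: delta[i] for i in diff_idx},
        housekeeping_proteins=[accessions[i] for i in hk_idx],
        hazard_coefficients=link_acc,
        sample_bias=pd.Series(bias, index=sample_ids),
        surv_covariates=pd.DataFrame(cov_cols, index=sample_ids),
        true_log_abundance=true_log,
        event_counts={"DFS": int(dfs_e.sum()), "OS": int(os_e.sum()),
                      "DMFS": int(dmfs_e.sum())},
        seed=spec.seed,
    )
    return qm, ct, truth


def mask_entries(qm: QuantMatrix, fraction: float, seed: int
                 ) -> tuple[QuantMatrix, pd.DataFrame]:
    """Hide a fraction of currently observed cells, keeping their true values.

    Returns the masked matrix and a hidden-truth table with columns
    ``sample_id, protein_id, value`` for recovery scoring.  One observed
    cell per protein is reserved so no protein ever goes fully missing;
    if the requested fraction makes that impossible an error is raised.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must lie in [0, 1)")
    if fraction == 0:
        return qm.copy(), pd.DataFrame(columns=["sample_id", "protein_id",
                                                "value"])
    rng = np.random.default_rng(seed)
    arr = qm.values.to_numpy().copy()
    obs_r, obs_c = np.nonzero(~np.isnan(arr))
    n_hide = int(round(fraction * len(obs_r)))
    # reserve one observed cell per (partly observed) protein so masking
    # never turns a protein fully missing
    reserved = np.zeros(len(obs_r), dtype=bool)
    for c in range(arr.shape[1]):
        cells = np.nonzero(obs_c == c)[0]
        if len(cells):
            reserved[rng.choice(cells)] = True
    if n_hide > (~reserved).sum():
        raise ValueError("masking would leave some protein fully missing")
    eligible = np.nonzero(~reserved)[0]
    pick = rng.choice(eligible, size=n_hide, replace=False)
    rows = [(qm.sample_ids[r], qm.protein_ids[c], arr[r, c])
            for r, c in zip(obs_r[pick], obs_c[pick])]
    arr[obs_r[pick], obs_c[pick]] = np.nan
    out = qm.with_values(pd.DataFrame(arr, index=qm.values.index,
                                      columns=qm.values.columns))
    return out, pd.DataFrame(rows, columns=["sample_id", "protein_id", "value"])
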