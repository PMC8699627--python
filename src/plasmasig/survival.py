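"""Survival stratification: endpoint construction, Kaplan-Meier curves,
log-rank testing, maximally selected rank statistics cutpoints, a
proteome-wide marker screen, and multivariate Cox regression.

Endpoints follow the usual oncology definitions: DFS is time to any
recurrence, DMFS time to distant metastasis, OS time to death from any
cause.  A marker is dichotomized at the cutpoint maximizing the absolute
standardized two-group log-rank statistic over all splits that leave at
least a minimal proportion of samples in each group; the multiplicity of
that search is accounted for by an improved-Bonferroni approximation of
the maximally-selected-statistic null distribution (with an exact
permutation option).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .clinical import ClinicalTable, ENDPOINTS
from .matrix import QuantMatrix

__all__ = ["SurvivalEndpoint", "build_endpoints", "km_estimate",
           "logrank_test", "maxstat_cutpoint", "MaxstatResult",
           "marker_screen", "cox_fit", "CoxFit"]


@dataclass
class SurvivalEndpoint:
    """One time-to-event endpoint over the cohort."""

    name: str
    time: pd.Series   # months, indexed by sample id
    event: pd.Series  # 1 = event observed, 0 = censored

    def __post_init__(self) -> None:
        if self.name not in ENDPOINTS:
            raise ValueError(f"unknown endpoint {self.name!r}")
        if not self.time.index.equals(self.event.index):
            raise ValueError("time and event indices differ")
        if self.time.isna().any() or (self.time <= 0).any():
            raise ValueError("all times must be positive and present")
        if not self.event.isin([0, 1]).all():
            raise ValueError("event flags must be 0/1")

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, ids) -> "SurvivalEndpoint":
        return SurvivalEndpoint(self.name, self.time.loc[ids],
                                self.event.loc[ids])


def build_endpoints(ct: ClinicalTable) -> dict[str, SurvivalEndpoint]:
    """Extract the DFS/OS/DMFS endpoints from a validated clinical table."""
    df = ct.data.set_index("sample_id")
    out = {}
    for ep in ENDPOINTS:
        lo = ep.lower()
        out[ep] = SurvivalEndpoint(ep, df[f"{lo}_months"].astype(float),
                                   df[f"{lo}_event"].astype(int))
    return out


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

def km_estimate(ep: SurvivalEndpoint, group=None
                ) -> tuple[dict[str, pd.DataFrame], float]:
    """Product-limit survival curves per group + reverse-KM median follow-up.

    Returns ({group label: DataFrame(time, survival)}, median_followup).
    """
    if group is None:
        group = pd.Series("all", index=ep.time.index)
    else:
        group = pd.Series(np.asarray(group), index=ep.time.index)
    curves = {}
    for lv in group.unique():
        m = (group == lv).to_numpy()
        if m.sum() == 0:
            raise ValueError(f"empty group {lv!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(ep.time[m], ep.event[m])
        sf = kmf.survival_function_
        curves[lv] = pd.DataFrame({"time": sf.index.to_numpy(),
                                   "survival": sf.iloc[:, 0].to_numpy()})
    rkm = KaplanMeierFitter()
    rkm.fit(ep.time, 1 - ep.event)  # censoring as the event
    return curves, float(rkm.median_survival_time_)


def logrank_test(ep: SurvivalEndpoint, group) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p)."""
    g = np.asarray(group)
    levels = np.unique(g)
    if len(levels) != 2:
        raise ValueError("group must be binary")
    if ep.n_events == 0:
        raise ValueError("no events: log-rank test undefined")
    m = g == levels[0]
    res = _ll_logrank(ep.time[m], ep.time[~m], ep.event[m], ep.event[~m])
    return float(res.test_statistic), float(res.p_value)


def _logrank_z(time: np.ndarray, event: np.ndarray,
               in_group1: np.ndarray) -> float:
    """Standardized log-rank statistic (O1 - E1)/sqrt(V) by risk-set sums."""
    order = np.argsort(time, kind="stable")
    t, e, g = time[order], event[order], in_group1[order]
    n = len(t)
    num = 0.0
    var = 0.0
    i = 0
    at_risk = n
    at_risk1 = int(g.sum())
    while i < n:
        j = i
        d = d1 = r_leave = r1_leave = 0
        while j < n and t[j] == t[i]:
            if e[j]:
                d += 1
                d1 += int(g[j])
            r_leave += 1
            r1_leave += int(g[j])
            j += 1
        if d > 0 and at_risk > 1:
            frac = at_risk1 / at_risk
            num += d1 - d * frac
            var += d * frac * (1 - frac) * (at_risk - d) / (at_risk - 1)
        at_risk -= r_leave
        at_risk1 -= r1_leave
        i = j
    if var <= 0:
        return 0.0
    return num / np.sqrt(var)


@dataclass
class MaxstatResult:
    """Outcome of a maximally-selected-rank-statistics cutpoint search."""

    marker_id: str
    cutpoints: np.ndarray        # candidate cut values (split at value <= cut)
    statistics: np.ndarray       # standardized log-rank z per candidate
    cutpoint: float              # optimal (ties -> smallest)
    statistic: float             # max |z|
    p_adjusted: float            # improved-Bonferroni approximation
    p_logrank: float             # raw log-rank p at the optimal split
    n_low: int
    n_high: int


def _maxstat_p(b: float, min_prop: float) -> float:
    """Improved-Bonferroni bound for sup |standardized Brownian bridge| over
    [eps, 1-eps] exceeding b (Miller-Siegmund / Lausen-Schumacher)."""
    if b <= 0:
        return 1.0
    eps = min_prop
    band = 2.0 * np.log((1 - eps) / eps)
    phi = stats.norm.pdf(b)
    p = 4 * phi / b + phi * (b - 1 / b) * band
    return float(min(max(p, 0.0), 1.0))


def maxstat_cutpoint(marker, ep: SurvivalEndpoint,
                     min_prop: float = 0.20, marker_id: str = "marker",
                     n_perm: int = 0, seed: int = 0) -> MaxstatResult:
    """Optimal survival cutpoint by maximally selected rank statistics.

    Candidates are the observed marker values whose split (low = value <=
    cut) leaves at least `min_prop` of samples in each group.  The optimal
    cutpoint maximizes |standardized log-rank statistic|, ties resolved
    toward the smaller cutpoint.  `n_perm > 0` replaces the approximate
    adjusted p with an exact permutation p of the maximal statistic.
    """
    x = np.asarray(marker, float)
    time = np.asarray(ep.time, float)
    event = np.asarray(ep.event, int)
    n = len(x)
    if ep.n_events == 0:
        raise ValueError("no events: cutpoint search undefined")
    lo = int(np.ceil(min_prop * n))
    order = np.sort(x)
    cand = np.unique(order[lo - 1:n - lo])  # value<=cut keeps >=lo low, >=lo high
    cand = np.array([c for c in cand
                     if lo <= (x <= c).sum() <= n - lo])
    if len(cand) == 0:
        raise ValueError(f"marker {marker_id!r}: no feasible cutpoint "
                         f"respecting min_prop={min_prop}")

    def _max_z(xv):
        zs = np.array([_logrank_z(time, event, xv <= c) for c in cand])
        k = int(np.argmax(np.abs(zs)))  # argmax takes first = smallest cut
        return zs, k

    zs, k = _max_z(x)
    b = float(np.abs(zs[k]))
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_perm):
            zp, kp = _max_z(rng.permutation(x))
            if np.abs(zp[kp]) >= b:
                exceed += 1
        p_adj = (1 + exceed) / (n_perm + 1)
    else:
        p_adj = _maxstat_p(b, min_prop)
    p_raw = float(stats.chi2.sf(b ** 2, df=1))
    low = int((x <= cand[k]).sum())
    return MaxstatResult(marker_id=marker_id, cutpoints=cand, statistics=zs,
                         cutpoint=float(cand[k]), statistic=b,
                         p_adjusted=p_adj, p_logrank=p_raw,
                         n_low=low, n_high=n - low)


def marker_screen(qm: QuantMatrix, endpoints: dict[str, SurvivalEndpoint],
                  min_prop: float = 0.20, alpha: float = 0.05
                  ) -> pd.DataFrame:
    """Cutpoint + log-rank screen of every protein against every endpoint.

    ``significant`` flags the raw log-rank p at the optimal cutpoint (the
    discovery convention); ``significant_adjusted`` flags the
    multiplicity-adjusted p, which is the calibrated quantity.  BH q-values
    over the raw p are reported per endpoint.  Per-protein failures (e.g. a
    constant marker) are logged as rows with NaN statistics, not fatal.
    """
    rows = []
    for ep_name, ep in endpoints.items():
        x_all = qm.values.loc[ep.time.index]
        for pid in qm.protein_ids:
            try:
                res = maxstat_cutpoint(x_all[pid].to_numpy(), ep,
                                       min_prop=min_prop, marker_id=pid)
                rows.append((ep_name, pid, res.cutpoint, res.statistic,
                             res.p_logrank, res.p_adjusted,
                             res.n_low, res.n_high, ""))
            except ValueError as exc:
                rows.append((ep_name, pid, np.nan, np.nan, np.nan, np.nan,
                             0, 0, str(exc)))
    out = pd.DataFrame(rows, columns=[
        "endpoint", "protein_id", "cutpoint", "statistic", "p_logrank",
        "p_adjusted", "n_low", "n_high", "note"])
    out["q_logrank"] = np.nan
    for ep_name in endpoints:
        m = (out["endpoint"] == ep_name) & out["p_logrank"].notna()
        if m.any():
            from statsmodels.stats.multitest import multipletests
            out.loc[m, "q_logrank"] = multipletests(
                out.loc[m, "p_logrank"], method="fdr_bh")[1]
    out["significant"] = out["p_logrank"] < alpha
    out["significant_adjusted"] = out["p_adjusted"] < alpha
    return out


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    """Multivariate Cox fit with separation diagnostics."""

    summary: pd.DataFrame          # covariate, coef, hr, ci, p, separation
    log_likelihood: float
    converged: bool
    separation: dict[str, bool]

    def hazard_ratio(self, covariate: str) -> float:
        return float(self.summary.set_index("covariate").loc[covariate, "hr"])


def _separation_flags(design: pd.DataFrame, event: pd.Series) -> dict[str, bool]:
    """A binary covariate level with zero events yields monotone likelihood."""
    flags = {}
    ev = event.to_numpy().astype(bool)
    for col in design.columns:
        x = design[col].to_numpy()
        lv = np.unique(x)
        flags[col] = bool(len(lv) == 2 and any(
            ev[x == v].sum() == 0 for v in lv))
    return flags


def cox_fit(ep: SurvivalEndpoint, design: pd.DataFrame) -> CoxFit:
    """Cox proportional-hazards regression (Efron ties) with Wald CIs.

    Covariates exhibiting monotone likelihood (a level with no events) are
    flagged as separated and reported unstable rather than as a finite
    hazard ratio.
    """
    if ep.n_events == 0:
        raise ValueError("no events: Cox model undefined")
    design = design.loc[ep.time.index]
    dup = design.T.duplicated()
    if dup.any():
        raise ValueError("collinear duplicate covariate columns: "
                         f"{list(design.columns[dup])}")
    sep = _separation_flags(design, ep.event)
    df = design.copy()
    df["_time"] = ep.time
    df["_event"] = ep.event
    cph = CoxPHFitter()
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(df, duration_col="_time", event_col="_event")
        except ConvergenceError as exc:
            if not any(sep.values()):
                raise RuntimeError(
                    f"Cox fit failed to converge: {exc}") from exc
            cph = CoxPHFitter(penalizer=1e-6)
            try:
                cph.fit(df, duration_col="_time", event_col="_event")
            except ConvergenceError:
                cph.fit(df, duration_col="_time", event_col="_event",
                        fit_options={"step_size": 0.1})
            converged = False
    s = cph.summary
    rows = []
    with np.errstate(over="ignore"):  # exp() of a diverging separated coef
        for cov in design.columns:
            r = s.loc[cov]
            unstable = sep[cov] or abs(r["coef"]) > 15
            rows.append({
                "covariate": cov,
                "coef": r["coef"],
                "hr": np.exp(r["coef"]),
                "ci_low": np.exp(r["coef lower 95%"]),
                "ci_high": np.exp(r["coef upper 95%"]),
                "p": r["p"],
                "separation": sep[cov],
                "stable": not unstable,
            })
    return CoxFit(summary=pd.DataFrame(rows),
                  log_likelihood=float(cph.log_likelihood_),
                  converged=converged, separation=sep)
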