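"""Clinical table: phenotype, subtype, covariates, and survival endpoints.

One row per sample.  The pathological-complete-response flag (pCR) is the
binary outcome of neoadjuvant chemotherapy; subtype is derived from the
hormone-receptor and HER2 flags; DFS/OS/DMFS are (months, event) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ClinicalTable", "read_clinical_table", "write_clinical_table",
           "summarize_clinical", "derive_subtype", "SUBTYPES", "ENDPOINTS"]

SUBTYPES = ("HR+/HER2-", "HR+/HER2+", "HER2+", "TN")
ENDPOINTS = ("DFS", "OS", "DMFS")

REQUIRED_COLUMNS = (
    "sample_id", "pcr", "hr_status", "her2_status", "age_years",
    "tumor_size_gt5cm", "node_positive", "grade3",
    "dfs_months", "dfs_event", "os_months", "os_event",
    "dmfs_months", "dmfs_event",
)


def derive_subtype(hr: int, her2: int) -> str:
    """Four-level breast-cancer subtype from the HR / HER2 flags."""
    if hr not in (0, 1) or her2 not in (0, 1):
        raise ValueError(f"hr/her2 flags must be 0/1, got ({hr}, {her2})")
    if hr == 1:
        return "HR+/HER2+" if her2 == 1 else "HR+/HER2-"
    return "HER2+" if her2 == 1 else "TN"


@dataclass
class ClinicalTable:
    """Validated per-sample clinical data backed by a DataFrame."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"clinical table missing columns: {missing}")
        if df["sample_id"].duplicated().any():
            dups = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"])
            raise ValueError(f"duplicate sample IDs: {dups}")
        for col in ("pcr", "hr_status", "her2_status", "tumor_size_gt5cm",
                    "node_positive", "grade3"):
            if not df[col].isin([0, 1]).all():
                raise ValueError(f"column {col!r} must be binary 0/1")
        if (df["age_years"] <= 0).any():
            raise ValueError("age_years must be positive")
        for ep in ENDPOINTS:
            lo = ep.lower()
            t, e = df[f"{lo}_months"], df[f"{lo}_event"]
            if not e.isin([0, 1]).all():
                raise ValueError(f"{ep} event flag must be binary")
            bad = t.isna() & (e == 1)
            if bad.any():
                raise ValueError(
                    f"{ep}: event recorded without a time for samples "
                    f"{sorted(df.loc[bad, 'sample_id'])}")
            if (t.dropna() <= 0).any():
                raise ValueError(f"{ep} times must be positive")
        # a distant metastasis is also a recurrence: DMFS event implies DFS event
        if ((df["dmfs_event"] == 1) & (df["dfs_event"] == 0)).any():
            raise ValueError("DMFS event without a DFS event is incoherent")
        if "subtype" not in df.columns:
            df = df.copy()
            df["subtype"] = [derive_subtype(h, r) for h, r in
                             zip(df["hr_status"], df["her2_status"])]
        else:
            expect = [derive_subtype(h, r) for h, r in
                      zip(df["hr_status"], df["her2_status"])]
            bad = df["subtype"].to_numpy() != np.asarray(expect)
            if bad.any():
                raise ValueError(
                    "subtype labels inconsistent with hr/her2 flags for samples "
                    f"{sorted(df.loc[bad, 'sample_id'])}")
        if "age_gt40" not in df.columns:
            df = df if df is not self.data else df.copy()
            df["age_gt40"] = (df["age_years"] > 40).astype(int)
        self.data = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def pcr(self) -> pd.Series:
        return self.data.set_index("sample_id")["pcr"]

    @property
    def subtype(self) -> pd.Series:
        return self.data.set_index("sample_id")["subtype"]

    def subset(self, sample_ids: list[str]) -> "ClinicalTable":
        df = self.data.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return replace(self, data=df)


def read_clinical_table(path: str | Path) -> ClinicalTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return ClinicalTable(pd.read_csv(path))


def write_clinical_table(ct: ClinicalTable, path: str | Path) -> None:
    ct.data.to_csv(path, index=False)


def summarize_clinical(ct: ClinicalTable) -> pd.DataFrame:
    """Per-subtype sample counts and pCR rates, with an overall row.

    Rates are plain event counts over group sizes, reported both as
    fractions and percentages.
    """
    if ct.n_samples == 0:
        raise ValueError("empty clinical table")
    rows = []
    df = ct.data
    for subtype in SUBTYPES:
        sub = df[df["subtype"] == subtype]
        if len(sub) == 0:
            continue
        rows.append((subtype, len(sub), int(sub["pcr"].sum())))
    rows.append(("overall", len(df), int(df["pcr"].sum())))
    out = pd.DataFrame(rows, columns=["group", "n", "n_pcr"])
    out["pcr_rate"] = out["n_pcr"] / out["n"]
    out["pcr_pct"] = 100.0 * out["pcr_rate"]
    return out
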