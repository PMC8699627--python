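"""Protein quantification matrix container and delimited-text IO.

The central object of the pipeline is a samples x proteins abundance table
with an explicit observed/missing mask.  Files on disk follow the vendor
convention of proteins in rows (first column = UniProt accession, optional
second column = gene symbol, remaining columns = samples); in memory the
orientation is samples x proteins.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["QuantMatrix", "read_quant_matrix", "write_quant_matrix"]

#: allowed quantification-scale states, in pipeline order
SCALE_TAGS = ("raw", "imputed", "normalized")

_GENE_COL = "gene_symbol"


@dataclass
class QuantMatrix:
    """Samples x proteins abundance matrix with missing cells stored as NaN.

    Parameters
    ----------
    values
        DataFrame indexed by sample id with protein accessions as columns.
        Missing (unquantified) cells are NaN; observed cells are finite and
        nonnegative.
    gene_symbols
        Optional accession -> gene symbol map.
    scale_tag
        One of ``raw``, ``imputed``, ``normalized``; may only advance in
        that order.
    norm_protein_ids
        Accessions of the endogenous normalization proteins, flagged once
        normalization has run (they are carried through unscaled).
    """

    values: pd.DataFrame
    gene_symbols: dict[str, str] | None = None
    scale_tag: str = "raw"
    norm_protein_ids: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.scale_tag not in SCALE_TAGS:
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")
        self.values = self.values.astype(float)
        _check_unique("sample", self.values.index)
        _check_unique("protein", self.values.columns)
        arr = self.values.to_numpy()
        observed = ~np.isnan(arr)
        if np.any(~np.isfinite(arr[observed])):
            raise ValueError("observed abundances must be finite")
        if np.any(arr[observed] < 0):
            raise ValueError("observed abundances must be nonnegative")
        if self.scale_tag == "normalized" and not observed.all():
            raise ValueError("a normalized matrix may not contain missing cells")

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_proteins(self) -> int:
        return self.values.shape[1]

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean DataFrame, True where the cell is observed."""
        return self.values.notna()

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def presence_fraction(self) -> pd.Series:
        """Per-protein fraction of samples in which it was quantified."""
        return self.mask.mean(axis=0)

    def gene_symbol(self, accession: str) -> str | None:
        if self.gene_symbols is None:
            return None
        return self.gene_symbols.get(accession)

    # -- transformations -------------------------------------------------
    def with_values(self, values: pd.DataFrame, scale_tag: str | None = None,
                    **kwargs) -> "QuantMatrix":
        """Return a copy with new values, enforcing scale-tag ordering."""
        tag = self.scale_tag if scale_tag is None else scale_tag
        if SCALE_TAGS.index(tag) < SCALE_TAGS.index(self.scale_tag):
            raise ValueError(
                f"scale_tag may not move backwards ({self.scale_tag} -> {tag})")
        return replace(self, values=values, scale_tag=tag, **kwargs)

    def subset_proteins(self, keep: list[str]) -> "QuantMatrix":
        missing = set(keep) - set(self.values.columns)
        if missing:
            raise KeyError(f"proteins not in matrix: {sorted(missing)}")
        return replace(self, values=self.values.loc[:, list(keep)])

    def subset_samples(self, keep: list[str]) -> "QuantMatrix":
        return replace(self, values=self.values.loc[list(keep)])

    def copy(self) -> "QuantMatrix":
        return replace(self, values=self.values.copy())


def _check_unique(what: str, index: pd.Index) -> None:
    if index.has_duplicates:
        dups = sorted(index[index.duplicated()].unique())
        raise ValueError(f"duplicate {what} IDs: {dups}")


def _infer_sep(path: str | Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if str(path).endswith(".csv") else "\t"


def read_quant_matrix(path: str | Path, sep: str | None = None,
                      zero_as_missing: bool = True,
                      gene_column: bool = True) -> QuantMatrix:
    """Read a proteins-in-rows quantification table.

    Empty cells and ``NA`` are treated as missing; zeros too by default,
    because a zero intensity in a label-free export means "not quantified"
    rather than a measured abundance.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_infer_sep(path, sep), na_values=["NA", ""],
                     index_col=0)
    symbols = None
    if gene_column and len(df.columns) and df.columns[0] == _GENE_COL:
        symbols = df[_GENE_COL].astype(str).to_dict()
        df = df.drop(columns=[_GENE_COL])
    df = df.astype(float)
    if zero_as_missing:
        df = df.where(df != 0.0)
    values = df.T
    values.index.name = None
    values.columns.name = None
    return QuantMatrix(values=values, gene_symbols=symbols)


def write_quant_matrix(qm: QuantMatrix, path: str | Path,
                       sep: str | None = None) -> None:
    """Write proteins-in-rows; missing cells become empty fields."""
    path = Path(path)
    out = qm.values.T
    if qm.gene_symbols is not None:
        out = out.copy()
        out.insert(0, _GENE_COL, [qm.gene_symbols.get(p, "") for p in out.index])
    out.index.name = "accession"
    out.to_csv(path, sep=_infer_sep(path, sep), na_rep="")
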