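"""Run configuration shared across pipeline stages."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    """Tunable parameters of the pipeline, one field per knob.

    Defaults reproduce the discovery workflow: presence filtering at 80%,
    four endogenous normalization proteins, differential selection at
    p < 0.05 and |fold-change| > 2, VIP > 1.5, AUC-based random-forest
    backward elimination with 10,000 trees, probability of selection over
    50 iterations of three-fold cross-validation, 100 random trisections
    for classifier evaluation, and maximally selected rank statistics with
    a 20% minimal group proportion.
    """

    seed: int = 0
    presence_threshold: float = 0.80
    n_norm_proteins: int = 4
    lls_k: int = 10
    dap_p_cut: float = 0.05
    dap_fc_cut: float = 2.0
    vip_cut: float = 1.5
    plsda_ncomp: int = 2
    rf_ntree: int = 10_000
    rf_nodesize: int = 5
    cv_folds: int = 3
    cv_repeats: int = 3
    probsel_iterations: int = 50
    probsel_threshold: float = 0.5
    eval_splits: int = 100
    maxstat_min_prop: float = 0.20
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.presence_threshold <= 1:
            raise ValueError("presence_threshold must lie in (0, 1]")
        if not 0 < self.maxstat_min_prop < 0.5:
            raise ValueError("maxstat_min_prop must lie in (0, 0.5)")
        for name in ("n_norm_proteins", "lls_k", "plsda_ncomp", "rf_ntree",
                     "rf_nodesize", "cv_folds", "cv_repeats",
                     "probsel_iterations", "eval_splits"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("dap_p_cut", "alpha", "probsel_threshold"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.dap_fc_cut < 1:
            raise ValueError("dap_fc_cut must be >= 1")

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> RunConfig:
    """Read a key: value config file (YAML-compatible)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
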