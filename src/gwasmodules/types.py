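"""Core record types shared across the pipeline.

All genomic coordinates held in these records are 1-based and inclusive;
BED input/output converts at the file boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional

import numpy as np


@dataclass(frozen=True)
class SnpAssoc:
    """One SNP's association summary in one cohort.

    ``beta`` is the per-allele effect of ``effect_allele`` on the phenotype,
    ``se`` its standard error and ``pvalue`` the two-sided association p-value.
    ``eaf`` (effect-allele frequency) may be missing (``None``).
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: Optional[float] = None

    def validate(self) -> Optional[str]:
        """Return a reason string if an invariant is violated, else None."""
        if not (self.se > 0 and np.isfinite(self.se)):
            return f"se must be positive and finite, got {self.se}"
        if not (0 < self.pvalue <= 1):
            return f"pvalue must lie in (0, 1], got {self.pvalue}"
        if self.effect_allele == self.other_allele:
            return f"effect and other allele are identical ({self.effect_allele})"
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            return f"eaf must lie in [0, 1], got {self.eaf}"
        if self.pos < 1:
            return f"pos must be a positive 1-based coordinate, got {self.pos}"
        return None


@dataclass(frozen=True)
class GeneModel:
    """A gene's transcribed span. ``tx_start``/``tx_end`` are 1-based inclusive."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int

    def __post_init__(self) -> None:
        if self.tx_start > self.tx_end:
            raise ValueError(
                f"{self.gene_id}: tx_start ({self.tx_start}) > tx_end ({self.tx_end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class ExpressionSummary:
    """A gene's 25th-percentile RPKM across samples — the tissue-expression gate."""

    gene_id: str
    rpkm_q25: float

    def __post_init__(self) -> None:
        if self.rpkm_q25 < 0:
            raise ValueError(f"{self.gene_id}: rpkm_q25 must be non-negative")


@dataclass(frozen=True)
class GeneScore:
    """A gene's significance score: minimum mapped SNP p-value and its normal quantile.

    ``z_i = Phi^-1(1 - p_i)`` after clamping ``p_i`` away from {0, 1}.
    """

    gene_id: str
    p_i: float
    best_snp: str
    z_i: float


@dataclass(frozen=True)
class ScoredModule:
    """A connected node set with its raw aggregate score and calibrated score.

    ``z_A = sum(z_i) / sqrt(k)`` over the ``k`` member genes;
    ``s_A = (z_A - mu_k) / sigma_k`` against the Monte-Carlo size calibration.
    """

    nodes: frozenset
    k: int
    z_A: float
    s_A: float


@dataclass
class CalibrationTable:
    """Per-size Monte-Carlo moments of the aggregate score over random gene sets.

    ``mu[k-1]``/``sigma[k-1]`` are the mean and SD of ``z_A`` over ``n_samples``
    uniform k-subsets of the scored node set, for k = 1..max_k.
    """

    mu: np.ndarray
    sigma: np.ndarray
    n_samples: int

    @property
    def max_k(self) -> int:
        return len(self.mu)

    def mu_k(self, k: int) -> float:
        return float(self.mu[k - 1])

    def sigma_k(self, k: int) -> float:
        return float(self.sigma[k - 1])


@dataclass
class ConsensusNetwork:
    """Genes recurring across the top second-order modules, with driving SNPs."""

    genes: set
    driving_snps: dict
    edges: set
    occurrence: dict


@dataclass(frozen=True)
class EmpiricalTestResult:
    """An observed statistic against a resampled null.

    ``empirical_p`` uses the (r+1)/(N+1) estimator so it can never be zero.
    """

    observed: float
    null_draws: int
    n_ge: int
    empirical_p: float
    null_mean: float = float("nan")
    null_sd: float = float("nan")


@dataclass(frozen=True)
class MetaResult:
    """Inverse-variance fixed-effect meta-analysis result for one SNP."""

    snp_id: str
    beta_meta: float
    se_meta: float
    p_meta: float
    lambda_by_study: dict
    lambda_meta: float


@dataclass(frozen=True)
class PrsResult:
    """Summary-statistic polygenic-score association estimate."""

    alpha_hat: float
    se_alpha: float
    p: float
    n_snps: int


@dataclass
class SimulationTruth:
    """Ground truth of a synthetic two-cohort study with a planted module."""

    planted_genes: set
    causal_snps: dict
    true_effect: float
    n_discovery: int
    n_validation: int


@dataclass
class RunConfig:
    """All tunable pipeline parameters, with the study defaults.

    The gene window (110 kb upstream / 40 kb downstream of the transcribed
    span) reflects the span covering the bulk of cis-eQTLs; ``n_calibration``
    and ``n_empirical`` default to 100,000 Monte-Carlo draws.
    """

    window_up: int = 110_000
    window_down: int = 40_000
    rpkm_threshold: float = 1.0
    n_seeds: int = 100
    n_calibration: int = 100_000
    n_score_permutations: int = 10
    n_second_order_modules: int = 15
    min_occurrence: int = 2
    snp_selection_p: float = 5e-4
    n_empirical: int = 100_000
    ld_r2_prune: float = 0.8
    ld_r2_proxy: float = 0.8
    rng_seed: int = 0
    max_module_size: int = 300
    p_clamp_eps: float = 1e-12

    def __post_init__(self) -> None:
        for name in (
            "window_up", "window_down", "n_seeds", "n_calibration",
            "n_score_permutations", "n_second_order_modules", "min_occurrence",
            "n_empirical", "max_module_size",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0 < self.snp_selection_p <= 1):
            raise ValueError("snp_selection_p must lie in (0, 1]")
        for name in ("ld_r2_prune", "ld_r2_proxy"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not (0 < self.p_clamp_eps < 0.5):
            raise ValueError("p_clamp_eps must lie in (0, 0.5)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}
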