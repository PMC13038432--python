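"""Core record types shared across the MR prioritization pipeline.

The unit of work for two-sample MR is a harmonized :class:`InstrumentSet`:
per-SNP exposure (gene expression) and outcome (disease risk) effects that
refer to the same effect allele. Per-gene results are carried as
:class:`GeneMRRecord` (transcriptome-wide MR) and :class:`SMRRecord`
(summary-data-based MR with the top cis-eQTL as sole instrument).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

_VALID_BASES = frozenset("ACGT")

#: allele pairs that read the same on both DNA strands
PALINDROMIC_PAIRS = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})


@dataclass(frozen=True)
class VariantRecord:
    """One SNP row of a GWAS/eQTL summary-statistics table."""

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: Optional[float] = None
    n: Optional[float] = None

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if not (0.0 < self.pval <= 1.0):
            raise ValueError(f"{self.snp_id}: pval must be in (0, 1], got {self.pval}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele are identical")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise ValueError(f"{self.snp_id}: eaf must be in [0, 1], got {self.eaf}")

    @property
    def has_valid_alleles(self) -> bool:
        return (
            self.effect_allele in _VALID_BASES and self.other_allele in _VALID_BASES
        )

    @property
    def is_palindromic(self) -> bool:
        return (self.effect_allele, self.other_allele) in PALINDROMIC_PAIRS


@dataclass
class InstrumentSet:
    """Harmonized instruments for one gene.

    Parallel arrays ordered by ascending ``snp_id``; exposure and outcome
    effects refer to the exposure's effect allele.
    """

    gene: str
    snp_ids: list[str]
    beta_exp: list[float]
    se_exp: list[float]
    beta_out: list[float]
    se_out: list[float]
    pval_exp: list[float] = field(default_factory=list)
    f_stats: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.snp_ids)
        for name in ("beta_exp", "se_exp", "beta_out", "se_out"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != {n}")
        if len(set(self.snp_ids)) != n:
            raise ValueError("duplicate snp_id in instrument set")
        if not self.f_stats:
            self.f_stats = [(b / s) ** 2 for b, s in zip(self.beta_exp, self.se_exp)]

    def __len__(self) -> int:
        return len(self.snp_ids)


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate from one MR estimator."""

    method: str
    beta: float
    se: float
    pval: float

    @property
    def or_(self) -> float:
        """Odds ratio, exp(beta)."""
        return math.exp(self.beta)

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2.0)
        return self.beta - z * self.se, self.beta + z * self.se


@dataclass(frozen=True)
class GeneMRRecord:
    """Per-gene, per-cohort transcriptome-wide MR metrics."""

    gene: str
    cohort: str
    or_: float
    pval: float
    pleiotropy_pval: float
    heterogeneity_pval: float

    def __post_init__(self) -> None:
        if self.or_ <= 0:
            raise ValueError(f"{self.gene}: odds ratio must be > 0")
        for name in ("pval", "pleiotropy_pval", "heterogeneity_pval"):
            p = getattr(self, name)
            if not (0.0 < p <= 1.0):
                raise ValueError(f"{self.gene}: {name}={p} outside (0, 1]")


@dataclass(frozen=True)
class SMRRecord:
    """Per-gene, per-cohort summary-data MR metrics (top cis-eQTL instrument)."""

    gene: str
    cohort: str
    top_snp: str
    b_smr: float
    p_smr: float
    p_heidi: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.p_smr <= 1.0):
            raise ValueError(f"{self.gene}: p_smr outside (0, 1]")
        if self.p_heidi is not None and not (0.0 < self.p_heidi <= 1.0):
            raise ValueError(f"{self.gene}: p_heidi outside (0, 1]")


@dataclass
class CandidateGene:
    """A gene carried through the two-stage + intersection prioritization."""

    gene: str
    tmr_records: list[GeneMRRecord]
    smr_records: list[SMRRecord]
    retained: bool = False
    direction: Optional[str] = None  # risk_increasing | protective | discordant
    reason: str = ""
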