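"""Summary-data-based MR (SMR) and the HEIDI linkage test.

SMR uses the single top cis-eQTL as instrument: b_SMR = beta_GWAS/beta_eQTL,
tested with T_SMR = z1^2 z2^2 / (z1^2 + z2^2) against chi-square(1). HEIDI
(heterogeneity in dependent instruments) asks whether the SMR effects at
flanking cis-SNPs are consistent with a single shared causal variant: under
sharing, every SNP in LD with the causal variant yields the same b_SMR, so
the deviations d_i = b_SMR(i) - b_SMR(top) are jointly zero up to correlated
sampling noise. A small HEIDI p indicates two distinct variants in linkage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class SMRResult:
    b_smr: float
    t_smr: float
    p_smr: float


def smr_test(
    beta_eqtl: float, se_eqtl: float, beta_gwas: float, se_gwas: float
) -> SMRResult:
    """Top-SNP SMR effect and chi-square(1) p-value."""
    if beta_eqtl == 0:
        raise ZeroDivisionError("SMR effect undefined: eQTL beta is 0")
    if se_eqtl <= 0 or se_gwas <= 0:
        raise ValueError("standard errors must be > 0")
    z1 = beta_eqtl / se_eqtl
    z2 = beta_gwas / se_gwas
    t = (z1**2 * z2**2) / (z1**2 + z2**2)
    return SMRResult(
        b_smr=beta_gwas / beta_eqtl, t_smr=float(t), p_smr=float(stats.chi2.sf(t, 1))
    )


class InsufficientHeidiSnpsError(ValueError):
    """Fewer than the minimum flanking SNPs pass the eligibility filter."""


def heidi_test(
    cis: list[tuple[float, float, float, float]],
    ld: np.ndarray,
    top_index: int,
    max_snps: int = 20,
    eqtl_p_max: float = 1.57e-3,
    r2_min: float = 0.05,
    r2_max: float = 0.9,
    min_snps: int = 3,
) -> float:
    """HEIDI p-value for one cis locus.

    Parameters
    ----------
    cis
        Per-SNP tuples ``(beta_eqtl, se_eqtl, beta_gwas, se_gwas)``.
    ld
        Square matrix of LD correlations r (signed) covering all cis SNPs.
    top_index
        Index of the top cis-eQTL (the SMR instrument) in ``cis``.

    Flanking SNPs are eligible when their eQTL p < ``eqtl_p_max`` and their
    r^2 with the top SNP lies in [``r2_min``, ``r2_max``]; at most
    ``max_snps`` are used, by ascending eQTL p. The statistic is the sum of
    squared standardized deviations d_i = b_SMR(i) - b_SMR(top); its null is
    a sum of correlated chi-squares, approximated Satterthwaite-style by a
    scaled chi-square matched on mean and variance.

    Raises :class:`InsufficientHeidiSnpsError` when fewer than ``min_snps``
    flanking SNPs are eligible; callers may fall back to a supplied p_HEIDI.
    """
    ld = np.asarray(ld, float)
    m_all = len(cis)
    if ld.shape != (m_all, m_all):
        raise ValueError("LD matrix does not cover all cis SNPs")

    bx = np.array([c[0] for c in cis])
    sx = np.array([c[1] for c in cis])
    bz = np.array([c[2] for c in cis])
    sz = np.array([c[3] for c in cis])
    if bx[top_index] == 0:
        raise ZeroDivisionError("top SNP has zero eQTL effect")
    p_eqtl = 2.0 * stats.norm.sf(np.abs(bx / sx))

    eligible = []
    for i in range(m_all):
        if i == top_index:
            continue
        r2 = ld[i, top_index] ** 2
        if p_eqtl[i] < eqtl_p_max and r2_min <= r2 <= r2_max and bx[i] != 0:
            eligible.append(i)
    if len(eligible) < min_snps:
        raise InsufficientHeidiSnpsError(
            f"{len(eligible)} eligible flanking SNPs (< {min_snps})"
        )
    eligible = sorted(eligible, key=lambda i: p_eqtl[i])[:max_snps]

    idx = np.array([top_index] + eligible)
    b = bz[idx] / bx[idx]
    # delta-method variance of each b_SMR and covariance between SNPs; the
    # eQTL and GWAS samples are independent, so the two terms add.
    var_b = sz[idx] ** 2 / bx[idx] ** 2 + bz[idx] ** 2 * sx[idx] ** 2 / bx[idx] ** 4
    r_sub = ld[np.ix_(idx, idx)]
    denom = np.outer(bx[idx], bx[idx])
    cov_b = (
        r_sub * np.outer(sz[idx], sz[idx]) / denom
        + np.outer(b, b) * r_sub * np.outer(sx[idx], sx[idx]) / denom
    )
    np.fill_diagonal(cov_b, var_b)

    d = b[1:] - b[0]
    m = d.size
    cov_d = (
        cov_b[1:, 1:]
        - cov_b[1:, [0]]
        - cov_b[[0], 1:]
        + cov_b[0, 0]
    )
    sd = np.sqrt(np.diag(cov_d))
    z = d / sd
    corr_d = cov_d / np.outer(sd, sd)
    t_heidi = float(np.sum(z**2))

    # Satterthwaite: match the scaled chi-square g*chi2(h) on mean/variance
    mean_t = float(m)
    var_t = 2.0 * float(np.sum(corr_d**2))
    g = var_t / (2.0 * mean_t)
    h = 2.0 * mean_t**2 / var_t
    return float(stats.chi2.sf(t_heidi / g, h))


def smr_record_for_locus(
    gene: str,
    cohort: str,
    snp_ids: list[str],
    cis: list[tuple[float, float, float, float]],
    ld: np.ndarray,
    top_p_max: float = 1e-5,
    supplied_p_heidi: Optional[float] = None,
):
    """Full SMR screen for one gene/cohort: pick the top cis-eQTL, test, HEIDI.

    The top SNP is the smallest eQTL p-value; it must pass ``top_p_max``.
    Returns ``None`` when no SNP qualifies as instrument. When HEIDI has too
    few eligible flanking SNPs, ``supplied_p_heidi`` (possibly None) is used.
    """
    from .types import SMRRecord

    bx = np.array([c[0] for c in cis])
    sx = np.array([c[1] for c in cis])
    p_eqtl = 2.0 * stats.norm.sf(np.abs(bx / sx))
    top = int(np.argmin(p_eqtl))
    if p_eqtl[top] >= top_p_max:
        return None
    res = smr_test(*cis[top])
    try:
        p_heidi: Optional[float] = heidi_test(cis, ld, top)
    except InsufficientHeidiSnpsError:
        p_heidi = supplied_p_heidi
    return SMRRecord(
        gene=gene,
        cohort=cohort,
        top_snp=snp_ids[top],
        b_smr=res.b_smr,
        p_smr=res.p_smr,
        p_heidi=p_heidi,
    )
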