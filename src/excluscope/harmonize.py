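"""Allele harmonization, instrument-strength filtering and LD clumping.

Two-sample MR requires the exposure and outcome effect sizes to refer to the
same effect allele. Harmonization re-signs outcome effects where the allele
coding is flipped, drops variants whose alleles cannot be reconciled, and
drops strand-ambiguous (palindromic) variants whose allele frequency cannot
resolve the strand.
"""

from __future__ import annotations

import logging

import numpy as np

from .types import InstrumentSet, VariantRecord

logger = logging.getLogger(__name__)


class NoSharedInstrumentsError(ValueError):
    """Exposure and outcome tables share no SNPs."""


class NoValidInstrumentsError(ValueError):
    """Every instrument was removed by quality filters; skip the gene."""


def harmonize(
    exposure: list[VariantRecord],
    outcome: list[VariantRecord],
    palindrome_eaf_window: float = 0.08,
    gene: str = "",
) -> InstrumentSet:
    """Align outcome effects to the exposure's effect allele.

    For each SNP present in both tables the outcome beta is kept as-is when
    the allele coding matches, negated when effect/other are swapped, and the
    SNP is dropped when the alleles cannot be reconciled. Palindromic SNPs
    (A/T or C/G) are dropped when the exposure EAF is missing or within
    ``palindrome_eaf_window`` of 0.5, since strand cannot be resolved.
    Output order is ascending ``snp_id``.
    """
    exp_by_id = {r.snp_id: r for r in exposure}
    out_by_id = {r.snp_id: r for r in outcome}
    shared = sorted(set(exp_by_id) & set(out_by_id))
    if not shared:
        raise NoSharedInstrumentsError("no shared instruments")

    snp_ids: list[str] = []
    beta_exp: list[float] = []
    se_exp: list[float] = []
    beta_out: list[float] = []
    se_out: list[float] = []
    pval_exp: list[float] = []

    for snp in shared:
        e, o = exp_by_id[snp], out_by_id[snp]
        if not (e.has_valid_alleles and o.has_valid_alleles):
            logger.info("%s: dropped (invalid alleles)", snp)
            continue
        if e.is_palindromic:
            if e.eaf is None or abs(e.eaf - 0.5) < palindrome_eaf_window:
                logger.info("%s: dropped (palindromic, ambiguous EAF)", snp)
                continue
        if (o.effect_allele, o.other_allele) == (e.effect_allele, e.other_allele):
            b_out = o.beta
        elif (o.effect_allele, o.other_allele) == (e.other_allele, e.effect_allele):
            b_out = -o.beta
        else:
            logger.info("%s: dropped (allele mismatch %s/%s vs %s/%s)", snp,
                        e.effect_allele, e.other_allele,
                        o.effect_allele, o.other_allele)
            continue
        snp_ids.append(snp)
        beta_exp.append(e.beta)
        se_exp.append(e.se)
        beta_out.append(b_out)
        se_out.append(o.se)
        pval_exp.append(e.pval)

    return InstrumentSet(
        gene=gene,
        snp_ids=snp_ids,
        beta_exp=beta_exp,
        se_exp=se_exp,
        beta_out=beta_out,
        se_out=se_out,
        pval_exp=pval_exp,
    )


def filter_instruments(
    iset: InstrumentSet, p_max: float = 5e-8, f_min: float = 10.0
) -> InstrumentSet:
    """Keep genome-wide-significant, strong instruments.

    Retains SNPs with exposure p < ``p_max`` and per-SNP F-statistic
    ``(beta_exp/se_exp)^2`` >= ``f_min`` (weak instruments excluded).
    Raises :class:`NoValidInstrumentsError` if nothing survives.
    """
    keep = []
    for i in range(len(iset)):
        f = (iset.beta_exp[i] / iset.se_exp[i]) ** 2
        p = iset.pval_exp[i] if iset.pval_exp else 0.0
        if p < p_max and f >= f_min:
            keep.append((i, f))
    if not keep:
        raise NoValidInstrumentsError(f"no valid instruments for {iset.gene!r}")
    idx = [i for i, _ in keep]
    return InstrumentSet(
        gene=iset.gene,
        snp_ids=[iset.snp_ids[i] for i in idx],
        beta_exp=[iset.beta_exp[i] for i in idx],
        se_exp=[iset.se_exp[i] for i in idx],
        beta_out=[iset.beta_out[i] for i in idx],
        se_out=[iset.se_out[i] for i in idx],
        pval_exp=[iset.pval_exp[i] for i in idx] if iset.pval_exp else [],
        f_stats=[f for _, f in keep],
    )


def ld_clump(
    records: list[VariantRecord],
    ld: "np.ndarray | dict",
    ld_snp_ids: list[str] | None = None,
    r2_max: float = 0.001,
) -> list[VariantRecord]:
    """Greedy LD clumping to approximately independent instruments.

    SNPs are visited by ascending p-value (ties broken by snp_id); a SNP is
    kept iff its squared correlation with every already-kept SNP is below
    ``r2_max``. ``ld`` is a square r^2 matrix whose rows/columns follow
    ``ld_snp_ids`` (or a dict keyed by frozenset pairs).

    Raises ``KeyError`` naming the pair when an LD entry is missing.
    """
    if isinstance(ld, dict):
        def r2(a: str, b: str) -> float:
            if a == b:
                return 1.0
            key = frozenset((a, b))
            if key not in ld:
                raise KeyError(f"missing LD entry for pair ({a}, {b})")
            return ld[key]
    else:
        ld = np.asarray(ld, dtype=float)
        if ld_snp_ids is None:
            raise ValueError("ld_snp_ids required with a matrix LD input")
        pos = {s: i for i, s in enumerate(ld_snp_ids)}
        def r2(a: str, b: str) -> float:
            if a not in pos or b not in pos:
                missing = a if a not in pos else b
                raise KeyError(f"missing LD entry for pair ({a}, {b}): {missing}")
            return float(ld[pos[a], pos[b]])

    order = sorted(records, key=lambda r: (r.pval, r.snp_id))
    kept: list[VariantRecord] = []
    for rec in order:
        if all(r2(rec.snp_id, k.snp_id) < r2_max for k in kept):
            kept.append(rec)
    return kept
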