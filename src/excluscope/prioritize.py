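"""Two-stage MR retention, SMR intersection and risk-direction classification.

The prioritization mirrors a discovery/replication design: a gene passes the
transcriptome-wide MR (TMR) stage when its IVW association is nominally
significant in the discovery cohort with no evidence of directional
pleiotropy (Egger intercept p above threshold), replicates at nominal
significance, and keeps the same effect direction in both cohorts. The
surviving genes are intersected with a tissue-specific SMR screen
(p_SMR below and p_HEIDI above threshold), and each retained candidate is
classified as risk-increasing, protective, or discordant from the signs of
its TMR odds ratios and SMR effects.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable

from .types import CandidateGene, GeneMRRecord, SMRRecord

logger = logging.getLogger(__name__)


def two_stage_filter(
    discovery: list[GeneMRRecord],
    replication: list[GeneMRRecord],
    p_thresh: float = 0.05,
    pleio_thresh: float = 0.05,
    require_het: bool = False,
    het_thresh: float = 0.05,
) -> set[str]:
    """Genes retained by the discovery + replication TMR stages.

    A gene is retained iff discovery IVW p < ``p_thresh``, discovery
    pleiotropy (Egger intercept) p > ``pleio_thresh``, replication IVW
    p < ``p_thresh``, and sign(log OR) agrees across cohorts. Heterogeneity
    p is reported but only filtered on when ``require_het`` is set.
    """
    repl_by_gene = {r.gene: r for r in replication}
    retained: set[str] = set()
    for d in discovery:
        r = repl_by_gene.get(d.gene)
        if r is None:
            logger.info("%s: missing in replication cohort, excluded", d.gene)
            continue
        if d.pval >= p_thresh or r.pval >= p_thresh:
            continue
        if d.pleiotropy_pval <= pleio_thresh:
            continue
        if require_het and (
            d.heterogeneity_pval <= het_thresh or r.heterogeneity_pval <= het_thresh
        ):
            continue
        sign_d = math.copysign(1.0, math.log(d.or_)) if d.or_ != 1.0 else 0.0
        sign_r = math.copysign(1.0, math.log(r.or_)) if r.or_ != 1.0 else 0.0
        if sign_d == 0.0 or sign_d != sign_r:
            continue
        retained.add(d.gene)
    return retained


def classify_direction(c: CandidateGene) -> str:
    """Risk direction from the signs of TMR ORs and SMR effects.

    ``risk_increasing`` iff OR > 1 in both TMR cohorts and b_SMR > 0 in both
    SMR cohorts; ``protective`` iff OR < 1 and b_SMR < 0 throughout;
    anything else (including boundary values OR = 1, b_SMR = 0) is
    ``discordant``.
    """
    if len(c.tmr_records) < 2 or len(c.smr_records) < 2:
        raise ValueError(f"{c.gene}: direction needs 2 TMR and 2 SMR records")
    ors = [t.or_ for t in c.tmr_records]
    bs = [s.b_smr for s in c.smr_records]
    if all(o > 1 for o in ors) and all(b > 0 for b in bs):
        return "risk_increasing"
    if all(o < 1 for o in ors) and all(b < 0 for b in bs):
        return "protective"
    return "discordant"


def _smr_pass(s: SMRRecord, p_smr_thresh: float, p_heidi_thresh: float) -> bool:
    return (
        s.p_smr < p_smr_thresh
        and s.p_heidi is not None
        and s.p_heidi > p_heidi_thresh
    )


def prioritize_candidates(
    tmr_supported: set[str],
    smr: Iterable[SMRRecord],
    tmr: Iterable[GeneMRRecord] = (),
    p_smr_thresh: float = 0.05,
    p_heidi_thresh: float = 0.05,
    smr_cohort_rule: str = "any",
) -> list[CandidateGene]:
    """Intersect TMR-supported genes with the SMR/HEIDI screen.

    A gene is retained iff it is TMR-supported and its SMR records satisfy
    p_SMR < ``p_smr_thresh`` and p_HEIDI > ``p_heidi_thresh`` in at least one
    cohort (``smr_cohort_rule='any'``, the default) or in every cohort
    (``'all'``). Retained genes carry a :func:`classify_direction` label when
    both TMR and both SMR records are available.
    """
    if smr_cohort_rule not in ("any", "all"):
        raise ValueError(f"smr_cohort_rule must be 'any' or 'all', got {smr_cohort_rule!r}")
    smr_by_gene: dict[str, list[SMRRecord]] = {}
    for s in smr:
        smr_by_gene.setdefault(s.gene, []).append(s)
    tmr_by_gene: dict[str, list[GeneMRRecord]] = {}
    for t in tmr:
        tmr_by_gene.setdefault(t.gene, []).append(t)

    rule = any if smr_cohort_rule == "any" else all
    out: list[CandidateGene] = []
    for gene in sorted(set(smr_by_gene) | set(tmr_by_gene) | tmr_supported):
        recs = smr_by_gene.get(gene, [])
        cand = CandidateGene(
            gene=gene, tmr_records=tmr_by_gene.get(gene, []), smr_records=recs
        )
        if gene not in tmr_supported:
            cand.reason = "not TMR-supported"
        elif not recs:
            cand.reason = "no SMR records"
        elif not rule(_smr_pass(s, p_smr_thresh, p_heidi_thresh) for s in recs):
            cand.reason = f"SMR criterion failed ({smr_cohort_rule} cohorts)"
        else:
            cand.retained = True
            cand.reason = "TMR-supported and SMR-consistent"
        if len(cand.tmr_records) >= 2 and len(cand.smr_records) >= 2:
            cand.direction = classify_direction(cand)
        out.append(cand)
    return out
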