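"""Expression stratification and nonparametric group comparisons.

Links the single-cell and bulk layers of the study design: cells are called
marker-positive on detectable expression (raw count > 0, robust under
dropout-heavy sparse counts); marker genes between the resulting
subpopulations come from a Wilcoxon rank-sum screen on library-size
normalized counts with an absolute log2 fold-change floor and BH FDR; bulk
cohorts are median-dichotomized on the marker gene and immune factors are
compared between the halves with Mann-Whitney U.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_IMMUNE_PANEL = ("CXCL14", "TNFSF13B", "TNFSF18")


@dataclass
class CellMatrix:
    """Sparse gene x cell raw count matrix with name vectors."""

    genes: list[str]
    cells: list[str]
    counts: sparse.spmatrix
    cell_labels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = sparse.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"counts shape {self.counts.shape} != "
                f"({len(self.genes)}, {len(self.cells)})"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None


@dataclass
class BulkCohort:
    """Gene x sample expression on the log2 scale with sample group masks."""

    expression: pd.DataFrame  # genes as index, samples as columns
    groups: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return list(self.expression.columns)


def classify_marker_positive(m: CellMatrix, gene: str) -> np.ndarray:
    """Boolean per-cell mask: positive iff the gene's raw count is > 0."""
    row = m.counts[m.gene_index(gene)]
    mask = np.zeros(len(m.cells), bool)
    mask[row.indices[row.data > 0]] = True
    return mask


def _counts_per_10k(counts: sparse.spmatrix) -> sparse.csr_matrix:
    totals = np.asarray(counts.sum(axis=0)).ravel()
    totals[totals == 0] = 1.0
    return sparse.csr_matrix(counts.multiply(1e4 / totals))


def find_markers(
    m: CellMatrix,
    partition: np.ndarray,
    lfc_min: float = 0.5,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Screen for genes differing between the positive and negative groups.

    Per gene, on counts-per-10k normalized values:
    log2fc = log2((mean_pos + 1)/(mean_neg + 1)); two-sided Wilcoxon
    rank-sum p; BH FDR over all tested genes. Reported rows satisfy
    |log2fc| >= ``lfc_min`` and fdr < ``fdr_max``.
    """
    partition = np.asarray(partition, bool)
    n_pos, n_neg = int(partition.sum()), int((~partition).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both groups must be non-empty")
    norm = _counts_per_10k(m.counts).toarray()
    pos, neg = norm[:, partition], norm[:, ~partition]
    mean_pos, mean_neg = pos.mean(axis=1), neg.mean(axis=1)
    log2fc = np.log2((mean_pos + 1.0) / (mean_neg + 1.0))

    pvals = np.ones(len(m.genes))
    for g in range(len(m.genes)):
        if np.all(pos[g] == pos[g, 0]) and np.all(neg[g] == neg[g, 0]) and pos[g, 0] == neg[g, 0]:
            continue  # constant gene: no evidence, p stays 1
        pvals[g] = stats.mannwhitneyu(pos[g], neg[g], alternative="two-sided").pvalue
    fdr = multipletests(pvals, method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "gene": m.genes,
            "log2fc": log2fc,
            "pval": pvals,
            "fdr": fdr,
            "mean_pos": mean_pos,
            "mean_neg": mean_neg,
        }
    )
    out = table[(table.log2fc.abs() >= lfc_min) & (table.fdr < fdr_max)]
    return out.sort_values("fdr").reset_index(drop=True)


def median_dichotomize(values: "pd.Series | np.ndarray") -> np.ndarray:
    """High/low split at the empirical median; ties at the median go low.

    Returns a boolean mask, True = high (value strictly above the median).
    """
    arr = np.asarray(values, float)
    if arr.size < 2:
        raise ValueError("median dichotomization needs >= 2 samples")
    return arr > np.median(arr)


def compare_groups(
    values: np.ndarray, partition: np.ndarray, exact_max_n: int = 8
) -> tuple[float, float, tuple[float, float]]:
    """Two-sided Mann-Whitney U between the two halves of a partition.

    Uses exact enumeration when both groups have at most ``exact_max_n``
    observations and no ties straddle the groups; otherwise the normal
    approximation with tie correction. Returns (U, p, (median_hi, median_lo)).
    """
    values = np.asarray(values, float)
    partition = np.asarray(partition, bool)
    a, b = values[partition], values[~partition]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    use_exact = a.size <= exact_max_n and b.size <= exact_max_n
    method = "exact" if use_exact else "asymptotic"
    try:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    except ValueError:
        # exact method rejects ties; fall back to the tie-corrected normal
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue), (float(np.median(a)), float(np.median(b)))


def spearman_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with t-approximation p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("spearman needs two equal-length vectors of size >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("spearman undefined for a constant input")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def immune_factor_panel(
    cohort: BulkCohort,
    marker_gene: str,
    panel: tuple[str, ...] = DEFAULT_IMMUNE_PANEL,
) -> pd.DataFrame:
    """Compare immune-factor expression between marker-high and -low samples.

    Samples are median-dichotomized on ``marker_gene``; each panel gene is
    compared between the halves with Mann-Whitney U, with BH correction
    across the panel. ``direction`` is median(high) - median(low), so a
    negative value means the factor is depressed in marker-high samples.
    """
    expr = cohort.expression
    if marker_gene not in expr.index:
        raise KeyError(f"marker gene {marker_gene!r} not in cohort")
    high = median_dichotomize(expr.loc[marker_gene].to_numpy())

    rows = []
    for gene in panel:
        if gene not in expr.index:
            warnings.warn(f"panel gene {gene!r} missing, skipped", stacklevel=2)
            continue
        vals = expr.loc[gene].to_numpy()
        if np.all(vals == vals[0]):
            warnings.warn(f"panel gene {gene!r} constant, skipped", stacklevel=2)
            continue
        u, p, (med_hi, med_lo) = compare_groups(vals, high)
        rows.append(
            {"gene": gene, "u": u, "pval": p,
             "median_high": med_hi, "median_low": med_lo,
             "direction": med_hi - med_lo}
        )
    table = pd.DataFrame(rows, columns=["gene", "u", "pval", "median_high",
                                        "median_low", "direction"])
    if len(table):
        table["fdr"] = multipletests(table.pval.to_numpy(), method="fdr_bh")[1]
    else:
        table["fdr"] = []
    return table
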