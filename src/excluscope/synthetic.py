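"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its spec (seed included): the same spec
always produces identical output. The generators emulate the statistical
structure each analysis stage assumes — instrument-grade eQTL effects with an
optional directional-pleiotropy shift, cis loci with AR(1)-style LD and one
or two causal variants, spot lattices with planted null/exclusion/
co-localization immune patterns, sparse negative-binomial counts with a
marker-positive subpopulation, and bulk cohorts with group shifts on named
genes — without attempting genome-wide LD, real capture chemistry, or a
realistic transcriptome-wide covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .spatial import SpotGrid
from .strata import BulkCohort, CellMatrix
from .types import VariantRecord

_NONPALINDROMIC = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


def _pval_from_z(z: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(z))
    return np.clip(p, 1e-300, 1.0)


@dataclass(frozen=True)
class MRSimSpec:
    """Conditions for a two-sample MR instrument simulation."""

    n_snps: int = 50
    true_beta: float = 0.1
    pleiotropy_delta: float = 0.0
    se_exp: float = 0.01
    se_out: float = 0.01
    maf_range: tuple[float, float] = (0.1, 0.5)
    frac_palindromic: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.se_exp <= 0 or self.se_out <= 0:
            raise ValueError("noise scales must be > 0")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not (0.0 <= self.frac_palindromic <= 1.0):
            raise ValueError("frac_palindromic must be in [0, 1]")


def simulate_mr_dataset(
    spec: MRSimSpec,
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Exposure and outcome summary statistics for one gene.

    True exposure effects are strong (|beta| in [0.15, 0.5] against
    ``se_exp``, i.e. instrument-grade z-scores) and coded on the
    expression-increasing allele, so directional pleiotropy keeps a
    consistent orientation. Outcome effects follow
    ``true_beta * beta_exp + pleiotropy_delta`` plus noise.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_snps
    bx_true = rng.uniform(0.15, 0.5, n)
    bz_true = spec.true_beta * bx_true + spec.pleiotropy_delta
    bx_obs = bx_true + spec.se_exp * rng.standard_normal(n)
    bz_obs = bz_true + spec.se_out * rng.standard_normal(n)
    eaf = rng.uniform(*spec.maf_range, n)
    is_pal = rng.random(n) < spec.frac_palindromic
    pair_idx = rng.integers(0, 4, n)

    exposure, outcome = [], []
    for j in range(n):
        pool = _PALINDROMIC if is_pal[j] else _NONPALINDROMIC
        ea, oa = pool[pair_idx[j]]
        snp = f"rs{j + 1:05d}"
        exposure.append(
            VariantRecord(
                snp_id=snp, effect_allele=ea, other_allele=oa,
                beta=float(bx_obs[j]), se=spec.se_exp,
                pval=float(_pval_from_z(np.array([bx_obs[j] / spec.se_exp]))[0]),
                eaf=float(eaf[j]),
            )
        )
        outcome.append(
            VariantRecord(
                snp_id=snp, effect_allele=ea, other_allele=oa,
                beta=float(bz_obs[j]), se=spec.se_out,
                pval=float(_pval_from_z(np.array([bz_obs[j] / spec.se_out]))[0]),
                eaf=float(eaf[j]),
            )
        )
    return exposure, outcome


def simulate_smr_locus(
    n_snps: int = 30,
    ld_decay: float = 0.9,
    true_shared: bool = True,
    seed: int = 0,
    bx_causal: float = 0.3,
    se_eqtl: float = 0.02,
    se_gwas: float = 0.01,
    shared_effect: float = 0.2,
    distinct_effect: float = 0.15,
) -> tuple[list[str], list[tuple[float, float, float, float]], np.ndarray]:
    """One cis locus: per-SNP summary stats plus the LD correlation matrix.

    LD is AR(1)-style, r_ij = ld_decay^|i-j|. Under ``true_shared`` a single
    causal variant drives both the eQTL and the GWAS signal, so every SNP's
    SMR effect is the same up to noise (HEIDI-consistent). Otherwise the
    GWAS signal comes from a second causal variant elsewhere in the locus
    (HEIDI-inconsistent). Summary-statistic noise is drawn jointly with the
    LD correlation, as for estimates from one sample.

    Returns ``(snp_ids, cis_tuples, ld)`` with cis tuples
    ``(beta_eqtl, se_eqtl, beta_gwas, se_gwas)``.
    """
    if n_snps < 5:
        raise ValueError("n_snps must be >= 5")
    if not (0.0 < ld_decay < 1.0):
        raise ValueError("ld_decay must be in (0, 1)")
    rng = np.random.default_rng(seed)
    idx = np.arange(n_snps)
    ld = ld_decay ** np.abs(idx[:, None] - idx[None, :])
    chol = np.linalg.cholesky(ld + 1e-10 * np.eye(n_snps))

    c_eqtl = n_snps // 4
    bx_true = bx_causal * ld[:, c_eqtl]
    if true_shared:
        bz_true = shared_effect * bx_true
    else:
        c_gwas = min(n_snps - 3, c_eqtl + n_snps // 2)
        bz_true = distinct_effect * ld[:, c_gwas]
    bx_obs = bx_true + se_eqtl * (chol @ rng.standard_normal(n_snps))
    bz_obs = bz_true + se_gwas * (chol @ rng.standard_normal(n_snps))

    snp_ids = [f"rs{j + 1:05d}" for j in range(n_snps)]
    cis = [
        (float(bx_obs[j]), se_eqtl, float(bz_obs[j]), se_gwas)
        for j in range(n_snps)
    ]
    return snp_ids, cis, ld


@dataclass(frozen=True)
class SpatialSimSpec:
    """Conditions for a planted spatial immune pattern on a square lattice."""

    n_side: int = 16
    pattern: str = "null"  # null | exclusion | colocalized
    effect: float = 0.0
    tumor_fraction: float = 0.25
    immune_baseline: float = 1.0
    noise_sd: float = 0.5
    marker_high_value: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_side < 4:
            raise ValueError("n_side must be >= 4")
        if self.pattern not in ("null", "exclusion", "colocalized"):
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")
        if self.pattern == "null" and self.effect != 0:
            raise ValueError("effect must be 0 under the null pattern")
        if not (0.0 < self.tumor_fraction < 1.0):
            raise ValueError("tumor_fraction must be in (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


def simulate_spot_grid(spec: SpatialSimSpec) -> SpotGrid:
    """Square spot lattice with a contiguous tumor patch.

    The patch is the square block nearest the origin whose area is closest
    to ``tumor_fraction`` of the section; spots inside it get a high marker
    score. The immune score is baseline plus i.i.d. noise everywhere, and is
    additionally lowered (exclusion) or raised (colocalized) by ``effect``
    inside the patch; under the null the immune score has no spatial
    structure, so values are exchangeable across spots by construction.
    """
    rng = np.random.default_rng(spec.seed)
    n_side = spec.n_side
    xs, ys = np.meshgrid(np.arange(n_side), np.arange(n_side), indexing="ij")
    coords = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    n = coords.shape[0]

    patch_side = max(2, int(round(n_side * np.sqrt(spec.tumor_fraction))))
    in_patch = (coords[:, 0] < patch_side) & (coords[:, 1] < patch_side)

    marker = rng.normal(0.0, spec.noise_sd, n)
    marker[in_patch] += spec.marker_high_value
    immune = spec.immune_baseline + rng.normal(0.0, spec.noise_sd, n)
    if spec.pattern == "exclusion":
        immune[in_patch] -= spec.effect
    elif spec.pattern == "colocalized":
        immune[in_patch] += spec.effect

    return SpotGrid(
        spot_ids=[f"spot_{i:04d}" for i in range(n)],
        coords=coords,
        signals={"marker_score": marker, "immune_score": immune},
        labels={"tumor_patch": in_patch},
    )


def simulate_counts(
    n_genes: int = 50,
    n_cells: int = 400,
    marker_gene: str = "PGAP3",
    frac_positive: float = 0.5,
    de_genes: dict[str, float] | None = None,
    seed: int = 0,
    mean_range: tuple[float, float] = (1.0, 8.0),
    dispersion: float = 0.5,
    de_mean: float = 1.0,
    marker_mean: float = 2.0,
) -> tuple[CellMatrix, np.ndarray]:
    """Sparse negative-binomial counts with a marker-positive subpopulation.

    The marker gene is non-zero in exactly the planted positive cells and
    zero elsewhere. Genes named in ``de_genes`` have their mean multiplied
    by the given fold in positive cells. The marker and the planted DE genes
    sit at low baseline means (``marker_mean``, ``de_mean``) so that planting
    a fold-change leaves per-cell library size approximately unchanged, as
    in a full transcriptome where DE genes are a negligible mass fraction;
    otherwise library-size normalization would induce spurious fold-changes
    on every null gene. Returns the matrix and the planted positive mask
    (generator truth, for benchmarking the classifiers).
    """
    if not (0.0 < frac_positive < 1.0):
        raise ValueError("frac_positive must be in (0, 1)")
    de_genes = de_genes or {}
    rng = np.random.default_rng(seed)

    genes = [marker_gene] + [f"GENE{j:04d}" for j in range(1, n_genes)]
    unknown = set(de_genes) - set(genes)
    if unknown:
        raise ValueError(f"de_genes not in matrix: {sorted(unknown)}")
    n_pos = int(round(frac_positive * n_cells))
    positive = np.zeros(n_cells, bool)
    positive[rng.choice(n_cells, n_pos, replace=False)] = True

    base_mean = rng.uniform(*mean_range, n_genes)
    base_mean[0] = marker_mean
    for g, gene in enumerate(genes):
        if gene in de_genes:
            base_mean[g] = de_mean
    mat = np.empty((n_genes, n_cells))
    r = 1.0 / dispersion  # NB size parameter
    for g, gene in enumerate(genes):
        mu = np.full(n_cells, base_mean[g])
        if gene in de_genes:
            mu[positive] *= de_genes[gene]
        if gene == marker_gene:
            mu[~positive] = 0.0
        p = r / (r + np.maximum(mu, 1e-12))
        draw = rng.negative_binomial(r, p)
        draw[mu == 0.0] = 0
        if gene == marker_gene:
            draw[positive] = np.maximum(draw[positive], 1)  # detectable by design
        mat[g] = draw

    cm = CellMatrix(
        genes=genes,
        cells=[f"cell_{i:05d}" for i in range(n_cells)],
        counts=sparse.csr_matrix(mat),
        cell_labels={"planted_positive": positive},
    )
    return cm, positive


def simulate_bulk(
    n_samples: int = 100,
    marker_gene: str = "PGAP3",
    panel_effects: dict[str, float] | None = None,
    noise_sd: float = 0.5,
    seed: int = 0,
    n_background: int = 10,
    baseline: float = 5.0,
) -> BulkCohort:
    """Bulk cohort on the log2 scale with group shifts on named panel genes.

    The marker gene is drawn around ``baseline``; samples above its median
    form the marker-high group, in which each panel gene is shifted down by
    its effect size (a positive shift plants lower panel expression in
    marker-high samples, the immune-exclusion direction).
    """
    if n_samples < 4:
        raise ValueError("n_samples must be >= 4")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    panel_effects = panel_effects or {}
    rng = np.random.default_rng(seed)

    samples = [f"sample_{i:03d}" for i in range(n_samples)]
    marker = baseline + rng.normal(0.0, 1.0, n_samples)
    high = marker > np.median(marker)

    rows = {marker_gene: marker}
    for gene, shift in panel_effects.items():
        vals = baseline + rng.normal(0.0, noise_sd, n_samples)
        vals[high] -= shift
        rows[gene] = vals
    for j in range(n_background):
        rows[f"BG{j:03d}"] = baseline + rng.normal(0.0, noise_sd, n_samples)

    expr = pd.DataFrame(rows, index=samples).T
    return BulkCohort(expression=expr, groups={"marker_high": high})
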