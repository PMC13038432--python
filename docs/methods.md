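# Methods

This document records the statistical methods implemented in `excluscope`,
every tunable parameter with its default and rationale, the numerical
choices that affect reproducibility, and the known limitations.

## 1. Harmonization and instrument selection

Two-sample MR requires exposure (cis-eQTL) and outcome (GWAS) effects to be
coded on the same effect allele.

- **Allele flip**: when the outcome's effect/other alleles are swapped
  relative to the exposure, the outcome beta is negated; irreconcilable
  allele pairs are dropped with a logged reason.
- **Palindromic variants** (A/T, C/G) cannot be strand-resolved from
  alleles alone. They are dropped when the exposure effect-allele frequency
  is missing or within `palindrome_eaf_window = 0.08` of 0.5; outside that
  window the major/minor assignment resolves the strand. The 0.08 window is
  the conventional ambiguity band for palindromic filtering.
- **Instrument strength**: SNPs are retained when the exposure association
  reaches genome-wide significance (`p < 5e-8`) and the per-SNP
  F-statistic `(beta/se)² ≥ 10`, the standard weak-instrument cutoff.
- **LD clumping**: greedy selection by ascending p-value (ties broken by
  SNP id for determinism); a SNP is kept iff its r² with every kept SNP is
  below `r2_max = 0.001`, yielding approximately independent instruments.

Output order is ascending SNP id, so downstream estimates do not depend on
input file order.

## 2. MR estimators

All estimators consume a harmonized instrument set. The per-SNP Wald ratio
is `b_j = beta_out_j / beta_exp_j` with first-order delta SE
`se_out_j / |beta_exp_j|` (outcome uncertainty only — the standard
two-sample convention, conservative when instruments pass the F ≥ 10
filter).

- **IVW** (primary): fixed-effects meta-analysis of ratios with weights
  `w_j = beta_exp_j² / se_out_j²`; SE `(Σ w_j)^(-1/2)`; optional
  multiplicative random-effects inflation by `sqrt(Q/(n−1))` when the
  heterogeneity ratio exceeds 1. With a single instrument IVW reduces
  exactly to the Wald ratio.
- **MR-Egger**: exposure betas oriented non-negative (outcome re-signed
  with them), then weighted regression of outcome on exposure with an
  intercept, weights `1/se_out²`. The intercept estimates directional
  pleiotropy; its test is two-sided t with n−2 degrees of freedom. Needs
  ≥ 3 instruments.
- **Weighted median**: the ratio at interpolated cumulative weight 0.5;
  SE from a seeded parametric bootstrap (200 replicates redrawing each
  ratio from N(b_j, se_j)).
- **Simple/weighted mode**: mode of a Gaussian-kernel density of the
  ratios on a 512-point grid spanning the ratio range padded by three
  bandwidths; bandwidth 0.9·min(sd, IQR/1.349)·n^(−1/5) (modified
  Silverman rule). Diagnostic only; no p-value is attached.
- **Cochran's Q**: `Σ w_j (b_j − β̂_IVW)²` against χ²(n−1). Reported, and
  optionally (off by default) used as a retention filter.

## 3. SMR and HEIDI

At the top cis-eQTL (required eQTL `p < 1e-5`), the SMR effect is
`b_SMR = beta_gwas / beta_eqtl` and the test statistic
`T_SMR = z_x² z_y² / (z_x² + z_y²)` against χ²(1). T_SMR is symmetric in
the two z-scores and bounded by min(z_x², z_y²).

HEIDI asks whether flanking SNPs' SMR effects are consistent with a single
shared causal variant. For flanking SNP *i*, the deviation
`d_i = b_SMR(i) − b_SMR(top)` has a delta-method covariance built from the
LD correlation r between SNPs (eQTL and GWAS noise are independent across
studies, so their contributions add). Eligible flanking SNPs have eQTL
`p < 1.57e-3` (|z| > 3.16) and r² with the top SNP in [0.05, 0.9]; at most
20 are used (ascending eQTL p) and at least 3 are required, otherwise the
test is flagged as not computable (a caller-supplied p_HEIDI can then be
used). The sum of squared standardized deviations is referred to a
Satterthwaite-scaled chi-square matching its first two moments under the
null.

## 4. Prioritization

- **Two-stage retention**: discovery IVW p < 0.05 AND discovery Egger
  intercept p > 0.05 AND replication IVW p < 0.05 AND same sign of log OR
  in both cohorts. Heterogeneity p is reported but not filtered on unless
  `require_het` is set.
- **SMR intersection**: the gene must additionally satisfy p_SMR < 0.05
  and p_HEIDI > 0.05 in ≥ 1 SMR cohort (`smr_cohort_rule="any"`, default)
  or in all cohorts (`"all"`).
- **Direction**: `risk_increasing` iff OR > 1 in both TMR cohorts and
  b_SMR > 0 in both SMR cohorts; `protective` iff all reversed;
  anything else — including boundary values OR = 1 or b_SMR = 0 — is
  `discordant`.

On the bundled five-gene example this retains PGAP3 and VAMP3 as
risk-increasing, DRAM2 and RNASEH2C as protective, and PYROXD2 as
discordant.

## 5. Spatial exclusion statistics

- **kNN graph** (k = 6 by default, matching a hexagonal spot neighborhood):
  brute-force Euclidean distances with exact tie-breaking by ascending spot
  index via `np.lexsort`. Brute force was chosen over tree-based neighbor
  search deliberately: on regular lattices distance ties are ubiquitous and
  library tie-breaking is unspecified, which would make the graph — and
  every downstream p-value — platform-dependent. Sections of ≤ ~10⁴ spots
  are well within the O(n²) budget.
- **Neighborhood statistic**: mean over source (marker-high) spots of the
  mean immune signal among each spot's k neighbors. Exclusion depresses
  it, so the test is one-sided `less`.
- **Nearest-neighbor distance statistic**: mean over source spots of the
  distance to the nearest target (immune-high) spot. Exclusion inflates
  it, so the test is one-sided `greater`.
- **Thresholding**: marker-high and immune-high masks are spots strictly
  above the 0.75 empirical quantile of the respective signal.
- **Permutation null** (B = 10,000 by default): immune values (neighborhood
  test) or immune-high labels (distance test) are permuted across spots
  while coordinates and the tumor mask stay fixed. The empirical p-value
  uses the +1 correction p = (1 + #extreme)/(B + 1), ties counting as
  extreme, so p is bounded in [1/(B+1), 1] and never exactly zero.

## 6. Expression stratification

- **Marker-positive classification**: raw count > 0 for the marker gene.
- **Marker screen** (`find_markers`): counts are scaled to counts-per-10k
  per cell; `log2fc = log2((mean_pos + 1)/(mean_neg + 1))`; the per-gene
  test is the Wilcoxon rank-sum; Benjamini–Hochberg FDR across genes.
  Reported genes satisfy `|log2fc| ≥ 0.5` and `FDR < 0.05`.
- **Median dichotomization**: high group is strictly above the median;
  values equal to the median go to the low group (deterministic under
  ties).
- **Group comparison**: two-sided Mann–Whitney U; exact enumeration when
  both groups have ≤ 8 samples (falling back to the asymptotic form under
  ties), continuity-corrected normal approximation otherwise.
- **Immune factor panel**: CXCL14, TNFSF13B, TNFSF18 compared between
  marker-high and marker-low samples, with the high−low median difference
  reported as the direction and BH FDR across the panel. Constant or
  missing panel genes are skipped with a warning.

## 7. Synthetic data generators

Each generator is a pure function of its spec (seed included). The defaults
define the package's study conditions and are not tuned to any particular
test outcome.

- **MR instruments** (`MRSimSpec`): true exposure effects uniform in
  [0.15, 0.5] against `se_exp = 0.01` (instrument-grade z-scores ≥ 15),
  coded on the expression-increasing allele so that an injected
  directional-pleiotropy shift `pleiotropy_delta` keeps one orientation
  and is recoverable as the Egger intercept. Outcome effects are
  `true_beta·beta_exp + delta` plus noise with `se_out = 0.01`. 10% of
  variants are palindromic to exercise the harmonizer.
- **SMR locus** (`simulate_smr_locus`): AR(1)-style LD `r_ij = 0.9^|i−j|`,
  eQTL causal variant at position n/4; under the shared alternative the
  GWAS signal is proportional to the eQTL signal, otherwise it comes from
  a distinct variant half a locus away. Noise is drawn with the LD
  correlation (Cholesky), as for estimates from a single sample.
- **Spot grids** (`SpatialSimSpec`): a square lattice with a contiguous
  square tumor patch of ≈ `tumor_fraction` (default 0.25) of the section;
  marker score raised by 3.0 in the patch; immune score baseline 1.0 plus
  N(0, 0.5) noise, lowered (exclusion) or raised (colocalized) by
  `effect` inside the patch. Under the null the immune score is i.i.d.,
  so values are exchangeable by construction and the permutation null is
  exactly valid.
- **Counts** (`simulate_counts`): negative-binomial with dispersion 0.5;
  the marker gene is non-zero in exactly the planted positive cells. The
  marker and planted DE genes sit at low baseline means
  (`marker_mean = 2`, `de_mean = 1`) so that planting a fold-change leaves
  per-cell library size approximately unchanged — as in a real
  transcriptome, where any handful of DE genes is a negligible mass
  fraction. Without this, library-size normalization induces spurious
  fold-changes on every null gene (a composition artifact of the small
  simulated gene panel, not of the screen).
- **Bulk cohorts** (`simulate_bulk`): log2-scale expression around a
  baseline of 5; panel genes are shifted down by their effect size in
  marker-high samples (the immune-exclusion direction).

Generator realism limits: no genome-wide LD structure, no capture
chemistry or dropout model beyond NB sparsity, no transcriptome-wide
correlation; the spot lattice is square rather than hexagonal (the
statistics only consume coordinates, so the geometry is immaterial to
correctness).

## 8. Numerical and reproducibility choices

- All randomness uses `numpy.random.default_rng` with explicit seeds;
  pipeline sub-stage seeds derive from the run seed via `SeedSequence`
  spawning (reduced mod 2³¹).
- Summary-statistic TSVs are written with `%.17g` floats and read with
  round-trip float parsing, so files round-trip bit-exactly.
- The kNN graph, clumping order, harmonization order and marker tables
  are all deterministically ordered (index or id tie-breaks), making the
  full pipeline byte-deterministic: the same config produces byte-identical
  `report.json` files.
- Empirical p-values never return 0; parametric p-values are clipped to
  [0, 1].

## 9. Open design resolutions

- "Consistent direction and magnitude of effect" across cohorts is
  implemented as direction-only (a magnitude criterion is undefined
  without an equivalence margin); flagged in the retention reason.
- Heterogeneity (Q) p-values are reported but not part of the default
  retention rule, which names only the IVW and pleiotropy tests; a config
  flag (`require_het`) can add it.
- Genome-wide screens (hundreds of genes) are out of scope for the bundled
  example, which carries the five-candidate metrics; the pipeline accepts
  arbitrarily many genes through the same table interfaces.

## 10. Limitations

- The MR stage assumes valid instruments after filtering; the Egger
  intercept detects only *directional* pleiotropy.
- HEIDI needs ≥ 3 eligible flanking SNPs; sparse loci fall back to a
  caller-supplied value or report the test as unavailable.
- Permutation tests assume exchangeability of the immune signal across
  spots under the null; strong spatial autocorrelation unrelated to the
  tumor mask would inflate rejection rates.
- Problem sizes (50-instrument genes, 30-SNP loci, 16×16 sections,
  400-cell matrices, 100-sample cohorts) are the package's own desk-scale
  validation choices, selected so the complete validation suite runs in
  well under a minute per module on one CPU.
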