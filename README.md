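# excluscope

Multi-omics prioritization of tumor-intrinsic genes associated with
CD8+ T-cell exclusion, with spatial and expression-stratified validation.

## Scientific problem

Immune exclusion — cytotoxic T lymphocytes (CTLs) confined to peritumoral
regions with minimal infiltration into tumor nests — limits response to
immunotherapy in prostate cancer. `excluscope` implements the statistical
core of a study design that asks: *which genes causally raise prostate
cancer risk through their expression, and do those genes mark tumors that
spatially exclude CTLs?*

The package combines three analysis layers:

1. **Genetic prioritization** (`harmonize`, `estimators`, `smr`,
   `prioritize`): two-sample Mendelian randomization (MR) using cis-eQTLs
   as instruments for gene expression, replicated across two GWAS cohorts,
   then intersected with a summary-data-based MR (SMR) screen that uses
   the HEIDI test to discard linkage artifacts.
2. **Spatial exclusion testing** (`spatial`): permutation tests on spot-level
   spatial transcriptomics asking whether the immune signal in the
   k-nearest-neighborhood of marker-high tumor spots is depressed, and
   whether marker-high spots sit far from immune-high spots.
3. **Expression stratification** (`strata`): marker-positive cell
   classification and a Wilcoxon/fold-change marker screen in single-cell
   counts, plus median-dichotomized bulk cohorts compared on an immune
   factor panel (CXCL14, TNFSF13B, TNFSF18).

A seeded synthetic-data module generates every input the pipeline consumes,
so all statistical claims are validated against planted ground truth.

## Model

For gene *g* with independent cis-eQTL instruments *j = 1..n*, let
β̂_xj (SE σ_xj) be the variant's effect on expression and β̂_yj (SE σ_yj)
its effect on prostate cancer risk (log odds). Under the MR assumptions
each Wald ratio b_j = β̂_yj / β̂_xj estimates the causal effect, and the
inverse-variance-weighted (IVW) estimate is

    β̂_IVW = Σ_j w_j b_j / Σ_j w_j,   w_j = β̂_xj² / σ_yj²,

with SE (Σ_j w_j)^(-1/2). MR-Egger regression adds an intercept that
estimates directional pleiotropy; the weighted median and mode estimators
are reported as sensitivity analyses; Cochran's Q quantifies instrument
heterogeneity. The SMR statistic at the top cis-eQTL is
T_SMR = z_x² z_y² / (z_x² + z_y²) ~ χ²(1), and HEIDI tests whether flanking
SNPs' SMR effects are consistent with one shared causal variant.

A gene is retained when (i) IVW p < 0.05 in discovery with Egger intercept
p > 0.05, (ii) IVW p < 0.05 in replication with the same effect direction,
and (iii) p_SMR < 0.05 with p_HEIDI > 0.05 in at least one SMR cohort.
Retained genes are classified `risk_increasing` (OR > 1 and b_SMR > 0
everywhere), `protective` (all reversed), else `discordant`.

On a spatial section with spots *i* at coordinates (x_i, y_i), the
neighborhood statistic is the mean over marker-high spots of the mean
immune signal among each spot's k = 6 nearest neighbors; the distance
statistic is the mean distance from marker-high spots to the nearest
immune-high spot. Both are tested against a coordinate-preserving
permutation null with the +1-corrected empirical p-value
p = (1 + #extreme) / (B + 1), B = 10,000 by default.

## Worked example

The package ships the per-gene MR/SMR metrics for five prostate cancer
candidate genes across a discovery and a replication cohort:

```python
from excluscope import prioritize_candidates, two_stage_filter
from excluscope.io import load_candidate_metrics

tmr, smr = load_candidate_metrics()
cohorts = sorted({t.cohort for t in tmr})
discovery = [t for t in tmr if t.cohort == cohorts[0]]
replication = [t for t in tmr if t.cohort == cohorts[1]]
supported = two_stage_filter(discovery, replication)
for c in prioritize_candidates(supported, smr, tmr):
    print(f"{c.gene:9s} retained={c.retained} direction={c.direction}")
```

prints

```
DRAM2     retained=True direction=protective
PGAP3     retained=True direction=risk_increasing
PYROXD2   retained=True direction=discordant
RNASEH2C  retained=True direction=protective
VAMP3     retained=True direction=risk_increasing
```

A planted spatial exclusion pattern is detected like this:

```python
from excluscope import SpatialSimSpec, exclusion_report, simulate_spot_grid

grid = simulate_spot_grid(
    SpatialSimSpec(n_side=16, pattern="exclusion", effect=2.0, seed=1)
)
rep = exclusion_report(grid, "marker_score", "immune_score", B=4999, seed=1)
print(rep["neighborhood"].observed, rep["neighborhood"].pval)
print(rep["nn_distance"].observed, rep["nn_distance"].pval)
```

prints

```
-0.9101597747088606 0.0002
3.5358898960381794 0.0002
```

(both tests reject at the permutation floor 1/(B+1) = 0.0002), while the
same report on a `pattern="null"` grid gives p = 0.25 and p = 0.33.

## Command line

```sh
excluscope simulate spots --pattern exclusion --effect 2.0 --out spots.tsv
excluscope spatial test --spots spots.tsv --b 4999 --out spatial.json
excluscope mr run --discovery disc.tsv --replication repl.tsv \
    --smr smr.tsv --out candidates/
excluscope run --config run.cfg       # full pipeline, writes report.json
```

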