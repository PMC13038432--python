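"""End-to-end orchestration: simulate -> prioritize -> spatial -> strata.

A :class:`RunConfig` is the single source of truth for a run: every
threshold, the seed, the input paths and the output directory. Each stage
writes its own outputs under the run directory and appends its settings and
headline numbers to ``report.json``, so a run is fully reproducible from the
report alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as eio
from .prioritize import prioritize_candidates, two_stage_filter
from .spatial import exclusion_report
from .strata import classify_marker_positive, find_markers, immune_factor_panel
from .synthetic import (
    MRSimSpec,
    SpatialSimSpec,
    simulate_bulk,
    simulate_counts,
    simulate_mr_dataset,
    simulate_spot_grid,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs for one pipeline run."""

    out_dir: str = "excluscope_run"
    seed: int = 0
    # mr_prioritize stage
    discovery_tmr: Optional[str] = None
    replication_tmr: Optional[str] = None
    smr_table: Optional[str] = None
    use_bundled_candidates: bool = False
    p_thresh: float = 0.05
    pleio_thresh: float = 0.05
    p_smr_thresh: float = 0.05
    p_heidi_thresh: float = 0.05
    smr_cohort_rule: str = "any"
    # spatial stage
    spots: Optional[str] = None
    marker_signal: str = "marker_score"
    immune_signal: str = "immune_score"
    k: int = 6
    B: int = 10_000
    quantile: float = 0.75
    # strata stage
    counts_mtx: Optional[str] = None
    counts_genes: Optional[str] = None
    counts_cells: Optional[str] = None
    bulk_expr: Optional[str] = None
    marker_gene: str = "PGAP3"
    panel: tuple[str, ...] = ("CXCL14", "TNFSF13B", "TNFSF18")
    lfc_min: float = 0.5
    fdr_max: float = 0.05
    # simulate stage
    simulate: bool = False

    def validate(self) -> None:
        for name, lo, hi in [
            ("p_thresh", 0, 1), ("pleio_thresh", 0, 1),
            ("p_smr_thresh", 0, 1), ("p_heidi_thresh", 0, 1),
            ("quantile", 0, 1), ("fdr_max", 0, 1),
        ]:
            v = getattr(self, name)
            if not (lo < v < hi):
                raise ValueError(f"{name}={v} outside ({lo}, {hi})")
        if self.smr_cohort_rule not in ("any", "all"):
            raise ValueError("smr_cohort_rule must be 'any' or 'all'")
        if self.k < 1 or self.B < 1:
            raise ValueError("k and B must be >= 1")


def validate_inputs(paths: dict[str, str]) -> list[str]:
    """Schema-check input files before any work; returns diagnostics.

    ``paths`` maps a kind in {summary, ld, tmr, smr, spots, bulk} to a file
    path. An empty list means everything validated.
    """
    readers = {
        "summary": eio.read_summary_stats,
        "ld": eio.read_ld_matrix,
        "tmr": eio.read_gene_mr_table,
        "smr": eio.read_smr_table,
        "spots": eio.read_spot_table,
        "bulk": eio.read_bulk_expression,
    }
    diags: list[str] = []
    for kind, path in paths.items():
        reader = readers.get(kind)
        if reader is None:
            diags.append(f"{path}: unknown input kind {kind!r}")
            continue
        if not Path(path).exists():
            diags.append(f"{path}: file not found")
            continue
        try:
            reader(path)
        except Exception as exc:  # noqa: BLE001 - surfaced as diagnostics
            diags.append(f"{path}: {exc}")
    return diags


def _candidate_table(candidates) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"gene": c.gene, "retained": c.retained,
             "direction": c.direction or "", "reason": c.reason}
            for c in candidates
        ]
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order and write ``report.json``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "settings": asdict(config), "stages": {}}

    try:
        if config.simulate:
            report["stages"]["simulate"] = _stage_simulate(config, out)
        if config.use_bundled_candidates or (
            config.discovery_tmr and config.replication_tmr and config.smr_table
        ):
            report["stages"]["mr_prioritize"] = _stage_mr(config, out)
        if config.spots or config.simulate:
            report["stages"]["spatial"] = _stage_spatial(config, out)
        if config.counts_mtx or config.bulk_expr or config.simulate:
            report["stages"]["strata"] = _stage_strata(config, out)
    except Exception as exc:
        report["error"] = str(exc)
        (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
        raise
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def _stage_simulate(config: RunConfig, out: Path) -> dict:
    seq = np.random.SeedSequence(config.seed)
    s_mr, s_spot, s_counts, s_bulk = [int(s.generate_state(1)[0] % 2**31)
                                      for s in seq.spawn(4)]
    exp, outc = simulate_mr_dataset(MRSimSpec(seed=s_mr))
    eio.write_summary_stats(exp, out / "sim_exposure.tsv")
    eio.write_summary_stats(outc, out / "sim_outcome.tsv")
    grid = simulate_spot_grid(SpatialSimSpec(pattern="exclusion", effect=2.0, seed=s_spot))
    eio.write_spot_table(grid, out / "sim_spots.tsv")
    cm, _ = simulate_counts(seed=s_counts, de_genes={"GENE0001": 4.0})
    eio.write_cell_matrix(cm, out, prefix="sim_counts")
    bulk = simulate_bulk(seed=s_bulk,
                         panel_effects={g: 2.0 for g in config.panel})
    eio.write_bulk_expression(bulk, out / "sim_bulk.tsv")
    config.spots = str(out / "sim_spots.tsv")
    config.counts_mtx = str(out / "sim_counts.mtx")
    config.counts_genes = str(out / "sim_counts_genes.txt")
    config.counts_cells = str(out / "sim_counts_cells.txt")
    config.bulk_expr = str(out / "sim_bulk.tsv")
    return {"seeds": {"mr": s_mr, "spots": s_spot, "counts": s_counts, "bulk": s_bulk}}


def _stage_mr(config: RunConfig, out: Path) -> dict:
    if config.use_bundled_candidates:
        tmr, smr = eio.load_candidate_metrics()
    else:
        tmr = eio.read_gene_mr_table(config.discovery_tmr)
        tmr += eio.read_gene_mr_table(config.replication_tmr)
        smr = eio.read_smr_table(config.smr_table)
    cohorts = sorted({t.cohort for t in tmr})
    discovery = [t for t in tmr if t.cohort == cohorts[0]]
    replication = [t for t in tmr if t.cohort != cohorts[0]]
    supported = two_stage_filter(
        discovery, replication,
        p_thresh=config.p_thresh, pleio_thresh=config.pleio_thresh,
    )
    candidates = prioritize_candidates(
        supported, smr, tmr,
        p_smr_thresh=config.p_smr_thresh,
        p_heidi_thresh=config.p_heidi_thresh,
        smr_cohort_rule=config.smr_cohort_rule,
    )
    table = _candidate_table(candidates)
    table.to_csv(out / "candidates.tsv", sep="\t", index=False)
    retained = table[table.retained]
    return {
        "n_genes_input": len({t.gene for t in tmr}),
        "n_tmr_supported": len(supported),
        "n_retained": int(table.retained.sum()),
        "retained_genes": sorted(retained.gene),
        "directions": dict(zip(retained.gene, retained.direction)),
        "thresholds": {
            "p_thresh": config.p_thresh, "pleio_thresh": config.pleio_thresh,
            "p_smr_thresh": config.p_smr_thresh,
            "p_heidi_thresh": config.p_heidi_thresh,
            "smr_cohort_rule": config.smr_cohort_rule,
        },
    }


def _stage_spatial(config: RunConfig, out: Path) -> dict:
    grid = eio.read_spot_table(config.spots)
    rep = exclusion_report(
        grid, config.marker_signal, config.immune_signal,
        k=config.k, B=config.B, quantile=config.quantile, seed=config.seed,
    )
    np.savetxt(out / "null_neighborhood.txt", rep["neighborhood"].null_draws)
    np.savetxt(out / "null_nn_distance.txt", rep["nn_distance"].null_draws)
    summary = {
        "neighborhood": {"observed": rep["neighborhood"].observed,
                         "pval": rep["neighborhood"].pval,
                         "alternative": rep["neighborhood"].alternative},
        "nn_distance": {"observed": rep["nn_distance"].observed,
                        "pval": rep["nn_distance"].pval,
                        "alternative": rep["nn_distance"].alternative},
        "settings": rep["settings"],
    }
    (out / "spatial_report.json").write_text(json.dumps(summary, indent=2))
    return summary


def _stage_strata(config: RunConfig, out: Path) -> dict:
    result: dict = {}
    if config.counts_mtx:
        cm = eio.read_cell_matrix(
            config.counts_mtx, config.counts_genes, config.counts_cells
        )
        positive = classify_marker_positive(cm, config.marker_gene)
        markers = find_markers(cm, positive, lfc_min=config.lfc_min,
                               fdr_max=config.fdr_max)
        markers.to_csv(out / "markers.tsv", sep="\t", index=False)
        result["markers"] = {
            "n_positive": int(positive.sum()),
            "n_negative": int((~positive).sum()),
            "n_marker_genes": len(markers),
            "marker_genes": list(markers.gene),
        }
    if config.bulk_expr:
        cohort = eio.read_bulk_expression(config.bulk_expr)
        panel = immune_factor_panel(cohort, config.marker_gene, config.panel)
        panel.to_csv(out / "immune_panel.tsv", sep="\t", index=False)
        result["immune_panel"] = panel.to_dict(orient="records")
    return result
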