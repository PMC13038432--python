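"""Readers and writers for the pipeline's delimited-table interfaces.

Summary statistics, LD matrices, per-gene metric tables and spot tables are
all plain delimited text; sparse counts use MatrixMarket with gene/cell
sidecar files. The bundled example dataset holds the published per-gene
MR/SMR metrics for the five prostate cancer candidate genes (PGAP3, VAMP3,
DRAM2, RNASEH2C, PYROXD2) across a discovery and a replication cohort.
"""

from __future__ import annotations

import math
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .spatial import SpotGrid
from .strata import BulkCohort, CellMatrix
from .types import GeneMRRecord, SMRRecord, VariantRecord

SUMMARY_COLUMNS = ["snp", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n"]


class SchemaError(ValueError):
    """An input table violates its declared schema."""


def read_summary_stats(path: "str | Path") -> list[VariantRecord]:
    """Read a GWAS/eQTL summary table (TSV; eaf and n may be empty)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in SUMMARY_COLUMNS[:7] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    records = []
    for i, row in df.iterrows():
        se = float(row["se"])
        if se <= 0:
            raise SchemaError(f"{path}: row {i + 2}: se must be > 0, got {se}")
        eaf = row.get("eaf")
        eaf = None if eaf is None or (isinstance(eaf, float) and math.isnan(eaf)) else float(eaf)
        n = row.get("n")
        n = None if n is None or (isinstance(n, float) and math.isnan(n)) else float(n)
        records.append(
            VariantRecord(
                snp_id=str(row["snp"]),
                effect_allele=str(row["effect_allele"]),
                other_allele=str(row["other_allele"]),
                beta=float(row["beta"]),
                se=se,
                pval=float(row["pval"]),
                eaf=eaf,
                n=n,
            )
        )
    return records


def write_summary_stats(records: list[VariantRecord], path: "str | Path") -> None:
    pd.DataFrame(
        [
            {
                "snp": r.snp_id, "effect_allele": r.effect_allele,
                "other_allele": r.other_allele, "eaf": r.eaf,
                "beta": r.beta, "se": r.se, "pval": r.pval, "n": r.n,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_ld_matrix(path: "str | Path") -> tuple[np.ndarray, list[str]]:
    """Square LD matrix with SNP ids as header row and first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise SchemaError(f"{path}: row and column SNP ids differ")
    return df.to_numpy(float), [str(s) for s in df.columns]


def write_ld_matrix(ld: np.ndarray, snp_ids: list[str], path: "str | Path") -> None:
    pd.DataFrame(ld, index=snp_ids, columns=snp_ids).to_csv(path, sep="\t")


def read_gene_mr_table(path: "str | Path") -> list[GeneMRRecord]:
    df = pd.read_csv(path, sep="\t")
    need = ["gene", "cohort", "or", "pval", "pleiotropy_pval", "heterogeneity_pval"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return [
        GeneMRRecord(
            gene=str(r["gene"]), cohort=str(r["cohort"]), or_=float(r["or"]),
            pval=float(r["pval"]), pleiotropy_pval=float(r["pleiotropy_pval"]),
            heterogeneity_pval=float(r["heterogeneity_pval"]),
        )
        for _, r in df.iterrows()
    ]


def read_smr_table(path: "str | Path") -> list[SMRRecord]:
    df = pd.read_csv(path, sep="\t")
    need = ["gene", "cohort", "top_snp", "b_smr", "p_smr", "p_heidi"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    out = []
    for _, r in df.iterrows():
        ph = r["p_heidi"]
        ph = None if isinstance(ph, float) and math.isnan(ph) else float(ph)
        out.append(
            SMRRecord(
                gene=str(r["gene"]), cohort=str(r["cohort"]),
                top_snp=str(r["top_snp"]), b_smr=float(r["b_smr"]),
                p_smr=float(r["p_smr"]), p_heidi=ph,
            )
        )
    return out


def load_candidate_metrics() -> tuple[list[GeneMRRecord], list[SMRRecord]]:
    """The bundled five-gene prostate-cancer candidate metrics fixture."""
    pkg = resources.files("excluscope.data")
    with resources.as_file(pkg / "candidate_tmr.tsv") as p:
        tmr = read_gene_mr_table(p)
    with resources.as_file(pkg / "candidate_smr.tsv") as p:
        smr = read_smr_table(p)
    return tmr, smr


def read_spot_table(path: "str | Path") -> SpotGrid:
    """Spot table (CSV or TSV) with ``spot_id, x, y`` plus signal columns.

    Columns whose values are all 0/1 are loaded as labels, the rest as
    continuous signals.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    need = ["spot_id", "x", "y"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    coords = df[["x", "y"]].to_numpy(float)
    if len({tuple(c) for c in coords.tolist()}) != len(df):
        raise SchemaError(f"{path}: duplicate spot coordinates")
    signals: dict[str, np.ndarray] = {}
    labels: dict[str, np.ndarray] = {}
    for col in df.columns:
        if col in need:
            continue
        vals = df[col].to_numpy()
        if set(np.unique(vals)).issubset({0, 1}):
            labels[col] = vals.astype(bool)
        else:
            signals[col] = vals.astype(float)
    return SpotGrid(
        spot_ids=[str(s) for s in df["spot_id"]],
        coords=coords, signals=signals, labels=labels,
    )


def write_spot_table(grid: SpotGrid, path: "str | Path") -> None:
    df = pd.DataFrame({"spot_id": grid.spot_ids,
                       "x": grid.coords[:, 0], "y": grid.coords[:, 1]})
    for name, sig in grid.signals.items():
        df[name] = sig
    for name, lab in grid.labels.items():
        df[name] = lab.astype(int)
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df.to_csv(path, sep=sep, index=False)


def read_cell_matrix(
    mtx_path: "str | Path", genes_path: "str | Path", cells_path: "str | Path"
) -> CellMatrix:
    """MatrixMarket counts with one-name-per-line gene and cell sidecars."""
    counts = sparse.csr_matrix(spio.mmread(mtx_path))
    genes = Path(genes_path).read_text().split()
    cells = Path(cells_path).read_text().split()
    return CellMatrix(genes=genes, cells=cells, counts=counts)


def write_cell_matrix(m: CellMatrix, out_dir: "str | Path", prefix: str = "counts") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(out / f"{prefix}.mtx", sparse.coo_matrix(m.counts))
    (out / f"{prefix}_genes.txt").write_text("\n".join(m.genes) + "\n")
    (out / f"{prefix}_cells.txt").write_text("\n".join(m.cells) + "\n")


def read_bulk_expression(path: "str | Path") -> BulkCohort:
    """Tab-separated gene x sample expression matrix with a header row."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return BulkCohort(expression=df.astype(float))


def write_bulk_expression(cohort: BulkCohort, path: "str | Path") -> None:
    cohort.expression.to_csv(path, sep="\t")
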