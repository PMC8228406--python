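"""Reading and writing the TSV/JSON formats used by the pipeline.

Matrices travel as UTF-8 tab-separated text with a header row of column
IDs and a first column of sample IDs (the dialect of TCGA-style matrix
exports).  ``NA`` and the empty string are the accepted missing-value
tokens.  Floats are serialised with 17 significant digits so write/read
round-trips are exact.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    CoefficientMatrix,
    ExpressionMatrix,
    LowRankComponent,
    MethylationMatrix,
)
from .preprocess import ClinicalTable, SiteAnnotation
from .solver import FitConfig, FitResult

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_site_annotation",
    "read_clinical_table",
    "write_fit_result",
    "read_fit_result",
]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"
_NA_TOKENS = ["NA", ""]


def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            index_col=0,
            na_values=_NA_TOKENS,
            keep_default_na=False,
            float_precision="round_trip",
        )
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed TSV ({exc})") from exc
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate sample IDs in first column")
    if df.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate column IDs in header")
    return df


def read_matrix(path, kind: str):
    """Read a samples-by-features TSV matrix.

    ``kind="methylation"`` returns a :class:`MethylationMatrix` (values
    validated to [0, 1], missing entries preserved as NaN for
    preprocessing); ``kind="expression"`` returns an
    :class:`ExpressionMatrix` (all entries must be present and finite).
    """
    if kind not in ("methylation", "expression"):
        raise ValueError("kind must be 'methylation' or 'expression'")
    df = _read_tsv(path)
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        for col in df.columns:
            coerced = pd.to_numeric(df[col].fillna("nan"), errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = df.index[bad.to_numpy().argmax()]
                raise ValueError(
                    f"{path}: non-numeric cell at row {row!r}, column {col!r}"
                ) from exc
        raise ValueError(f"{path}: non-numeric data") from exc
    ids = [str(i) for i in df.index]
    cols = [str(c) for c in df.columns]
    if kind == "methylation":
        out_of_range = (values < 0) | (values > 1)
        if np.any(out_of_range):
            i, j = np.argwhere(out_of_range)[0]
            raise ValueError(
                f"{path}: beta value {values[i, j]!r} outside [0, 1] at row "
                f"{ids[i]!r}, column {cols[j]!r}"
            )
        return MethylationMatrix(values, ids, cols)
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ValueError(
            f"{path}: missing expression value at row {ids[i]!r}, column {cols[j]!r}"
        )
    return ExpressionMatrix(values, ids, cols)


def write_matrix(matrix, path) -> Path:
    """Write a matrix container (or DataFrame) as full-precision TSV."""
    path = Path(path)
    frame = matrix if isinstance(matrix, pd.DataFrame) else matrix.to_frame()
    frame.to_csv(path, sep="\t", float_format=_FLOAT_FMT, na_rep="NA")
    return path


def read_site_annotation(path) -> SiteAnnotation:
    """Read a BED-like annotation: chromosome, site_id, tss_offset columns.

    Accepts either a headered TSV with those column names or a headerless
    3-column BED-like file in (chromosome, site_id, tss_offset) order.
    """
    path = Path(path)
    first = path.read_text().splitlines()[0].split("\t") if path.exists() else []
    if not path.exists():
        raise FileNotFoundError(path)
    if "site_id" in first:
        df = pd.read_csv(path, sep="\t")
    else:
        df = pd.read_csv(
            path, sep="\t", header=None, names=["chromosome", "site_id", "tss_offset"]
        )
    df["tss_offset"] = df["tss_offset"].astype(int)
    return SiteAnnotation(df[["site_id", "chromosome", "tss_offset"]])


def read_clinical_table(path) -> ClinicalTable:
    """Read the clinical TSV: sample_id, follow_up_days, group_label."""
    df = pd.read_csv(
        path, sep="\t", na_values=_NA_TOKENS, keep_default_na=False, dtype=str
    )
    df["follow_up_days"] = pd.to_numeric(df["follow_up_days"], errors="raise")
    return ClinicalTable(df)


def write_fit_result(result: FitResult, out_dir) -> dict[str, Path]:
    """Persist a fit: B as sparse triplets, L dense, and a JSON report.

    The report carries the objective trace, convergence diagnostics, the
    config echo, the centering offsets and the full ID lists, so
    :func:`read_fit_result` can reconstruct both matrices exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "B": out_dir / "B.tsv",
        "L": out_dir / "L.tsv",
        "report": out_dir / "report.json",
    }
    result.B.to_triplets().to_csv(
        paths["B"], sep="\t", index=False, float_format=_FLOAT_FMT
    )
    write_matrix(pd.DataFrame(result.L.values, columns=result.B.gene_ids), paths["L"])
    report = {
        "objective_trace": result.objective_trace,
        "n_iter": result.n_iter,
        "converged": result.converged,
        "rank_L": result.rank,
        "nnz_B": result.B.nnz,
        "singular_values_L": [float(s) for s in result.L.singular_values],
        "config": {
            "rho": result.config.rho,
            "lam": result.config.lam,
            "max_iter": result.config.max_iter,
            "tol": result.config.tol,
            "rank_tol": result.config.rank_tol,
            "cd_tol": result.config.cd_tol,
            "cd_max_iter": result.config.cd_max_iter,
            "center": result.config.center,
            "seed": result.config.seed,
        },
        "site_ids": result.B.site_ids,
        "gene_ids": result.B.gene_ids,
        "column_means_Y": [float(v) for v in result.column_means_Y],
        "column_means_X": [float(v) for v in result.column_means_X],
    }
    paths["report"].write_text(json.dumps(report, indent=1))
    logger.info("fit result written to %s", out_dir)
    return paths


def read_fit_result(out_dir) -> FitResult:
    """Reconstruct a :class:`FitResult` written by :func:`write_fit_result`."""
    out_dir = Path(out_dir)
    report = json.loads((out_dir / "report.json").read_text())
    site_ids = report["site_ids"]
    gene_ids = report["gene_ids"]
    trip = pd.read_csv(out_dir / "B.tsv", sep="\t", float_precision="round_trip")
    B = np.zeros((len(site_ids), len(gene_ids)))
    si = {s: i for i, s in enumerate(site_ids)}
    gi = {g: j for j, g in enumerate(gene_ids)}
    for site, gene, coef in trip.itertuples(index=False):
        B[si[str(site)], gi[str(gene)]] = coef
    Lv = pd.read_csv(
        out_dir / "L.tsv", sep="\t", index_col=0, float_precision="round_trip"
    ).to_numpy(dtype=float)
    cfg = FitConfig(**report["config"])
    L = LowRankComponent(
        values=Lv,
        singular_values=np.asarray(report["singular_values_L"], dtype=float),
        rank_tol=cfg.rank_tol,
    )
    return FitResult(
        B=CoefficientMatrix(B, site_ids, gene_ids),
        L=L,
        objective_trace=list(report["objective_trace"]),
        n_iter=int(report["n_iter"]),
        converged=bool(report["converged"]),
        config=cfg,
        column_means_Y=np.asarray(report["column_means_Y"], dtype=float),
        column_means_X=np.asarray(report["column_means_X"], dtype=float),
    )
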