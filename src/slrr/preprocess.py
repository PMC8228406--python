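"""Data filtration turning raw paired matrices into model-ready inputs.

The funnel, in the order a typical methylation/expression study applies it:

1. drop CpG sites missing in more than 70% of samples and mean-impute the
   survivors (:func:`filter_missing_sites`);
2. restrict to promoter CpGs, 2 kb upstream to 0.5 kb downstream of the
   TSS (:func:`filter_promoter_sites`);
3. drop clinical records with follow-up under 30 days or no follow-up
   (:func:`filter_clinical`);
4. intersect the sample sets of the two matrices (and, optionally, the
   clinical table) so rows align (:func:`intersect_samples`);
5. keep only genes differentially expressed between tumor and normal
   samples as responses (:func:`select_de_genes`).

Every filter is idempotent and only removes rows/columns or imputes
missing entries; retained non-missing values are never altered.  Drop
counts are emitted through the module logger so the funnel is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, MethylationMatrix

__all__ = [
    "SiteAnnotation",
    "ClinicalTable",
    "filter_missing_sites",
    "filter_promoter_sites",
    "filter_clinical",
    "intersect_samples",
    "select_de_genes",
]

logger = logging.getLogger(__name__)


@dataclass
class SiteAnnotation:
    """CpG site -> (chromosome, signed bp offset to the nearest TSS).

    Negative offsets are upstream of the TSS.  Backed by a DataFrame with
    columns ``site_id``, ``chromosome``, ``tss_offset``.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"site_id", "chromosome", "tss_offset"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        if self.frame["site_id"].duplicated().any():
            raise ValueError("duplicate site_ids in annotation")
        if not np.all(np.isfinite(self.frame["tss_offset"].to_numpy(dtype=float))):
            raise ValueError("tss_offset must be finite")

    def offsets(self) -> pd.Series:
        return self.frame.set_index("site_id")["tss_offset"].astype(int)


@dataclass
class ClinicalTable:
    """Per-sample clinical record: follow-up duration and tumor/normal label.

    Backed by a DataFrame with columns ``sample_id``, ``follow_up_days``
    (nullable) and ``group_label`` in {"tumor", "normal"}.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "follow_up_days", "group_label"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"clinical table missing columns: {sorted(missing)}")
        if self.frame["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_ids in clinical table")
        labels = set(self.frame["group_label"].dropna())
        if not labels <= {"tumor", "normal"}:
            raise ValueError(f"unknown group labels: {sorted(labels - {'tumor', 'normal'})}")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.frame["sample_id"]]


def filter_missing_sites(
    meth: MethylationMatrix, max_missing_fraction: float = 0.7
) -> MethylationMatrix:
    """Drop sites missing in more than ``max_missing_fraction`` of samples.

    Surviving missing beta values are imputed with the per-site mean of
    the observed values.  Returns a complete matrix.
    """
    if not 0 < max_missing_fraction <= 1:
        raise ValueError("max_missing_fraction must lie in (0, 1]")
    missing = np.isnan(meth.values)
    frac = missing.mean(axis=0)
    keep = frac <= max_missing_fraction
    if not keep.any():
        raise ValueError("all methylation sites exceed the missingness threshold")
    values = meth.values[:, keep].copy()
    site_ids = [s for s, k in zip(meth.site_ids, keep) if k]
    n_imputed = int(np.isnan(values).sum())
    if n_imputed:
        col_means = np.nanmean(values, axis=0)
        idx = np.where(np.isnan(values))
        values[idx] = col_means[idx[1]]
    logger.info(
        "filter_missing_sites: dropped %d/%d sites, imputed %d entries",
        int((~keep).sum()),
        meth.n_sites,
        n_imputed,
    )
    return MethylationMatrix(values, list(meth.sample_ids), site_ids)


def filter_promoter_sites(
    meth: MethylationMatrix,
    annot: SiteAnnotation,
    upstream_bp: int = 2000,
    downstream_bp: int = 500,
) -> MethylationMatrix:
    """Keep CpGs within the promoter window around the TSS.

    The window is the closed interval ``[-upstream_bp, +downstream_bp]``
    (upstream offsets negative).  Sites without an annotation row are
    dropped with a logged count.
    """
    offsets = annot.offsets()
    annotated = np.array([s in offsets.index for s in meth.site_ids])
    keep = annotated.copy()
    for i, site in enumerate(meth.site_ids):
        if annotated[i]:
            off = int(offsets.loc[site])
            keep[i] = -upstream_bp <= off <= downstream_bp
    if not keep.any():
        raise ValueError("no CpG sites fall in the promoter window")
    logger.info(
        "filter_promoter_sites: %d unannotated dropped, %d outside window, %d kept",
        int((~annotated).sum()),
        int((annotated & ~keep).sum()),
        int(keep.sum()),
    )
    return MethylationMatrix(
        meth.values[:, keep],
        list(meth.sample_ids),
        [s for s, k in zip(meth.site_ids, keep) if k],
    )


def filter_clinical(clin: ClinicalTable, min_follow_up_days: int = 30) -> ClinicalTable:
    """Drop records with missing follow-up or follow-up below the minimum.

    The cut is strict: a follow-up of exactly ``min_follow_up_days`` is
    kept.  An empty result is allowed (with a warning), since downstream
    sample intersection reports the failure in context.
    """
    days = pd.to_numeric(clin.frame["follow_up_days"], errors="coerce")
    keep = days.notna() & (days >= min_follow_up_days)
    out = clin.frame.loc[keep].reset_index(drop=True)
    logger.info(
        "filter_clinical: dropped %d/%d records", int((~keep).sum()), len(keep)
    )
    if out.empty:
        logger.warning("filter_clinical: no clinical records survive")
    return ClinicalTable(out)


def intersect_samples(
    meth: MethylationMatrix,
    expr: ExpressionMatrix,
    clin: ClinicalTable | None = None,
) -> tuple[MethylationMatrix, ExpressionMatrix]:
    """Restrict both matrices to their common samples, in sorted ID order.

    When a clinical table is given, only its sample IDs are eligible.
    Both outputs carry identical ``sample_ids`` sequences.
    """
    common = set(meth.sample_ids) & set(expr.sample_ids)
    if clin is not None:
        common &= set(clin.sample_ids)
    if not common:
        raise ValueError("no samples shared between the input datasets")
    order = sorted(common)
    mi = [meth.sample_ids.index(s) for s in order]
    ei = [expr.sample_ids.index(s) for s in order]
    logger.info(
        "intersect_samples: %d common samples (meth %d, expr %d%s)",
        len(order),
        meth.n_samples,
        expr.n_samples,
        f", clinical {len(clin.sample_ids)}" if clin is not None else "",
    )
    return (
        MethylationMatrix(meth.values[mi], order, list(meth.site_ids)),
        ExpressionMatrix(expr.values[ei], order, list(expr.gene_ids)),
    )


def select_de_genes(
    expr: ExpressionMatrix,
    labels,
    alpha: float = 0.05,
    min_abs_logfc: float = 1.0,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Keep genes differentially expressed between tumor and normal samples.

    Per gene, a two-sided Wilcoxon rank-sum test compares tumor vs normal
    values; p-values are Benjamini-Hochberg adjusted.  A gene is kept when
    its adjusted p-value is below ``alpha`` AND
    ``|log2((mean_tumor + 1) / (mean_normal + 1))| >= min_abs_logfc``.

    ``labels`` maps each sample (dict keyed by sample_id, or a sequence
    aligned with ``expr.sample_ids``) to "tumor" or "normal".  Returns the
    reduced matrix and the full per-gene DE table.
    """
    if isinstance(labels, dict):
        lab = np.array([labels[s] for s in expr.sample_ids])
    else:
        lab = np.asarray(list(labels))
        if lab.shape[0] != expr.n_samples:
            raise ValueError("labels length must match the number of samples")
    bad = set(lab) - {"tumor", "normal"}
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")
    tumor = expr.values[lab == "tumor"]
    normal = expr.values[lab == "normal"]
    if tumor.shape[0] < 2 or normal.shape[0] < 2:
        raise ValueError("need at least 2 samples in each of tumor and normal")

    pvals = stats.mannwhitneyu(
        tumor, normal, axis=0, alternative="two-sided", method="asymptotic"
    ).pvalue
    padj = multipletests(pvals, method="fdr_bh")[1]
    log2fc = np.log2((tumor.mean(axis=0) + 1.0) / (normal.mean(axis=0) + 1.0))
    # alpha >= 1 disables the significance filter (adjusted p can equal 1.0)
    sig = padj < alpha if alpha < 1 else np.ones(padj.shape, dtype=bool)
    keep = sig & (np.abs(log2fc) >= min_abs_logfc)

    table = pd.DataFrame(
        {
            "gene_id": expr.gene_ids,
            "p_value": pvals,
            "p_adjusted": padj,
            "log2_fold_change": log2fc,
            "selected": keep,
        }
    )
    logger.info(
        "select_de_genes: %d/%d genes selected (alpha=%g, |log2FC|>=%g)",
        int(keep.sum()),
        expr.n_genes,
        alpha,
        min_abs_logfc,
    )
    reduced = ExpressionMatrix(
        expr.values[:, keep],
        list(expr.sample_ids),
        [g for g, k in zip(expr.gene_ids, keep) if k],
    )
    return reduced, table
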