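"""Post-fit analyses: association ranking, L-based subtyping, subtype CpGs.

No significance test is attached to the coefficient matrix B; ranking by
|B| is the supported interface for association extraction.  Sample
subtyping reads the number of clusters off the numerical rank of the
fitted low-rank component L and groups samples by k-means on its scaled
left singular subspace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .containers import CoefficientMatrix, LowRankComponent, MethylationMatrix
from .solver import numerical_rank

__all__ = [
    "SampleClustering",
    "SubtypeSiteResult",
    "top_associations",
    "cluster_samples",
    "subtype_differential_sites",
]

logger = logging.getLogger(__name__)


@dataclass
class SampleClustering:
    """k-means grouping of samples in the row space of L.

    ``labels`` holds one cluster index in 1..k per sample; ``embedding``
    is the n x k coordinate matrix (left singular vectors of L scaled by
    their singular values) that was clustered.
    """

    labels: np.ndarray
    k: int
    embedding: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.labels.min(initial=1) < 1 or self.labels.max(initial=1) > self.k:
            raise ValueError("labels must lie in 1..k")


@dataclass
class SubtypeSiteResult:
    """Per-site one-vs-rest differential methylation across clusters.

    ``frame`` has one row per site: a p-value column per tested cluster,
    ``n_significant_clusters`` and ``flagged`` (true when the count
    exceeds ``min_clusters``).  A BH-adjusted significance count is
    included alongside for transparency; flagging uses the raw p-values.
    """

    frame: pd.DataFrame
    p_threshold: float
    min_clusters: int
    tested_clusters: list[int]

    @property
    def flagged_sites(self) -> list[str]:
        return list(self.frame.loc[self.frame["flagged"], "site_id"])


def top_associations(
    B: CoefficientMatrix,
    top_n: int | None = None,
    per_gene_d: int | None = None,
) -> pd.DataFrame:
    """Rank non-zero site-gene associations by coefficient magnitude.

    Exactly one of ``top_n`` (global top-n entries) or ``per_gene_d``
    (top d sites within each gene column) must be given.  Ties in
    |coefficient| are broken by (site_id, gene_id) lexicographic order so
    repeat calls are bitwise identical.
    """
    if (top_n is None) == (per_gene_d is None):
        raise ValueError("give exactly one of top_n or per_gene_d")
    trip = B.to_triplets()
    trip["abs_coefficient"] = trip["coefficient"].abs()
    trip = trip.sort_values(
        ["abs_coefficient", "site_id", "gene_id"],
        ascending=[False, True, True],
        kind="stable",
    ).reset_index(drop=True)
    if top_n is not None:
        if top_n < 1:
            raise ValueError("top_n must be >= 1")
        if top_n > len(trip):
            logger.warning(
                "top_n=%d exceeds nnz(B)=%d; returning all non-zero entries",
                top_n,
                len(trip),
            )
        out = trip.head(top_n)
    else:
        if per_gene_d < 1:
            raise ValueError("per_gene_d must be >= 1")
        out = (
            trip.groupby("gene_id", sort=False, group_keys=False)
            .head(per_gene_d)
            .sort_values(
                ["abs_coefficient", "site_id", "gene_id"],
                ascending=[False, True, True],
                kind="stable",
            )
        )
    out = out.reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out[["site_id", "gene_id", "coefficient", "abs_coefficient", "rank"]]


def cluster_samples(
    L: LowRankComponent, rank_tol: float = 1e-8, seed: int = 0
) -> SampleClustering:
    """Group samples by k-means on the scaled left singular subspace of L.

    The cluster count k is the numerical rank of L (floored at 1): samples
    sharing the same low-rank structure fall in the same group.  The
    embedding is U_k diag(sigma_1..sigma_k); k-means runs with 20 restarts
    and a fixed seed, so results are reproducible.
    """
    n = L.values.shape[0]
    k = max(numerical_rank(L, rank_tol), 1)
    if n < k:
        raise ValueError(f"cannot form k={k} clusters from n={n} samples")
    U, s, _ = np.linalg.svd(L.values, full_matrices=False)
    embedding = U[:, :k] * s[:k]
    if k == 1:
        labels = np.ones(n, dtype=int)
    else:
        km = KMeans(n_clusters=k, n_init=20, random_state=seed)
        labels = km.fit_predict(embedding) + 1
    return SampleClustering(labels=labels, k=k, embedding=embedding, seed=seed)


def subtype_differential_sites(
    meth: MethylationMatrix,
    clustering: SampleClustering,
    p_threshold: float = 1e-10,
    min_clusters: int = 2,
) -> SubtypeSiteResult:
    """Flag CpG sites differentially methylated across sample subtypes.

    For every site and every cluster with at least 2 members, a two-sided
    Wilcoxon rank-sum test compares the cluster's beta values against all
    remaining samples.  A site is flagged when more than ``min_clusters``
    clusters are significant at ``p_threshold``.
    """
    if meth.has_missing:
        raise ValueError("methylation matrix has missing values; run preprocess")
    labels = clustering.labels
    if labels.shape[0] != meth.n_samples:
        raise ValueError("clustering labels must align with methylation samples")
    clusters = np.unique(labels)
    testable = [int(c) for c in clusters if (labels == c).sum() >= 2]
    skipped = [int(c) for c in clusters if int(c) not in testable]
    if skipped:
        logger.warning(
            "clusters %s have fewer than 2 samples and are excluded", skipped
        )
    frame = pd.DataFrame({"site_id": meth.site_ids})
    if len(clusters) < 2 or not testable:
        logger.warning("fewer than two testable clusters; no sites can be flagged")
        frame["n_significant_clusters"] = 0
        frame["n_significant_adjusted"] = 0
        frame["flagged"] = False
        return SubtypeSiteResult(frame, p_threshold, min_clusters, [])

    pmat = np.empty((len(testable), meth.n_sites))
    for row, c in enumerate(testable):
        inside = meth.values[labels == c]
        outside = meth.values[labels != c]
        pmat[row] = stats.mannwhitneyu(
            inside, outside, axis=0, alternative="two-sided", method="asymptotic"
        ).pvalue
    padj = multipletests(pmat.ravel(), method="fdr_bh")[1].reshape(pmat.shape)

    for row, c in enumerate(testable):
        frame[f"p_cluster_{c}"] = pmat[row]
        frame[f"p_adj_cluster_{c}"] = padj[row]
    n_sig = (pmat < p_threshold).sum(axis=0)
    frame["n_significant_clusters"] = n_sig
    frame["n_significant_adjusted"] = (padj < p_threshold).sum(axis=0)
    frame["flagged"] = n_sig > min_clusters
    return SubtypeSiteResult(frame, p_threshold, min_clusters, testable)
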