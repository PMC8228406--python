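"""Typed containers for the paired methylation/expression matrices.

All containers wrap a plain ``numpy`` array together with the row/column
identifiers, validate their invariants at construction time, and convert
to and from :class:`pandas.DataFrame` for I/O.  Missing methylation
entries are represented as ``NaN`` until :mod:`slrr.preprocess` imputes
them; every downstream consumer requires complete matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MethylationMatrix",
    "ExpressionMatrix",
    "CoefficientMatrix",
    "LowRankComponent",
]


def _as_id_list(ids, n: int, what: str) -> list[str]:
    out = [str(i) for i in ids]
    if len(out) != n:
        raise ValueError(f"expected {n} {what}, got {len(out)}")
    if len(set(out)) != len(out):
        raise ValueError(f"duplicate {what} are not allowed")
    return out


def _as_2d_float(values, what: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{what} must be a 2-D matrix, got ndim={arr.ndim}")
    return arr


@dataclass
class MethylationMatrix:
    """Beta-value matrix X: ``n`` samples x ``p`` CpG sites, entries in [0, 1].

    ``NaN`` marks a missing measurement; :func:`slrr.preprocess.filter_missing_sites`
    removes or imputes them before model fitting.
    """

    values: np.ndarray
    sample_ids: list[str]
    site_ids: list[str]

    def __post_init__(self) -> None:
        self.values = _as_2d_float(self.values, "methylation values")
        n, p = self.values.shape
        self.sample_ids = _as_id_list(self.sample_ids, n, "sample_ids")
        self.site_ids = _as_id_list(self.site_ids, p, "site_ids")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and (np.any(finite < 0) or np.any(finite > 1)):
            bad = np.argwhere((self.values < 0) | (self.values > 1))
            i, j = bad[0]
            raise ValueError(
                f"beta value {self.values[i, j]!r} out of [0, 1] at "
                f"sample {self.sample_ids[i]!r}, site {self.site_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_sites(self) -> int:
        return self.values.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.site_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MethylationMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))


@dataclass
class ExpressionMatrix:
    """Expression matrix Y: ``n`` samples x ``q`` genes, finite entries.

    Values are assumed to be already normalised / log-transformed upstream;
    sample rows align one-for-one with the paired :class:`MethylationMatrix`
    after :func:`slrr.preprocess.intersect_samples`.
    """

    values: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = _as_2d_float(self.values, "expression values")
        n, q = self.values.shape
        self.sample_ids = _as_id_list(self.sample_ids, n, "sample_ids")
        self.gene_ids = _as_id_list(self.gene_ids, q, "gene_ids")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite expression value at sample {self.sample_ids[i]!r}, "
                f"gene {self.gene_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))


@dataclass
class CoefficientMatrix:
    """Sparse effect matrix B: ``p`` sites x ``q`` genes.

    Entry (i, j) is the linear effect of methylation at site i on the
    expression of gene j; the l1 penalty drives most entries to exactly zero.
    """

    values: np.ndarray
    site_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = _as_2d_float(self.values, "coefficient values")
        p, q = self.values.shape
        self.site_ids = _as_id_list(self.site_ids, p, "site_ids")
        self.gene_ids = _as_id_list(self.gene_ids, q, "gene_ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("coefficient matrix contains non-finite entries")

    @property
    def nnz(self) -> int:
        """Count of entries with non-zero magnitude."""
        return int(np.count_nonzero(self.values))

    def to_triplets(self) -> pd.DataFrame:
        """Non-zero entries as a (site_id, gene_id, coefficient) table."""
        rows, cols = np.nonzero(self.values)
        return pd.DataFrame(
            {
                "site_id": [self.site_ids[i] for i in rows],
                "gene_id": [self.gene_ids[j] for j in cols],
                "coefficient": self.values[rows, cols],
            }
        )


@dataclass
class LowRankComponent:
    """Expression-heterogeneity matrix L: ``n`` samples x ``q`` genes.

    Holds the matrix together with its singular spectrum; ``numerical_rank``
    counts singular values above ``rank_tol * max(sigma_1, 1)``.
    """

    values: np.ndarray
    singular_values: np.ndarray = field(default=None)  # type: ignore[assignment]
    rank_tol: float = 1e-8

    def __post_init__(self) -> None:
        self.values = _as_2d_float(self.values, "low-rank component")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("low-rank component contains non-finite entries")
        if self.singular_values is None:
            self.singular_values = np.linalg.svd(self.values, compute_uv=False)
        self.singular_values = np.asarray(self.singular_values, dtype=float).ravel()
        if np.any(np.diff(self.singular_values) > 1e-12):
            raise ValueError("singular_values must be non-increasing")
        if np.any(self.singular_values < -1e-12):
            raise ValueError("singular_values must be non-negative")

    @property
    def numerical_rank(self) -> int:
        from .solver import numerical_rank  # local import avoids a cycle

        return numerical_rank(self, self.rank_tol)

    @property
    def nuclear_norm(self) -> float:
        return float(self.singular_values.sum())

    def to_frame(self, sample_ids=None, gene_ids=None) -> pd.DataFrame:
        n, q = self.values.shape
        index = sample_ids if sample_ids is not None else range(n)
        cols = gene_ids if gene_ids is not None else range(q)
        return pd.DataFrame(self.values, index=index, columns=cols)
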