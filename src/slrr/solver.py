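"""Alternating solver for the sparse-plus-low-rank regression model.

The model decomposes an expression matrix as

    Y = X B + L + e,

where X is the (binary or beta-value) methylation matrix, B is a sparse
site-by-gene coefficient matrix and L is a low-rank matrix absorbing
expression heterogeneity (hidden confounders: subtype structure, batch,
sequence changes).  The convex surrogate objective is

    f(B, L) = 1/2 ||Y - X B - L||_F^2 + rho ||B||_1 + lambda ||L||_*,

with ||.||_1 element-wise and ||.||_* the nuclear norm.  Block coordinate
descent alternates two exact minimisations:

* L-step: singular value thresholding of the residual Y - X B
  (the proximal operator of the nuclear norm);
* B-step: q independent Lasso problems, one per gene column, solved by
  cyclic coordinate descent with warm starts.

Both steps minimise their block exactly, so the objective is
non-increasing; an increase beyond floating-point slack is a bug and
raises.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .containers import (
    CoefficientMatrix,
    ExpressionMatrix,
    LowRankComponent,
    MethylationMatrix,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "objective",
    "svt_prox",
    "lasso_column",
    "lasso_kkt_gap",
    "fit",
    "numerical_rank",
    "penalty_grid",
    "select_penalties",
]

#: slack allowed on the objective trace before an increase is treated as a bug
_MONOTONE_SLACK = 1e-8


@dataclass(frozen=True)
class FitConfig:
    """Solver configuration.

    Parameters
    ----------
    rho
        l1 penalty weight on B (>= 0).  Larger values give sparser B.
    lam
        Nuclear-norm penalty weight on L (>= 0).  Larger values give
        lower-rank L; ``lam >= sigma_1(Y - XB)`` forces L = 0.
    max_iter
        Maximum number of outer (L-step + B-step) iterations.
    tol
        Relative objective-change convergence threshold.
    rank_tol
        Relative singular-value cutoff used when reporting the numerical
        rank of the fitted L.
    cd_tol, cd_max_iter
        Coordinate-descent stopping rule for each Lasso column: stop when
        the largest absolute coefficient update in a sweep falls below
        ``cd_tol``, or after ``cd_max_iter`` sweeps.
    center
        Column-center Y and X before fitting (absorbs per-gene intercepts;
        the model has no explicit intercept term).
    seed
        Reserved for randomized sub-steps; the default solver is
        deterministic and never consumes it.
    """

    rho: float
    lam: float
    max_iter: int = 100
    tol: float = 1e-6
    rank_tol: float = 1e-8
    cd_tol: float = 1e-7
    cd_max_iter: int = 1000
    center: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ValueError("rho must be >= 0")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.tol <= 0 or self.cd_tol <= 0 or self.rank_tol <= 0:
            raise ValueError("tol, cd_tol and rank_tol must be > 0")
        if self.max_iter < 1 or self.cd_max_iter < 1:
            raise ValueError("max_iter and cd_max_iter must be >= 1")


@dataclass
class FitResult:
    """Converged decomposition plus convergence diagnostics."""

    B: CoefficientMatrix
    L: LowRankComponent
    objective_trace: list[float]
    n_iter: int
    converged: bool
    config: FitConfig
    column_means_Y: np.ndarray = field(default_factory=lambda: np.empty(0))
    column_means_X: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def rank(self) -> int:
        return numerical_rank(self.L, self.config.rank_tol)


def _values(obj) -> np.ndarray:
    return np.asarray(getattr(obj, "values", obj), dtype=float)


def numerical_rank(L, rank_tol: float = 1e-8) -> int:
    """Count singular values above ``rank_tol * max(sigma_1, 1)``.

    Accepts a :class:`LowRankComponent`, a raw matrix, or a 1-D vector of
    singular values.
    """
    s = getattr(L, "singular_values", None)
    if s is None:
        arr = np.asarray(L, dtype=float)
        s = arr if arr.ndim == 1 else np.linalg.svd(arr, compute_uv=False)
    s = np.asarray(s, dtype=float)
    if s.size == 0:
        return 0
    cutoff = rank_tol * max(float(s.max()), 1.0)
    return int(np.count_nonzero(s > cutoff))


def objective(Y, X, B, L, rho: float, lam: float) -> float:
    """Evaluate 1/2||Y - XB - L||_F^2 + rho||B||_1 + lam||L||_*."""
    Yv, Xv, Bv, Lv = _values(Y), _values(X), _values(B), _values(L)
    n, q = Yv.shape
    if Xv.shape[0] != n:
        raise ValueError(
            f"sample axis mismatch: Y has {n} rows but X has {Xv.shape[0]}"
        )
    if Bv.shape[0] != Xv.shape[1]:
        raise ValueError(
            f"site axis mismatch: X has {Xv.shape[1]} columns but B has "
            f"{Bv.shape[0]} rows"
        )
    if Bv.shape[1] != q or Lv.shape != (n, q):
        raise ValueError(
            f"gene axis mismatch: Y is {Yv.shape}, X B is "
            f"{(Xv.shape[0], Bv.shape[1])}, L is {Lv.shape}"
        )
    for name, arr in (("Y", Yv), ("X", Xv)):
        if np.isnan(arr).any():
            raise ValueError(
                f"{name} contains missing values; run slrr.preprocess first"
            )
    resid = Yv - Xv @ Bv - Lv
    nuclear = (
        float(L.singular_values.sum())
        if isinstance(L, LowRankComponent)
        else float(np.linalg.svd(Lv, compute_uv=False).sum())
    )
    return 0.5 * float(np.sum(resid * resid)) + rho * float(
        np.abs(Bv).sum()
    ) + lam * nuclear


def svt_prox(M, lam: float, rank_tol: float = 1e-8) -> LowRankComponent:
    """Singular value thresholding: the proximal operator of ``lam * ||.||_*``.

    Returns the minimiser of ``1/2 ||M - L||_F^2 + lam ||L||_*``:
    the SVD of M with each singular value soft-thresholded by ``lam``.
    """
    Mv = _values(M)
    if Mv.ndim != 2:
        raise ValueError("svt_prox expects a 2-D matrix")
    if not np.all(np.isfinite(Mv)):
        raise ValueError("svt_prox input contains non-finite entries")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    U, d, Vt = np.linalg.svd(Mv, full_matrices=False)
    shrunk = np.maximum(d - lam, 0.0)
    L = (U * shrunk) @ Vt
    cutoff = rank_tol * max(float(shrunk.max(initial=0.0)), 1.0)
    kept = shrunk[shrunk > cutoff]
    return LowRankComponent(values=L, singular_values=kept, rank_tol=rank_tol)


@njit(cache=False)
def _cd_sweeps(G, c, b, rho, tol, max_iter):  # pragma: no cover - compiled
    """Cyclic coordinate descent on 1/2 b'Gb - c'b + rho||b||_1 in place.

    G = X'X (Gram), c = X'y.  Each coordinate update is the exact
    univariate minimiser (soft threshold).  Returns (sweeps, converged).
    """
    p = b.shape[0]
    for sweep in range(max_iter):
        delta = 0.0
        for j in range(p):
            gjj = G[j, j]
            if gjj <= 0.0:
                # all-zero predictor column: coefficient pinned to 0
                if b[j] != 0.0:
                    b[j] = 0.0
                continue
            fj = c[j] - np.dot(G[j], b) + gjj * b[j]
            if fj > rho:
                bj = (fj - rho) / gjj
            elif fj < -rho:
                bj = (fj + rho) / gjj
            else:
                bj = 0.0
            d = abs(bj - b[j])
            if d > delta:
                delta = d
            b[j] = bj
        if delta < tol:
            return sweep + 1, True
    return max_iter, False


def lasso_column(
    y,
    X,
    rho: float,
    b_init=None,
    cd_tol: float = 1e-7,
    cd_max_iter: int = 1000,
    *,
    gram=None,
) -> np.ndarray:
    """Solve one Lasso problem ``min_b 1/2||y - Xb||^2 + rho||b||_1``.

    Cyclic coordinate descent with soft-threshold updates, warm-started
    from ``b_init``.  ``gram`` may carry a precomputed ``X.T @ X`` so that
    many columns sharing X reuse it.  On hitting ``cd_max_iter`` without
    meeting ``cd_tol`` the best iterate is returned and a warning issued.
    """
    y = np.asarray(y, dtype=float).ravel()
    Xv = _values(X)
    if rho < 0:
        raise ValueError("rho must be >= 0")
    if Xv.shape[0] != y.shape[0]:
        raise ValueError("y length must match the number of rows of X")
    p = Xv.shape[1]
    b = (
        np.zeros(p)
        if b_init is None
        else np.asarray(b_init, dtype=float).copy().ravel()
    )
    if b.shape[0] != p:
        raise ValueError("b_init length must match the number of columns of X")
    G = Xv.T @ Xv if gram is None else np.asarray(gram, dtype=float)
    c = Xv.T @ y
    _, ok = _cd_sweeps(G, c, b, float(rho), float(cd_tol), int(cd_max_iter))
    if not ok:
        warnings.warn(
            f"coordinate descent hit cd_max_iter={cd_max_iter} before "
            f"cd_tol={cd_tol}; returning best iterate",
            RuntimeWarning,
            stacklevel=2,
        )
    return b


def lasso_kkt_gap(y, X, b, rho: float) -> float:
    """Maximum KKT violation of a Lasso iterate (0 at the exact optimum).

    For active coordinates the stationarity residual is
    ``|x_j'(y - Xb) - rho * sign(b_j)|``; for zero coordinates it is
    ``(|x_j'(y - Xb)| - rho)_+``.
    """
    y = np.asarray(y, dtype=float).ravel()
    Xv, b = _values(X), np.asarray(b, dtype=float).ravel()
    grad = Xv.T @ (y - Xv @ b)
    active = b != 0
    gap_active = np.abs(grad[active] - rho * np.sign(b[active]))
    gap_zero = np.maximum(np.abs(grad[~active]) - rho, 0.0)
    return float(max(gap_active.max(initial=0.0), gap_zero.max(initial=0.0)))


def _check_fit_inputs(Yv: np.ndarray, Xv: np.ndarray, Y, X) -> None:
    if Yv.ndim != 2 or Xv.ndim != 2:
        raise ValueError("Y and X must be 2-D matrices")
    if Yv.shape[0] != Xv.shape[0]:
        raise ValueError(
            f"sample axis mismatch: Y has {Yv.shape[0]} rows, X has {Xv.shape[0]}"
        )
    if isinstance(Y, ExpressionMatrix) and isinstance(X, MethylationMatrix):
        if Y.sample_ids != X.sample_ids:
            raise ValueError(
                "sample_ids of Y and X differ; align them with "
                "slrr.preprocess.intersect_samples"
            )
    for name, arr in (("Y", Yv), ("X", Xv)):
        if np.isnan(arr).any():
            raise ValueError(
                f"{name} contains missing values; run slrr.preprocess first"
            )


def fit(Y, X, config: FitConfig) -> FitResult:
    """Fit the sparse-plus-low-rank decomposition by alternating minimisation.

    Starts from B = 0, L = 0 and alternates an exact L-step
    (:func:`svt_prox` of ``Y - XB``) with an exact B-step (one warm-started
    Lasso per gene column of ``Y - L``).  Stops when the relative change of
    the objective falls below ``config.tol`` or after ``config.max_iter``
    outer iterations.
    """
    Yv, Xv = _values(Y), _values(X)
    _check_fit_inputs(Yv, Xv, Y, X)
    n, q = Yv.shape
    p = Xv.shape[1]

    if config.center:
        mu_Y = Yv.mean(axis=0)
        mu_X = Xv.mean(axis=0)
        Yc = Yv - mu_Y
        Xc = Xv - mu_X
    else:
        mu_Y = np.empty(0)
        mu_X = np.empty(0)
        Yc, Xc = Yv, Xv

    G = Xc.T @ Xc
    XtY = Xc.T @ Yc

    Bt = np.zeros((q, p))  # row j holds gene j's coefficients, contiguous for CD
    Lv = np.zeros((n, q))
    sv = np.zeros(0)
    trace: list[float] = []
    converged = False
    cd_warned = False

    for it in range(1, config.max_iter + 1):
        # L-step: exact nuclear-norm prox of the current residual
        R = Yc - Xc @ Bt.T
        U, d, Vt = np.linalg.svd(R, full_matrices=False)
        shrunk = np.maximum(d - config.lam, 0.0)
        Lv = (U * shrunk) @ Vt
        sv = shrunk

        # B-step: q independent Lasso columns against Y - L, warm-started
        C = np.ascontiguousarray((XtY - Xc.T @ Lv).T)
        for j in range(q):
            _, ok = _cd_sweeps(
                G,
                C[j],
                Bt[j],
                float(config.rho),
                float(config.cd_tol),
                int(config.cd_max_iter),
            )
            if not ok:
                cd_warned = True

        B = Bt.T
        resid = Yc - Xc @ B - Lv
        obj = (
            0.5 * float(np.sum(resid * resid))
            + config.rho * float(np.abs(B).sum())
            + config.lam * float(sv.sum())
        )
        if trace:
            prev = trace[-1]
            if obj > prev + _MONOTONE_SLACK * max(1.0, abs(prev)):
                raise RuntimeError(
                    f"objective increased from {prev!r} to {obj!r} at outer "
                    f"iteration {it}; this violates the block-descent "
                    "guarantee and indicates a solver bug"
                )
            if abs(prev - obj) < config.tol * max(1.0, abs(prev)):
                trace.append(obj)
                converged = True
                break
        trace.append(obj)

    if cd_warned:
        warnings.warn(
            "some Lasso columns hit cd_max_iter before cd_tol; consider "
            "raising cd_max_iter or loosening cd_tol",
            RuntimeWarning,
            stacklevel=2,
        )

    site_ids = (
        X.site_ids if isinstance(X, MethylationMatrix) else [f"site{i}" for i in range(p)]
    )
    gene_ids = (
        Y.gene_ids if isinstance(Y, ExpressionMatrix) else [f"gene{j}" for j in range(q)]
    )
    cutoff = config.rank_tol * max(float(sv.max(initial=0.0)), 1.0)
    L = LowRankComponent(
        values=Lv, singular_values=sv[sv > cutoff], rank_tol=config.rank_tol
    )
    return FitResult(
        B=CoefficientMatrix(
            values=np.ascontiguousarray(Bt.T), site_ids=site_ids, gene_ids=gene_ids
        ),
        L=L,
        objective_trace=trace,
        n_iter=len(trace),
        converged=converged,
        config=config,
        column_means_Y=mu_Y,
        column_means_X=mu_X,
    )


def penalty_grid(Y, X, n_rho: int = 4, n_lam: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Default penalty candidates derived from the data scale.

    rho candidates are ``rho_max * {1, 1/2, 1/4, ...}`` where
    ``rho_max = max |X' Y|`` (the smallest rho with B = 0 identically);
    lam candidates are ``sigma_1(Y) * {1/2, 1/4, ...}``.
    Both are computed on column-centered matrices.
    """
    Yv, Xv = _values(Y), _values(X)
    Yc = Yv - Yv.mean(axis=0)
    Xc = Xv - Xv.mean(axis=0)
    rho_max = float(np.abs(Xc.T @ Yc).max())
    sigma1 = float(np.linalg.svd(Yc, compute_uv=False)[0])
    rhos = rho_max * 0.5 ** np.arange(n_rho)
    lams = sigma1 * 0.5 ** np.arange(1, n_lam + 1)
    return rhos, lams


def select_penalties(
    Y,
    X,
    rhos=None,
    lams=None,
    base_config: FitConfig | None = None,
) -> tuple[float, float, "object"]:
    """Pick (rho, lam) from a grid by a BIC-like complexity score.

    The score is ``n*q * log(RSS / (n*q)) + log(n*q) * df`` with degrees of
    freedom ``df = nnz(B) + rank(L) * (n + q - rank(L))`` (the parameter
    count of a rank-r matrix).  This selector is convenience plumbing, not
    part of the model; rho and lam can always be supplied directly.

    Returns ``(rho, lam, table)`` where ``table`` is a tidy DataFrame of
    all grid evaluations.
    """
    import pandas as pd

    Yv = _values(Y)
    n, q = Yv.shape
    if rhos is None or lams is None:
        grid_r, grid_l = penalty_grid(Y, X)
        rhos = grid_r if rhos is None else rhos
        lams = grid_l if lams is None else lams
    if base_config is None:
        base_config = FitConfig(rho=1.0, lam=1.0)
    rows = []
    for rho in np.atleast_1d(rhos):
        for lam in np.atleast_1d(lams):
            cfg = replace(base_config, rho=float(rho), lam=float(lam))
            res = fit(Y, X, cfg)
            Yc = Yv - Yv.mean(axis=0) if cfg.center else Yv
            Xv = _values(X)
            Xc = Xv - Xv.mean(axis=0) if cfg.center else Xv
            rss = float(np.sum((Yc - Xc @ res.B.values - res.L.values) ** 2))
            r = res.rank
            df = res.B.nnz + r * (n + q - r)
            score = n * q * np.log(max(rss, 1e-300) / (n * q)) + np.log(n * q) * df
            rows.append(
                {
                    "rho": float(rho),
                    "lam": float(lam),
                    "rss": rss,
                    "nnz": res.B.nnz,
                    "rank": r,
                    "score": float(score),
                    "converged": res.converged,
                }
            )
    table = pd.DataFrame(rows).sort_values("score", kind="stable").reset_index(drop=True)
    best = table.iloc[0]
    return float(best["rho"]), float(best["lam"]), table
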