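"""Vectorised MB-MDR scan engine.

Computes steps 1-2 for every pair (or every single locus) and every trait
permutation at once. The key observation is that both the cell-versus-rest
step-1 tests and the H/L-versus-rest step-2 tests are Wald t statistics of
a 0/1 indicator in an OLS fit of the trait on intercept + covariates +
indicator, and by Frisch-Waugh-Lovell the whole scan reduces to products of
a residualised cell-membership matrix with a residualised trait matrix:

    X  = [1 | D]                      (covariates; D empty when unadjusted)
    Yt = Y - Qx (Qx' Y)               (traits residualised on X; Y holds the
                                       observed trait and all permutations)
    R  = M - Qx (Qx' M)               (one-hot cell membership residualised)
    A  = R' Yt                        (9 x n_columns cross-products)
    G  = R' R                         (9 x 9 Gram matrix)

For any cell set with 0/1 weight vector h, the Wald t of its indicator is

    t = (h'A_col / sqrt(h'Gh)) / sqrt((||yt_col||^2 - (h'A_col)^2 / h'Gh) / df)

with df = n - q - 2. Everything in the scan — step-1 statistics for the 9
singleton cells, H/L/O labels, and the step-2 H-vs-rest / L-vs-rest
statistics — follows from A, G and the per-column residual sums of squares,
so one pair costs two slim matrix products regardless of the number of
permutations. Cell membership depends only on the genotypes, never on the
permuted trait, so M, G and R are computed once per pair.

The scalar reference path in :mod:`mbmdr.core` implements the same tests
one OLS fit at a time; the test-suite checks the two paths agree to
floating-point accuracy.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .core import ScanSettings, iter_pairs
from .data import GenotypeMatrix

_EYE9 = np.eye(9)
_EYE3 = np.eye(3)

# relative tolerance deciding that an indicator lies in the covariate span
# (its residual norm is numerically zero) and is therefore untestable
_RANK_TOL = 1e-9


def orthonormal_basis(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column span of X, dropping dependent columns."""
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    keep = diag > _RANK_TOL * max(diag.max(initial=0.0), 1.0)
    return q[:, keep]


def _wald_t(num: np.ndarray, r2, yss: np.ndarray, df: int) -> np.ndarray:
    """Wald t from indicator cross-product, residual norm^2 and trait SS.

    Zero residual variance yields +/-inf (the scan-level convention for a
    perfect fit, equivalent to p = 0); an indicator with zero residual norm
    (collinear with the covariates) yields 0 (untestable).
    """
    r2 = np.asarray(r2, dtype=float)
    testable = r2 > _RANK_TOL
    safe_r2 = np.where(testable, r2, 1.0)
    rss = np.maximum(yss - num * num / safe_r2, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (num / np.sqrt(safe_r2)) / np.sqrt(rss / df)
    perfect = rss <= _RANK_TOL * np.maximum(yss, 1.0)
    # perfect fit with a numerically zero coefficient (e.g. constant trait)
    # is no evidence, not infinite evidence
    coef_zero = num * num <= _RANK_TOL * safe_r2
    t = np.where(
        perfect,
        np.where(coef_zero, 0.0, np.where(num >= 0, np.inf, -np.inf)),
        t,
    )
    return np.where(testable, t, 0.0)


def _mdr_statistics(
    A: np.ndarray,
    G: np.ndarray,
    yss: np.ndarray,
    sizes: np.ndarray,
    n: int,
    df: int,
    settings: ScanSettings,
) -> np.ndarray:
    """Steps 1-2 for one partition across all trait columns.

    A : (k, C) residualised cross-products, G : (k, k), yss : (C,),
    sizes : (k,) cell sizes. Returns the (C,) pair statistic.
    """
    tcrit = stats.t.isf(settings.alpha1 / 2.0, df)
    eligible = (sizes >= settings.min_cell) & (sizes <= n - settings.min_cell)
    t1 = _wald_t(A, np.diag(G)[:, None], yss[None, :], df)  # (k, C)
    h = eligible[:, None] & (t1 > tcrit)
    l = eligible[:, None] & (t1 < -tcrit)
    t_sides = np.empty((2, A.shape[1]))
    for row, mask in enumerate((h, l)):
        w = mask.astype(float)
        num = (w * A).sum(axis=0)
        r2 = np.einsum("ic,ij,jc->c", w, G, w)
        t_sides[row] = _wald_t(num, r2, yss, df)
    return np.maximum(np.maximum(t_sides[0], -t_sides[1]), 0.0)


def _residualise(Y: np.ndarray, Qx: np.ndarray) -> np.ndarray:
    return Y - Qx @ (Qx.T @ Y)


def scan_matrix(
    genotypes: GenotypeMatrix,
    Y: np.ndarray,
    settings: ScanSettings,
    designs=None,
    order: int = 2,
) -> np.ndarray:
    """MB-MDR statistics for all hypotheses and all trait columns.

    Parameters
    ----------
    Y : (n, C) matrix whose columns are trait vectors (the observed trait
        and any permutations of it).
    designs : None for an unadjusted scan, or a callable mapping the
        hypothesis (pair tuple or SNP index) to its n x q covariate matrix.
        Covariates are a fixed function of the genotypes: the same design
        is applied to every column of Y.
    order : 2 for the pairwise scan (9 cells), 1 for the single-locus scan
        (3 cells).

    Returns the (n_hypotheses, C) statistic matrix, hypotheses in
    lexicographic order.
    """
    n, m = genotypes.values.shape
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    gv = genotypes.values.astype(np.intp)

    if order == 2:
        hypotheses = list(iter_pairs(m))
        cell_of = lambda hyp: 3 * gv[:, hyp[0]] + gv[:, hyp[1]]
        onehot, k = _EYE9, 9
    elif order == 1:
        hypotheses = list(range(m))
        cell_of = lambda hyp: gv[:, hyp]
        onehot, k = _EYE3, 3
    else:
        raise ValueError("order must be 1 or 2")

    # unadjusted scans share the centred trait matrix across hypotheses
    shared = designs is None
    if shared:
        Yt0 = Y - Y.mean(axis=0, keepdims=True)
        yss0 = (Yt0 * Yt0).sum(axis=0)
        df0 = n - 2

    out = np.empty((len(hypotheses), Y.shape[1]))
    for i, hyp in enumerate(hypotheses):
        ci = cell_of(hyp)
        M = onehot[ci]
        sizes = np.bincount(ci, minlength=k)
        if shared:
            # R = M - column means; G has the closed form diag(N) - N N'/n
            A = M.T @ Yt0
            G = np.diag(sizes.astype(float)) - np.outer(sizes, sizes) / n
            out[i] = _mdr_statistics(A, G, yss0, sizes, n, df0, settings)
        else:
            D = designs(hyp)
            q = 0 if D is None else D.shape[1]
            X = np.ones((n, 1)) if q == 0 else np.column_stack([np.ones(n), D])
            Qx = orthonormal_basis(X)
            df = n - q - 2
            Yt = _residualise(Y, Qx)
            R = _residualise(M, Qx)
            A = R.T @ Yt
            G = R.T @ R
            yss = (Yt * Yt).sum(axis=0)
            out[i] = _mdr_statistics(A, G, yss, sizes, n, df, settings)
    return out
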