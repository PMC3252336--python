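"""Lower-order (main) effect screening and adjustment strategies.

Two families of corrections are supported, mirroring how practitioners
handle confounding main effects in epistasis screening:

* residual-based: select SNPs with apparent main effects (permutation-
  corrected significance, raw-p significance, top-k ranking, or stepwise
  AIC search), regress the trait on their coded columns, and hand the
  residuals to the epistasis scan as a new trait;
* on-the-fly: keep the original trait but enter coded SNP columns as
  covariates inside every MB-MDR cell test (always the pair under
  investigation, or only pair members flagged by a prior one-locus scan).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import engine
from .core import maxt_adjust, permutation_indices
from .data import (
    AdjustmentPolicy,
    CodingScheme,
    GenotypeMatrix,
    Trait,
    encode,
    pair_design,
)


@dataclass(frozen=True)
class MainEffectScan:
    """Per-SNP single-locus regression scan (overall F for the coded columns)."""

    snp_ids: tuple[str, ...]
    statistic: np.ndarray       # F, >= 0; 0 for monomorphic SNPs
    p_raw: np.ndarray
    p_adjusted: np.ndarray | None = None  # step-down maxT, if computed


@dataclass(frozen=True)
class SelectionResult:
    method: str
    snp_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate SNPs in selection")

    @property
    def is_empty(self) -> bool:
        return not self.snp_ids


def _snp_bases(
    genotypes: GenotypeMatrix, coding: CodingScheme
) -> list[np.ndarray]:
    """Per SNP, orthonormal basis of its centred coded columns."""
    bases = []
    for j in range(genotypes.n_snps):
        C = encode(genotypes.values[:, j], coding)
        C = C - C.mean(axis=0, keepdims=True)
        bases.append(engine.orthonormal_basis(C))
    return bases


def main_effect_f_matrix(
    genotypes: GenotypeMatrix, Y: np.ndarray, coding: CodingScheme
) -> tuple[np.ndarray, np.ndarray]:
    """F statistics of every SNP for every trait column.

    Returns (F, dfn) with F of shape (n_snps, n_columns) and dfn the
    per-SNP numerator degrees of freedom (0 for monomorphic SNPs).
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = Y.shape[0]
    Yc = Y - Y.mean(axis=0, keepdims=True)
    yss = (Yc * Yc).sum(axis=0)
    F = np.zeros((genotypes.n_snps, Y.shape[1]))
    dfn = np.zeros(genotypes.n_snps, dtype=int)
    for j, Q in enumerate(_snp_bases(genotypes, coding)):
        p = Q.shape[1]
        dfn[j] = p
        if p == 0:
            continue  # monomorphic: no information
        proj = Q.T @ Yc
        ess = (proj * proj).sum(axis=0)
        rss = np.maximum(yss - ess, 0.0)
        dfd = n - p - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ess / p) / (rss / dfd)
        F[j] = np.where(rss > 0, f, np.inf)
    return F, dfn


def single_snp_scan(
    trait: Trait, genotypes: GenotypeMatrix, coding: CodingScheme
) -> MainEffectScan:
    """OLS of the trait on each SNP separately; overall F of the coded columns.

    Under additive coding the 1-df F is the squared slope t. Monomorphic
    SNPs carry no information and get F = 0, p = 1.
    """
    F, dfn = main_effect_f_matrix(genotypes, trait.values, coding)
    F = F[:, 0]
    n = trait.n_samples
    p_raw = np.ones_like(F)
    for j in range(F.size):
        if dfn[j] > 0:
            p_raw[j] = float(stats.f.sf(F[j], dfn[j], n - dfn[j] - 1))
    return MainEffectScan(genotypes.snp_ids, F, p_raw)


def select_snps(
    scan: MainEffectScan,
    method: str,
    *,
    k: int = 10,
    alpha: float = 0.05,
    permutations: int = 999,
    seed: int | np.random.SeedSequence = 0,
    trait: Trait | None = None,
    genotypes: GenotypeMatrix | None = None,
    coding: CodingScheme | None = None,
) -> SelectionResult:
    """Pick SNPs to adjust for, by one of the single-regression criteria.

    sr_perm needs ``trait``/``genotypes``/``coding`` to rerun the F scan on
    permuted traits; the permutation null calibrates the F statistics, so
    additive (1 df) and codominant (2 df) scans are handled uniformly.
    """
    ids = np.asarray(scan.snp_ids)
    if method == "sr_alpha":
        chosen = ids[scan.p_raw < alpha]
    elif method == "sr_topk":
        if not 1 <= k <= ids.size:
            raise ValueError("k out of range")
        order = np.argsort(scan.p_raw, kind="stable")
        chosen = ids[np.sort(order[:k])]
    elif method == "sr_perm":
        if trait is None or genotypes is None or coding is None:
            raise ValueError("sr_perm needs trait, genotypes and coding")
        perms = permutation_indices(trait.n_samples, permutations, seed)
        Fp, _ = main_effect_f_matrix(genotypes, trait.values[perms.T], coding)
        p_adj = maxt_adjust(scan.statistic, Fp)
        object.__setattr__(scan, "p_adjusted", p_adj)
        chosen = ids[p_adj < alpha]
    else:
        raise ValueError(f"unknown selection method {method!r}")
    return SelectionResult(method, tuple(chosen))


def _gaussian_aic(rss: float, n: int, n_params: int) -> float:
    # up to the shared additive constant n*(ln(2*pi) + 1)
    return n * np.log(max(rss, 1e-300) / n) + 2.0 * n_params


def stepwise_aic_select(
    trait: Trait,
    genotypes: GenotypeMatrix,
    coding: CodingScheme,
    start: str = "null",
    max_steps: int = 1000,
) -> SelectionResult:
    """Bidirectional stepwise SNP selection minimising Gaussian AIC.

    SNPs enter and leave as blocks (all coded columns of a SNP move as a
    unit). Starting from the intercept-only model (or the full model with
    ``start='full'``), each iteration applies the single add-or-drop move
    that most decreases AIC and stops when no move improves it.
    """
    if start not in ("null", "full"):
        raise ValueError("start must be 'null' or 'full'")
    y = trait.values
    n = y.size
    m = genotypes.n_snps
    blocks = [encode(genotypes.values[:, j], coding) for j in range(m)]

    def fit_rss(members: frozenset[int]) -> tuple[float, int]:
        cols = [blocks[j] for j in sorted(members)]
        X = np.column_stack([np.ones(n)] + cols) if cols else np.ones((n, 1))
        Q = engine.orthonormal_basis(X)
        resid = y - Q @ (Q.T @ y)
        return float(resid @ resid), Q.shape[1]

    current = frozenset(range(m)) if start == "full" else frozenset()
    rss, n_params = fit_rss(current)
    current_aic = _gaussian_aic(rss, n, n_params)
    cache: dict[frozenset, float] = {current: current_aic}

    for _ in range(max_steps):
        best_aic, best_set = current_aic, None
        moves = [current | {j} for j in range(m) if j not in current]
        moves += [current - {j} for j in current]
        for cand in moves:
            if cand not in cache:
                r, p = fit_rss(cand)
                cache[cand] = _gaussian_aic(r, n, p)
            if cache[cand] < best_aic - 1e-12:
                best_aic, best_set = cache[cand], cand
        if best_set is None:
            break
        current, current_aic = best_set, best_aic
    return SelectionResult(
        "mr_aic", tuple(genotypes.snp_ids[j] for j in sorted(current))
    )


def residualize(
    trait: Trait,
    genotypes: GenotypeMatrix,
    selection: SelectionResult,
    coding: CodingScheme,
) -> Trait:
    """Replace the trait by its OLS residuals on the selected SNPs' columns.

    An empty selection returns the trait unchanged (the original trait is
    submitted to the epistasis scan). Rank-deficient designs drop dependent
    columns with a warning.
    """
    if selection.is_empty:
        return trait
    D = pair_design(genotypes, selection.snp_ids, coding)
    X = np.column_stack([np.ones(trait.n_samples), D])
    Q = engine.orthonormal_basis(X)
    if Q.shape[1] < X.shape[1]:
        warnings.warn(
            "rank-deficient adjustment design; dependent columns dropped",
            RuntimeWarning,
            stacklevel=2,
        )
    resid = trait.values - Q @ (Q.T @ trait.values)
    return trait.with_values(resid)


def resolve_adjust_design(
    policy: AdjustmentPolicy,
    pair: tuple[int, int],
    significant: frozenset[int],
    genotypes: GenotypeMatrix,
) -> np.ndarray | None:
    """Covariate matrix entering the cell tests of one pair (None if empty).

    pair_always adjusts for both pair members unconditionally; the
    significance-gated selectors adjust only for pair members in the
    precomputed significant set — neither, one, or both, as the case may be.
    """
    if policy.kind != "on_the_fly":
        return None
    if policy.selector == "pair_always":
        members = pair
    else:  # one_d_significant / list_significant
        members = tuple(s for s in pair if s in significant)
    if not members:
        return None
    return pair_design(genotypes, members, policy.coding)
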