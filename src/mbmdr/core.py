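"""MB-MDR steps 1-3 for a single SNP pair, plus step-down maxT adjustment.

The two-locus MB-MDR procedure:

1. Partition samples into the 9 two-locus genotype cells. For each cell of
   sufficient size, test the cell against all remaining samples (Student
   t-test, or a Wald test on the cell indicator when main-effect covariates
   are adjusted for on the fly).
2. Label each cell H(igh) / L(ow) when the step-1 test is significant at
   ``alpha1`` with positive / negative sign, O (no evidence) otherwise.
   The pair statistic is the larger of the H-versus-rest and L-versus-rest
   test statistics (0 when a side has no labelled cells).
3. Assess overall significance of the whole scan by permutation-based
   step-down maxT, which controls the familywise error rate.

The functions here are the readable single-pair reference path; the
vectorised scan used for full studies lives in :mod:`mbmdr.engine` and is
tested element-for-element against these.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .data import AdjustmentPolicy, GenotypeMatrix, NO_ADJUSTMENT, Trait


@dataclass(frozen=True)
class ScanSettings:
    """Tuning parameters of an MB-MDR scan.

    alpha1
        Significance level of the step-1 cell tests (H/L/O labelling).
    min_cell
        Minimum cell size for a cell to be testable; smaller cells are
        labelled O outright. Cells leaving fewer than ``min_cell`` samples
        in the comparison group are likewise untestable.
    permutations
        Number of trait permutations B for maxT; adjusted p-values live on
        the grid k/(B+1).
    """

    alpha1: float = 0.1
    min_cell: int = 10
    permutations: int = 999
    seed: int = 0
    policy: AdjustmentPolicy = NO_ADJUSTMENT

    def __post_init__(self) -> None:
        if not 0 < self.alpha1 < 1:
            raise ValueError("alpha1 must be in (0, 1)")
        if self.min_cell < 2:
            raise ValueError("min_cell must be >= 2")
        if self.permutations < 19:
            raise ValueError("need at least 19 permutations")


@dataclass(frozen=True)
class CellPartition:
    """Assignment of samples to the 9 two-locus genotype cells."""

    pair: tuple[int, int]
    cell_index: np.ndarray  # length n, values 0..8 (3*g_a + g_b)
    cell_sizes: np.ndarray  # length 9, sums to n

    @property
    def n_samples(self) -> int:
        return int(self.cell_sizes.sum())


@dataclass(frozen=True)
class HLOLabels:
    """Step-1/2 classification of the 9 cells into H / L / O."""

    labels: np.ndarray          # length 9, dtype '<U1'
    step1_stats: np.ndarray     # signed statistics, 0.0 for untested cells
    step1_pvalues: np.ndarray   # NaN for untested cells

    @property
    def h_cells(self) -> np.ndarray:
        return self.labels == "H"

    @property
    def l_cells(self) -> np.ndarray:
        return self.labels == "L"


@dataclass(frozen=True)
class PairResult:
    snp_a: str
    snp_b: str
    statistic: float
    p_adjusted: float


def partition_pair(genotypes: GenotypeMatrix, a: int, b: int) -> CellPartition:
    """Partition samples by the two-locus genotype (cell = 3*g_a + g_b)."""
    if a == b:
        raise ValueError("a pair needs two distinct SNPs")
    g_a = genotypes.values[:, a].astype(np.intp)
    g_b = genotypes.values[:, b].astype(np.intp)
    cell_index = 3 * g_a + g_b
    return CellPartition(
        pair=(a, b),
        cell_index=cell_index,
        cell_sizes=np.bincount(cell_index, minlength=9),
    )


def association_test(
    trait: Trait,
    indicator: np.ndarray,
    adjust_design: np.ndarray | None = None,
) -> tuple[float, float, int]:
    """Test a 0/1 group indicator against the trait.

    Without covariates this is the classical pooled-variance Student t-test
    (group 1 = indicator 1), df = n - 2. With a non-empty ``adjust_design``
    it is the Wald t of the indicator coefficient in an OLS fit of the trait
    on intercept + design + indicator, df = n - q - 2. The two coincide for
    q = 0, which keeps unadjusted and adjusted scans on one formula.

    Returns (signed statistic, two-sided p, df). A zero-residual-variance
    fit returns p = 0 with a warning (degenerate, but scans must not abort).
    """
    y = trait.values
    ind = np.asarray(indicator, dtype=float).ravel()
    n = y.size
    if ind.size != n:
        raise ValueError("indicator length does not match trait")
    if adjust_design is None or adjust_design.size == 0:
        q = 0
        X = np.column_stack([np.ones(n), ind])
    else:
        D = np.asarray(adjust_design, dtype=float)
        q = D.shape[1]
        X = np.column_stack([np.ones(n), D, ind])
    df = n - q - 2
    if df <= 0:
        raise ValueError("not enough samples for the requested adjustment")
    XtX = X.T @ X
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError:
        # collinear design (e.g. indicator in span of covariates): no test
        return 0.0, 1.0, df
    beta = XtX_inv @ (X.T @ y)
    rss = float(y @ y - beta @ (X.T @ y))
    rss = max(rss, 0.0)
    var_last = XtX_inv[-1, -1]
    if var_last <= 0:
        return 0.0, 1.0, df
    denom = np.sqrt(rss / df * var_last)
    if denom == 0.0:
        if abs(beta[-1]) <= 1e-10:
            return 0.0, 1.0, df  # e.g. constant trait: no evidence
        warnings.warn(
            "zero residual variance in association test; p set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return float(np.sign(beta[-1]) * np.inf), 0.0, df
    t = float(beta[-1] / denom)
    p = float(2.0 * stats.t.sf(abs(t), df))
    return t, p, df


def hlo_classify(
    partition: CellPartition,
    trait: Trait,
    adjust_design: np.ndarray | None,
    settings: ScanSettings,
) -> HLOLabels:
    """Label the 9 cells H / L / O from cell-versus-rest tests at alpha1."""
    n = partition.n_samples
    labels = np.full(9, "O", dtype="<U1")
    t_stats = np.zeros(9)
    pvals = np.full(9, np.nan)
    for c in range(9):
        size = int(partition.cell_sizes[c])
        if size < settings.min_cell or size > n - settings.min_cell:
            continue
        indicator = (partition.cell_index == c).astype(float)
        t, p, _ = association_test(trait, indicator, adjust_design)
        t_stats[c], pvals[c] = t, p
        if p < settings.alpha1:
            labels[c] = "H" if t > 0 else "L"
    return HLOLabels(labels=labels, step1_stats=t_stats, step1_pvalues=pvals)


def pair_statistic(
    labels: HLOLabels,
    partition: CellPartition,
    trait: Trait,
    adjust_design: np.ndarray | None = None,
) -> float:
    """Step-2 statistic: max of the H-vs-rest and L-vs-rest tests, >= 0."""
    t_h = 0.0
    if labels.h_cells.any():
        ind = labels.h_cells[partition.cell_index].astype(float)
        t_h, _, _ = association_test(trait, ind, adjust_design)
    t_l = 0.0
    if labels.l_cells.any():
        ind = labels.l_cells[partition.cell_index].astype(float)
        t, _, _ = association_test(trait, ind, adjust_design)
        t_l = -t
    return max(t_h, t_l, 0.0)


def pair_statistic_from_scratch(
    genotypes: GenotypeMatrix,
    trait: Trait,
    a: int,
    b: int,
    settings: ScanSettings,
    adjust_design: np.ndarray | None = None,
) -> float:
    """Steps 1-2 for one pair on one trait vector (reference path)."""
    part = partition_pair(genotypes, a, b)
    labels = hlo_classify(part, trait, adjust_design, settings)
    return pair_statistic(labels, part, trait, adjust_design)


# ---------------------------------------------------------------------------
# step-down maxT


def maxt_adjust(
    observed: np.ndarray,
    perm_stats: np.ndarray,
) -> np.ndarray:
    """Westfall-Young free step-down maxT adjusted p-values.

    Parameters
    ----------
    observed : (m,) statistics of the m hypotheses on the original trait.
    perm_stats : (m, B) the same statistics on B permuted traits; each
        column must come from one joint permutation of the trait so that the
        dependence between hypotheses is preserved.

    Hypotheses are ranked by decreasing observed statistic (ties broken by
    original order, so results are reproducible). Within each permutation,
    successive maxima are taken from the bottom of the ranking upward; the
    adjusted p for rank i is (1 + #{b : u_i^b >= T_(i)}) / (B + 1), then
    monotonicity is enforced down the ranking.
    """
    observed = np.asarray(observed, dtype=float)
    perm_stats = np.asarray(perm_stats, dtype=float)
    m = observed.size
    if perm_stats.shape[0] != m:
        raise ValueError("permutation statistics have wrong first dimension")
    B = perm_stats.shape[1]
    order = np.argsort(-observed, kind="stable")  # rank 0 = largest
    sorted_obs = observed[order]
    # successive maxima from the smallest-ranked statistic upward
    u = perm_stats[order][::-1]          # reversed: rank m-1 first
    u = np.maximum.accumulate(u, axis=0)[::-1]
    exceed = (u >= sorted_obs[:, None]).sum(axis=1)
    p_sorted = (1.0 + exceed) / (B + 1.0)
    p_sorted = np.maximum.accumulate(p_sorted)  # monotone down the ranking
    p_adj = np.empty(m)
    p_adj[order] = p_sorted
    return p_adj


def permutation_indices(
    n: int, B: int, seed: int | np.random.SeedSequence
) -> np.ndarray:
    """(B, n) array of trait permutations, one reproducible substream each."""
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(int(seed))
    children = ss.spawn(B)
    out = np.empty((B, n), dtype=np.intp)
    for b, child in enumerate(children):
        out[b] = np.random.default_rng(child).permutation(n)
    return out


def iter_pairs(m: int):
    """Lexicographic (a, b) pairs with a < b."""
    for a in range(m - 1):
        for b in range(a + 1, m):
            yield a, b
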