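"""Model/results interface for MB-MDR epistasis and single-locus scans.

`MBMDRScan` is built from a trait and a genotype matrix (statsmodels
style); `fit()` executes steps 1-3 — including whichever lower-order
adjustment the policy requests — and returns an `MBMDRResults` object
carrying the pair statistics, maxT-adjusted p-values and a summary table.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from . import adjust as _adj
from . import engine
from .core import (
    PairResult,
    ScanSettings,
    iter_pairs,
    maxt_adjust,
    permutation_indices,
)
from .data import (
    AdjustmentPolicy,
    GenotypeMatrix,
    NO_ADJUSTMENT,
    Trait,
    check_aligned,
    save_results,
)

FWER_LEVEL = 0.05  # familywise significance level used throughout


class MBMDRScan:
    """Quantitative-trait MB-MDR scan of all SNP pairs (or single loci).

    Parameters
    ----------
    trait, genotypes
        Aligned phenotype and minor-allele-count data.
    policy
        Lower-order effect handling; default is no adjustment.
    alpha1, min_cell
        Step-1 cell-test level and minimum testable cell size.
    order
        2 = pairwise epistasis scan (the default), 1 = single-locus scan.

    Examples
    --------
    >>> res = MBMDRScan(trait, genotypes).fit(permutations=999, seed=7)
    >>> res.significant_pairs()
    """

    def __init__(
        self,
        trait: Trait,
        genotypes: GenotypeMatrix,
        policy: AdjustmentPolicy = NO_ADJUSTMENT,
        alpha1: float = 0.1,
        min_cell: int = 10,
        order: int = 2,
    ) -> None:
        check_aligned(genotypes, trait)
        if order == 2 and genotypes.n_snps < 2:
            raise ValueError("pairwise scan needs at least 2 SNPs")
        self.trait = trait
        self.genotypes = genotypes
        self.policy = policy
        self.alpha1 = alpha1
        self.min_cell = min_cell
        self.order = order

    # -- policy resolution --------------------------------------------------

    def _resolve_policy(
        self, settings: ScanSettings, ss: np.random.SeedSequence
    ) -> tuple[Trait, Callable | None, _adj.SelectionResult | None, frozenset[int]]:
        """Working trait, per-pair design resolver, selection, significant set."""
        pol = self.policy
        if pol.kind == "none":
            return self.trait, None, None, frozenset()

        if pol.kind == "residual":
            if pol.selector == "mr_aic":
                sel = _adj.stepwise_aic_select(self.trait, self.genotypes, pol.coding)
            else:
                scan = _adj.single_snp_scan(self.trait, self.genotypes, pol.coding)
                sel = _adj.select_snps(
                    scan,
                    pol.selector,
                    k=pol.k,
                    alpha=FWER_LEVEL,
                    permutations=settings.permutations,
                    seed=ss,
                    trait=self.trait,
                    genotypes=self.genotypes,
                    coding=pol.coding,
                )
            working = _adj.residualize(self.trait, self.genotypes, sel, pol.coding)
            return working, None, sel, frozenset()

        # on-the-fly: significant set fixed per dataset, then per-pair designs
        if pol.selector == "one_d_significant":
            one_d = MBMDRScan(
                self.trait,
                self.genotypes,
                alpha1=self.alpha1,
                min_cell=self.min_cell,
                order=1,
            ).fit(permutations=settings.permutations, seed=ss)
            sig = frozenset(np.flatnonzero(one_d.p_adjusted <= FWER_LEVEL).tolist())
            sel = _adj.SelectionResult(
                "one_d_significant",
                tuple(self.genotypes.snp_ids[j] for j in sorted(sig)),
            )
        elif pol.selector == "list_significant":
            scan = _adj.single_snp_scan(self.trait, self.genotypes, pol.coding)
            sel = _adj.select_snps(
                scan,
                "sr_perm",
                alpha=FWER_LEVEL,
                permutations=settings.permutations,
                seed=ss,
                trait=self.trait,
                genotypes=self.genotypes,
                coding=pol.coding,
            )
            sig = frozenset(self.genotypes.index_of(s) for s in sel.snp_ids)
        else:  # pair_always
            sel, sig = None, frozenset()

        def designs(pair):
            return _adj.resolve_adjust_design(pol, pair, sig, self.genotypes)

        return self.trait, designs, sel, sig

    # -- fitting ------------------------------------------------------------

    def fit(
        self, permutations: int = 999, seed: int | np.random.SeedSequence = 0
    ) -> "MBMDRResults":
        """Run steps 1-3 and return results with maxT-adjusted p-values."""
        settings = ScanSettings(
            alpha1=self.alpha1,
            min_cell=self.min_cell,
            permutations=permutations,
            seed=seed if isinstance(seed, int) else 0,
            policy=self.policy,
        )
        t0 = time.perf_counter()
        ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(int(seed))
        ss_select, ss_perm = ss.spawn(2)
        working, designs, selection, sig = self._resolve_policy(settings, ss_select)

        n = working.n_samples
        perms = permutation_indices(n, permutations, ss_perm)
        Y = np.empty((n, permutations + 1))
        Y[:, 0] = working.values
        Y[:, 1:] = working.values[perms.T]

        stats_matrix = engine.scan_matrix(
            self.genotypes, Y, settings, designs, order=self.order
        )
        observed = stats_matrix[:, 0]
        p_adj = maxt_adjust(observed, stats_matrix[:, 1:])
        return MBMDRResults(
            model=self,
            settings=settings,
            statistics=observed,
            p_adjusted=p_adj,
            selection=selection,
            significant_snp_set=sig,
            working_trait=working,
            wall_time=time.perf_counter() - t0,
        )

    def statistics_for_trait_matrix(
        self, Y: np.ndarray, permutations: int = 999, seed: int = 0
    ) -> np.ndarray:
        """Steps 1-2 statistics for explicit trait columns (no maxT).

        Exposed for oracle-style testing; `fit` is the normal entry point.
        """
        settings = ScanSettings(
            alpha1=self.alpha1, min_cell=self.min_cell,
            permutations=permutations, seed=seed, policy=self.policy,
        )
        ss = np.random.SeedSequence(seed)
        _, designs, _, _ = self._resolve_policy(settings, ss)
        return engine.scan_matrix(self.genotypes, Y, settings, designs, order=self.order)


@dataclass
class MBMDRResults:
    """Fitted MB-MDR scan: statistics, adjusted p-values, diagnostics."""

    model: MBMDRScan
    settings: ScanSettings
    statistics: np.ndarray
    p_adjusted: np.ndarray
    selection: _adj.SelectionResult | None
    significant_snp_set: frozenset[int]
    working_trait: Trait
    wall_time: float

    @property
    def hypothesis_ids(self) -> list[tuple[str, str]] | list[str]:
        ids = self.model.genotypes.snp_ids
        if self.model.order == 1:
            return list(ids)
        return [(ids[a], ids[b]) for a, b in iter_pairs(len(ids))]

    @property
    def frame(self) -> pd.DataFrame:
        if self.model.order == 1:
            return pd.DataFrame(
                {
                    "snp": self.hypothesis_ids,
                    "statistic": self.statistics,
                    "p_adjusted": self.p_adjusted,
                }
            )
        pairs = self.hypothesis_ids
        return pd.DataFrame(
            {
                "snp_a": [p[0] for p in pairs],
                "snp_b": [p[1] for p in pairs],
                "statistic": self.statistics,
                "p_adjusted": self.p_adjusted,
            }
        )

    def significant_pairs(self, alpha: float = FWER_LEVEL) -> set[tuple[str, str]]:
        if self.model.order == 1:
            raise ValueError("single-locus results: use significant_snps()")
        pairs = self.hypothesis_ids
        return {pairs[i] for i in np.flatnonzero(self.p_adjusted <= alpha)}

    def significant_snps(self, alpha: float = FWER_LEVEL) -> set[str]:
        if self.model.order == 2:
            raise ValueError("pairwise results: use significant_pairs()")
        ids = self.hypothesis_ids
        return {ids[i] for i in np.flatnonzero(self.p_adjusted <= alpha)}

    def pair_results(self) -> list[PairResult]:
        if self.model.order == 1:
            raise ValueError("single-locus results have no pairs")
        return [
            PairResult(p[0], p[1], float(s), float(q))
            for p, s, q in zip(self.hypothesis_ids, self.statistics, self.p_adjusted)
        ]

    def save(self, path) -> None:
        save_results(self.frame, path)

    def summary(self, top: int = 10) -> str:
        g = self.model.genotypes
        pol = self.model.policy
        kind = "pairs" if self.model.order == 2 else "SNPs"
        lines = [
            "MB-MDR scan results",
            "=" * 60,
            f"samples: {g.n_samples}    SNPs: {g.n_snps}    "
            f"hypotheses ({kind}): {len(self.statistics)}",
            f"adjustment: {pol.kind}/{pol.selector}  coding: {pol.coding.name}",
            f"alpha1: {self.settings.alpha1}  min cell: {self.settings.min_cell}  "
            f"permutations: {self.settings.permutations}",
            f"wall time: {self.wall_time:.2f} s",
        ]
        if self.selection is not None:
            shown = ", ".join(self.selection.snp_ids) or "(none)"
            lines.append(f"adjusted-for SNPs [{self.selection.method}]: {shown}")
        lines.append("-" * 60)
        df = self.frame.sort_values(
            ["p_adjusted", "statistic"], ascending=[True, False], kind="stable"
        ).head(top)
        lines.append(df.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
        n_sig = int((self.p_adjusted <= FWER_LEVEL).sum())
        lines.append("-" * 60)
        lines.append(f"significant at FWER {FWER_LEVEL}: {n_sig}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional wrappers


def scan_pairs(
    genotypes: GenotypeMatrix, trait: Trait, settings: ScanSettings
) -> np.ndarray:
    """Steps 1-2 statistics for all pairs on the observed trait only."""
    model = MBMDRScan(
        trait, genotypes, policy=settings.policy,
        alpha1=settings.alpha1, min_cell=settings.min_cell,
    )
    ss = np.random.SeedSequence(settings.seed)
    working, designs, _, _ = model._resolve_policy(settings, ss.spawn(1)[0])
    return engine.scan_matrix(
        genotypes, working.values[:, None], settings, designs, order=2
    )[:, 0]


def run_epistasis_scan(
    genotypes: GenotypeMatrix, trait: Trait, settings: ScanSettings
) -> list[PairResult]:
    """Full pairwise scan with maxT adjustment (steps 1-3)."""
    res = MBMDRScan(
        trait, genotypes, policy=settings.policy,
        alpha1=settings.alpha1, min_cell=settings.min_cell,
    ).fit(permutations=settings.permutations, seed=settings.seed)
    return res.pair_results()


def run_1d_scan(
    genotypes: GenotypeMatrix, trait: Trait, settings: ScanSettings
) -> pd.DataFrame:
    """Single-locus MB-MDR scan (3 genotype cells per SNP) with maxT."""
    res = MBMDRScan(
        trait, genotypes, alpha1=settings.alpha1, min_cell=settings.min_cell, order=1
    ).fit(permutations=settings.permutations, seed=settings.seed)
    return res.frame
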