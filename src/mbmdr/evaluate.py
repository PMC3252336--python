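"""Replicate-level aggregation: power, familywise error, false-positive rates.

A replicate outcome is the set of SNP pairs a scan declared significant
(adjusted p <= 0.05) together with the ground truth of the simulated
dataset. Across replicates these are summarised into

* power — fraction of replicates detecting the causal pair (SNP1, SNP2);
* fp_any — fraction with at least one significant pair other than the
  causal one (under the null scenarios every pair counts, which is the
  familywise type-I error);
* pairings with the main-effect loci — fractions of replicates where
  SNP3 pairs with something other than SNP4, where the specific
  (SNP3, SNP4) pair is significant, and where SNP4 pairs with something
  other than SNP3. These isolate the failure mode in which a residual
  main-effect signal masquerades as epistasis.

Bradley's liberal robustness criterion judges an empirical type-I rate
adequate when it falls inside the open interval (alpha/2, 3*alpha/2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data import AdjustmentPolicy, NO_ADJUSTMENT
from .model import FWER_LEVEL, MBMDRScan
from .simulate import SimulationConfig, TruthRecord, simulate_study


@dataclass(frozen=True)
class ReplicateOutcome:
    replicate: int
    significant_pairs: frozenset[tuple[str, str]]
    truth: TruthRecord

    def __post_init__(self) -> None:
        # store pairs orientation-free
        norm = frozenset(tuple(sorted(p)) for p in self.significant_pairs)
        object.__setattr__(self, "significant_pairs", norm)


@dataclass(frozen=True)
class OutcomeFlags:
    causal: bool
    any_noncausal: bool
    snp3_other: bool
    snp3_snp4: bool
    snp4_other: bool


def classify_outcome(outcome: ReplicateOutcome) -> OutcomeFlags:
    """Indicators for one replicate (see module docstring for definitions)."""
    t = outcome.truth
    causal = tuple(sorted((t.snp1, t.snp2)))
    s34 = tuple(sorted((t.snp3, t.snp4)))
    pairs = outcome.significant_pairs
    is_null = t.scenario != "alternative"
    causal_hit = (not is_null) and causal in pairs
    noncausal = pairs if is_null else pairs - {causal}
    return OutcomeFlags(
        causal=causal_hit,
        any_noncausal=bool(noncausal),
        snp3_other=any(
            t.snp3 in p and p != s34 for p in pairs
        ),
        snp3_snp4=s34 in pairs,
        snp4_other=any(
            t.snp4 in p and p != s34 for p in pairs
        ),
    )


@dataclass(frozen=True)
class StudySummary:
    replicates: int
    power: float
    fp_any: float
    fp_snp3_other: float
    fp_snp3_snp4: float
    fp_snp4_other: float

    def as_dict(self) -> dict:
        return {
            "replicates": self.replicates,
            "power": self.power,
            "fp_any": self.fp_any,
            "fp_snp3_other": self.fp_snp3_other,
            "fp_snp3_snp4": self.fp_snp3_snp4,
            "fp_snp4_other": self.fp_snp4_other,
        }


def summarize(outcomes: Sequence[ReplicateOutcome]) -> StudySummary:
    """Fractions of replicates with each event; order-invariant."""
    if not outcomes:
        raise ValueError("no outcomes to summarise")
    flags = [classify_outcome(o) for o in outcomes]
    mean = lambda attr: float(np.mean([getattr(f, attr) for f in flags]))
    return StudySummary(
        replicates=len(outcomes),
        power=mean("causal"),
        fp_any=mean("any_noncausal"),
        fp_snp3_other=mean("snp3_other"),
        fp_snp3_snp4=mean("snp3_snp4"),
        fp_snp4_other=mean("snp4_other"),
    )


def bradley_robust(rate: float, alpha: float = FWER_LEVEL) -> bool:
    """Liberal robustness: rate strictly inside (alpha/2, 3*alpha/2)."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be a fraction")
    lo, hi = alpha / 2.0, 1.5 * alpha
    # the interval is open: values at an endpoint (to rounding) are outside
    if math.isclose(rate, lo, rel_tol=1e-12) or math.isclose(rate, hi, rel_tol=1e-12):
        return False
    return lo < rate < hi


def run_study(
    config: SimulationConfig,
    policy: AdjustmentPolicy = NO_ADJUSTMENT,
    permutations: int = 999,
    alpha1: float = 0.1,
    min_cell: int = 10,
    alpha: float = FWER_LEVEL,
    progress=None,
) -> StudySummary:
    """simulate -> scan -> summarise for one simulation setting.

    Each replicate's scan derives its permutation stream from the replicate
    dataset seed, so individual replicates are reproducible in isolation.
    """
    outcomes = []
    for r, genotypes, trait, truth in simulate_study(config):
        scan_seed = np.random.SeedSequence([config.seed, r, 1])
        res = MBMDRScan(
            trait, genotypes, policy=policy, alpha1=alpha1, min_cell=min_cell
        ).fit(permutations=permutations, seed=scan_seed)
        outcomes.append(
            ReplicateOutcome(r, frozenset(res.significant_pairs(alpha)), truth)
        )
        if progress is not None:
            progress(r, config.replicates)
    return summarize(outcomes)


def study_frame(
    configs: Iterable[SimulationConfig],
    policy: AdjustmentPolicy = NO_ADJUSTMENT,
    **kwargs,
) -> pd.DataFrame:
    """Summaries for a grid of settings, one row per configuration."""
    rows = []
    for cfg in configs:
        summary = run_study(cfg, policy=policy, **kwargs)
        rows.append(
            {
                "scenario": cfg.scenario,
                "model": cfg.model,
                "maf": cfg.maf,
                "g2": cfg.g2,
                "policy": f"{policy.kind}/{policy.selector}",
                "coding": policy.coding.name,
                **summary.as_dict(),
                "bradley_ok": bradley_robust(summary.fp_any),
            }
        )
    return pd.DataFrame(rows)
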