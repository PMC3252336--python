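"""Two-locus quantitative-trait simulator and analytic variance decomposition.

The study design emulated here: n unrelated individuals typed at m SNPs in
Hardy-Weinberg and linkage equilibrium. Two functional SNPs (SNP1, SNP2,
shared minor allele frequency p) interact through a binary genotypic mean
pattern — model M27 (high mean iff at least one minor allele at both loci)
or M170 (high mean iff exactly one locus is heterozygous) — scaled so the
two-locus genetic variance equals a target broad-sense heritability g2.
Two further SNPs carry pure main effects: SNP3 additive and SNP4
over-dominant (advantageous heterozygous), with variances drawn from
U(0, 0.06). Remaining SNPs are noise with MAFs from U(0.05, 0.5).
Environmental noise tops total phenotypic variance up to 1.

Null scenarios: H01 keeps the SNP3/SNP4 main effects but removes the
two-locus effect (g2 = 0); H02 removes every genetic effect.

The variance decomposition is computed analytically (no simulation) from
the HWE cell probabilities: main effects are the per-locus variances of the
marginal genotype means, the additive part is the frequency-weighted
least-squares regression of those marginal means on allele count, dominance
is the remainder, and epistasis is total genetic minus main.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .data import GenotypeMatrix, Trait

MODEL_NAMES = ("M27", "M170")
SCENARIOS = ("alternative", "H01", "H02")

#: MAF grid and heritability grid of the simulation study
MAF_GRID = (0.1, 0.25, 0.5)
G2_GRID = (0.01, 0.02, 0.03, 0.05, 0.1)


def epistasis_pattern(name: str) -> np.ndarray:
    """3x3 binary mean pattern over (g1, g2); 0 = hom major, 2 = hom minor."""
    i, j = np.meshgrid(np.arange(3), np.arange(3), indexing="ij")
    if name == "M27":
        return ((i >= 1) & (j >= 1)).astype(float)
    if name == "M170":
        return ((i == 1) ^ (j == 1)).astype(float)
    raise ValueError(f"unknown epistasis model {name!r}")


def hwe_freqs(p: float) -> np.ndarray:
    """Genotype frequencies ((1-p)^2, 2p(1-p), p^2) under HWE."""
    if not 0.0 < p <= 0.5:
        raise ValueError("minor allele frequency must be in (0, 0.5]")
    return np.array([(1.0 - p) ** 2, 2.0 * p * (1.0 - p), p ** 2])


@dataclass(frozen=True)
class VarianceDecomposition:
    """Analytic variance components of a two-locus genotypic mean pattern.

    Ratios are NaN when their denominator is exactly zero (e.g. the M170
    pattern at MAF 0.5 has constant marginal means, so the main-effects
    variance vanishes and additive/dominance shares are undefined).
    """

    sigma2_gen: float
    sigma2_main: float
    sigma2_add: float
    sigma2_dom: float
    sigma2_epi: float

    def _ratio(self, num: float, den: float) -> float:
        return num / den if den > 1e-15 else float("nan")

    @property
    def main_over_gen(self) -> float:
        return self._ratio(self.sigma2_main, self.sigma2_gen)

    @property
    def add_over_main(self) -> float:
        return self._ratio(self.sigma2_add, self.sigma2_main)

    @property
    def dom_over_main(self) -> float:
        return self._ratio(self.sigma2_dom, self.sigma2_main)

    @property
    def epi_over_gen(self) -> float:
        return self._ratio(self.sigma2_epi, self.sigma2_gen)

    @property
    def degenerate(self) -> bool:
        return self.sigma2_gen <= 1e-15


def variance_components(pattern: np.ndarray, p: float) -> VarianceDecomposition:
    """Decompose a 3x3 genotypic mean pattern at shared MAF p (HWE + LE)."""
    pattern = np.asarray(pattern, dtype=float)
    if pattern.shape != (3, 3):
        raise ValueError("pattern must be 3x3")
    f = hwe_freqs(p)
    joint = np.outer(f, f)
    mu = float((joint * pattern).sum())
    sigma2_gen = float((joint * (pattern - mu) ** 2).sum())
    g = np.arange(3, dtype=float)
    mean_g = float(f @ g)
    var_g = float(f @ g ** 2 - mean_g ** 2)
    sigma2_main = sigma2_add = 0.0
    marginals = (pattern @ f, pattern.T @ f)  # locus 1 then locus 2
    for m in marginals:
        mean_m = float(f @ m)
        sigma2_main += float(f @ (m - mean_m) ** 2)
        cov = float(f @ (g * m)) - mean_g * mean_m
        sigma2_add += cov ** 2 / var_g
    sigma2_dom = max(sigma2_main - sigma2_add, 0.0)
    sigma2_epi = max(sigma2_gen - sigma2_main, 0.0)
    return VarianceDecomposition(
        sigma2_gen=sigma2_gen,
        sigma2_main=sigma2_main,
        sigma2_add=sigma2_add,
        sigma2_dom=sigma2_dom,
        sigma2_epi=sigma2_epi,
    )


def pattern_variance(pattern: np.ndarray, p: float) -> float:
    """HWE + LE variance of the (unscaled) pattern values."""
    return variance_components(pattern, p).sigma2_gen


def scaled_offset(pattern: np.ndarray, p: float, g2: float) -> float:
    """Mean offset d such that d * pattern has genetic variance g2."""
    if g2 < 0:
        raise ValueError("g2 must be >= 0")
    if g2 == 0.0:
        return 0.0
    var_p = pattern_variance(pattern, p)
    if var_p <= 1e-15:
        raise ValueError("constant pattern cannot carry genetic variance")
    return float(np.sqrt(g2 / var_p))


def decomposition_table(models=MODEL_NAMES, mafs=MAF_GRID) -> pd.DataFrame:
    """Analytic main/additive/dominance/epistasis shares per model and MAF."""
    rows = []
    for name in models:
        pat = epistasis_pattern(name)
        for p in mafs:
            d = variance_components(pat, p)
            rows.append(
                {
                    "model": name,
                    "maf": p,
                    "main_over_gen": d.main_over_gen,
                    "add_over_main": d.add_over_main,
                    "dom_over_main": d.dom_over_main,
                    "epi_over_gen": d.epi_over_gen,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# replicate generation


@dataclass(frozen=True)
class SimulationConfig:
    """One simulation setting (model x MAF x heritability x scenario)."""

    scenario: str = "alternative"
    model: str = "M27"
    maf: float = 0.25              # shared MAF of SNP1 and SNP2
    g2: float = 0.0                # two-locus genetic variance target
    n_samples: int = 2000
    n_snps: int = 100
    replicates: int = 500
    seed: int = 0
    main_effect_var_max: float = 0.06   # sigma2_3, sigma2_4 ~ U(0, this)
    noise_maf_range: tuple[float, float] = (0.05, 0.5)

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.model not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.model!r}")
        if not 0.0 < self.maf <= 0.5:
            raise ValueError("maf must be in (0, 0.5]")
        if self.scenario != "alternative" and self.g2 != 0.0:
            raise ValueError("null scenarios require g2 = 0")
        if self.n_snps < 4:
            raise ValueError("need at least 4 SNPs (SNP1..SNP4)")
        if self.n_samples < 2 or self.replicates < 1:
            raise ValueError("invalid sample or replicate count")
        lo, hi = self.noise_maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError("noise MAF range must lie in (0, 0.5]")

    @property
    def snp_ids(self) -> tuple[str, ...]:
        return tuple(f"SNP{j + 1}" for j in range(self.n_snps))


@dataclass(frozen=True)
class TruthRecord:
    """Everything a replicate drew: functional loci and effect parameters."""

    replicate: int
    scenario: str
    model: str
    snp1: str
    snp2: str
    snp3: str
    snp4: str
    maf_pair: float
    g2: float
    d: float
    maf3: float
    maf4: float
    var3: float
    var4: float
    beta3: float
    beta4: float
    sigma2_env: float

    @property
    def causal_pair(self) -> tuple[str, str]:
        return (self.snp1, self.snp2)


def _replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    # independent, randomly-accessible substream per replicate
    return np.random.default_rng(np.random.SeedSequence([seed, replicate]))


def simulate_replicate(
    config: SimulationConfig, replicate: int
) -> tuple[GenotypeMatrix, Trait, TruthRecord]:
    """Draw one replicate dataset: genotypes, trait, and the ground truth."""
    rng = _replicate_rng(config.seed, replicate)
    n, m = config.n_samples, config.n_snps
    lo, hi = config.noise_maf_range

    null_pair = config.scenario in ("H01", "H02")
    null_all = config.scenario == "H02"

    # effect parameters ------------------------------------------------
    pat = epistasis_pattern(config.model)
    d = 0.0 if null_pair else scaled_offset(pat, config.maf, config.g2)
    maf3, maf4 = rng.uniform(lo, hi, size=2)
    if null_all:
        var3 = var4 = 0.0
    else:
        var3, var4 = rng.uniform(0.0, config.main_effect_var_max, size=2)
    g2_eff = 0.0 if null_pair else config.g2
    sigma2_env = 1.0 - g2_eff - var3 - var4
    if sigma2_env <= 0:
        raise ValueError("environmental variance non-positive; lower g2/var3/var4")
    beta3 = float(np.sqrt(var3 / (2.0 * maf3 * (1.0 - maf3))))
    q4 = 2.0 * maf4 * (1.0 - maf4)  # heterozygote frequency under HWE
    beta4 = float(np.sqrt(var4 / (q4 * (1.0 - q4))))

    # genotypes ----------------------------------------------------------
    mafs = np.empty(m)
    mafs[0] = mafs[1] = config.maf
    mafs[2], mafs[3] = maf3, maf4
    mafs[4:] = rng.uniform(lo, hi, size=m - 4)
    # allele-count draws: sum of two Bernoulli(maf) gametes per SNP
    geno = rng.binomial(2, mafs[None, :].repeat(n, axis=0)).astype(np.int8)
    ids = config.snp_ids
    samples = tuple(f"S{i + 1:04d}" for i in range(n))
    genotypes = GenotypeMatrix(geno, ids, samples)

    # trait --------------------------------------------------------------
    y = rng.normal(0.0, np.sqrt(sigma2_env), size=n)
    y += d * pat[geno[:, 0], geno[:, 1]]
    y += beta3 * geno[:, 2]
    y += beta4 * (geno[:, 3] == 1)
    trait = Trait(y, samples)

    truth = TruthRecord(
        replicate=replicate,
        scenario=config.scenario,
        model=config.model,
        snp1=ids[0],
        snp2=ids[1],
        snp3=ids[2],
        snp4=ids[3],
        maf_pair=config.maf,
        g2=g2_eff,
        d=d,
        maf3=float(maf3),
        maf4=float(maf4),
        var3=float(var3),
        var4=float(var4),
        beta3=beta3,
        beta4=beta4,
        sigma2_env=float(sigma2_env),
    )
    return genotypes, trait, truth


def simulate_study(
    config: SimulationConfig,
) -> Iterator[tuple[int, GenotypeMatrix, Trait, TruthRecord]]:
    """Yield the configured replicates; each is reproducible in isolation."""
    for r in range(config.replicates):
        genotypes, trait, truth = simulate_replicate(config, r)
        yield r, genotypes, trait, truth


def study_settings(
    models=MODEL_NAMES, mafs=MAF_GRID, g2s=G2_GRID, **overrides
) -> list[SimulationConfig]:
    """The full simulation grid: alternatives plus the H01/H02 nulls.

    2 models x 3 MAFs x 5 heritabilities = 30 alternative settings, plus
    H01 and H02 at each MAF — the 36 settings of the study design.
    """
    configs = [
        SimulationConfig(
            scenario="alternative", model=mod, maf=p, g2=g2, **overrides
        )
        for mod in models
        for p in mafs
        for g2 in g2s
    ]
    for scenario in ("H01", "H02"):
        for p in mafs:
            configs.append(
                SimulationConfig(scenario=scenario, model="M27", maf=p, **overrides)
            )
    return configs
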