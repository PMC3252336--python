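"""Domain containers and delimited-text I/O for genotype, trait and result data.

Genotypes are stored as minor-allele counts with the orientation fixed
throughout the package: 0 = homozygous major, 1 = heterozygote,
2 = homozygous minor. Missing genotypes are rejected rather than imputed —
a silently imputed cell would contaminate every downstream test statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A file or matrix violates the genotype/trait format contract."""


@dataclass(frozen=True)
class CodingScheme:
    """How a single SNP enters a regression design.

    ``additive`` contributes one column (the allele count itself);
    ``codominant`` contributes two indicator columns (het, hom-minor) that,
    with an intercept, span the full 3-level genotype factor.
    """

    name: str

    _N_COLUMNS = {"additive": 1, "codominant": 2}

    def __post_init__(self) -> None:
        if self.name not in self._N_COLUMNS:
            raise ValueError(f"unknown coding scheme {self.name!r}")

    @property
    def n_columns(self) -> int:
        return self._N_COLUMNS[self.name]


ADDITIVE = CodingScheme("additive")
CODOMINANT = CodingScheme("codominant")


def _as_coding(coding: "CodingScheme | str") -> CodingScheme:
    return coding if isinstance(coding, CodingScheme) else CodingScheme(coding)


@dataclass(frozen=True)
class AdjustmentPolicy:
    """How lower-order (main) effects are handled during an epistasis scan.

    kind
        ``none`` — no adjustment; ``residual`` — SNPs are selected and the
        trait is replaced by regression residuals before scanning;
        ``on_the_fly`` — coded SNP columns enter every cell-wise test as
        covariates (the t-test becomes a Wald test).
    selector
        Which SNPs to adjust for. Residual kind: ``sr_perm`` (maxT-significant
        single-SNP effects), ``sr_alpha`` (raw p < alpha), ``sr_topk``
        (k smallest raw p), ``mr_aic`` (stepwise AIC). On-the-fly kind:
        ``pair_always`` (both SNPs of the pair under investigation),
        ``one_d_significant`` (pair SNPs that a one-locus MB-MDR scan flags),
        ``list_significant`` (pair SNPs that a maxT single-SNP regression
        scan flags).
    """

    kind: str = "none"
    selector: str = "not_applicable"
    k: int = 10
    coding: CodingScheme = ADDITIVE

    _VALID = {
        "none": {"not_applicable"},
        "residual": {"sr_perm", "sr_alpha", "sr_topk", "mr_aic"},
        "on_the_fly": {"pair_always", "one_d_significant", "list_significant"},
    }

    def __post_init__(self) -> None:
        if self.kind not in self._VALID:
            raise ValueError(f"unknown adjustment kind {self.kind!r}")
        if self.selector not in self._VALID[self.kind]:
            raise ValueError(
                f"selector {self.selector!r} inconsistent with kind {self.kind!r}"
            )
        if self.selector == "sr_topk" and self.k < 1:
            raise ValueError("top-k selector needs k >= 1")


NO_ADJUSTMENT = AdjustmentPolicy()


def _check_unique(ids: Sequence[str], what: str) -> tuple[str, ...]:
    ids = tuple(str(i) for i in ids)
    if len(set(ids)) != len(ids):
        raise FormatError(f"duplicate {what} identifiers")
    return ids


@dataclass(frozen=True)
class GenotypeMatrix:
    """n_samples x n_snps matrix of minor-allele counts in {0, 1, 2}."""

    values: np.ndarray
    snp_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise FormatError("genotype values must be a 2-D matrix")
        if not np.issubdtype(values.dtype, np.integer):
            if np.any(values != np.floor(values)) or np.any(~np.isfinite(values)):
                raise FormatError("genotype values must be integers")
            values = values.astype(np.int8)
        bad = (values < 0) | (values > 2)
        if bad.any():
            r, c = map(int, np.argwhere(bad)[0])
            raise FormatError(
                f"genotype value {values[r, c]} at sample row {r}, SNP column {c} "
                "is not in {0,1,2}"
            )
        n, m = values.shape
        if n < 2 or m < 1:
            raise FormatError("need at least 2 samples and 1 SNP")
        object.__setattr__(self, "values", values.astype(np.int8))
        object.__setattr__(self, "snp_ids", _check_unique(self.snp_ids, "SNP"))
        object.__setattr__(self, "sample_ids", _check_unique(self.sample_ids, "sample"))
        if len(self.snp_ids) != m or len(self.sample_ids) != n:
            raise FormatError("identifier list lengths do not match matrix shape")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def column(self, snp: "int | str") -> np.ndarray:
        return self.values[:, self.index_of(snp)]

    def index_of(self, snp: "int | str") -> int:
        if isinstance(snp, str):
            return self.snp_ids.index(snp)
        return int(snp)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        return cls(df.to_numpy(), tuple(map(str, df.columns)), tuple(map(str, df.index)))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(),
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=list(self.snp_ids),
        )


@dataclass(frozen=True)
class Trait:
    """Quantitative trait vector aligned with a :class:`GenotypeMatrix`."""

    values: np.ndarray
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(values)):
            raise FormatError("trait contains non-finite values")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", _check_unique(self.sample_ids, "sample"))
        if len(self.sample_ids) != values.size:
            raise FormatError("trait length does not match sample ids")

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def is_constant(self) -> bool:
        return bool(np.ptp(self.values) == 0)

    def with_values(self, values: np.ndarray) -> "Trait":
        return Trait(values, self.sample_ids)


def check_aligned(genotypes: GenotypeMatrix, trait: Trait) -> None:
    if genotypes.sample_ids != trait.sample_ids:
        raise FormatError("genotype and trait sample identifiers do not align")


# ---------------------------------------------------------------------------
# encoding


def encode(genotype_column: np.ndarray, coding: "CodingScheme | str") -> np.ndarray:
    """Expand a {0,1,2} genotype vector into regression design columns.

    additive -> one column equal to the allele count; codominant -> two
    indicator columns [g == 1, g == 2].
    """
    coding = _as_coding(coding)
    g = np.asarray(genotype_column)
    if g.ndim != 1:
        raise FormatError("genotype column must be 1-D")
    if np.any((g < 0) | (g > 2)) or np.any(g != np.floor(g)):
        raise FormatError("genotype values must be integers in {0,1,2}")
    if coding.name == "additive":
        return g.astype(float)[:, None]
    return np.column_stack([(g == 1).astype(float), (g == 2).astype(float)])


def pair_design(
    genotypes: GenotypeMatrix,
    snps: Iterable["int | str"],
    coding: "CodingScheme | str",
) -> np.ndarray:
    """Concatenate coded columns of the given SNPs (n x q; q may be 0)."""
    cols = [encode(genotypes.column(s), coding) for s in snps]
    if not cols:
        return np.empty((genotypes.n_samples, 0))
    return np.hstack(cols)


# ---------------------------------------------------------------------------
# file I/O (plain TSV; simulated studies have no missing data)


def load_genotypes(path: "str | Path", dialect: str = "matrix_tsv") -> GenotypeMatrix:
    """Read a genotype matrix from delimited text.

    ``matrix_tsv``: tab-separated, header ``sample_id<TAB>snp...``, one row
    per sample. ``plink_raw_like``: same layout but any whitespace delimiter —
    a convenience reader for allele-count exports, not a full PLINK parser.
    """
    if dialect not in ("matrix_tsv", "plink_raw_like"):
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = "\t" if dialect == "matrix_tsv" else r"\s+"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.isna().any().any():
        raise FormatError(f"{path}: missing genotype values are not supported")
    try:
        return GenotypeMatrix.from_dataframe(df)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def save_genotypes(genotypes: GenotypeMatrix, path: "str | Path") -> None:
    genotypes.to_dataframe().to_csv(path, sep="\t")


def load_trait(path: "str | Path") -> Trait:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["sample_id", "trait"]:
        raise FormatError(f"{path}: expected columns sample_id, trait")
    if df["trait"].isna().any():
        raise FormatError(f"{path}: missing trait values are not supported")
    return Trait(df["trait"].to_numpy(float), tuple(df["sample_id"].astype(str)))


def save_trait(trait: Trait, path: "str | Path") -> None:
    pd.DataFrame({"sample_id": trait.sample_ids, "trait": trait.values}).to_csv(
        path, sep="\t", index=False
    )


def save_results(results: pd.DataFrame, path: "str | Path") -> None:
    """Write a pair-result table sorted by adjusted p then pair ids."""
    out = results.sort_values(
        ["p_adjusted", "snp_a", "snp_b"], kind="stable"
    ).reset_index(drop=True)
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def load_results(path: "str | Path") -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
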