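"""Core domain types and genotype I/O.

Genotypes are coded by minor-allele dosage: 0 = homozygous major,
1 = heterozygous, 2 = homozygous minor.  The phenotype is binary,
1 = case and 0 = control.  All SNP indices are 0-based internally;
user-facing reports always use SNP names.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CaseControlDataset",
    "SnpCombination",
    "ContingencyTable",
    "GenotypeParseError",
    "DatasetValidationError",
    "read_genotype_table",
    "write_genotype_table",
    "count_genotype_contingency",
    "combination_count",
]

_VALID_GENOTYPES = frozenset({0, 1, 2})


class GenotypeParseError(ValueError):
    """A genotype cell could not be decoded to 0/1/2."""


class DatasetValidationError(ValueError):
    """A dataset violates a structural invariant."""


@dataclass
class CaseControlDataset:
    """Genotype matrix (individuals x SNPs) with a binary phenotype.

    Parameters
    ----------
    genotypes
        Integer matrix with values in {0, 1, 2}.
    phenotype
        Binary vector, one entry per row of ``genotypes`` (1 = case).
    snp_names
        One name per genotype column.
    n_dropped_rows
        Number of rows discarded during parsing because of missing
        genotypes (informational only).
    """

    genotypes: np.ndarray
    phenotype: np.ndarray
    snp_names: list[str]
    n_dropped_rows: int = 0
    _lgamma_cache: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.genotypes = np.ascontiguousarray(self.genotypes, dtype=np.int8)
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise DatasetValidationError("genotype matrix must be 2-dimensional")
        if self.phenotype.ndim != 1 or len(self.phenotype) != self.genotypes.shape[0]:
            raise DatasetValidationError(
                "phenotype length must equal the number of genotype rows"
            )
        if len(self.snp_names) != self.genotypes.shape[1]:
            raise DatasetValidationError(
                "snp_names length must equal the number of genotype columns"
            )
        if self.genotypes.size and not np.isin(self.genotypes, (0, 1, 2)).all():
            bad = np.argwhere(~np.isin(self.genotypes, (0, 1, 2)))[0]
            raise DatasetValidationError(
                f"genotype value outside {{0,1,2}} at row {bad[0]}, column {bad[1]}"
            )
        if not np.isin(self.phenotype, (0, 1)).all():
            raise DatasetValidationError("phenotype values must be 0 or 1")
        if self.n_cases == 0 or self.n_controls == 0:
            raise DatasetValidationError(
                "dataset must contain at least one case and one control"
            )

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_cases(self) -> int:
        return int(self.phenotype.sum())

    @property
    def n_controls(self) -> int:
        return int(self.n - self.phenotype.sum())

    def lgamma_table(self) -> np.ndarray:
        """log-Gamma lookup for integer arguments 0..n+2 (index 0 unused)."""
        if self._lgamma_cache is None or len(self._lgamma_cache) < self.n + 3:
            from scipy.special import gammaln

            self._lgamma_cache = gammaln(np.arange(self.n + 3, dtype=np.float64))
        return self._lgamma_cache

    def name_combination(self, combo: Sequence[int]) -> tuple[str, ...]:
        return tuple(self.snp_names[i] for i in combo)


class SnpCombination(tuple):
    """A sorted tuple of k distinct SNP column indices (k >= 2)."""

    __slots__ = ()

    def __new__(cls, indices: Iterable[int]) -> "SnpCombination":
        idx = tuple(int(i) for i in indices)
        if len(idx) < 2:
            raise ValueError("a SNP combination needs at least 2 loci")
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError(f"indices must be strictly increasing, got {idx}")
        if idx[0] < 0:
            raise ValueError("indices must be non-negative")
        return super().__new__(cls, idx)

    @classmethod
    def from_unsorted(cls, indices: Iterable[int]) -> "SnpCombination":
        return cls(sorted(int(i) for i in indices))

    @property
    def k(self) -> int:
        return len(self)

    def validate_against(self, dataset: CaseControlDataset) -> None:
        if self[-1] >= dataset.n_snps:
            raise ValueError(
                f"SNP index {self[-1]} out of range for dataset with "
                f"{dataset.n_snps} SNPs"
            )


@dataclass
class ContingencyTable:
    """Genotype-combination x phenotype counts for one k-way SNP set.

    Only genotype combinations observed in the data appear as rows,
    so ``I <= 3**k``.  Column j corresponds to phenotype value j
    (0 = control, 1 = case).
    """

    counts: np.ndarray
    genotype_keys: list[tuple[int, ...]]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if len(self.genotype_keys) != self.counts.shape[0]:
            raise ValueError("one genotype key required per count row")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def I(self) -> int:  # noqa: E743 - matches standard contingency notation
        return self.counts.shape[0]

    @property
    def J(self) -> int:
        return self.counts.shape[1]

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def column_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())


_POW3 = 3 ** np.arange(16, dtype=np.int64)


def _genotype_codes(dataset: CaseControlDataset, columns: Sequence[int]) -> np.ndarray:
    """Encode each individual's k-locus genotype as an integer in [0, 3^k).

    Big-endian so that sorting codes sorts genotype tuples lexicographically.
    """
    sub = dataset.genotypes[:, list(columns)].astype(np.int64)
    return sub @ _POW3[: len(columns)][::-1]


def _decode_key(code: int, k: int) -> tuple[int, ...]:
    out = []
    for _ in range(k):
        out.append(code % 3)
        code //= 3
    return tuple(reversed(out))


def contingency_counts(
    dataset: CaseControlDataset, columns: Sequence[int]
) -> np.ndarray:
    """Dense (3^k x 2) genotype-by-phenotype count matrix (fast path).

    Includes unobserved genotype rows as zeros; used internally by the
    scoring hot loop, where empty rows contribute nothing.
    """
    k = len(columns)
    codes = _genotype_codes(dataset, columns)
    flat = np.bincount(codes * 2 + dataset.phenotype, minlength=2 * 3**k)
    return flat.reshape(3**k, 2)


def count_genotype_contingency(
    dataset: CaseControlDataset, combo: Sequence[int]
) -> ContingencyTable:
    """Tally genotype-combination x phenotype counts in one pass.

    Rows are ordered canonically by genotype tuple; combinations absent
    from the data are omitted.
    """
    if isinstance(combo, SnpCombination):
        combo.validate_against(dataset)
    columns = list(combo)
    if any(c < 0 or c >= dataset.n_snps for c in columns):
        raise ValueError("SNP index out of range")
    k = len(columns)
    dense = contingency_counts(dataset, columns)
    observed = np.flatnonzero(dense.sum(axis=1) > 0)
    keys = [_decode_key(int(code), k) for code in observed]
    return ContingencyTable(counts=dense[observed], genotype_keys=keys)


def combination_count(n: int, k: int) -> int:
    """Number of unordered k-subsets of n items, exact integer arithmetic."""
    if k < 1 or n < 1:
        raise ValueError("n and k must be positive")
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    return math.comb(n, k)


# ---------------------------------------------------------------------------
# I/O


_PLINK_META_COLUMNS = {"FID", "IID", "PAT", "MAT", "SEX"}


def read_genotype_table(
    path,
    dialect: str = "tsv",
    phenotype_column: str = "Class",
) -> CaseControlDataset:
    """Read a delimited genotype table into a validated dataset.

    ``dialect`` is one of ``tsv``, ``csv`` or ``plink_raw``.  The plink_raw
    dialect drops the FID/IID/PAT/MAT/SEX metadata columns, uses the
    PHENOTYPE column recoded 1/2 -> 0/1, and strips the trailing
    ``_<allele>`` suffix from SNP column names.  Rows containing any
    missing genotype are dropped; the count is recorded on the dataset.
    """
    if dialect == "tsv":
        frame = pd.read_csv(path, sep="\t")
    elif dialect == "csv":
        frame = pd.read_csv(path, sep=",")
    elif dialect == "plink_raw":
        frame = pd.read_csv(path, sep=r"\s+")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if dialect == "plink_raw":
        frame = frame.drop(
            columns=[c for c in frame.columns if c.upper() in _PLINK_META_COLUMNS]
        )
        pheno_col = "PHENOTYPE"
        if pheno_col not in frame.columns:
            raise GenotypeParseError("plink_raw file lacks a PHENOTYPE column")
        phenotype = frame[pheno_col].to_numpy()
        if not np.isin(phenotype[~pd.isna(phenotype)], (1, 2)).all():
            raise GenotypeParseError("plink_raw phenotype must be coded 1/2")
        phenotype = phenotype - 1
        snp_frame = frame.drop(columns=[pheno_col])
        snp_names = [
            name.rsplit("_", 1)[0] if "_" in name else name
            for name in snp_frame.columns
        ]
    else:
        if phenotype_column not in frame.columns:
            raise GenotypeParseError(
                f"phenotype column {phenotype_column!r} not found"
            )
        phenotype = frame[phenotype_column].to_numpy()
        snp_frame = frame.drop(columns=[phenotype_column])
        snp_names = list(snp_frame.columns)

    if snp_frame.shape[1] < 2:
        raise GenotypeParseError("need at least 2 SNP columns")

    geno = snp_frame.to_numpy()
    pheno_missing = pd.isna(phenotype)
    missing = pd.isna(geno).any(axis=1) | pheno_missing
    n_dropped = int(missing.sum())
    geno = geno[~missing]
    phenotype = np.asarray(phenotype[~missing])
    if geno.shape[0] == 0:
        raise GenotypeParseError("no complete rows left after dropping missing data")

    values = np.asarray(geno, dtype=np.float64)
    bad = ~np.isin(values, (0.0, 1.0, 2.0))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise GenotypeParseError(
            f"invalid genotype {geno[r, c]!r} at row {int(r)}, "
            f"column {snp_names[int(c)]!r} (expected 0/1/2)"
        )
    return CaseControlDataset(
        genotypes=values.astype(np.int8),
        phenotype=np.asarray(phenotype, dtype=np.int8),
        snp_names=snp_names,
        n_dropped_rows=n_dropped,
    )


def write_genotype_table(
    dataset: CaseControlDataset,
    path,
    dialect: str = "tsv",
    phenotype_column: str = "Class",
) -> None:
    """Write a dataset back to delimited text (inverse of the tsv/csv read)."""
    if dialect not in ("tsv", "csv"):
        raise ValueError("only tsv/csv writing is supported")
    frame = pd.DataFrame(dataset.genotypes, columns=dataset.snp_names)
    frame[phenotype_column] = dataset.phenotype
    frame.to_csv(path, sep="\t" if dialect == "tsv" else ",", index=False)
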