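"""Stage-two verification: modified G-test with sparse-row exclusion.

G = 2 * sum_ij O_ij * ln(O_ij / E_ij) over the genotype rows kept by the
sparsity rule; the degrees of freedom shrink accordingly to
(I_kept - 1) * (J - 1).  A genotype row is excluded when its smallest
per-phenotype observed count falls below the threshold ``xi``
(default 5): with that rule the nine-genotype worked example of a 2-way
table loses exactly its three sparse columns and its df drops from 8
to 5.

Two constructions of the expected counts are provided.  The ``hwe``
mode follows the Hardy-Weinberg principle: pooled-sample minor-allele
frequencies give per-locus genotype probabilities (1-q)^2, 2q(1-q),
q^2, multiplied across loci (linkage equilibrium) and scaled by the
per-phenotype column totals.  That construction folds a
genotype-distribution goodness-of-fit component into G, so its
chi-square reference with (I-1)(J-1) degrees of freedom is markedly
anti-conservative under the null.  The default ``independence`` mode
(E_ij = n_i * n_j / n, the classical row-by-column null) matches the
(I-1)(J-1) reference and is calibrated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import chi2

from .data_model import (
    CaseControlDataset,
    ContingencyTable,
    SnpCombination,
    count_genotype_contingency,
)

__all__ = [
    "GTestResult",
    "hwe_expected_counts",
    "independence_expected_counts",
    "g_statistic",
    "g_test_pvalue",
    "bonferroni_threshold",
    "g_test",
]

DEFAULT_XI = 5


@dataclass
class GTestResult:
    """Outcome of one modified G-test."""

    g: float
    df: int
    p_value: float | None
    excluded_columns: list[tuple[int, ...]]
    threshold: float | None = None
    infinite_divergence: bool = False
    combo_names: tuple[str, ...] | None = None

    @property
    def untestable(self) -> bool:
        return self.df < 1

    @property
    def significant(self) -> bool:
        if self.untestable or self.p_value is None or self.threshold is None:
            return False
        return self.p_value < self.threshold


def pooled_minor_allele_frequency(
    dataset: CaseControlDataset, snp_index: int
) -> float:
    """Minor-allele frequency estimated from the pooled case+control sample."""
    column = dataset.genotypes[:, snp_index]
    return float(column.sum() / (2 * dataset.n))


def hwe_expected_counts(
    dataset: CaseControlDataset,
    combo: Sequence[int],
    table: ContingencyTable | None = None,
) -> np.ndarray:
    """Expected I x J counts under Hardy-Weinberg genotype proportions.

    Per-locus genotype probabilities derive from the pooled minor-allele
    frequency; the joint probability of a genotype combination is their
    product across loci, and E_ij = P_i * n_j with n_j the phenotype-j
    column total.  Rows align with the observed table's genotype keys.
    A monomorphic locus (q = 0 or 1) concentrates the expected mass and
    triggers a warning, not an error.
    """
    if isinstance(combo, SnpCombination):
        combo.validate_against(dataset)
    columns = list(combo)
    if table is None:
        table = count_genotype_contingency(dataset, columns)
    locus_probs = []
    for snp in columns:
        q = pooled_minor_allele_frequency(dataset, snp)
        if q in (0.0, 1.0):
            warnings.warn(
                f"SNP column {snp} is monomorphic (q={q}); expected counts "
                "concentrate on a single genotype",
                stacklevel=2,
            )
        locus_probs.append(np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2]))
    joint = np.array(
        [
            float(np.prod([locus_probs[l][g] for l, g in enumerate(key)]))
            for key in table.genotype_keys
        ]
    )
    return joint[:, None] * table.column_totals[None, :].astype(np.float64)


def independence_expected_counts(table: ContingencyTable) -> np.ndarray:
    """Classical independence null: E_ij = n_i * n_j / n."""
    n = table.grand_total
    if n == 0:
        raise ValueError("empty table")
    return np.outer(table.row_totals, table.column_totals).astype(np.float64) / n


def g_statistic(
    observed: ContingencyTable,
    expected: np.ndarray | None = None,
    xi: int = DEFAULT_XI,
) -> GTestResult:
    """Modified G statistic with sparse-row exclusion (p-value not yet set).

    Rows whose minimum observed count over the phenotype states is below
    ``xi`` are dropped from both the sum and the degrees of freedom.
    Kept rows with E_ij = 0 but O_ij > 0 would diverge; they are excluded
    too, with a warning and a flag on the result.  With ``expected=None``
    the independence expectation from the table margins is used.
    """
    if xi < 0:
        raise ValueError("xi must be non-negative")
    if expected is None:
        expected = independence_expected_counts(observed)
    expected = np.asarray(expected, dtype=np.float64)
    if expected.shape != observed.counts.shape:
        raise ValueError("observed and expected must share shape/row keys")

    counts = observed.counts.astype(np.float64)
    keep = counts.min(axis=1) >= xi
    diverging = ((expected <= 0) & (counts > 0)).any(axis=1) & keep
    infinite = bool(diverging.any())
    if infinite:
        warnings.warn(
            "expected count 0 with positive observed count; row(s) excluded "
            "from the G-test",
            stacklevel=2,
        )
        keep &= ~diverging

    excluded = [
        key for key, kept in zip(observed.genotype_keys, keep) if not kept
    ]
    o = counts[keep]
    e = expected[keep]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(o > 0, o * np.log(np.where(o > 0, o / e, 1.0)), 0.0)
    g = float(2.0 * terms.sum())
    df = (int(keep.sum()) - 1) * (observed.J - 1)
    return GTestResult(
        g=g,
        df=df,
        p_value=None,
        excluded_columns=excluded,
        infinite_divergence=infinite,
    )


def g_test_pvalue(g: float, df: int) -> float:
    """Upper-tail chi-square probability of the G statistic."""
    if g < 0:
        raise ValueError("G must be non-negative")
    if df < 1:
        raise ValueError("df < 1: untestable, no p-value is defined")
    return float(chi2.sf(g, df))


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test significance cutoff alpha / n_tests."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def g_test(
    dataset: CaseControlDataset,
    combo: Sequence[int],
    xi: int = DEFAULT_XI,
    expected_mode: str = "independence",
    threshold: float | None = None,
) -> GTestResult:
    """Convenience wrapper: count, expected counts, G, df and p-value."""
    table = count_genotype_contingency(dataset, combo)
    if expected_mode == "hwe":
        expected = hwe_expected_counts(dataset, combo, table=table)
    elif expected_mode == "independence":
        expected = independence_expected_counts(table)
    else:
        raise ValueError(f"unknown expected_mode {expected_mode!r}")
    result = g_statistic(table, expected, xi=xi)
    if not result.untestable:
        # row exclusion can leave a slightly negative G; clamp for the tail
        result.p_value = g_test_pvalue(max(result.g, 0.0), result.df)
    result.threshold = threshold
    result.combo_names = dataset.name_combination(combo)
    return result
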