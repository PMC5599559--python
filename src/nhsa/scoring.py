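"""Stage-one evaluation functions: K2, Gini impurity and joint entropy.

All three scores are computed from a single genotype-count pass over the
dataset and all three are *minimized*: the K2 score is stored as the
negative natural log of the Bayesian marginal-likelihood product (the raw
product underflows for realistic sample sizes, and lower -ln means a
larger product, i.e. a stronger genotype-phenotype fit), while Gini and
joint entropy are already smaller-is-stronger.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from .data_model import (
    CaseControlDataset,
    ContingencyTable,
    SnpCombination,
    contingency_counts,
)

__all__ = [
    "ScoreTriple",
    "EvaluationCounter",
    "GLOBAL_COUNTER",
    "k2_score",
    "gini_score",
    "joint_entropy",
    "score_combination",
    "score_counts",
    "is_synergistic",
]


@dataclass(frozen=True)
class ScoreTriple:
    """The three stage-one scores of one k-way combination (all minimized)."""

    k2: float
    gini: float
    entropy: float
    evaluations_consumed: int = 1

    def by_objective(self, objective: str) -> float:
        return getattr(self, objective)


class EvaluationCounter:
    """Counts scored SNP combinations; this is the MEs metric."""

    __slots__ = ("count",)

    def __init__(self) -> None:
        self.count = 0

    def increment(self) -> None:
        self.count += 1

    def reset(self) -> None:
        self.count = 0


#: Default process-wide counter used when no explicit counter is supplied.
GLOBAL_COUNTER = EvaluationCounter()


def k2_score(table: ContingencyTable) -> float:
    """Negative log of the K2 marginal-likelihood product.

    Computed in the log-gamma domain:
    sum_i [ lnGamma(n_i + J) - lnGamma(J) - sum_j lnGamma(n_ij + 1) ].
    """
    counts = table.counts
    j = table.J
    n_i = counts.sum(axis=1)
    return float(
        (gammaln(n_i + j) - gammaln(j)).sum() - gammaln(counts + 1).sum()
    )


def gini_score(table: ContingencyTable) -> float:
    """Expected phenotype impurity across genotype rows; 0 = pure mapping."""
    counts = table.counts.astype(np.float64)
    n_i = counts.sum(axis=1)
    n = n_i.sum()
    if n == 0:
        return 0.0
    keep = n_i > 0
    p = counts[keep] / n_i[keep, None]
    return float(((n_i[keep] / n) * (1.0 - (p**2).sum(axis=1))).sum())


def joint_entropy(table: ContingencyTable) -> float:
    """Base-2 entropy of the genotype-combination marginal (phenotype-blind)."""
    n_i = table.row_totals.astype(np.float64)
    n = n_i.sum()
    if n == 0:
        return 0.0
    p = n_i[n_i > 0] / n
    return float(-(p * np.log2(p)).sum())


def score_counts(counts: np.ndarray, lgamma: np.ndarray | None = None) -> ScoreTriple:
    """Score a dense (rows x 2) count matrix; zero rows contribute nothing.

    ``lgamma`` is an optional precomputed lnGamma lookup over integers
    (index m -> lnGamma(m)); it removes the per-call gammaln cost in the
    search hot loop.
    """
    n_i = counts.sum(axis=1)
    keep = n_i > 0
    counts = counts[keep]
    n_i = n_i[keep]
    n = n_i.sum()
    if n == 0:
        return ScoreTriple(0.0, 0.0, 0.0)
    if lgamma is not None:
        k2 = float(lgamma[n_i + 2].sum() - lgamma[counts + 1].sum())
    else:
        k2 = float(gammaln(n_i + 2).sum() - gammaln(counts + 1).sum())
    p_i = n_i / n
    pij = counts / n_i[:, None]
    gini = float((p_i * (1.0 - (pij**2).sum(axis=1))).sum())
    entropy = float(-(p_i * np.log2(p_i)).sum())
    return ScoreTriple(k2=k2, gini=gini, entropy=entropy)


def score_combination(
    dataset: CaseControlDataset,
    combo: Sequence[int],
    counter: EvaluationCounter | None = None,
) -> ScoreTriple:
    """One contingency pass feeding all three scores.

    Increments ``counter`` (default: the global counter) by exactly 1.
    """
    if isinstance(combo, SnpCombination):
        combo.validate_against(dataset)
    triple = score_counts(
        contingency_counts(dataset, list(combo)), lgamma=dataset.lgamma_table()
    )
    (counter if counter is not None else GLOBAL_COUNTER).increment()
    return triple


_OBJECTIVE_FUNCS = {"k2": k2_score, "gini": gini_score, "entropy": joint_entropy}


def _subset_score(dataset: CaseControlDataset, columns: tuple[int, ...], score: str) -> float:
    triple = score_counts(
        contingency_counts(dataset, list(columns)), lgamma=dataset.lgamma_table()
    )
    return triple.by_objective(score)


def is_synergistic(
    dataset: CaseControlDataset,
    combo: SnpCombination,
    score: str = "k2",
    max_k: int = 6,
) -> bool:
    """True iff the full combination scores strictly stronger (lower) than
    every nonempty proper subset.  Ties fail the strict comparison.

    Refuses k > ``max_k`` because subset enumeration is exponential.
    """
    if score not in ("k2", "gini"):
        raise ValueError("synergy is defined for the phenotype-aware scores k2/gini")
    k = len(combo)
    if k > max_k:
        raise ValueError(f"k={k} exceeds the subset-enumeration cap ({max_k})")
    combo.validate_against(dataset)
    full = _subset_score(dataset, tuple(combo), score)
    for size in range(1, k):
        for subset in itertools.combinations(combo, size):
            if _subset_score(dataset, subset, score) <= full:
                return False
    return True
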