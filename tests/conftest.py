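"""Shared fixtures: small deterministic datasets and session-scoped models."""

from __future__ import annotations

import numpy as np
import pytest

from nhsa.data_model import CaseControlDataset, ContingencyTable
from nhsa.simulate import build_dme_model, search_dnme_model

# Worked nine-genotype example of a 2-way contingency table
# (case row / control row per 2-way genotype 0-0 .. 2-2).
TABLE5_KEYS = [(i, j) for i in range(3) for j in range(3)]
TABLE5_CASE = [50, 50, 0, 5, 0, 0, 240, 18, 30]
TABLE5_CONTROL = [60, 5, 1, 5, 80, 0, 50, 31, 35]


@pytest.fixture()
def table5() -> ContingencyTable:
    counts = np.column_stack([TABLE5_CONTROL, TABLE5_CASE])  # column 0 = control
    return ContingencyTable(counts=counts, genotype_keys=list(TABLE5_KEYS))


def make_random_dataset(
    seed: int, n: int = 50, n_snps: int = 5, balanced: bool = True
) -> CaseControlDataset:
    rng = np.random.default_rng(seed)
    genotypes = rng.integers(0, 3, size=(n, n_snps), dtype=np.int8)
    if balanced:
        phenotype = np.zeros(n, dtype=np.int8)
        phenotype[: n // 2] = 1
        rng.shuffle(phenotype)
    else:
        phenotype = rng.integers(0, 2, size=n, dtype=np.int8)
        phenotype[0], phenotype[1] = 0, 1  # guarantee both classes
    return CaseControlDataset(
        genotypes=genotypes,
        phenotype=phenotype,
        snp_names=[f"SNP{i}" for i in range(n_snps)],
    )


@pytest.fixture()
def small_dataset() -> CaseControlDataset:
    return make_random_dataset(0, n=60, n_snps=6)


@pytest.fixture(scope="session")
def threshold_model():
    return build_dme_model("threshold", maf=0.2, h2_target=0.02)


@pytest.fixture(scope="session")
def dnme_model():
    return search_dnme_model(
        k=3, maf=0.25, h2_target=0.1, marginal_tol=0.005,
        rng=np.random.default_rng(42), prevalence_target=0.1,
    )


@pytest.fixture()
def tiny_tsv(tmp_path):
    path = tmp_path / "tiny.tsv"
    path.write_text(
        "rs1\trs2\tClass\n"
        "0\t1\t1\n"
        "1\t2\t0\n"
        "2\t0\t1\n"
        "0\t0\t0\n"
    )
    return path
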