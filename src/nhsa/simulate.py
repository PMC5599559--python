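"""Penetrance-model case-control simulator.

Two model families are supported: two-locus models with marginal effects
(multiplicative and threshold penetrance, calibrated to a target
heritability by bisection) and higher-order models with (near-)zero
single-locus marginal effects, found by constrained stochastic search.
Datasets embed the causal loci at random positions among independent
Hardy-Weinberg background SNPs and are emitted together with a truth
record.

Heritability is defined as Var_g(f) / (K * (1 - K)) with K the
population prevalence under product-HWE genotype probabilities — the
standard definition used by penetrance-table epistasis generators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .data_model import CaseControlDataset

__all__ = [
    "PenetranceModel",
    "SimTruth",
    "heritability",
    "prevalence",
    "marginal_penetrance",
    "build_dme_model",
    "search_dnme_model",
    "generate_dataset",
    "generate_null_dataset",
    "write_truth",
    "read_truth",
]


def _hwe_probs(q: float) -> np.ndarray:
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])


@dataclass
class PenetranceModel:
    """Per-genotype-combination disease probabilities.

    ``table`` has shape (3,) * k, indexed by minor-allele dosage at each
    causal locus.
    """

    mafs: tuple[float, ...]
    table: np.ndarray
    model_class: str
    h2: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.mafs = tuple(float(m) for m in self.mafs)
        self.table = np.asarray(self.table, dtype=np.float64)
        k = len(self.mafs)
        if self.table.shape != (3,) * k:
            raise ValueError(f"table must have shape {(3,) * k}")
        if ((self.table < 0) | (self.table > 1)).any():
            raise ValueError("penetrances must lie in [0, 1]")
        if any(not 0 < m <= 0.5 for m in self.mafs):
            raise ValueError("MAFs must lie in (0, 0.5]")
        if self.h2 is None:
            self.h2 = heritability(self)
        elif abs(self.h2 - heritability(self)) > 1e-9:
            raise ValueError("stored h2 inconsistent with penetrance table")

    @property
    def k(self) -> int:
        return len(self.mafs)

    def genotype_probs(self) -> np.ndarray:
        """Product-HWE probability of each genotype combination, shape (3,)*k."""
        probs = _hwe_probs(self.mafs[0])
        for maf in self.mafs[1:]:
            probs = np.multiply.outer(probs, _hwe_probs(maf))
        return probs


def prevalence(model: PenetranceModel) -> float:
    """Population disease prevalence K = sum_g p_g * f_g."""
    return float((model.genotype_probs() * model.table).sum())


def heritability(model: PenetranceModel) -> float:
    """h2 = sum_g p_g (f_g - K)^2 / (K (1 - K))."""
    p = model.genotype_probs()
    k_prev = float((p * model.table).sum())
    if k_prev <= 0.0 or k_prev >= 1.0:
        raise ValueError(f"prevalence {k_prev} leaves heritability undefined")
    var = float((p * (model.table - k_prev) ** 2).sum())
    return var / (k_prev * (1.0 - k_prev))


def marginal_penetrance(model: PenetranceModel, locus: int) -> np.ndarray:
    """Single-locus penetrance, marginalized over the other loci (HWE weights)."""
    if not 0 <= locus < model.k:
        raise ValueError("locus out of range")
    p = model.genotype_probs()
    axes = tuple(a for a in range(model.k) if a != locus)
    weights = p.sum(axis=axes) if axes else np.ones(3)
    joint = (p * model.table).sum(axis=axes) if axes else p * model.table
    if axes:
        return joint / p.sum(axis=axes)
    return model.table.copy()


def _dme_table(model_class: str, theta: float, baseline: float) -> np.ndarray:
    g = np.add.outer(np.arange(3), np.arange(3))
    if model_class == "multiplicative":
        return baseline * (1.0 + theta) ** g
    if model_class == "threshold":
        return np.where(g >= 2, baseline * (1.0 + theta), baseline)
    raise ValueError(f"unknown DME model class {model_class!r}")


def build_dme_model(
    model_class: str,
    maf: float,
    h2_target: float,
    baseline: float = 0.1,
    tol: float = 1e-6,
) -> PenetranceModel:
    """Two-locus marginal-effect model at an exact target heritability.

    Multiplicative: f = b (1+theta)^(g1+g2); threshold: f = b below two
    minor alleles, b (1+theta) at or above.  theta is solved by bisection
    so that the recomputed heritability matches ``h2_target`` within
    ``tol``.
    """
    if not 0 < maf <= 0.5:
        raise ValueError("maf must be in (0, 0.5]")
    if h2_target <= 0:
        raise ValueError("h2_target must be positive")
    mafs = (maf, maf)
    if model_class == "multiplicative":
        theta_max = (1.0 / baseline) ** 0.25 - 1.0
    elif model_class == "threshold":
        theta_max = 1.0 / baseline - 1.0
    else:
        raise ValueError(f"unknown DME model class {model_class!r}")

    def h2_at(theta: float) -> float:
        return heritability(
            PenetranceModel(mafs, _dme_table(model_class, theta, baseline), model_class)
        )

    h2_hi = h2_at(theta_max)
    if h2_target > h2_hi:
        raise ValueError(
            f"h2_target={h2_target} unreachable for {model_class} with "
            f"baseline={baseline}: attainable range is (0, {h2_hi:.6g}]"
        )
    lo, hi = 0.0, theta_max
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if h2_at(mid) < h2_target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-14:
            break
    theta = 0.5 * (lo + hi)
    model = PenetranceModel(mafs, _dme_table(model_class, theta, baseline), model_class)
    if abs(model.h2 - h2_target) > tol:
        raise ValueError(
            f"bisection failed to reach h2_target within {tol}: got {model.h2}"
        )
    return model


def _marginal_devs(table: np.ndarray, probs: np.ndarray, k: int) -> list[np.ndarray]:
    k_prev = float((probs * table).sum())
    devs = []
    for locus in range(k):
        axes = tuple(a for a in range(k) if a != locus)
        marg = (probs * table).sum(axis=axes) / probs.sum(axis=axes)
        devs.append(marg - k_prev)
    return devs


def search_dnme_model(
    k: int,
    maf: float,
    h2_target: float,
    marginal_tol: float = 0.005,
    rng: np.random.Generator | None = None,
    prevalence_target: float | None = None,
    max_restarts: int = 50,
    max_iters: int = 400,
) -> PenetranceModel:
    """Find a k-locus penetrance table with strong joint but (near-)zero
    single-locus marginal effects.

    Stochastic search: random start, then alternate (a) subtracting each
    locus' marginal deviation (projecting toward flat marginals) and
    (b) rescaling the table around its prevalence to hit the target
    heritability, clipping to [0, 1] throughout.  Accepted when every
    locus satisfies max_g |marginal_g - K| < marginal_tol and
    |h2 - h2_target| < 0.1 * h2_target.

    ``prevalence_target`` optionally pins the population prevalence K
    (within 10%).  Low K strengthens the genotype-distribution
    distortion induced by balanced case/control sampling, and with it
    the joint-entropy signal of causal combinations.
    """
    if not 2 <= k <= 5:
        raise ValueError("k must be in 2..5")
    if marginal_tol <= 0:
        raise ValueError("marginal_tol must be positive")
    rng = np.random.default_rng(rng)
    mafs = (maf,) * k
    probs = PenetranceModel(mafs, np.full((3,) * k, 0.5), "dnme_searched").genotype_probs()

    if prevalence_target is not None and not 0 < prevalence_target < 1:
        raise ValueError("prevalence_target must lie in (0, 1)")

    best_residual = np.inf
    best_report = ""
    for _ in range(max_restarts):
        if prevalence_target is None:
            table = rng.uniform(0.1, 0.9, size=(3,) * k)
        else:
            spread = min(prevalence_target, 1 - prevalence_target)
            table = rng.uniform(
                prevalence_target - spread, prevalence_target + spread,
                size=(3,) * k,
            )
        for _ in range(max_iters):
            devs = _marginal_devs(table, probs, k)
            for locus, dev in enumerate(devs):
                shape = [1] * k
                shape[locus] = 3
                table = table - dev.reshape(shape)
            if prevalence_target is not None:
                table = table + (
                    prevalence_target - float((probs * table).sum())
                )
            table = np.clip(table, 0.0, 1.0)
            k_prev = float((probs * table).sum())
            if not 0.02 < k_prev < 0.98:
                break
            var = float((probs * (table - k_prev) ** 2).sum())
            target_var = h2_target * k_prev * (1.0 - k_prev)
            if var > 0:
                scale = np.sqrt(target_var / var)
                # damp the rescale so projection and scaling can co-converge
                scale = 1.0 + 0.5 * (scale - 1.0)
                table = np.clip(k_prev + scale * (table - k_prev), 0.0, 1.0)
            model = PenetranceModel(mafs, table, "dnme_searched")
            marg_dev = max(
                float(np.abs(d).max()) for d in _marginal_devs(table, probs, k)
            )
            h2_err = abs(model.h2 - h2_target)
            residual = marg_dev / marginal_tol + h2_err / (0.1 * h2_target)
            if residual < best_residual:
                best_residual = residual
                best_report = f"max marginal dev {marg_dev:.3g}, h2 {model.h2:.4g}"
            prev_ok = (
                prevalence_target is None
                or abs(k_prev - prevalence_target) < 0.1 * prevalence_target
            )
            if marg_dev < marginal_tol and h2_err < 0.1 * h2_target and prev_ok:
                return model
    raise RuntimeError(
        f"no admissible DNME table found (best attempt: {best_report})"
    )


@dataclass
class SimTruth:
    """Ground truth for one simulated dataset."""

    causal_snp_names: tuple[str, ...]
    causal_column_indices: tuple[int, ...]
    model: PenetranceModel
    seed: int | None = None


def _sample_causal_genotypes(
    model: PenetranceModel, size: int, rng: np.random.Generator
) -> np.ndarray:
    geno = np.empty((size, model.k), dtype=np.int8)
    for locus, maf in enumerate(model.mafs):
        geno[:, locus] = rng.binomial(2, maf, size=size)
    return geno


def generate_dataset(
    model: PenetranceModel,
    n_cases: int,
    n_controls: int,
    n_background_snps: int,
    background_maf_range: tuple[float, float] = (0.05, 0.5),
    rng: np.random.Generator | int | None = None,
    max_expected_draws: int = 50_000_000,
) -> tuple[CaseControlDataset, SimTruth]:
    """Rejection-sample a case/control dataset from a penetrance model.

    Causal genotypes are drawn under HWE, disease status with probability
    f_g, and sampling continues until both quotas are filled.  Background
    SNPs are phenotype-independent HWE draws with MAF uniform in
    ``background_maf_range``.  Causal columns are placed at random
    positions and reported in the truth record.
    """
    if n_cases < 1 or n_controls < 1:
        raise ValueError("need at least one case and one control")
    rng = np.random.default_rng(rng)
    k_prev = prevalence(model)
    expected_draws = n_cases / max(k_prev, 1e-12) + n_controls / max(1 - k_prev, 1e-12)
    if expected_draws > max_expected_draws:
        raise ValueError(
            f"prevalence {k_prev:.3g} makes rejection sampling impractical "
            f"(~{expected_draws:.3g} expected draws)"
        )

    cases: list[np.ndarray] = []
    controls: list[np.ndarray] = []
    need_cases, need_controls = n_cases, n_controls
    while need_cases > 0 or need_controls > 0:
        batch = int(min(max(2 * expected_draws / 4, 1000), 500_000))
        geno = _sample_causal_genotypes(model, batch, rng)
        f = model.table[tuple(geno.T)]
        is_case = rng.random(batch) < f
        if need_cases > 0:
            take = geno[is_case][:need_cases]
            cases.append(take)
            need_cases -= len(take)
        if need_controls > 0:
            take = geno[~is_case][:need_controls]
            controls.append(take)
            need_controls -= len(take)

    causal = np.vstack([np.concatenate(cases), np.concatenate(controls)])
    phenotype = np.concatenate(
        [np.ones(n_cases, dtype=np.int8), np.zeros(n_controls, dtype=np.int8)]
    )
    n = n_cases + n_controls

    total = model.k + n_background_snps
    if n_background_snps > 0:
        lo, hi = background_maf_range
        bg_mafs = rng.uniform(lo, hi, size=n_background_snps)
        background = rng.binomial(
            2, bg_mafs[None, :], size=(n, n_background_snps)
        ).astype(np.int8)
    else:
        background = np.empty((n, 0), dtype=np.int8)

    causal_positions = np.sort(rng.choice(total, size=model.k, replace=False))
    genotypes = np.empty((n, total), dtype=np.int8)
    genotypes[:, causal_positions] = causal
    bg_positions = np.setdiff1d(np.arange(total), causal_positions)
    genotypes[:, bg_positions] = background
    snp_names = [f"SNP{i}" for i in range(total)]

    dataset = CaseControlDataset(
        genotypes=genotypes, phenotype=phenotype, snp_names=snp_names
    )
    truth = SimTruth(
        causal_snp_names=tuple(snp_names[i] for i in causal_positions),
        causal_column_indices=tuple(int(i) for i in causal_positions),
        model=model,
    )
    return dataset, truth


def generate_null_dataset(
    n_cases: int,
    n_controls: int,
    n_snps: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    rng: np.random.Generator | int | None = None,
) -> CaseControlDataset:
    """Phenotype-independent HWE genotypes: no association anywhere."""
    rng = np.random.default_rng(rng)
    n = n_cases + n_controls
    mafs = rng.uniform(*maf_range, size=n_snps)
    genotypes = rng.binomial(2, mafs[None, :], size=(n, n_snps)).astype(np.int8)
    phenotype = np.concatenate(
        [np.ones(n_cases, dtype=np.int8), np.zeros(n_controls, dtype=np.int8)]
    )
    return CaseControlDataset(
        genotypes=genotypes,
        phenotype=phenotype,
        snp_names=[f"SNP{i}" for i in range(n_snps)],
    )


def write_truth(truth: SimTruth, path) -> None:
    payload = {
        "causal_snp_names": list(truth.causal_snp_names),
        "causal_column_indices": list(truth.causal_column_indices),
        "seed": truth.seed,
        "model": {
            "model_class": truth.model.model_class,
            "mafs": list(truth.model.mafs),
            "h2": float(truth.model.h2),
            "prevalence": prevalence(truth.model),
            "penetrance_table": truth.model.table.tolist(),
        },
    }
    with open(path, "w") as handle:
        yaml.safe_dump(payload, handle, sort_keys=False)


def read_truth(path) -> SimTruth:
    with open(path) as handle:
        payload = yaml.safe_load(handle)
    model = PenetranceModel(
        mafs=tuple(payload["model"]["mafs"]),
        table=np.array(payload["model"]["penetrance_table"]),
        model_class=payload["model"]["model_class"],
    )
    return SimTruth(
        causal_snp_names=tuple(payload["causal_snp_names"]),
        causal_column_indices=tuple(payload["causal_column_indices"]),
        model=model,
        seed=payload.get("seed"),
    )
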