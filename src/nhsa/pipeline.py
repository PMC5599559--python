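"""Two-stage orchestration: niche-harmony screening, then G-test verification.

``screen`` runs the harmony-search loop under a fixed evaluation budget,
accumulating per-objective elite sets across niche-triggered restarts and
merging them into a candidate set.  ``verify`` applies the modified
G-test with a Bonferroni (or fixed) threshold to every candidate.
``run`` composes both and can persist a reproducible run directory.
"""

from __future__ import annotations

import itertools
import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .data_model import CaseControlDataset, SnpCombination, combination_count
from .gtest import (
    GTestResult,
    bonferroni_threshold,
    g_test,
)
from .scoring import EvaluationCounter, ScoreTriple, score_combination
from .search import (
    OBJECTIVES,
    EliteSet,
    NicheRegion,
    SearchExhaustionError,
    TabooTable,
    harvest_elites,
    identify_niche,
    improvise_harmony,
    initialize_memories,
)

logger = logging.getLogger(__name__)

__all__ = ["NhsaConfig", "ScreenResult", "DetectionResult", "screen", "verify", "run"]


@dataclass
class NhsaConfig:
    """Run parameters; unset sizes resolve against the dataset.

    Defaults follow the published settings: HMCR 0.9, PAR 0.35, memory
    and elite sizes 50 for datasets up to 100 SNPs (100 above), candidate
    set capacity 10, T_max 4500 for 100 SNPs (60000 for 1000).
    """

    k: int = 2
    hms: int | None = None
    elite_capacity: int | None = None
    cs_capacity: int = 10
    hmcr: float = 0.9
    par: float = 0.35
    stagnation_T: int = 50
    t_max: int | None = None
    xi: int = 5
    alpha: float = 0.05
    n_tests_mode: str = "all_combinations"
    fixed_threshold: float | None = None
    expected_mode: str = "independence"
    seed: int = 0
    early_stop_truth: tuple[int, ...] | None = None
    max_iteration_factor: int = 5

    def resolved(self, dataset: CaseControlDataset) -> "NhsaConfig":
        cfg = replace(self)
        if cfg.hms is None:
            cfg.hms = 50 if dataset.n_snps <= 100 else 100
        if cfg.elite_capacity is None:
            cfg.elite_capacity = cfg.hms
        if cfg.t_max is None:
            cfg.t_max = 4500 if dataset.n_snps <= 100 else 60000
        if cfg.early_stop_truth is not None:
            cfg.early_stop_truth = tuple(sorted(cfg.early_stop_truth))
        self._validate(cfg, dataset)
        return cfg

    @staticmethod
    def _validate(cfg: "NhsaConfig", dataset: CaseControlDataset) -> None:
        if not 0 <= cfg.hmcr <= 1 or not 0 <= cfg.par <= 1:
            raise ValueError("hmcr/par must lie in [0, 1]")
        if cfg.k < 2 or cfg.k > dataset.n_snps:
            raise ValueError("k must be in [2, n_snps]")
        if cfg.cs_capacity < 1 or cfg.elite_capacity < 1 or cfg.hms < 2:
            raise ValueError("capacities must be positive (hms >= 2)")
        if cfg.t_max < 3 * cfg.hms:
            raise ValueError("t_max must be at least 3 * hms")
        if not 0 < cfg.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if cfg.n_tests_mode not in ("all_combinations", "candidates", "fixed"):
            raise ValueError("unknown n_tests_mode")
        if cfg.n_tests_mode == "fixed" and cfg.fixed_threshold is None:
            raise ValueError("fixed n_tests_mode requires fixed_threshold")

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "hms": self.hms,
            "elite_capacity": self.elite_capacity,
            "cs_capacity": self.cs_capacity,
            "hmcr": self.hmcr,
            "par": self.par,
            "stagnation_T": self.stagnation_T,
            "t_max": self.t_max,
            "xi": self.xi,
            "alpha": self.alpha,
            "n_tests_mode": self.n_tests_mode,
            "fixed_threshold": self.fixed_threshold,
            "expected_mode": self.expected_mode,
            "seed": self.seed,
        }


@dataclass
class ScreenResult:
    """Stage-one output: candidate combinations plus search diagnostics."""

    candidates: list[tuple[SnpCombination, ScoreTriple]]
    evaluations_used: int
    restarts: int
    niches: list[NicheRegion]
    trace: list[dict] = field(default_factory=list)
    exhausted: bool = False
    early_stop_hit: bool = False
    evaluations_to_hit: int | None = None


@dataclass
class DetectionResult:
    """Full two-stage output."""

    candidates: list[tuple[SnpCombination, ScoreTriple]]
    tested: list[GTestResult]
    significant: list[GTestResult]
    untestable: list[GTestResult]
    evaluations_used: int
    wall_time: float
    restarts: int
    niches: list[NicheRegion]
    threshold: float
    config: NhsaConfig
    early_stop_hit: bool = False
    evaluations_to_hit: int | None = None


def _exploit_niche(
    dataset: CaseControlDataset,
    region: NicheRegion,
    config: NhsaConfig,
    taboo: TabooTable,
    elites: tuple[EliteSet, ...],
    evaluate,
    budget_left,
) -> NicheRegion:
    """Sweep a niche region before it is tabooed, so its true best member
    is on record.

    Tabooing a region bans every future visit of combinations sharing its
    defining loci, so whatever the region's best combination is must be
    found *now*.  For defining sets of size k-1 or k, every (k-1)-subset
    is completed with each non-tabooed remaining locus (cost linear in
    the SNP count per subset) and the evaluations are offered to the
    elite sets.  Smaller defining sets are left unswept (the completion
    cost would be combinatorial) and the memory's best member stands.
    Sweeping never exceeds the evaluation budget.
    """
    defining = sorted(region.defining_snps)
    if not config.k - 1 <= len(defining) <= config.k:
        return region
    best_combo, best_score = region.best_member, region.best_score
    for core in itertools.combinations(defining, config.k - 1):
        core_set = set(core)
        for snp in range(dataset.n_snps):
            if snp in core_set:
                continue
            combo = SnpCombination(sorted(core + (snp,)))
            if taboo.is_tabooed(combo) or not budget_left(combo):
                continue
            triple = evaluate(combo)
            for elite in elites:
                elite.offer(combo, triple.by_objective(elite.objective))
            score = triple.by_objective(region.objective)
            if score < best_score:
                best_combo, best_score = combo, score
    return NicheRegion(
        defining_snps=region.defining_snps,
        radius=region.radius,
        best_member=best_combo,
        best_score=best_score,
        objective=region.objective,
    )


def screen(
    dataset: CaseControlDataset,
    config: NhsaConfig,
    trace: bool = False,
) -> ScreenResult:
    """Niche-harmony screening loop under a fixed evaluation budget.

    One candidate per iteration is improvised, scored once (a single
    contingency pass shared by the three objectives) and offered to
    HM1/HM2/HM3 independently.  When all three memories have stagnated
    for ``stagnation_T`` iterations, each memory contributes a niche to
    the taboo table, elites are harvested and the memories are
    reinitialized outside all taboo regions.
    """
    config = config.resolved(dataset)
    rng = np.random.default_rng(config.seed)
    counter = EvaluationCounter()
    cache: dict[SnpCombination, ScoreTriple] = {}
    taboo = TabooTable()
    elites = tuple(EliteSet(obj, config.elite_capacity) for obj in OBJECTIVES)
    niches: list[NicheRegion] = []
    trace_rows: list[dict] = []
    restarts = 0
    exhausted = False
    early_stop_hit = False
    evaluations_to_hit: int | None = None
    truth = config.early_stop_truth

    def evaluate(combo: SnpCombination) -> ScoreTriple:
        nonlocal early_stop_hit, evaluations_to_hit
        if combo in cache:
            return cache[combo]
        triple = score_combination(dataset, combo, counter=counter)
        cache[combo] = triple
        if truth is not None and tuple(combo) == truth and not early_stop_hit:
            early_stop_hit = True
            evaluations_to_hit = counter.count
        return triple

    try:
        memories = initialize_memories(
            dataset, config.k, config.hms, taboo, rng,
            counter=counter, score_cache=cache,
        )
        if truth is not None and truth in cache and not early_stop_hit:
            early_stop_hit = True
            evaluations_to_hit = counter.count
    except SearchExhaustionError:
        logger.warning("search space exhausted during initialization")
        return ScreenResult([], counter.count, 0, [], trace_rows, exhausted=True)

    iteration = 0
    max_iterations = config.max_iteration_factor * config.t_max
    space_size = combination_count(dataset.n_snps, config.k)
    while (
        counter.count < config.t_max
        and len(cache) < space_size
        and not early_stop_hit
    ):
        iteration += 1
        if iteration > max_iterations:
            break
        try:
            candidate = improvise_harmony(
                memories, config.hmcr, config.par,
                dataset.n_snps, config.k, taboo, rng,
            )
        except SearchExhaustionError:
            exhausted = True
            break
        triple = evaluate(candidate)
        accepted = [
            memory.update(candidate, triple.by_objective(memory.objective))
            for memory in memories
        ]
        if trace:
            trace_rows.append(
                {
                    "iteration": iteration,
                    "combo": dataset.name_combination(candidate),
                    "k2": triple.k2,
                    "gini": triple.gini,
                    "entropy": triple.entropy,
                    "accepted": "".join("1" if a else "0" for a in accepted),
                }
            )
        if all(m.stagnation_counter >= config.stagnation_T for m in memories):
            seen_regions = {r.defining_snps for r in taboo.regions}
            for memory in memories:
                region = identify_niche(memory, config.k)
                if region.defining_snps not in seen_regions:
                    region = _exploit_niche(
                        dataset, region, config, taboo, elites, evaluate,
                        budget_left=lambda combo: (
                            combo in cache or counter.count < config.t_max
                        ),
                    )
                    seen_regions.add(region.defining_snps)
                taboo.add(region)
                niches.append(region)
            harvest_elites(memories, elites, config.hms)
            restarts += 1
            try:
                memories = initialize_memories(
                    dataset, config.k, config.hms, taboo, rng,
                    counter=counter, score_cache=cache,
                )
            except SearchExhaustionError:
                exhausted = True
                break

    harvest_elites(memories, elites, config.hms)

    merged: dict[SnpCombination, ScoreTriple] = {}
    for elite in elites:
        for combo, _score in elite.top(config.cs_capacity):
            merged.setdefault(combo, cache[combo])
    candidates = sorted(merged.items(), key=lambda kv: (kv[1].k2, kv[0]))
    return ScreenResult(
        candidates=candidates,
        evaluations_used=counter.count,
        restarts=restarts,
        niches=niches,
        trace=trace_rows,
        exhausted=exhausted,
        early_stop_hit=early_stop_hit,
        evaluations_to_hit=evaluations_to_hit,
    )


def resolve_threshold(
    dataset: CaseControlDataset, config: NhsaConfig, n_candidates: int
) -> float:
    if config.n_tests_mode == "fixed":
        return float(config.fixed_threshold)
    if config.n_tests_mode == "candidates":
        return bonferroni_threshold(config.alpha, max(n_candidates, 1))
    n_tests = combination_count(dataset.n_snps, config.k)
    return bonferroni_threshold(config.alpha, n_tests)


def verify(
    dataset: CaseControlDataset,
    screen_result: ScreenResult,
    config: NhsaConfig,
    wall_time: float = 0.0,
) -> DetectionResult:
    """Modified G-test over the candidate set with Bonferroni thresholding."""
    config = config.resolved(dataset)
    candidates = screen_result.candidates
    threshold = resolve_threshold(dataset, config, len(candidates))
    tested: list[GTestResult] = []
    for combo, _triple in candidates:
        result = g_test(
            dataset, combo, xi=config.xi,
            expected_mode=config.expected_mode, threshold=threshold,
        )
        tested.append(result)
    significant = [r for r in tested if r.significant]
    untestable = [r for r in tested if r.untestable]
    return DetectionResult(
        candidates=candidates,
        tested=tested,
        significant=significant,
        untestable=untestable,
        evaluations_used=screen_result.evaluations_used,
        wall_time=wall_time,
        restarts=screen_result.restarts,
        niches=screen_result.niches,
        threshold=threshold,
        config=config,
        early_stop_hit=screen_result.early_stop_hit,
        evaluations_to_hit=screen_result.evaluations_to_hit,
    )


def run(
    dataset: CaseControlDataset,
    config: NhsaConfig,
    out_dir=None,
    trace: bool = False,
) -> DetectionResult:
    """Screen then verify; optionally persist a reproducible run directory."""
    start = time.perf_counter()
    screen_result = screen(dataset, config, trace=trace)
    result = verify(
        dataset, screen_result, config,
        wall_time=time.perf_counter() - start,
    )
    if out_dir is not None:
        write_run_directory(dataset, result, screen_result, out_dir)
    return result


def write_run_directory(
    dataset: CaseControlDataset,
    result: DetectionResult,
    screen_result: ScreenResult,
    out_dir,
) -> None:
    """Persist config.yaml, candidates.tsv, results.tsv, trace.tsv, log.txt.

    Result files carry no timestamps, so identical (dataset, config,
    seed) runs produce byte-identical tables.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with open(out / "config.yaml", "w") as handle:
        yaml.safe_dump(result.config.to_dict(), handle, sort_keys=False)

    with open(out / "candidates.tsv", "w") as handle:
        handle.write("snp_names\tk\tk2\tgini\tentropy\n")
        for combo, triple in result.candidates:
            names = ",".join(dataset.name_combination(combo))
            handle.write(
                f"{names}\t{len(combo)}\t{triple.k2:.10g}\t"
                f"{triple.gini:.10g}\t{triple.entropy:.10g}\n"
            )

    with open(out / "results.tsv", "w") as handle:
        handle.write(
            "snp_names\tk\tG\tdf\tp_value\texcluded_genotypes\t"
            "significant\tthreshold\n"
        )
        for test in result.tested:
            names = ",".join(test.combo_names or ())
            excl = ";".join(
                "-".join(str(g) for g in key) for key in test.excluded_columns
            )
            p_txt = "NA" if test.p_value is None else f"{test.p_value:.10g}"
            handle.write(
                f"{names}\t{len(test.combo_names or ())}\t{test.g:.10g}\t"
                f"{test.df}\t{p_txt}\t{excl}\t"
                f"{str(test.significant).lower()}\t{test.threshold:.10g}\n"
            )

    with open(out / "trace.tsv", "w") as handle:
        handle.write("iteration\tsnp_names\tk2\tgini\tentropy\taccepted\n")
        for row in screen_result.trace:
            handle.write(
                f"{row['iteration']}\t{','.join(row['combo'])}\t"
                f"{row['k2']:.10g}\t{row['gini']:.10g}\t{row['entropy']:.10g}\t"
                f"{row['accepted']}\n"
            )

    with open(out / "log.txt", "w") as handle:
        handle.write(f"time: {time.strftime('%Y-%m-%dT%H:%M:%S')}\n")
        handle.write(f"n={dataset.n} n_snps={dataset.n_snps}\n")
        handle.write(
            f"evaluations={result.evaluations_used} restarts={result.restarts} "
            f"niches={len(result.niches)} wall_time={result.wall_time:.3f}s\n"
        )
        handle.write(
            f"candidates={len(result.candidates)} "
            f"significant={len(result.significant)} "
            f"untestable={len(result.untestable)}\n"
        )
        if result.early_stop_hit:
            handle.write(
                f"early_stop: truth evaluated after "
                f"{result.evaluations_to_hit} evaluations\n"
            )


def export_edge_list(result: DetectionResult, path) -> None:
    """Pairwise SNP-SNP edges with p-values, loadable by network tools."""
    with open(path, "w") as handle:
        handle.write("source\ttarget\tp_value\n")
        for test in result.significant:
            names = test.combo_names or ()
            p_txt = "NA" if test.p_value is None else f"{test.p_value:.10g}"
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    handle.write(f"{names[i]}\t{names[j]}\t{p_txt}\n")
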