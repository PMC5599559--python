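"""Niche harmony search core.

Three harmony memories (one per objective: k2, gini, entropy) share every
candidate evaluation: a new harmony is improvised, scored once, and
offered to each memory independently.  When all three memories stagnate,
each memory's convergence core is registered as a taboo niche region and
the memories are reinitialized away from all taboo regions; the best
members survive in per-objective elite sets.

The improvisation, niche-identification and taboo rules follow the
standard discrete harmony-search operator set (memory consideration at
rate HMCR, pitch adjustment at rate PAR, random choice otherwise), with
niches expressed as SNP-overlap bans: a candidate sharing more than
``radius`` loci with a region's defining SNP set is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import CaseControlDataset, SnpCombination
from .scoring import EvaluationCounter, ScoreTriple, score_combination

__all__ = [
    "OBJECTIVES",
    "HarmonyMemory",
    "NicheRegion",
    "TabooTable",
    "EliteSet",
    "SearchExhaustionError",
    "initialize_memories",
    "improvise_harmony",
    "update_memory",
    "identify_niche",
    "is_tabooed",
    "harvest_elites",
]

OBJECTIVES = ("k2", "gini", "entropy")


class SearchExhaustionError(RuntimeError):
    """The taboo table (or retry budget) leaves no combination to visit."""


@dataclass(frozen=True)
class NicheRegion:
    """A converged search region: ban combinations overlapping it too much."""

    defining_snps: frozenset[int]
    radius: int
    best_member: SnpCombination
    best_score: float
    objective: str

    def __post_init__(self) -> None:
        if not self.defining_snps:
            raise ValueError("defining_snps must be non-empty")
        if self.radius < 0:
            raise ValueError("radius must be non-negative")


class TabooTable:
    """Pure membership test over the registered niche regions."""

    def __init__(self, regions: list[NicheRegion] | None = None) -> None:
        self.regions: list[NicheRegion] = list(regions or [])

    def add(self, region: NicheRegion) -> None:
        self.regions.append(region)

    def __len__(self) -> int:
        return len(self.regions)

    def is_tabooed(self, combo: tuple[int, ...]) -> bool:
        for region in self.regions:
            if len(region.defining_snps.intersection(combo)) > region.radius:
                return True
        return False


def is_tabooed(combo: tuple[int, ...], taboo: TabooTable) -> bool:
    return taboo.is_tabooed(combo)


@dataclass
class HarmonyMemory:
    """Fixed-size archive of the best combinations under one objective."""

    objective: str
    hms: int
    harmonies: list[SnpCombination] = field(default_factory=list)
    scores: list[float] = field(default_factory=list)
    stagnation_counter: int = 0

    @property
    def worst_index(self) -> int:
        return int(np.argmax(self.scores))

    @property
    def best_index(self) -> int:
        return int(np.argmin(self.scores))

    @property
    def best(self) -> tuple[SnpCombination, float]:
        i = self.best_index
        return self.harmonies[i], self.scores[i]

    def fill(self, combos: list[SnpCombination], triples: list[ScoreTriple]) -> None:
        if len(combos) != self.hms:
            raise ValueError(f"expected {self.hms} harmonies, got {len(combos)}")
        self.harmonies = list(combos)
        self.scores = [t.by_objective(self.objective) for t in triples]
        self.stagnation_counter = 0

    def update(self, candidate: SnpCombination, score: float) -> bool:
        """Survival of the fittest: replace the worst member if strictly
        beaten; duplicates are rejected regardless of score."""
        if candidate in self.harmonies:
            self.stagnation_counter += 1
            return False
        w = self.worst_index
        if score < self.scores[w]:
            self.harmonies[w] = candidate
            self.scores[w] = score
            self.stagnation_counter = 0
            return True
        self.stagnation_counter += 1
        return False

    def top(self, m: int) -> list[tuple[SnpCombination, float]]:
        order = np.argsort(self.scores, kind="stable")[:m]
        return [(self.harmonies[i], self.scores[i]) for i in order]


def update_memory(
    memory: HarmonyMemory, candidate: SnpCombination, candidate_score: float
) -> bool:
    return memory.update(candidate, candidate_score)


def _random_combination(
    n_snps: int, k: int, taboo: TabooTable, rng: np.random.Generator,
    max_attempts: int = 5000,
) -> SnpCombination:
    for _ in range(max_attempts):
        combo = SnpCombination(sorted(rng.choice(n_snps, size=k, replace=False)))
        if not taboo.is_tabooed(combo):
            return combo
    raise SearchExhaustionError(
        "could not draw a non-tabooed combination; the taboo table may "
        "cover the whole space"
    )


def initialize_memories(
    dataset: CaseControlDataset,
    k: int,
    hms: int,
    taboo: TabooTable,
    rng: np.random.Generator,
    counter: EvaluationCounter | None = None,
    score_cache: dict[SnpCombination, ScoreTriple] | None = None,
) -> tuple[HarmonyMemory, HarmonyMemory, HarmonyMemory]:
    """Fill HM1/HM2/HM3 with ``hms`` distinct random non-tabooed combinations.

    Each combination is scored by a single contingency pass and the
    resulting triple populates all three memories (one evaluation per
    combination, not three).  Previously scored combinations are reused
    from ``score_cache`` without consuming budget.
    """
    if hms < 2:
        raise ValueError("hms must be >= 2")
    combos: list[SnpCombination] = []
    seen: set[SnpCombination] = set()
    attempts = 0
    while len(combos) < hms:
        attempts += 1
        if attempts > 200 * hms:
            raise SearchExhaustionError(
                "could not assemble enough distinct non-tabooed combinations"
            )
        combo = _random_combination(dataset.n_snps, k, taboo, rng)
        if combo in seen:
            continue
        seen.add(combo)
        combos.append(combo)
    triples = []
    for combo in combos:
        if score_cache is not None and combo in score_cache:
            triples.append(score_cache[combo])
            continue
        triple = score_combination(dataset, combo, counter=counter)
        if score_cache is not None:
            score_cache[combo] = triple
        triples.append(triple)
    memories = tuple(HarmonyMemory(obj, hms) for obj in OBJECTIVES)
    for memory in memories:
        memory.fill(combos, triples)
    return memories  # type: ignore[return-value]


def improvise_harmony(
    memories: tuple[HarmonyMemory, ...],
    hmcr: float,
    par: float,
    n_snps: int,
    k: int,
    taboo: TabooTable,
    rng: np.random.Generator,
    max_retries: int = 50,
) -> SnpCombination:
    """Improvise a new k-way combination.

    Per position: memory consideration with probability HMCR (draw the
    value at that position from a random harmony of a random memory),
    then pitch adjustment with probability PAR (shift the index +/-1,
    reflecting at the boundary); otherwise a uniform random index.
    Collisions are redrawn uniformly, the result sorted; tabooed
    candidates are regenerated up to ``max_retries`` before falling back
    to a pure random non-tabooed draw.
    """
    if not 0 <= hmcr <= 1 or not 0 <= par <= 1:
        raise ValueError("hmcr and par must lie in [0, 1]")
    for _ in range(max_retries):
        chosen: set[int] = set()
        for position in range(k):
            if rng.random() < hmcr:
                memory = memories[rng.integers(len(memories))]
                harmony = memory.harmonies[rng.integers(len(memory.harmonies))]
                value = harmony[position]
                if rng.random() < par:
                    value += 1 if rng.random() < 0.5 else -1
                    if value < 0:
                        value = 1
                    elif value >= n_snps:
                        value = n_snps - 2
            else:
                value = int(rng.integers(n_snps))
            while value in chosen:
                value = int(rng.integers(n_snps))
            chosen.add(value)
        candidate = SnpCombination(sorted(chosen))
        if not taboo.is_tabooed(candidate):
            return candidate
    return _random_combination(n_snps, k, taboo, rng)


def identify_niche(memory: HarmonyMemory, k: int) -> NicheRegion:
    """Characterize a stagnant memory's convergence core.

    The defining SNPs are those appearing in strictly more than HMS/2 of
    the memory's harmonies; if no SNP reaches a majority, the best
    harmony's full index set is used.  The radius is |defining| - 1
    capped at k - 1, so revisiting the converged core is banned while
    partial overlap stays allowed.
    """
    counts: dict[int, int] = {}
    for harmony in memory.harmonies:
        for snp in harmony:
            counts[snp] = counts.get(snp, 0) + 1
    half = len(memory.harmonies) / 2.0
    defining = frozenset(snp for snp, c in counts.items() if c > half)
    best_combo, best_score = memory.best
    if not defining:
        defining = frozenset(best_combo)
    radius = min(len(defining) - 1, k - 1)
    return NicheRegion(
        defining_snps=defining,
        radius=radius,
        best_member=best_combo,
        best_score=best_score,
        objective=memory.objective,
    )


class EliteSet:
    """Deduplicated best-combination archive for one objective."""

    def __init__(self, objective: str, capacity: int) -> None:
        if capacity < 1:
            raise ValueError("capacity must be positive")
        self.objective = objective
        self.capacity = capacity
        self._scores: dict[SnpCombination, float] = {}

    def __len__(self) -> int:
        return len(self._scores)

    @property
    def members(self) -> list[tuple[SnpCombination, float]]:
        return sorted(self._scores.items(), key=lambda kv: (kv[1], kv[0]))

    def offer(self, combo: SnpCombination, score: float) -> None:
        if combo in self._scores:
            self._scores[combo] = min(self._scores[combo], score)
        else:
            self._scores[combo] = score
        if len(self._scores) > self.capacity:
            worst = max(self._scores.items(), key=lambda kv: (kv[1], kv[0]))[0]
            del self._scores[worst]

    def top(self, m: int) -> list[tuple[SnpCombination, float]]:
        return self.members[:m]


def harvest_elites(
    memories: tuple[HarmonyMemory, ...],
    elite_sets: tuple[EliteSet, ...],
    m: int,
) -> None:
    """Merge each memory's top-m harmonies into its elite set (idempotent)."""
    for memory, elite in zip(memories, elite_sets):
        if memory.objective != elite.objective:
            raise ValueError("memory/elite objective mismatch")
        for combo, score in memory.top(m):
            elite.offer(combo, score)
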