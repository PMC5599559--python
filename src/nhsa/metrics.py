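"""Batch evaluation over replicate runs: power, TPR, SPC, ACC, FDR, MEs.

A candidate counts as *the* disease model only under exact set equality
with the causal SNP columns; confusion counts are taken over the
candidates carried into the verification stage.  Degenerate denominators
follow the published conventions: SPC = 0 when FP + TN = 0 and FDR = 0
when TP + FP = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

from .pipeline import DetectionResult
from .simulate import SimTruth

__all__ = ["ReplicateOutcome", "BatchEvaluation", "classify_outcomes", "summarize_batch"]


@dataclass
class ReplicateOutcome:
    tp: int
    fp: int
    tn: int
    fn: int
    found: bool
    significant_found: bool
    evaluations: int
    runtime: float = 0.0


@dataclass
class BatchEvaluation:
    power_stage1: float
    power_stage2: float
    tpr: float
    spc: float
    acc: float
    fdr: float
    mes: float
    runtime_mean: float
    per_replicate: list[ReplicateOutcome]


def classify_outcomes(result: DetectionResult, truth: SimTruth) -> ReplicateOutcome:
    """Confusion counts of one replicate's verification stage.

    TP: the causal model was a candidate and passed the threshold.
    FN: it was a candidate but failed.  If it never reached the candidate
    set, it contributes to neither (that loss is charged to stage-one
    power via ``found``).  FP/TN count the non-causal candidates.
    """
    causal = tuple(sorted(truth.causal_column_indices))
    tp = fp = tn = fn = 0
    found = False
    significant_found = False
    for test, (combo, _triple) in zip(result.tested, result.candidates):
        is_causal = tuple(combo) == causal
        if is_causal:
            found = True
            if test.significant:
                tp += 1
                significant_found = True
            else:
                fn += 1
        else:
            if test.significant:
                fp += 1
            else:
                tn += 1
    evaluations = (
        result.evaluations_to_hit
        if result.evaluations_to_hit is not None
        else result.evaluations_used
    )
    return ReplicateOutcome(
        tp=tp, fp=fp, tn=tn, fn=fn,
        found=found, significant_found=significant_found,
        evaluations=evaluations, runtime=result.wall_time,
    )


def summarize_batch(outcomes: list[ReplicateOutcome]) -> BatchEvaluation:
    if not outcomes:
        raise ValueError("need at least one replicate")
    n = len(outcomes)
    tp = sum(o.tp for o in outcomes)
    fp = sum(o.fp for o in outcomes)
    tn = sum(o.tn for o in outcomes)
    fn = sum(o.fn for o in outcomes)
    tpr = tp / (tp + fn) if tp + fn > 0 else 0.0
    spc = tn / (fp + tn) if fp + tn > 0 else 0.0
    total = tp + tn + fn + fp
    acc = (tp + tn) / total if total > 0 else 0.0
    fdr = fp / (tp + fp) if tp + fp > 0 else 0.0
    return BatchEvaluation(
        power_stage1=sum(o.found for o in outcomes) / n,
        power_stage2=sum(o.significant_found for o in outcomes) / n,
        tpr=tpr, spc=spc, acc=acc, fdr=fdr,
        mes=sum(o.evaluations for o in outcomes) / n,
        runtime_mean=sum(o.runtime for o in outcomes) / n,
        per_replicate=list(outcomes),
    )
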