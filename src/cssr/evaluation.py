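"""Base-pair level comparison of predicted and reference structures.

A predicted pair counts as a true positive only when the identical
unordered index pair is present in the reference (no slippage credit by
default).  The negative universe for MCC is all L(L-1)/2 unordered
nucleotide pairs of the sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .assignment import SecondaryStructure
from .params import pair_class

__all__ = ["EvalResult", "AggregateResult", "evaluate", "aggregate",
           "classify_pairs"]


@dataclass(frozen=True)
class EvalResult:
    """Pair-level confusion counts and summary metrics for one structure."""

    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f1: float
    mcc: float


@dataclass(frozen=True)
class AggregateResult:
    """Unweighted per-target mean and SEM of F1 and MCC."""

    mean_f1: float
    sem_f1: float
    mean_mcc: float
    sem_mcc: float
    n: int


def _slip_match(pair: tuple[int, int], reference: set[tuple[int, int]]) -> bool:
    i, j = pair
    return any((i + di, j + dj) in reference
               for di in (-1, 0, 1) for dj in (-1, 0, 1))


def evaluate(predicted: SecondaryStructure, reference: SecondaryStructure,
             slippage: bool = False) -> EvalResult:
    """Compare two structures over the same sequence positions.

    With ``slippage=True`` a predicted pair also counts as correct when
    one of its indices is off by one from a reference pair (a lenient
    mode; default off).

    Conventions: both sides empty -> precision = recall = F1 = MCC = 1;
    exactly one side empty -> F1 = 0.
    """
    if len(predicted) != len(reference):
        raise ValueError(
            f"length mismatch: predicted {len(predicted)} vs "
            f"reference {len(reference)}")
    L = len(predicted)
    pred = predicted.pairs
    ref = reference.pairs
    if slippage:
        tp = sum(1 for p in pred if _slip_match(p, ref))
    else:
        tp = len(pred & ref)
    fp = len(pred) - tp
    fn = len(ref) - len(pred & ref) if slippage else len(ref) - tp
    total = L * (L - 1) // 2
    tn = total - tp - fp - fn

    if not pred and not ref:
        return EvalResult(tp=0, fp=0, fn=0, tn=total,
                          precision=1.0, recall=1.0, f1=1.0, mcc=1.0)
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if (precision + recall) else 0.0)
    denom = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = ((tp * tn - fp * fn) / denom) if denom else 0.0
    return EvalResult(tp=tp, fp=fp, fn=fn, tn=tn, precision=precision,
                      recall=recall, f1=f1, mcc=mcc)


def aggregate(results: Sequence[EvalResult]) -> AggregateResult:
    """Per-target mean and standard error of the mean of F1 and MCC.

    SEM uses the sample standard deviation (ddof = 1) over sqrt(n); a
    single target gets SEM = 0.
    """
    if not results:
        raise ValueError("cannot aggregate an empty result list")
    n = len(results)

    def mean_sem(values: list[float]) -> tuple[float, float]:
        m = sum(values) / n
        if n == 1:
            return m, 0.0
        var = sum((v - m) ** 2 for v in values) / (n - 1)
        return m, math.sqrt(var / n)

    mean_f1, sem_f1 = mean_sem([r.f1 for r in results])
    mean_mcc, sem_mcc = mean_sem([r.mcc for r in results])
    return AggregateResult(mean_f1=mean_f1, sem_f1=sem_f1,
                           mean_mcc=mean_mcc, sem_mcc=sem_mcc, n=n)


def classify_pairs(ss: SecondaryStructure) -> dict[str, set[tuple[int, int]]]:
    """Partition pairs into Watson–Crick and wobble sets by base identity."""
    out: dict[str, set[tuple[int, int]]] = {"WC": set(), "WOBBLE": set()}
    for i, j in ss.pairs:
        cls = pair_class(ss.sequence[i], ss.sequence[j])
        if cls is None:
            raise ValueError(
                f"pair ({i}, {j}) with bases "
                f"{ss.sequence[i]}:{ss.sequence[j]} is not canonical")
        out[cls].add((i, j))
    return out
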