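"""Top-k ranking evaluation: precision/recall/F1, confusion matrix,
rank-bin distribution, and query-size sensitivity curves.

Conventions: a record counts as a true positive when its true disease
appears in the model's top k and the model scored at least one candidate
positively; a false positive when the model predicted but the truth is
outside the top k; a false negative when the model abstained (no positively
scored candidate).  F1 is the standard harmonic mean of precision and
recall.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import InputError
from .ml_models import PatientRecord
from .similarity_models import RankedResult

ABSTAIN = "__abstain__"


@dataclass
class TopKMetrics:
    k: int
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        denom = self.tp + self.fp
        return self.tp / denom if denom else 0.0

    @property
    def recall(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0

    def as_dict(self) -> dict:
        return {
            "k": self.k,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


@dataclass
class ConfusionMatrix:
    """rows = true disease, columns = predicted disease (+ abstain column)."""

    labels: list[str]
    counts: dict[tuple[str, str], int] = field(default_factory=dict)

    def increment(self, truth: str, predicted: str) -> None:
        self.counts[(truth, predicted)] = self.counts.get((truth, predicted), 0) + 1

    @property
    def grand_total(self) -> int:
        return sum(self.counts.values())

    def to_tsv(self) -> str:
        cols = self.labels + [ABSTAIN]
        lines = ["true\\predicted\t" + "\t".join(cols)]
        for t in self.labels:
            lines.append(t + "\t" + "\t".join(str(self.counts.get((t, c), 0)) for c in cols))
        return "\n".join(lines) + "\n"


@dataclass
class RankingDistribution:
    """Fractions of records whose truth ranks top-1, within top-10
    (cumulative, includes top-1), beyond 10, or not at all."""

    fractions: dict[str, float]


Result = tuple[RankedResult, str]


def evaluate_topk(results: Sequence[Result], k: int) -> TopKMetrics:
    """Tally TP/FP/FN over ranked results paired with truth labels."""
    if not results:
        raise InputError("no results to evaluate")
    if k < 1:
        raise InputError("k must be >= 1")
    tp = fp = fn = 0
    for ranked, truth in results:
        if ranked.abstained():
            fn += 1
        elif truth in {d for d, _ in ranked.top(k)}:
            tp += 1
        else:
            fp += 1
    return TopKMetrics(k=k, tp=tp, fp=fp, fn=fn)


def confusion_topk(results: Sequence[Result], k: int) -> ConfusionMatrix:
    """Confusion matrix at cutoff k.

    A record lands on the diagonal when the truth is in the top k, otherwise
    in the (truth, top-1 prediction) cell; abstentions go to a dedicated
    column.
    """
    if not results:
        raise InputError("no results to evaluate")
    labels = sorted(
        {truth for _, truth in results}
        | {d for ranked, _ in results if not ranked.abstained() for d, _ in ranked.top(1)}
    )
    cm = ConfusionMatrix(labels=labels)
    for ranked, truth in results:
        if ranked.abstained():
            cm.increment(truth, ABSTAIN)
        elif truth in {d for d, _ in ranked.top(k)}:
            cm.increment(truth, truth)
        else:
            cm.increment(truth, ranked.top(1)[0][0])
    return cm


def ranking_distribution(results: Sequence[Result]) -> RankingDistribution:
    """Bin each record's truth rank; the top10 fraction is cumulative
    (includes top1), so top10 + other + unranked = 1."""
    if not results:
        raise InputError("no results to evaluate")
    n = len(results)
    top1 = top10 = other = unranked = 0
    for ranked, truth in results:
        r = ranked.rank_of(truth)
        if r is None:
            unranked += 1
        elif r == 1:
            top1 += 1
            top10 += 1
        elif r <= 10:
            top10 += 1
        else:
            other += 1
    return RankingDistribution(
        fractions={
            "top1": top1 / n,
            "top10": top10 / n,
            "other": other / n,
            "unranked": unranked / n,
        }
    )


def sensitivity_by_query_size(
    model: Callable[[list[str]], RankedResult],
    cohort: Sequence[PatientRecord],
    sizes: Sequence[int],
    k: int,
    seed: int = 0,
) -> dict[int, TopKMetrics]:
    """Metric curve over query sizes.

    For each size s, each record's phenotype list is subsampled uniformly
    without replacement to ``min(s, available)`` terms (seeded), re-ranked
    through ``model`` and scored at ``k``.
    """
    if not cohort:
        raise InputError("empty cohort")
    if any(s < 1 for s in sizes):
        raise InputError("sizes must be positive")
    if any(not p.phenotypes for p in cohort):
        raise InputError("every cohort record needs >= 1 phenotype")
    out: dict[int, TopKMetrics] = {}
    for s in sizes:
        rng = np.random.default_rng([seed, s])
        results: list[Result] = []
        for p in cohort:
            terms = sorted(set(p.phenotypes))
            take = min(s, len(terms))
            chosen = [terms[i] for i in rng.choice(len(terms), size=take, replace=False)]
            results.append((model(chosen), p.true_disease or ""))
        out[s] = evaluate_topk(results, k)
    return out
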