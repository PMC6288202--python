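"""Score-distribution normalization and weighted averaging of model members.

Every ranking model produces one raw score map per classifier; each map is
min-max rescaled to [0, 1] and sum-normalized into a proper distribution,
and the member distributions are combined by a convex (weight-normalized)
average.  Min-max-then-sum preserves each member's internal ranking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ConsistencyError, InputError


@dataclass
class ScoreDistribution:
    scores: dict[str, float]
    normalized: bool = False

    def __getitem__(self, key: str) -> float:
        return self.scores[key]

    def items(self):
        return self.scores.items()


def normalize_scores(raw: dict[str, float]) -> ScoreDistribution:
    """Min-max rescale then divide by the sum; constant input -> uniform.

    Raises :class:`InputError` on an empty or non-finite map.
    """
    if not raw:
        raise InputError("cannot normalize an empty score map")
    values = list(raw.values())
    if not all(math.isfinite(v) for v in values):
        raise InputError("scores must be finite")
    lo, hi = min(values), max(values)
    n = len(raw)
    if hi == lo:
        return ScoreDistribution({k: 1.0 / n for k in raw}, normalized=True)
    scaled = {k: (v - lo) / (hi - lo) for k, v in raw.items()}
    total = sum(scaled.values())
    return ScoreDistribution({k: v / total for k, v in scaled.items()}, normalized=True)


def bayesian_average(
    members: list[tuple[ScoreDistribution, float]]
) -> ScoreDistribution:
    """Convex combination of member distributions with normalized weights.

    All members must share one label set and all weights must be
    non-negative with a positive total.
    """
    if not members:
        raise InputError("no members to combine")
    label_set = set(members[0][0].scores)
    for dist, _ in members[1:]:
        if set(dist.scores) != label_set:
            raise ConsistencyError("member distributions have mismatched label sets")
    weights = [w for _, w in members]
    if any(w < 0 for w in weights):
        raise InputError("member weights must be non-negative")
    total_w = sum(weights)
    if total_w <= 0:
        raise InputError("member weights must not all be zero")
    combined = {k: 0.0 for k in label_set}
    for dist, w in members:
        share = w / total_w
        if share == 0.0:
            continue
        for k, v in dist.items():
            combined[k] += share * v
    return ScoreDistribution(combined, normalized=True)
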