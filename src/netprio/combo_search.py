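"""Exhaustive feature-combination search.

All 2^n − 1 non-empty subsets of the effective features are evaluated by the
same balanced-resampling procedure used for single-feature screening, with
the per-round negative samples shared across subsets so that the combination
ranking is a paired comparison rather than confounded by sampling noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .network_io import GeneSetPartition
from .screening import EvalMetrics, SVMConfig, evaluate_feature_set
from .topo_features import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = ["ComboResult", "enumerate_combinations", "evaluate_combinations", "select_optima"]

_MAX_FEATURES = 20


@dataclass(frozen=True)
class ComboResult:
    subset: tuple[str, ...]
    metrics: EvalMetrics
    score: float
    rank: int


def enumerate_combinations(features: Sequence[str]) -> list[tuple[str, ...]]:
    """All non-empty subsets in bitmask-ascending order (bit i = features[i])."""
    features = tuple(features)
    n = len(features)
    if n == 0:
        raise ValueError("empty feature list")
    if n > _MAX_FEATURES:
        raise ValueError(f"refusing exhaustive enumeration for n > {_MAX_FEATURES}")
    subsets = []
    for mask in range(1, 2**n):
        subsets.append(tuple(features[i] for i in range(n) if mask >> i & 1))
    return subsets


def _youden(m: EvalMetrics) -> float:
    return m.tpr - m.fpr


def evaluate_combinations(
    matrix: FeatureMatrix,
    partition: GeneSetPartition,
    subsets: Sequence[Sequence[str]],
    n_rounds: int,
    cv_folds: int = 10,
    classifier_config: SVMConfig | None = None,
    seed: int = 0,
) -> list[ComboResult]:
    """Evaluate every subset on the same per-round negative draws."""
    neg = sorted(partition.negative.members)
    n_pos = len(partition.positive.members)
    if len(neg) < n_pos:
        raise ValueError("fewer negatives than positives")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    draws = [
        [neg[i] for i in rng.choice(len(neg), size=n_pos, replace=False)]
        for _ in range(n_rounds)
    ]
    results = []
    for subset in subsets:
        metrics = evaluate_feature_set(
            matrix,
            partition,
            subset,
            n_rounds=n_rounds,
            cv_folds=cv_folds,
            classifier_config=classifier_config,
            seed=seed,
            negative_draws=draws,
        )
        results.append((tuple(subset), metrics))
    scored = [
        ComboResult(subset=s, metrics=m, score=_youden(m), rank=0)
        for s, m in results
    ]
    order = sorted(
        range(len(scored)),
        key=lambda i: (-scored[i].score, -scored[i].metrics.precision, len(scored[i].subset), scored[i].subset),
    )
    ranked = [None] * len(scored)
    for rank, i in enumerate(order, start=1):
        c = scored[i]
        ranked[i] = ComboResult(subset=c.subset, metrics=c.metrics, score=c.score, rank=rank)
    return ranked  # type: ignore[return-value]


def select_optima(results: Sequence[ComboResult], rule: str = "youden") -> ComboResult:
    """Pick the best combination.

    ``youden``: maximize tpr − fpr; ties broken by higher precision, then
    smaller subset, then lexicographically.
    ``precision_first``: maximize precision; ties broken by tpr − fpr, then
    smaller subset, then lexicographically.
    """
    if not results:
        raise ValueError("no combination results")
    if rule == "youden":
        key = lambda c: (-(c.metrics.tpr - c.metrics.fpr), -c.metrics.precision, len(c.subset), c.subset)
    elif rule == "precision_first":
        key = lambda c: (-c.metrics.precision, -(c.metrics.tpr - c.metrics.fpr), len(c.subset), c.subset)
    else:
        raise ValueError(f"unknown optima rule: {rule!r}")
    best = min(results, key=key)
    logger.info(
        "optima subset: %s (precision=%.3f tpr=%.3f fpr=%.3f)",
        "+".join(best.subset), best.metrics.precision, best.metrics.tpr, best.metrics.fpr,
    )
    return best
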