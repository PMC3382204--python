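"""Per-feature disparity testing and balanced-resampling SVM evaluation.

Each evaluation round draws as many negatives as there are positives (without
replacement), z-scores features on the training split and runs stratified
k-fold cross-validation of an SVM, accumulating TP/FP/TN/FN over held-out
folds. Metrics are averaged over rounds; everything is reproducible from a
single seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .network_io import GeneSetPartition
from .topo_features import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DisparityResult",
    "EvalMetrics",
    "SVMConfig",
    "SelectionRule",
    "wilcoxon_disparity",
    "evaluate_feature_set",
    "select_effective_features",
]


@dataclass(frozen=True)
class DisparityResult:
    feature: str
    statistic: float  # rank-sum statistic W of the first sample
    p_value: float
    significant: bool
    alpha: float = 0.05


@dataclass(frozen=True)
class EvalMetrics:
    feature_subset: tuple[str, ...]
    precision: float
    tpr: float
    fpr: float
    n_rounds: int
    dispersion: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for name in ("precision", "tpr", "fpr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} out of [0,1]")


@dataclass(frozen=True)
class SVMConfig:
    """SVM hyperparameters; gamma follows scikit-learn's 'scale' heuristic."""

    kernel: str = "rbf"
    C: float = 1.0
    gamma: str | float = "scale"

    def build(self) -> SVC:
        return SVC(kernel=self.kernel, C=self.C, gamma=self.gamma)


@dataclass(frozen=True)
class SelectionRule:
    """Effectiveness rule applied after disparity significance."""

    p_min: float = 0.55
    t_min: float = 0.55
    f_max: float = 0.45
    method: str = "threshold"  # or "drop_worst_k"
    k: int = 1


def wilcoxon_disparity(
    pos_values: Sequence[float],
    neg_values: Sequence[float],
    alpha: float = 0.05,
    feature: str = "",
) -> DisparityResult:
    """Two-sided rank-sum test with tie correction."""
    pos = np.asarray(pos_values, dtype=float)
    neg = np.asarray(neg_values, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both value lists must be non-empty")
    # exact null distribution for small tie-free samples; normal approximation
    # with tie correction otherwise
    has_ties = len(np.unique(np.concatenate([pos, neg]))) < pos.size + neg.size
    method = "asymptotic" if (has_ties or max(pos.size, neg.size) > 25) else "exact"
    u, p = stats.mannwhitneyu(pos, neg, alternative="two-sided", method=method)
    n1 = pos.size
    w = float(u + n1 * (n1 + 1) / 2.0)  # rank-sum of the positive sample
    return DisparityResult(
        feature=feature,
        statistic=w,
        p_value=float(p),
        significant=bool(p < alpha),
        alpha=alpha,
    )


def _cv_round(
    X: np.ndarray,
    y: np.ndarray,
    cv_folds: int,
    config: SVMConfig,
    fold_seed: int,
) -> tuple[int, int, int, int]:
    """Stratified CV; returns (TP, FP, TN, FN) accumulated over held-out folds."""
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=fold_seed)
    tp = fp = tn = fn = 0
    for train_idx, test_idx in skf.split(X, y):
        scaler = StandardScaler()
        Xtr = scaler.fit_transform(X[train_idx])
        Xte = scaler.transform(X[test_idx])
        clf = config.build()
        clf.fit(Xtr, y[train_idx])
        pred = clf.predict(Xte)
        truth = y[test_idx]
        tp += int(np.sum((pred == 1) & (truth == 1)))
        fp += int(np.sum((pred == 1) & (truth == 0)))
        tn += int(np.sum((pred == 0) & (truth == 0)))
        fn += int(np.sum((pred == 0) & (truth == 1)))
    return tp, fp, tn, fn


def _safe_div(a: float, b: float) -> float:
    return a / b if b else 0.0


def evaluate_feature_set(
    matrix: FeatureMatrix,
    partition: GeneSetPartition,
    subset: Sequence[str],
    n_rounds: int,
    cv_folds: int = 10,
    classifier_config: SVMConfig | None = None,
    seed: int = 0,
    negative_draws: Sequence[Sequence[str]] | None = None,
) -> EvalMetrics:
    """Balanced-resampling cross-validated evaluation of one feature subset.

    ``negative_draws`` lets callers share the per-round negative samples
    across several subsets (paired comparison); when omitted, draws are
    generated from ``seed``.
    """
    subset = tuple(subset)
    missing = [f for f in subset if f not in matrix.feature_names]
    if missing:
        raise ValueError(f"subset features not in matrix: {missing}")
    config = classifier_config or SVMConfig()

    pos = sorted(partition.positive.members)
    neg = sorted(partition.negative.members)
    if len(pos) < cv_folds:
        raise ValueError(f"need at least {cv_folds} positives, got {len(pos)}")
    if len(neg) < len(pos):
        raise ValueError("fewer negatives than positives")
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")

    X_pos = matrix.values(subset, pos)
    for j, f in enumerate(subset):
        if np.allclose(np.var(matrix.values((f,), pos + neg)), 0.0):
            logger.info("feature %s has zero variance over labeled genes", f)

    ss = np.random.SeedSequence(seed)
    round_seeds = ss.spawn(n_rounds)
    precisions = np.empty(n_rounds)
    tprs = np.empty(n_rounds)
    fprs = np.empty(n_rounds)
    for r in range(n_rounds):
        rng = np.random.default_rng(round_seeds[r])
        if negative_draws is not None:
            neg_sample = list(negative_draws[r])
        else:
            idx = rng.choice(len(neg), size=len(pos), replace=False)
            neg_sample = [neg[i] for i in idx]
        X = np.vstack([X_pos, matrix.values(subset, neg_sample)])
        y = np.concatenate([np.ones(len(pos), dtype=int), np.zeros(len(neg_sample), dtype=int)])
        fold_seed = int(rng.integers(0, 2**31 - 1))
        tp, fp, tn, fn = _cv_round(X, y, cv_folds, config, fold_seed)
        precisions[r] = _safe_div(tp, tp + fp)
        tprs[r] = _safe_div(tp, tp + fn)
        fprs[r] = _safe_div(fp, fp + tn)

    return EvalMetrics(
        feature_subset=subset,
        precision=float(precisions.mean()),
        tpr=float(tprs.mean()),
        fpr=float(fprs.mean()),
        n_rounds=n_rounds,
        dispersion={
            "precision": float(precisions.std()),
            "tpr": float(tprs.std()),
            "fpr": float(fprs.std()),
        },
    )


def select_effective_features(
    results: Mapping[str, EvalMetrics],
    disparity: Mapping[str, DisparityResult],
    rule: SelectionRule | None = None,
) -> list[str]:
    """Retain features passing disparity significance and the effectiveness rule.

    ``threshold``: precision >= p_min AND tpr >= t_min AND fpr <= f_max.
    ``drop_worst_k``: among significant features, drop the k worst by
    Youden's index (tpr - fpr).
    """
    rule = rule or SelectionRule()
    candidates = []
    for feat, metrics in results.items():
        disp = disparity.get(feat)
        if disp is None:
            raise ValueError(f"no disparity result for feature {feat!r}")
        if not disp.significant:
            logger.info("feature %s: rejected (p=%.3g not significant)", feat, disp.p_value)
            continue
        candidates.append((feat, metrics))

    if rule.method == "threshold":
        retained = []
        for feat, m in candidates:
            ok = m.precision >= rule.p_min and m.tpr >= rule.t_min and m.fpr <= rule.f_max
            logger.info(
                "feature %s: precision=%.3f tpr=%.3f fpr=%.3f -> %s",
                feat, m.precision, m.tpr, m.fpr, "retained" if ok else "rejected",
            )
            if ok:
                retained.append(feat)
    elif rule.method == "drop_worst_k":
        ranked = sorted(candidates, key=lambda fm: fm[1].tpr - fm[1].fpr, reverse=True)
        kept_names = {f for f, _ in ranked[: max(len(ranked) - rule.k, 0)]}
        retained = [f for f, _ in candidates if f in kept_names]
    else:
        raise ValueError(f"unknown selection method: {rule.method!r}")

    if not retained:
        raise ValueError(
            "no features retained; relax thresholds (p_min/t_min/f_max or alpha)"
        )
    order = list(results.keys())
    return sorted(retained, key=order.index)
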