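"""Final candidate calling.

Each round trains the classifier on the positive set against a fresh balanced
negative sample and classifies the whole test set. A test gene's
call_fraction is the fraction of rounds it was classified positive;
candidates are the genes whose call_fraction reaches the agreement threshold
(1.0 = strict intersection over all rounds).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import IO, Mapping, Sequence

import numpy as np
from sklearn.preprocessing import StandardScaler

from .network_io import GeneSet, GeneSetPartition
from .screening import SVMConfig
from .topo_features import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = ["CandidateResult", "predict_candidates"]


@dataclass(frozen=True)
class CandidateResult:
    candidates: GeneSet
    call_fraction: dict[str, float]
    n_rounds: int
    subset_used: tuple[str, ...]
    agreement: float

    def candidates_at(self, agreement: float) -> frozenset[str]:
        """Candidate set at a different agreement threshold, same rounds."""
        return frozenset(g for g, f in self.call_fraction.items() if f >= agreement)

    def to_tsv(self, dest: IO[str], header: Mapping[str, str] | None = None) -> None:
        dest.write(f"#subset={'+'.join(self.subset_used)}\tn_rounds={self.n_rounds}"
                   f"\tagreement={self.agreement}\n")
        for key, val in (header or {}).items():
            dest.write(f"#{key}={val}\n")
        dest.write("gene\tcall_fraction\tcandidate\n")
        for gene in sorted(self.call_fraction):
            flag = "Y" if gene in self.candidates.members else "N"
            dest.write(f"{gene}\t{self.call_fraction[gene]:.6f}\t{flag}\n")


def predict_candidates(
    matrix: FeatureMatrix,
    partition: GeneSetPartition,
    subset: Sequence[str],
    n_rounds: int,
    classifier_config: SVMConfig | None = None,
    agreement: float = 1.0,
    seed: int = 0,
) -> CandidateResult:
    subset = tuple(subset)
    missing = [f for f in subset if f not in matrix.feature_names]
    if missing:
        raise ValueError(f"subset features not in matrix: {missing}")
    if not partition.test.members:
        raise ValueError("empty test set")
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    if not 0.0 <= agreement <= 1.0:
        raise ValueError("agreement must be in [0,1]")
    config = classifier_config or SVMConfig()

    pos = sorted(partition.positive.members)
    neg = sorted(partition.negative.members)
    test = sorted(partition.test.members)
    if len(neg) < len(pos):
        raise ValueError("fewer negatives than positives")

    X_pos = matrix.values(subset, pos)
    X_test = matrix.values(subset, test)
    y = np.concatenate([np.ones(len(pos), dtype=int), np.zeros(len(pos), dtype=int)])

    counts = np.zeros(len(test), dtype=int)
    round_seeds = np.random.SeedSequence(seed).spawn(n_rounds)
    for r in range(n_rounds):
        rng = np.random.default_rng(round_seeds[r])
        idx = rng.choice(len(neg), size=len(pos), replace=False)
        X_neg = matrix.values(subset, [neg[i] for i in idx])
        X_train = np.vstack([X_pos, X_neg])
        scaler = StandardScaler().fit(X_train)
        clf = config.build()
        clf.fit(scaler.transform(X_train), y)
        counts += clf.predict(scaler.transform(X_test)).astype(int)

    fractions = {g: counts[i] / n_rounds for i, g in enumerate(test)}
    candidates = frozenset(g for g, f in fractions.items() if f >= agreement)
    logger.info("%d/%d test genes called candidates at agreement %.2f",
                len(candidates), len(test), agreement)
    return CandidateResult(
        candidates=GeneSet("candidates", candidates),
        call_fraction=fractions,
        n_rounds=n_rounds,
        subset_used=subset,
        agreement=agreement,
    )
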