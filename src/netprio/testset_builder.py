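"""Expression preprocessing: median normalization, t-test DE screen,
cross-profile intersection.

Expression TSV layout: gene rows; first header row is sample IDs, second
header row is group labels ('case' / 'control').
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import IO, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .network_io import GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionProfile",
    "load_expression",
    "write_expression",
    "median_normalize",
    "differential_expression",
    "de_report",
    "intersect_profiles",
]

GROUPS = ("case", "control")


@dataclass
class ExpressionProfile:
    """Genes x samples log-intensity matrix with case/control sample labels."""

    data: pd.DataFrame  # index: gene, columns: sample IDs
    groups: pd.Series  # sample ID -> 'case' | 'control'

    def __post_init__(self):
        if list(self.groups.index) != list(self.data.columns):
            raise ValueError("group labels must cover exactly the sample columns")
        bad = set(self.groups.unique()) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {bad}")
        for g in GROUPS:
            if (self.groups == g).sum() < 2:
                raise ValueError(f"need >= 2 {g!r} samples")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate gene rows (collapse before constructing)")

    def samples(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])


def load_expression(source: IO[str]) -> ExpressionProfile:
    """Read the two-header-row TSV; duplicate gene rows collapsed by mean."""
    df = pd.read_csv(source, sep="\t", header=[0, 1], index_col=0)
    samples = [c[0] for c in df.columns]
    labels = [c[1] for c in df.columns]
    df.columns = samples
    n_before = len(df)
    df = df.groupby(level=0, sort=False).mean()
    n_dups = n_before - len(df)
    if n_dups:
        logger.info("collapsed %d duplicate gene rows by mean", n_dups)
    groups = pd.Series(labels, index=samples)
    return ExpressionProfile(data=df.astype(float), groups=groups)


def write_expression(profile: ExpressionProfile, dest: IO[str]) -> None:
    dest.write("gene\t" + "\t".join(profile.data.columns) + "\n")
    dest.write("group\t" + "\t".join(profile.groups[c] for c in profile.data.columns) + "\n")
    for gene, row in profile.data.iterrows():
        dest.write(gene + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def median_normalize(profile: ExpressionProfile) -> ExpressionProfile:
    """Shift each sample column so its median equals the pre-shift global median."""
    values = profile.data.to_numpy(dtype=float)
    if values.size == 0:
        raise ValueError("empty expression matrix")
    global_median = float(np.median(values))
    col_medians = np.median(values, axis=0)
    shifted = values + (global_median - col_medians)[None, :]
    return ExpressionProfile(
        data=pd.DataFrame(shifted, index=profile.data.index, columns=profile.data.columns),
        groups=profile.groups.copy(),
    )


def _ttest(profile: ExpressionProfile, equal_var: bool) -> pd.DataFrame:
    case = profile.data[profile.samples("case")].to_numpy(dtype=float)
    ctrl = profile.data[profile.samples("control")].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=equal_var)
    # zero variance in both groups: p=1 for equal means, p=0 otherwise
    nan_mask = np.isnan(p)
    if nan_mask.any():
        equal_means = np.isclose(case.mean(axis=1), ctrl.mean(axis=1))
        p = np.where(nan_mask, np.where(equal_means, 1.0, 0.0), p)
        t = np.where(np.isnan(t), 0.0, t)
    return pd.DataFrame({"t": t, "p": p}, index=profile.data.index)


def de_report(
    profile: ExpressionProfile, alpha: float = 0.05, equal_var: bool = False
) -> pd.DataFrame:
    """Per-gene t statistic, p-value and pass flag (Welch by default)."""
    rep = _ttest(profile, equal_var)
    rep["passed"] = rep["p"] < alpha
    return rep


def differential_expression(
    profile: ExpressionProfile,
    alpha: float = 0.05,
    equal_var: bool = False,
    name: str = "de",
) -> GeneSet:
    """Genes with two-sided t-test p < alpha. No multiple-testing correction."""
    rep = de_report(profile, alpha=alpha, equal_var=equal_var)
    members = frozenset(rep.index[rep["passed"]])
    logger.info("%d/%d genes pass DE screen at alpha=%g", len(members), len(rep), alpha)
    return GeneSet(name=name, members=members)


def intersect_profiles(de_sets: Sequence[GeneSet]) -> GeneSet:
    if not de_sets:
        raise ValueError("need at least one DE set")
    members = frozenset.intersection(*(s.members for s in de_sets))
    if not members:
        logger.warning("DE intersection across %d profiles is empty", len(de_sets))
    return GeneSet(name="de_common", members=members)
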