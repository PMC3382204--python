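"""Per-gene topological measurements relative to a disease gene set.

Six measurements make up the primary feature vector:

D  degree
N  number of neighbors in the disease set
R  N/D (0 when D = 0)
B  betweenness centrality, unnormalized, fractional path credit
C  local clustering coefficient (0 when D < 2)
M  mean shortest-path length (hops) to reachable disease genes

M is MISSING (NaN) when no disease gene is reachable; the matrix builder
imputes it as max-finite + 1 by default so the classifier sees every gene.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass
from typing import IO, Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .network_io import GeneSet, InteractionNetwork

logger = logging.getLogger(__name__)

ALL_FEATURES: tuple[str, ...] = ("D", "N", "R", "B", "C", "M")
MISSING = math.nan

__all__ = [
    "ALL_FEATURES",
    "MISSING",
    "FeatureMatrix",
    "degree",
    "disease_neighbor_count",
    "disease_neighbor_ratio",
    "betweenness_all",
    "clustering_coefficient",
    "mean_shortest_path_to_disease",
    "build_feature_matrix",
]


@dataclass
class FeatureMatrix:
    """Per-gene feature values with bookkeeping on how they were produced."""

    data: pd.DataFrame  # index: gene, columns: feature_names
    feature_names: tuple[str, ...]
    disease_set_used: GeneSet
    loo_applied: bool

    def __post_init__(self):
        if list(self.data.columns) != list(self.feature_names):
            raise ValueError("data columns must match feature_names")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate gene rows")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    def values(self, subset: Sequence[str], genes: Sequence[str]) -> np.ndarray:
        return self.data.loc[list(genes), list(subset)].to_numpy(dtype=float)

    def to_tsv(self, dest: IO[str]) -> None:
        checksum = hashlib.sha256(
            "\n".join(sorted(self.disease_set_used.members)).encode()
        ).hexdigest()[:12]
        dest.write(f"#loo={int(self.loo_applied)}\tdisease_sha={checksum}\n")
        out = self.data.copy()
        out.index.name = "gene"
        out.to_csv(dest, sep="\t", na_rep="NA")


def _require_node(network: InteractionNetwork, gene: str) -> None:
    if not network.has_node(gene):
        raise KeyError(f"unknown gene: {gene!r}")


def degree(network: InteractionNetwork, gene: str) -> int:
    _require_node(network, gene)
    return int(network.graph.degree(gene))


def disease_neighbor_count(
    network: InteractionNetwork, gene: str, disease: GeneSet, exclude_self: bool = True
) -> int:
    _require_node(network, gene)
    d = set(disease.members)
    if exclude_self:
        d.discard(gene)
    return len(network.neighbors(gene) & d)


def disease_neighbor_ratio(
    network: InteractionNetwork, gene: str, disease: GeneSet, exclude_self: bool = True
) -> float:
    d = degree(network, gene)
    if d == 0:
        return 0.0
    return disease_neighbor_count(network, gene, disease, exclude_self) / d


def betweenness_all(network: InteractionNetwork) -> dict[str, float]:
    """Unnormalized node betweenness over unordered pairs, fractional credit."""
    if network.n_nodes == 0:
        raise ValueError("empty network")
    return nx.betweenness_centrality(network.graph, normalized=False)


def clustering_coefficient(network: InteractionNetwork, gene: str) -> float:
    _require_node(network, gene)
    return float(nx.clustering(network.graph, gene))


def mean_shortest_path_to_disease(
    network: InteractionNetwork, gene: str, disease: GeneSet, exclude_self: bool = True
) -> float:
    """Mean hop distance from ``gene`` to reachable disease genes; NaN if none."""
    _require_node(network, gene)
    targets = set(disease.members)
    if exclude_self:
        targets.discard(gene)
    if not targets:
        raise ValueError("disease set empty after self-exclusion")
    dist = nx.single_source_shortest_path_length(network.graph, gene)
    hops = [dist[t] for t in targets if t in dist]
    if not hops:
        return MISSING
    return float(np.mean(hops))


def _disease_distance_sums(
    network: InteractionNetwork, disease_on: set[str]
) -> tuple[dict[str, float], dict[str, int], dict[str, int]]:
    """BFS from each disease gene; per node: Σ distances, count reachable, self hit."""
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for d in disease_on:
        dist = nx.single_source_shortest_path_length(network.graph, d)
        for node, h in dist.items():
            sums[node] = sums.get(node, 0.0) + h
            counts[node] = counts.get(node, 0) + 1
    return sums, counts, {}


def build_feature_matrix(
    network: InteractionNetwork,
    genes: Sequence[str],
    disease: GeneSet,
    features: Sequence[str] = ALL_FEATURES,
    leave_one_out: bool = True,
    impute_missing: bool = True,
) -> FeatureMatrix:
    """One feature row per gene.

    With ``leave_one_out`` (default), disease-relative features (N, R, M) of a
    gene that is itself in the disease set are computed against the disease
    set minus that gene, so labels do not leak into their own features.
    """
    genes = list(genes)
    unknown = [g for g in genes if not network.has_node(g)]
    if unknown:
        raise KeyError(f"genes not in network: {unknown[:5]}...")
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate genes requested")
    bad = [f for f in features if f not in ALL_FEATURES]
    if bad:
        raise ValueError(f"unknown features: {bad}")
    disease_on = disease.members & network.nodes
    if not disease_on:
        raise ValueError("disease set empty (after network intersection)")

    g = network.graph
    cols: dict[str, list[float]] = {f: [] for f in features}

    need_b = "B" in features
    need_c = "C" in features
    need_m = "M" in features
    btw = betweenness_all(network) if need_b else None
    clus = nx.clustering(g, genes) if need_c else None
    if need_m:
        msums, mcounts, _ = _disease_distance_sums(network, set(disease_on))

    for gene in genes:
        deg = g.degree(gene)
        in_disease = gene in disease_on
        dset = disease_on - {gene} if (leave_one_out and in_disease) else disease_on
        nbrs = set(g.neighbors(gene))
        n_val = len(nbrs & dset)
        for f in features:
            if f == "D":
                cols["D"].append(float(deg))
            elif f == "N":
                cols["N"].append(float(n_val))
            elif f == "R":
                cols["R"].append(n_val / deg if deg > 0 else 0.0)
            elif f == "B":
                cols["B"].append(float(btw[gene]))
            elif f == "C":
                cols["C"].append(float(clus[gene]))
            elif f == "M":
                s = msums.get(gene, 0.0)
                c = mcounts.get(gene, 0)
                if leave_one_out and in_disease and c > 0:
                    # remove the gene's own zero-distance contribution
                    c -= 1
                elif not leave_one_out and in_disease:
                    pass  # self distance 0 included by definition
                if not dset:
                    raise ValueError(
                        f"disease set empty after leave-one-out for {gene!r}"
                    )
                cols["M"].append(s / c if c > 0 else MISSING)

    df = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))[list(features)]
    if "M" in features and impute_missing:
        m = df["M"]
        n_missing = int(m.isna().sum())
        if n_missing:
            finite_max = m.dropna().max()
            fill = (finite_max + 1.0) if pd.notna(finite_max) else 1.0
            df["M"] = m.fillna(fill)
            logger.info("imputed %d MISSING M values as %.3f", n_missing, fill)
    return FeatureMatrix(
        data=df,
        feature_names=tuple(features),
        disease_set_used=GeneSet(disease.name, frozenset(disease_on)),
        loo_applied=bool(leave_one_out),
    )
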