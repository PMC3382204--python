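"""Synthetic benchmarks: a scale-free network with a planted disease module,
and expression matrices with planted differentially-expressed genes.

The planted module reproduces the qualitative regularities the pipeline
exploits: module genes are better connected than background genes, cluster
together, and sit close to each other in the graph.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import IO, Sequence

import networkx as nx
import numpy as np

from .network_io import GeneSet, InteractionNetwork
from .testset_builder import ExpressionProfile

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["PlantedTruth", "generate_network", "generate_expression"]

DEFAULTS = dict(
    n_background=2000,
    n_disease=60,
    n_hidden=40,
    attach_m=3,
    module_p=0.15,
    cross_p=0.005,
)


@dataclass(frozen=True)
class PlantedTruth:
    seed_disease: GeneSet      # given to the pipeline as positives
    hidden_disease: GeneSet    # withheld; the recovery target
    background: GeneSet
    generator_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.seed_disease.members & self.hidden_disease.members:
            raise ValueError("seed and hidden disease sets must be disjoint")

    def to_json(self, dest: IO[str]) -> None:
        json.dump(
            {
                "seed_disease": sorted(self.seed_disease.members),
                "hidden_disease": sorted(self.hidden_disease.members),
                "background": sorted(self.background.members),
                "generator_params": self.generator_params,
            },
            dest,
            indent=1,
            sort_keys=True,
        )


def generate_network(
    n_background: int = DEFAULTS["n_background"],
    n_disease: int = DEFAULTS["n_disease"],
    n_hidden: int = DEFAULTS["n_hidden"],
    attach_m: int = DEFAULTS["attach_m"],
    module_p: float = DEFAULTS["module_p"],
    cross_p: float = DEFAULTS["cross_p"],
    seed: int = 0,
) -> tuple[InteractionNetwork, PlantedTruth]:
    """Scale-free background plus a dense planted disease module.

    The background is grown by preferential attachment (``attach_m`` edges
    per node). The module has ``n_disease + n_hidden`` genes, wired
    internally with probability ``module_p`` and to random background genes
    with probability ``cross_p``; ``n_disease`` of them become the seed
    (known) disease genes and ``n_hidden`` are withheld as the planted truth.
    """
    if not (0.0 <= cross_p < module_p <= 1.0):
        raise ValueError("require 0 <= cross_p < module_p <= 1")
    if n_background < max(attach_m + 1, 1) or n_disease < 1 or n_hidden < 0 or attach_m < 1:
        raise ValueError("invalid counts: n_background > attach_m, n_disease >= 1, "
                         "n_hidden >= 0, attach_m >= 1 required")

    rng = np.random.default_rng(seed)
    bg_seed = int(rng.integers(0, 2**31 - 1))
    width = len(str(n_background))
    bg_names = [f"B{i:0{width}d}" for i in range(n_background)]
    g = nx.relabel_nodes(
        nx.barabasi_albert_graph(n_background, attach_m, seed=bg_seed),
        dict(enumerate(bg_names)),
    )

    n_module = n_disease + n_hidden
    module = [f"D{i:03d}" for i in range(n_disease)] + [f"H{i:03d}" for i in range(n_hidden)]
    g.add_nodes_from(module)
    # internal module edges
    for i in range(n_module):
        for j in range(i + 1, n_module):
            if rng.random() < module_p:
                g.add_edge(module[i], module[j])
    # cross edges to the background
    cross_mask = rng.random((n_module, n_background)) < cross_p
    for i, j in zip(*np.nonzero(cross_mask)):
        g.add_edge(module[i], bg_names[j])

    giant = max(nx.connected_components(g), key=len)
    logger.info("giant component covers %.1f%% of %d nodes",
                100 * len(giant) / g.number_of_nodes(), g.number_of_nodes())

    params = dict(
        n_background=n_background, n_disease=n_disease, n_hidden=n_hidden,
        attach_m=attach_m, module_p=module_p, cross_p=cross_p, seed=seed,
    )
    truth = PlantedTruth(
        seed_disease=GeneSet("seed_disease", frozenset(module[:n_disease])),
        hidden_disease=GeneSet("hidden_disease", frozenset(module[n_disease:])),
        background=GeneSet("background", frozenset(bg_names)),
        generator_params=params,
    )
    return InteractionNetwork.from_networkx(g), truth


def generate_expression(
    genes: Sequence[str],
    de_genes: GeneSet,
    n_case: int = 5,
    n_control: int = 5,
    effect: float = 2.0,
    sigma: float = 1.0,
    n_profiles: int = 3,
    baseline: float = 8.0,
    seed: int = 0,
) -> list[ExpressionProfile]:
    """Gaussian log-intensity matrices with ``de_genes`` shifted by ``effect``
    in the case samples of every profile; noise independent across profiles."""
    genes = list(genes)
    if not set(de_genes.members) <= set(genes):
        raise ValueError("de_genes must be a subset of genes")
    if effect < 0 or sigma <= 0 or n_case < 2 or n_control < 2 or n_profiles < 1:
        raise ValueError("invalid expression-generator parameters")
    rng = np.random.default_rng(seed)
    de_mask = np.array([g in de_genes.members for g in genes])
    profiles = []
    for k in range(n_profiles):
        n_samples = n_case + n_control
        values = baseline + rng.normal(0.0, sigma, size=(len(genes), n_samples))
        values[de_mask, :n_case] += effect
        samples = [f"P{k}_case{i}" for i in range(n_case)] + [
            f"P{k}_ctrl{i}" for i in range(n_control)
        ]
        labels = ["case"] * n_case + ["control"] * n_control
        profiles.append(
            ExpressionProfile(
                data=pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples),
                groups=pd.Series(labels, index=samples),
            )
        )
    return profiles
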