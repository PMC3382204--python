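"""End-to-end orchestration: test-set construction, partitioning, feature
computation, per-feature screening, combination search, candidate prediction.

A single master seed is expanded into independent per-stage seed streams so
any stage can be re-run in isolation; reports are plain TSV/JSON and the run
summary is byte-reproducible for a fixed config + seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from . import combo_search, network_io, predictor, screening, synthetic_data, testset_builder
from .network_io import GeneSet, GeneSetPartition, InteractionNetwork
from .screening import SelectionRule, SVMConfig
from .topo_features import ALL_FEATURES, FeatureMatrix, build_feature_matrix

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "generate_fixtures"]

_STAGES = ("generate", "features", "screen", "combos", "predict")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Validated run configuration; exactly one of inputs / synthetic."""

    inputs: dict[str, Any] | None = None      # network, positives, loci, expression|de_genes
    synthetic: dict[str, Any] | None = None   # generator parameters
    alpha: float = 0.05
    p_min: float = 0.55
    t_min: float = 0.55
    f_max: float = 0.45
    agreement: float = 1.0
    n_rounds_screen: int = 1000
    n_rounds_predict: int = 10000
    cv_folds: int = 10
    features: tuple[str, ...] = ALL_FEATURES
    leave_one_out: bool = True
    optima_rule: str = "youden"
    selection_method: str = "threshold"
    svm: SVMConfig = field(default_factory=SVMConfig)
    seed: int = 0

    def __post_init__(self):
        if (self.inputs is None) == (self.synthetic is None):
            raise ValueError("exactly one of 'inputs' or 'synthetic' must be given")
        for name in ("alpha", "p_min", "t_min", "f_max", "agreement"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} out of [0,1]")
        if self.n_rounds_screen < 1 or self.n_rounds_predict < 1 or self.cv_folds < 2:
            raise ValueError("round/fold counts out of range")
        bad = [f for f in self.features if f not in ALL_FEATURES]
        if bad:
            raise ValueError(f"unknown features: {bad}")

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        d = dict(d)
        svm = d.pop("svm", None)
        if isinstance(svm, Mapping):
            d["svm"] = SVMConfig(**svm)
        if "features" in d:
            d["features"] = tuple(d["features"])
        return cls(**d)

    def canonical(self) -> dict[str, Any]:
        return {
            "inputs": self.inputs,
            "synthetic": self.synthetic,
            "alpha": self.alpha,
            "p_min": self.p_min,
            "t_min": self.t_min,
            "f_max": self.f_max,
            "agreement": self.agreement,
            "n_rounds_screen": self.n_rounds_screen,
            "n_rounds_predict": self.n_rounds_predict,
            "cv_folds": self.cv_folds,
            "features": list(self.features),
            "leave_one_out": self.leave_one_out,
            "optima_rule": self.optima_rule,
            "selection_method": self.selection_method,
            "svm": {"kernel": self.svm.kernel, "C": self.svm.C, "gamma": self.svm.gamma},
            "seed": self.seed,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage_seeds(master: int) -> dict[str, int]:
    children = np.random.SeedSequence(master).spawn(len(_STAGES))
    return {name: int(ss.generate_state(1)[0]) for name, ss in zip(_STAGES, children)}


# ---------------------------------------------------------------------------
# data acquisition

def _synthetic_inputs(
    cfg: RunConfig, seeds: Mapping[str, int]
) -> tuple[InteractionNetwork, GeneSet, GeneSet, GeneSet, synthetic_data.PlantedTruth]:
    """Generate network + truth, then plant hidden genes (and decoy background
    genes) as DE and locus genes and run the expression arm for the DE set."""
    syn = dict(cfg.synthetic or {})
    n_decoy = int(syn.pop("n_decoy_de", 0))
    expr_keys = {k: syn.pop(k) for k in
                 ("n_case", "n_control", "effect", "sigma", "n_profiles", "baseline")
                 if k in syn}
    network, truth = synthetic_data.generate_network(seed=seeds["generate"], **syn)

    rng = np.random.default_rng(seeds["generate"] + 1)
    background = sorted(truth.background.members)
    decoys = [background[i] for i in rng.choice(len(background), size=n_decoy, replace=False)] \
        if n_decoy else []
    planted_de = frozenset(truth.hidden_disease.members) | frozenset(decoys)
    loci = GeneSet("loci", planted_de)

    profiles = synthetic_data.generate_expression(
        genes=sorted(network.nodes),
        de_genes=GeneSet("planted_de", planted_de),
        seed=seeds["generate"] + 2,
        **expr_keys,
    )
    de_sets = [
        testset_builder.differential_expression(
            testset_builder.median_normalize(p), alpha=cfg.alpha
        )
        for p in profiles
    ]
    de_common = testset_builder.intersect_profiles(de_sets)
    return network, truth.seed_disease, de_common, loci, truth


def _file_inputs(cfg: RunConfig) -> tuple[InteractionNetwork, GeneSet, GeneSet, GeneSet]:
    paths = cfg.inputs or {}
    with open(paths["network"]) as fh:
        network = network_io.load_network(fh, dialect=paths.get("dialect", "tsv2col"))
    with open(paths["positives"]) as fh:
        positives = network_io.load_gene_set(fh, "positive")
    with open(paths["loci"]) as fh:
        loci = network_io.load_gene_set(fh, "loci")
    if "de_genes" in paths:
        with open(paths["de_genes"]) as fh:
            de_common = network_io.load_gene_set(fh, "de_common")
    elif "expression" in paths:
        de_sets = []
        for p in paths["expression"]:
            with open(p) as fh:
                profile = testset_builder.load_expression(fh)
            de_sets.append(
                testset_builder.differential_expression(
                    testset_builder.median_normalize(profile), alpha=cfg.alpha
                )
            )
        de_common = testset_builder.intersect_profiles(de_sets)
    else:
        de_common = GeneSet("de_common", frozenset())
    return network, positives, de_common, loci


# ---------------------------------------------------------------------------
# reports

def _write_screen_report(path: Path, disparity, per_feature, retained: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write("feature\tstatistic\tp_value\tprecision\ttpr\tfpr\tretained\n")
        for feat in per_feature:
            d, m = disparity[feat], per_feature[feat]
            fh.write(
                f"{feat}\t{d.statistic:.6g}\t{d.p_value:.6g}\t{m.precision:.6f}"
                f"\t{m.tpr:.6f}\t{m.fpr:.6f}\t{'Y' if feat in retained else 'N'}\n"
            )


def _write_combo_report(path: Path, combos) -> None:
    with open(path, "w") as fh:
        fh.write("subset\tprecision\ttpr\tfpr\tscore\trank\n")
        for c in sorted(combos, key=lambda c: c.rank):
            fh.write(
                f"{'+'.join(c.subset)}\t{c.metrics.precision:.6f}\t{c.metrics.tpr:.6f}"
                f"\t{c.metrics.fpr:.6f}\t{c.score:.6f}\t{c.rank}\n"
            )


# ---------------------------------------------------------------------------
# pipeline

def run_pipeline(config: RunConfig, outdir: str | Path, upto: str = "predict") -> dict[str, Any]:
    """Execute the pipeline up to ``upto`` and write reports into ``outdir``.

    Returns the in-memory artifacts (network, partition, matrix, metrics,
    optima, candidate result, summary path).
    """
    if upto not in _STAGES:
        raise ValueError(f"unknown stage {upto!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    artifacts: dict[str, Any] = {"seeds": seeds, "config_hash": config.config_hash()}
    summary: dict[str, Any] = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_seeds": seeds,
    }
    stage_rank = {s: i for i, s in enumerate(_STAGES)}

    try:
        if config.synthetic is not None:
            network, positives, de_common, loci, truth = _synthetic_inputs(config, seeds)
            artifacts["truth"] = truth
        else:
            network, positives, de_common, loci = _file_inputs(config)
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineError("generate", exc) from exc
    artifacts["network"] = network
    summary["network"] = {"n_nodes": network.n_nodes, "n_edges": network.n_edges}
    summary["n_de_common"] = len(de_common)
    if upto == "generate":
        _finish(outdir, summary)
        return artifacts

    try:
        partition = network_io.build_partition(network, positives, de_common, loci)
        matrix = build_feature_matrix(
            network,
            sorted(network.nodes),
            partition.positive,
            features=config.features,
            leave_one_out=config.leave_one_out,
        )
    except Exception as exc:
        raise PipelineError("features", exc) from exc
    artifacts["partition"] = partition
    artifacts["matrix"] = matrix
    summary["partition"] = {
        "n_positive": len(partition.positive),
        "n_negative": len(partition.negative),
        "n_test": len(partition.test),
    }
    with open(outdir / "features.tsv", "w") as fh:
        matrix.to_tsv(fh)
    if stage_rank[upto] <= stage_rank["features"]:
        _finish(outdir, summary)
        return artifacts

    try:
        pos = sorted(partition.positive.members)
        neg = sorted(partition.negative.members)
        disparity = {}
        per_feature = {}
        for feat in config.features:
            disparity[feat] = screening.wilcoxon_disparity(
                matrix.values((feat,), pos).ravel(),
                matrix.values((feat,), neg).ravel(),
                alpha=config.alpha,
                feature=feat,
            )
            per_feature[feat] = screening.evaluate_feature_set(
                matrix, partition, (feat,),
                n_rounds=config.n_rounds_screen,
                cv_folds=config.cv_folds,
                classifier_config=config.svm,
                seed=seeds["screen"],
            )
        rule = SelectionRule(
            p_min=config.p_min, t_min=config.t_min, f_max=config.f_max,
            method=config.selection_method,
        )
        retained = screening.select_effective_features(per_feature, disparity, rule)
    except Exception as exc:
        raise PipelineError("screen", exc) from exc
    artifacts["disparity"] = disparity
    artifacts["per_feature"] = per_feature
    artifacts["retained"] = retained
    summary["screen"] = {
        "retained": retained,
        "p_values": {f: disparity[f].p_value for f in config.features},
        "metrics": {
            f: {"precision": per_feature[f].precision, "tpr": per_feature[f].tpr,
                "fpr": per_feature[f].fpr}
            for f in config.features
        },
    }
    _write_screen_report(outdir / "screening.tsv", disparity, per_feature, retained)
    if stage_rank[upto] <= stage_rank["screen"]:
        _finish(outdir, summary)
        return artifacts

    try:
        subsets = combo_search.enumerate_combinations(retained)
        combos = combo_search.evaluate_combinations(
            matrix, partition, subsets,
            n_rounds=config.n_rounds_screen,
            cv_folds=config.cv_folds,
            classifier_config=config.svm,
            seed=seeds["combos"],
        )
        optima = combo_search.select_optima(combos, rule=config.optima_rule)
    except Exception as exc:
        raise PipelineError("combos", exc) from exc
    artifacts["combos"] = combos
    artifacts["optima"] = optima
    summary["combos"] = {
        "n_subsets": len(combos),
        "optima_subset": list(optima.subset),
        "optima_metrics": {
            "precision": optima.metrics.precision,
            "tpr": optima.metrics.tpr,
            "fpr": optima.metrics.fpr,
        },
    }
    _write_combo_report(outdir / "combos.tsv", combos)
    if stage_rank[upto] <= stage_rank["combos"]:
        _finish(outdir, summary)
        return artifacts

    try:
        if not partition.test.members:
            logger.warning("empty test set: skipping prediction stage")
            summary["predict"] = {"skipped": "empty test set"}
            _finish(outdir, summary)
            return artifacts
        result = predictor.predict_candidates(
            matrix, partition, optima.subset,
            n_rounds=config.n_rounds_predict,
            classifier_config=config.svm,
            agreement=config.agreement,
            seed=seeds["predict"],
        )
    except Exception as exc:
        raise PipelineError("predict", exc) from exc
    artifacts["result"] = result
    summary["predict"] = {
        "n_rounds": result.n_rounds,
        "agreement": result.agreement,
        "candidates": sorted(result.candidates.members),
        "call_fraction": {g: result.call_fraction[g] for g in sorted(result.call_fraction)},
    }
    with open(outdir / "predictions.tsv", "w") as fh:
        result.to_tsv(fh, header={"config_hash": config.config_hash(),
                                  "seed": str(config.seed)})
    _finish(outdir, summary)
    artifacts["summary_path"] = outdir / "summary.json"
    return artifacts


def _finish(outdir: Path, summary: dict[str, Any]) -> None:
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")


def generate_fixtures(config: RunConfig, outdir: str | Path) -> dict[str, Path]:
    """Write synthetic network / gene-set / expression fixtures plus truth JSON."""
    if config.synthetic is None:
        raise ValueError("generate requires a synthetic config block")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)

    syn = dict(config.synthetic)
    n_decoy = int(syn.pop("n_decoy_de", 0))
    expr_keys = {k: syn.pop(k) for k in
                 ("n_case", "n_control", "effect", "sigma", "n_profiles", "baseline")
                 if k in syn}
    network, truth = synthetic_data.generate_network(seed=seeds["generate"], **syn)
    rng = np.random.default_rng(seeds["generate"] + 1)
    background = sorted(truth.background.members)
    decoys = [background[i] for i in rng.choice(len(background), size=n_decoy, replace=False)] \
        if n_decoy else []
    planted_de = frozenset(truth.hidden_disease.members) | frozenset(decoys)
    profiles = synthetic_data.generate_expression(
        genes=sorted(network.nodes),
        de_genes=GeneSet("planted_de", planted_de),
        seed=seeds["generate"] + 2,
        **expr_keys,
    )

    paths = {}
    paths["network"] = outdir / "network.tsv"
    with open(paths["network"], "w") as fh:
        network_io.write_network(network, fh)
    paths["positives"] = outdir / "positives.txt"
    with open(paths["positives"], "w") as fh:
        network_io.write_gene_set(truth.seed_disease, fh)
    paths["loci"] = outdir / "loci.txt"
    with open(paths["loci"], "w") as fh:
        network_io.write_gene_set(GeneSet("loci", planted_de), fh)
    for k, profile in enumerate(profiles):
        p = outdir / f"expression_{k}.tsv"
        with open(p, "w") as fh:
            testset_builder.write_expression(profile, fh)
        paths[f"expression_{k}"] = p
    paths["truth"] = outdir / "truth.json"
    with open(paths["truth"], "w") as fh:
        truth.to_json(fh)
    return paths
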