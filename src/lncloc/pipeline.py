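"""End-to-end orchestration: data -> features -> balancing -> graph ->
meta-trained GCN -> metrics, behind one serializable run configuration.

The stages run in the fixed order (1) build/load the labeled sequence set,
(2) SMOTE-balance the feature matrix, (3) construct the similarity graph and
ego graphs, (4) meta-train the GCN and fine-tune on the test support set,
(5) score the test query set.  Every stochastic stage draws its seed from
the run seed through a seed tree, so one config reproduces one result
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from sklearn.metrics.pairwise import cosine_similarity as _sk_cosine

from . import __version__
from .balancing import SmoteConfig, smote_balance
from .evaluation import MetricsReport, write_metrics_json
from .features import FeatureConfig, featurize_dataset
from .graph import GraphStats, build_similarity_graph, extract_local_graphs, graph_stats
from .model_meta import (
    EpisodeConfig,
    GcnConfig,
    GcnEpisodeModel,
    MetaConfig,
    Task,
    fine_tune_and_evaluate,
    meta_train,
    sample_tasks,
    split_dataset,
)
from .sequence_io import (
    FilterPolicy,
    SequenceRecord,
    attach_labels,
    filter_records,
    read_fasta,
    read_labels,
    write_removal_report,
)
from .synthetic_data import PRESETS, generate_imbalanced_benchmark

__all__ = [
    "DataSection",
    "GraphSection",
    "ModelSection",
    "MetaSection",
    "EvaluationSection",
    "RunConfig",
    "PipelineResult",
    "validate_config",
    "run_pipeline",
    "select_tau",
]


# --------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class DataSection:
    """Input source: FASTA + label TSV, or a synthetic preset."""

    fasta: str | None = None
    labels: str | None = None
    synthetic_preset: str | None = "dataset1-like"
    separation: float = 3.0
    length_min: int = 200
    length_max: int = 500
    max_length: int | None = None  # filter-policy cap; None = unbounded


@dataclass(frozen=True)
class GraphSection:
    tau: float = 0.7
    tau_grid: tuple[float, ...] | None = None  # validation-tuned if set
    layers: int = 1


@dataclass(frozen=True)
class ModelSection:
    hidden_dim: int = 64
    activation: str = "relu"
    dropout: float = 0.0
    normalize_features: bool = True


@dataclass(frozen=True)
class MetaSection:
    inner_lr: float = 0.01
    outer_lr: float = 0.001
    inner_steps: int = 5
    meta_iterations: int = 1000
    order: str = "second"
    m: int = 8
    k_support: int = 5
    k_query: int = 5
    fine_tune_steps: int | None = None


@dataclass(frozen=True)
class EvaluationSection:
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    real_test_only: bool = False


@dataclass(frozen=True)
class RunConfig:
    data: DataSection = DataSection()
    features: FeatureConfig = FeatureConfig(method="kmer", k=5)
    balancing: SmoteConfig = SmoteConfig()
    graph: GraphSection = GraphSection()
    model: ModelSection = ModelSection()
    meta: MetaSection = MetaSection()
    evaluation: EvaluationSection = EvaluationSection()
    seed: int = 0
    outdir: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        def build(section_cls, key):
            payload = dict(raw.get(key, {}) or {})
            for f in dataclasses.fields(section_cls):
                if f.name in payload and isinstance(payload[f.name], list):
                    payload[f.name] = tuple(payload[f.name])
            return section_cls(**payload)

        return cls(
            data=build(DataSection, "data"),
            features=build(FeatureConfig, "features"),
            balancing=build(SmoteConfig, "balancing"),
            graph=build(GraphSection, "graph"),
            model=build(ModelSection, "model"),
            meta=build(MetaSection, "meta"),
            evaluation=build(EvaluationSection, "evaluation"),
            seed=int(raw.get("seed", 0)),
            outdir=raw.get("outdir"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_config(config: RunConfig) -> list[str]:
    """Cross-field sanity checks; returns a list of problems (empty = valid)."""
    problems: list[str] = []
    d = config.data
    if d.synthetic_preset is None:
        if not d.fasta or not d.labels:
            problems.append("data: need fasta and labels paths (or a synthetic preset)")
    elif d.synthetic_preset not in PRESETS:
        problems.append(f"data: unknown synthetic preset {d.synthetic_preset!r}")
    if d.length_min < 1 or d.length_max < d.length_min:
        problems.append("data: need 1 <= length_min <= length_max")
    if config.features.method in ("kmer", "revkmer") and d.length_min <= config.features.k:
        problems.append(
            f"features: k={config.features.k} requires sequences longer than k "
            f"(length_min={d.length_min})"
        )
    if config.features.method == "psednc" and d.length_min < config.features.lam + 2:
        problems.append("features: lambda too large for the minimum sequence length")
    if not -1.0 <= config.graph.tau <= 1.0:
        problems.append(f"graph: tau={config.graph.tau} outside [-1, 1]")
    if config.graph.tau_grid is not None and not all(
        -1.0 <= t <= 1.0 for t in config.graph.tau_grid
    ):
        problems.append("graph: tau_grid values must lie in [-1, 1]")
    if config.graph.layers not in (1, 2):
        problems.append("graph: layers must be 1 or 2")
    if abs(sum(config.evaluation.fractions) - 1.0) > 1e-9:
        problems.append("evaluation: fractions must sum to 1")
    if not 0.0 <= config.model.dropout < 1.0:
        problems.append("model: dropout must lie in [0, 1)")
    if d.synthetic_preset in PRESETS:
        # after SMOTE every class reaches the majority count
        majority = max(PRESETS[d.synthetic_preset]["counts"])
        train_per_class = int(np.floor(majority * config.evaluation.fractions[0]))
        need = config.meta.k_support + config.meta.k_query
        if need > train_per_class:
            problems.append(
                f"meta: k_support + k_query = {need} exceeds the ~{train_per_class} "
                "training samples per class available after balancing and splitting"
            )
        test_per_class = int(np.floor(majority * config.evaluation.fractions[2]))
        if config.meta.k_support >= test_per_class:
            problems.append(
                f"meta: k_support={config.meta.k_support} leaves no query samples in "
                f"a test fold of ~{test_per_class} per class"
            )
    return problems


# --------------------------------------------------------------------------
# tau selection


def select_tau(
    similarity_features: np.ndarray,
    labels: Sequence[str],
    train_indices: np.ndarray,
    val_indices: np.ndarray,
    grid: Sequence[float],
) -> tuple[float, dict[float, float]]:
    """Pick tau from a grid by validation neighbor-vote accuracy.

    For each tau, every validation node is classified by the majority label
    of its training neighbors in the tau-thresholded graph (no vote counts
    as wrong, so over-sparse graphs are penalized as well as impure ones).
    Ties prefer the smaller tau.  This is a cheap proxy for the full model:
    it tracks the same trade-off between key-edge purity and connectivity.
    """
    labels = np.asarray(labels, dtype=object)
    sims = _sk_cosine(similarity_features)
    train = np.asarray(train_indices, dtype=int)
    val = np.asarray(val_indices, dtype=int)
    classes = sorted(set(map(str, labels)))
    class_idx = {c: i for i, c in enumerate(classes)}
    scores: dict[float, float] = {}
    for tau in grid:
        correct = 0
        for v in val:
            mask = sims[v, train] >= tau
            votes = np.zeros(len(classes))
            for t in train[mask]:
                votes[class_idx[str(labels[t])]] += 1
            if votes.sum() and classes[int(np.argmax(votes))] == str(labels[v]):
                correct += 1
        scores[float(tau)] = correct / max(len(val), 1)
    best = min(scores, key=lambda t: (-scores[t], t))
    return best, scores


# --------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineResult:
    metrics: MetricsReport
    tau: float
    graph_statistics: GraphStats
    theta: list[np.ndarray]
    training_log: list[dict]
    manifest: dict
    tau_scores: dict[float, float] = field(default_factory=dict)
    validation_metrics: MetricsReport | None = None


def _digest(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def _load_records(config: RunConfig, seed: int) -> list[SequenceRecord]:
    d = config.data
    if d.synthetic_preset is not None:
        return generate_imbalanced_benchmark(
            preset=d.synthetic_preset,
            separation=d.separation,
            seed=seed,
            length_range=(d.length_min, d.length_max),
        )
    records = read_fasta(d.fasta)
    return attach_labels(records, read_labels(d.labels))


def _single_test_task(
    labels: np.ndarray, test_indices: np.ndarray, k_support: int,
    rng: np.random.Generator,
) -> Task:
    """The meta-test task: k_support shots per class as support, rest query."""
    support, query = [], []
    for c in sorted(set(str(labels[i]) for i in test_indices)):
        members = np.array([i for i in test_indices if str(labels[i]) == c])
        if len(members) <= k_support:
            raise ValueError(
                f"class {c!r} has {len(members)} test samples; "
                f"needs more than k_support={k_support}"
            )
        members = rng.permutation(members)
        support.extend(members[:k_support])
        query.extend(members[k_support:])
    return Task(np.array(sorted(support)), np.array(sorted(query)))


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the five pipeline stages and return metrics plus artifacts.

    If ``config.outdir`` is set, metrics JSON, the training log, the final
    parameters, graph statistics, the removal report and a run manifest are
    written there.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid configuration: " + "; ".join(problems))
    seed_tree = np.random.SeedSequence(config.seed)
    seeds = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(
            ("data", "smote", "split", "init", "meta", "tasks", "test"),
            seed_tree.spawn(7),
        )
    }
    manifest: dict = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seeds": seeds,
        "stages": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    # (1) benchmark dataset
    records = _load_records(config, seeds["data"])
    policy = FilterPolicy(max_length=config.data.max_length)
    kept, removed = filter_records(records, policy)
    manifest["stages"]["data"] = {
        "n_input": len(records), "n_kept": len(kept), "n_removed": len(removed),
    }

    # (2) features + balancing
    features = featurize_dataset(kept, config.features)
    labels = [rec.label for rec in kept]
    balanced = smote_balance(
        features, labels,
        SmoteConfig(
            neighbor_count=config.balancing.neighbor_count,
            seed=seeds["smote"], mode=config.balancing.mode,
        ),
    )
    node_ids = [rec.id for rec in kept] + [
        f"smote_{i:04d}" for i in range(balanced.n_synthetic)
    ]
    manifest["stages"]["balance"] = {
        "n_total": len(balanced.labels),
        "n_synthetic": balanced.n_synthetic,
        "features_digest": _digest(balanced.vectors),
    }

    # (3) split, tau selection, graph construction
    y = np.array(balanced.labels, dtype=object)
    train_idx, val_idx, test_idx = split_dataset(
        y, config.evaluation.fractions, seed=seeds["split"]
    )
    tau_scores: dict[float, float] = {}
    tau = config.graph.tau
    if config.graph.tau_grid:
        tau, tau_scores = select_tau(
            balanced.vectors, y, train_idx, val_idx, config.graph.tau_grid
        )
    g = build_similarity_graph(
        balanced.vectors, y, tau,
        node_ids=node_ids, provenance=balanced.provenance,
    )
    stats = graph_stats(g)
    locals_ = extract_local_graphs(g, layers=config.graph.layers)
    manifest["stages"]["graph"] = {
        "tau": tau,
        "edges": stats.edge_count,
        "isolated": stats.isolated_count,
        "key_edge_fraction": stats.key_edge_fraction,
        "edges_digest": _digest(g.edges),
    }

    # (4) meta-train + meta-test
    class_names = sorted(set(map(str, y)))
    model = GcnEpisodeModel(
        locals_,
        GcnConfig(
            layer_dims=(balanced.vectors.shape[1], config.model.hidden_dim,
                        len(class_names)),
            activation=config.model.activation,
            dropout=config.model.dropout,
        ),
        class_names=class_names,
        normalize_features=config.model.normalize_features,
    )
    meta = MetaConfig(
        inner_lr=config.meta.inner_lr, outer_lr=config.meta.outer_lr,
        inner_steps=config.meta.inner_steps,
        meta_iterations=config.meta.meta_iterations,
        order=config.meta.order, seed=seeds["meta"],
        fine_tune_steps=config.meta.fine_tune_steps,
    )
    episode = EpisodeConfig(
        m=config.meta.m, k_support=config.meta.k_support,
        k_query=config.meta.k_query,
    )
    task_rng = np.random.default_rng(seeds["tasks"])

    def sampler(_rng: np.random.Generator) -> list[Task]:
        return sample_tasks(y, episode, task_rng, pool_indices=train_idx)

    init = model.init_params(np.random.default_rng(seeds["init"]))
    theta, log = meta_train(model, sampler, init, meta)

    test_rng = np.random.default_rng(seeds["test"])
    test_task = _single_test_task(y, test_idx, config.meta.k_support, test_rng)
    query_mask = None
    if config.evaluation.real_test_only:
        prov = np.array(balanced.provenance, dtype=object)
        query_mask = prov[test_task.query] == "real"
    metrics = fine_tune_and_evaluate(model, test_task, theta, meta, query_mask)

    val_metrics = None
    if len(val_idx):
        try:
            val_task = _single_test_task(y, val_idx, config.meta.k_support, test_rng)
            val_metrics = fine_tune_and_evaluate(model, val_task, theta, meta)
        except ValueError:
            val_metrics = None

    manifest["stages"]["meta"] = {
        "iterations": meta.meta_iterations,
        "final_query_loss": log[-1]["query_loss"] if log else None,
    }
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")

    # (5) artifacts
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_metrics_json(
            metrics, out / "metrics.json",
            extra={"tau": tau, "tau_scores": {str(k): v for k, v in tau_scores.items()}},
        )
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        (out / "graph_stats.json").write_text(json.dumps(
            {"isolated_count": stats.isolated_count, "edge_count": stats.edge_count,
             "key_edge_fraction": stats.key_edge_fraction}, indent=2) + "\n")
        with open(out / "training_log.jsonl", "w") as handle:
            for entry in log:
                handle.write(json.dumps(entry) + "\n")
        np.savez(out / "theta.npz",
                 **{f"W{i}": w for i, w in enumerate(theta)},
                 config_hash=config.config_hash())
        if removed:
            write_removal_report(removed, out / "removed.tsv")
        config.to_yaml(out / "config.yaml")

    return PipelineResult(
        metrics=metrics, tau=tau, graph_statistics=stats, theta=theta,
        training_log=log, manifest=manifest, tau_scores=tau_scores,
        validation_metrics=val_metrics,
    )


def run_cross_validation(
    config: RunConfig, folds: int = 10
) -> tuple[list[MetricsReport], dict]:
    """Stratified k-fold evaluation of the full meta-learning model.

    The graph is built once at ``config.graph.tau``; each fold meta-trains
    on the remaining folds' ego graphs and meta-tests on the held-out fold
    (k_support shots per class as the fine-tuning support).  Honors
    ``config.evaluation.real_test_only``.  Costly: one full meta-training
    run per fold.
    """
    from .evaluation import cross_validate

    problems = validate_config(config)
    if problems:
        raise ValueError("invalid configuration: " + "; ".join(problems))
    seed_tree = np.random.SeedSequence(config.seed)
    seeds = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(("data", "smote", "cv"), seed_tree.spawn(3))
    }
    records = _load_records(config, seeds["data"])
    kept, _removed = filter_records(records, FilterPolicy(max_length=config.data.max_length))
    features = featurize_dataset(kept, config.features)
    labels = [rec.label for rec in kept]
    balanced = smote_balance(
        features, labels,
        SmoteConfig(neighbor_count=config.balancing.neighbor_count,
                    seed=seeds["smote"], mode=config.balancing.mode),
    )
    y = np.array(balanced.labels, dtype=object)
    g = build_similarity_graph(balanced.vectors, y, config.graph.tau,
                               provenance=balanced.provenance)
    locals_ = extract_local_graphs(g, layers=config.graph.layers)
    class_names = sorted(set(map(str, y)))
    model = GcnEpisodeModel(
        locals_,
        GcnConfig(layer_dims=(balanced.vectors.shape[1], config.model.hidden_dim,
                              len(class_names)),
                  activation=config.model.activation,
                  dropout=config.model.dropout),
        class_names=class_names,
        normalize_features=config.model.normalize_features,
    )
    episode = EpisodeConfig(m=config.meta.m, k_support=config.meta.k_support,
                            k_query=config.meta.k_query)

    def model_spec(train_idx: np.ndarray, test_idx: np.ndarray,
                   fold_seed: int) -> MetricsReport:
        meta = MetaConfig(
            inner_lr=config.meta.inner_lr, outer_lr=config.meta.outer_lr,
            inner_steps=config.meta.inner_steps,
            meta_iterations=config.meta.meta_iterations,
            order=config.meta.order, seed=fold_seed,
            fine_tune_steps=config.meta.fine_tune_steps,
        )
        rng = np.random.default_rng(fold_seed)

        def sampler(_r: np.random.Generator) -> list[Task]:
            return sample_tasks(y, episode, rng, pool_indices=train_idx)

        theta, _log = meta_train(model, sampler, model.init_params(rng), meta)
        test_task = _single_test_task(y, test_idx, config.meta.k_support, rng)
        query_mask = None
        if config.evaluation.real_test_only:
            prov = np.array(balanced.provenance, dtype=object)
            query_mask = prov[test_task.query] == "real"
        return fine_tune_and_evaluate(model, test_task, theta, meta, query_mask)

    return cross_validate(y, model_spec, folds=folds, seed=seeds["cv"])
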