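"""Evaluation harness: end-to-end runs, seed averaging, template comparison, sweeps.

One run = sample shots from the labeled source domain, build the verbalizer
from those shots, train the backend's soft parameters, predict every target
document and score accuracy against the held-out truth.  Experiments repeat
the run over several seeds and report the per-seed values and their mean;
`compare_templates` varies only the template across otherwise identical runs
and `sweep` varies one hyperparameter axis (batch size, epochs or shots).

Every experiment produces a manifest — generator spec, pipeline config,
seeds, verbalizer hashes — sufficient for bit-identical replay on the stub
backend.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classification import predict_corpus
from .corpus_io import CorpusPair, Document, few_shot_sample
from .mlm import MLMBackend
from .stub import StubBackend, StubModelSpec
from .synthetic import GeneratorSpec, generate_corpus, synthetic_vectors
from .templating import get_template, wrap
from .training import TrainConfig, run_with_seeds, train
from .verbalizer import (
    DEFAULT_STOPWORDS,
    Verbalizer,
    WordVectorStore,
    build_verbalizer,
    expand_by_context,
    expand_by_mlm,
    expand_by_similarity,
)

__all__ = ["EvaluationError", "PipelineConfig", "RunResult", "evaluate", "macro_f1",
           "build_run_verbalizer", "run_task", "run_experiment",
           "run_synthetic_experiment", "compare_templates", "sweep", "replay"]


class EvaluationError(ValueError):
    pass


def evaluate(predictions: Mapping[str, str], truth: Mapping[str, str]) -> float:
    """Fraction of predictions whose class matches the truth label."""
    if not predictions:
        raise EvaluationError("no predictions to evaluate")
    missing = sorted(set(predictions) - set(truth))
    if missing:
        raise EvaluationError(f"prediction ids without truth labels: {missing}")
    correct = sum(predictions[i] == truth[i] for i in predictions)
    return correct / len(predictions)


def macro_f1(predictions: Mapping[str, str], truth: Mapping[str, str]) -> float:
    """Unweighted mean of per-class F1 (auxiliary metric; accuracy is primary)."""
    if not predictions:
        raise EvaluationError("no predictions to evaluate")
    classes = sorted({truth[i] for i in predictions} | set(predictions.values()))
    f1s = []
    for c in classes:
        tp = sum(predictions[i] == c and truth[i] == c for i in predictions)
        fp = sum(predictions[i] == c and truth[i] != c for i in predictions)
        fn = sum(predictions[i] != c and truth[i] == c for i in predictions)
        f1s.append(2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0)
    return float(np.mean(f1s))


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one end-to-end run needs beyond the data and the backend."""

    template_id: str = "soft"
    n_label_words: int = 15
    max_length: int = 128
    context_positions: int | None = 4  # maskable positions scored per shot
    use_mlm: bool = True
    use_similarity: bool = True
    use_context: bool = True
    stopwords: tuple[str, ...] = tuple(sorted(DEFAULT_STOPWORDS))
    train: TrainConfig = field(default_factory=TrainConfig)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stopwords"] = list(self.stopwords)
        d["train"]["seeds"] = list(self.train.seeds)
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "PipelineConfig":
        data = dict(data)
        train = data.pop("train", {})
        return cls(
            **{k: (tuple(v) if k == "stopwords" else v) for k, v in data.items()},
            train=TrainConfig(**{k: (tuple(v) if k == "seeds" else v) for k, v in train.items()}),
        )


def build_run_verbalizer(
    classes: Sequence[str],
    shots: Sequence[Document],
    template,
    backend: MLMBackend,
    cfg: PipelineConfig,
    vectors: WordVectorStore | None = None,
) -> Verbalizer:
    """Run the enabled expansion strategies per class and union them.

    The candidate pool is the backend vocabulary minus special markers,
    stop-words and class seed names (intersected with the vector store for
    the similarity strategy).  The similarity strategy is skipped when no
    vector store is supplied.
    """
    exclude = set(cfg.stopwords) | set(classes)
    pool = [w for w in backend.vocabulary.words if w not in exclude]
    strategy_words: dict[str, dict[str, list[str]]] = {}
    for cls in classes:
        cls_shots = [d for d in shots if d.label == cls]
        out: dict[str, list[str]] = {}
        if cfg.use_mlm:
            out["mlm"] = expand_by_mlm(cls, cls_shots, template, backend,
                                       cfg.n_label_words, exclude, cfg.max_length)
        if cfg.use_similarity and vectors is not None:
            out["similarity"] = expand_by_similarity(cls, vectors, pool, cfg.n_label_words)
        if cfg.use_context:
            out["context"] = expand_by_context(pool, cls_shots, template, backend,
                                               cfg.n_label_words, cfg.context_positions,
                                               cfg.max_length)
        strategy_words[cls] = out
    return build_verbalizer(strategy_words, classes, cfg.n_label_words)


def run_task(
    pair: CorpusPair,
    truth: Mapping[str, str],
    backend: MLMBackend,
    cfg: PipelineConfig,
    seed: int,
    vectors: WordVectorStore | None = None,
) -> tuple[float, Verbalizer, MLMBackend]:
    """One seeded end-to-end run; returns (accuracy, verbalizer, trained backend)."""
    template = get_template(cfg.template_id)
    shots = few_shot_sample(pair.source, cfg.train.shots, seed)
    verbalizer = build_run_verbalizer(pair.classes, shots, template, backend, cfg, vectors)
    instances = [wrap(d, template, cfg.max_length) for d in shots]
    trained = train(instances, verbalizer, backend, cfg.train, seed).backend
    predictions = predict_corpus(pair.target, template, verbalizer, trained,
                                 cfg.max_length, cfg.train.batch_size)
    accuracy = evaluate({doc_id: s.predicted for doc_id, s in predictions}, truth)
    return accuracy, verbalizer, trained


@dataclass(frozen=True)
class RunResult:
    """Seed-averaged accuracy of one experimental condition, replayable from its manifest."""

    task: str
    template_id: str
    per_seed: Mapping[int, float]
    mean: float
    config: Mapping
    verbalizer_hashes: Mapping[int, str]

    def __post_init__(self) -> None:
        expected = float(np.mean(list(self.per_seed.values())))
        if abs(self.mean - expected) > 1e-12:
            raise EvaluationError("mean accuracy inconsistent with per-seed values")

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "template_id": self.template_id,
            "per_seed": {str(k): v for k, v in self.per_seed.items()},
            "mean": self.mean,
            "config": dict(self.config),
            "verbalizer_hashes": {str(k): v for k, v in self.verbalizer_hashes.items()},
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2), "utf-8")


def run_experiment(
    pair: CorpusPair,
    truth: Mapping[str, str],
    stub_spec: StubModelSpec,
    cfg: PipelineConfig,
    task: str = "task",
    vectors: WordVectorStore | None = None,
    generator_spec: GeneratorSpec | None = None,
) -> RunResult:
    """Run one condition over the configured seeds and average the accuracies."""
    hashes: dict[int, str] = {}

    def one(seed: int) -> float:
        accuracy, verbalizer, _ = run_task(pair, truth, StubBackend(stub_spec), cfg,
                                           seed, vectors)
        hashes[seed] = verbalizer.content_hash()
        return accuracy

    summary = run_with_seeds(one, cfg.train.seeds)
    config = cfg.to_dict()
    if generator_spec is not None:
        config["generator"] = generator_spec.to_dict()
        config["n_per_class"] = len(pair.source) // len(pair.classes)
        config["stub_alpha"] = float(stub_spec.alpha)
    return RunResult(task=task, template_id=cfg.template_id, per_seed=summary.per_seed,
                     mean=summary.mean, config=config, verbalizer_hashes=hashes)


def run_synthetic_experiment(
    spec: GeneratorSpec,
    n_per_class: int,
    cfg: PipelineConfig,
    task: str = "synthetic",
    alpha: float = 1.0,
) -> RunResult:
    """Generate a corpus from ``spec`` and run one condition on it.

    Word vectors for the similarity strategy are derived from the generator
    spec (seeded by ``spec.seed``), so the returned manifest replays
    bit-identically via :func:`replay`.
    """
    pair, truth, stub_spec = generate_corpus(spec, n_per_class, alpha=alpha)
    vectors = synthetic_vectors(spec, seed=spec.seed) if cfg.use_similarity else None
    return run_experiment(pair, truth, stub_spec, cfg, task=task, vectors=vectors,
                          generator_spec=spec)


def compare_templates(
    tasks: Sequence[tuple[str, CorpusPair, Mapping[str, str], StubModelSpec]],
    template_ids: Sequence[str],
    cfg: PipelineConfig,
    vectors: WordVectorStore | None = None,
) -> pd.DataFrame:
    """Mean accuracy per (task, template): identical seeds and shots per column,
    so only the template varies."""
    table: dict[str, dict[str, float]] = {}
    for name, pair, truth, stub_spec in tasks:
        row = {}
        for tid in template_ids:
            result = run_experiment(pair, truth, stub_spec,
                                    replace(cfg, template_id=str(tid)), task=name,
                                    vectors=vectors)
            row[str(tid)] = result.mean
        table[name] = row
    return pd.DataFrame.from_dict(table, orient="index", columns=[str(t) for t in template_ids])


_SWEEP_AXES = {"batch_size", "epochs", "shots"}


def sweep(
    axis: str,
    values: Sequence[int],
    pair: CorpusPair,
    truth: Mapping[str, str],
    stub_spec: StubModelSpec,
    cfg: PipelineConfig,
    vectors: WordVectorStore | None = None,
) -> list[RunResult]:
    """One RunResult per axis value, everything else held fixed."""
    if axis not in _SWEEP_AXES:
        raise EvaluationError(f"sweep axis must be one of {sorted(_SWEEP_AXES)}, got {axis!r}")
    results = []
    for value in values:
        swept = replace(cfg, train=replace(cfg.train, **{axis: int(value)}))
        results.append(run_experiment(pair, truth, stub_spec, swept,
                                      task=f"{axis}={value}", vectors=vectors))
    return results


def replay(manifest: Mapping) -> RunResult:
    """Re-run a synthetic-run manifest from scratch; stub runs replay bit-identically."""
    config = dict(manifest["config"])
    gen = config.pop("generator", None)
    if gen is None:
        raise EvaluationError("manifest has no generator spec; only synthetic runs replay")
    n_per_class = int(config.pop("n_per_class"))
    alpha = float(config.pop("stub_alpha", 1.0))
    spec = GeneratorSpec.from_dict(gen)
    cfg = PipelineConfig.from_dict(config)
    return run_synthetic_experiment(spec, n_per_class, cfg, task=manifest["task"],
                                    alpha=alpha)
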