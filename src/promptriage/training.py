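"""Few-shot training of the backend's trainable parameters.

The loss is the class-posterior cross-entropy built from the mean-label-word
scores: for an instance with true class ``y``,

    L = -log( g_y / sum_c g_c )

which reduces to ordinary cross-entropy when every class has a single label
word.  The trainer is plain full-precision gradient descent — exactly
reproducible on the stub backend, where the loss is convex in the soft-token
weights; adapter backends may swap in an adaptive optimizer, recorded in the
run manifest either way.

Defaults follow the few-shot protocol: learning rate 3e-5, batch size 32,
5 epochs, dropout 0.5 (adapter backends only; the stub has no dropout
surface), 20 shots per class, results averaged over 3 seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from .mlm import MLMBackend
from .templating import PromptedInstance
from .verbalizer import Verbalizer
from .classification import _resolved_words

__all__ = ["TrainConfig", "TrainResult", "SeedSummary", "training_loss", "train",
           "run_with_seeds"]


class TrainingError(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 3e-5
    batch_size: int = 32
    epochs: int = 5
    dropout: float = 0.5
    shots: int = 20
    seeds: tuple[int, ...] = (0, 1, 2)

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 1 or self.shots < 1:
            raise ValueError("batch_size, epochs and shots must all be >= 1")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative (0 freezes training)")
        if not self.seeds:
            raise ValueError("at least one seed is required")
        object.__setattr__(self, "seeds", tuple(int(s) for s in self.seeds))


def _instance_loss_and_grad(
    instance: PromptedInstance,
    verbalizer: Verbalizer,
    backend: MLMBackend,
    resolved: Mapping[str, Sequence[int]],
) -> tuple[float, np.ndarray]:
    """Loss and its gradient w.r.t. the mask-fill probability vector."""
    if instance.label is None:
        raise TrainingError(f"instance {instance.doc_id!r} has no label")
    if instance.label not in verbalizer.classes:
        raise TrainingError(
            f"instance {instance.doc_id!r}: label {instance.label!r} not in verbalizer"
        )
    p = backend.mask_fill_distribution(instance).probabilities
    g = {cls: float(np.mean(p[list(idx)])) for cls, idx in resolved.items()}
    total = sum(g.values())
    loss = -math.log(g[instance.label] / total)
    # dL/dg_c = -1[c==y]/g_y + 1/total; spread over that class's words by 1/k
    dldp = np.zeros_like(p)
    for cls, idx in resolved.items():
        dldg = (1.0 / total) - (1.0 / g[cls] if cls == instance.label else 0.0)
        dldp[list(idx)] += dldg / len(idx)
    return loss, dldp


def training_loss(
    instances: Sequence[PromptedInstance],
    verbalizer: Verbalizer,
    backend: MLMBackend,
) -> float:
    """Mean class-posterior cross-entropy over a labeled batch."""
    if not instances:
        raise TrainingError("empty batch")
    resolved = _resolved_words(verbalizer, backend)
    return float(np.mean([
        _instance_loss_and_grad(inst, verbalizer, backend, resolved)[0]
        for inst in instances
    ]))


@dataclass(frozen=True)
class TrainResult:
    backend: MLMBackend
    epoch_losses: tuple[float, ...]


def train(
    instances: Sequence[PromptedInstance],
    verbalizer: Verbalizer,
    backend: MLMBackend,
    config: TrainConfig,
    seed: int,
) -> TrainResult:
    """Gradient-descent training on wrapped, labeled shots.

    Runs ``epochs * ceil(n / batch_size)`` steps; the data order is reshuffled
    every epoch by a generator seeded with ``seed``, so a fixed seed gives a
    bit-identical loss trajectory on the stub backend.  The input backend is
    never mutated; the trained copy is returned together with the per-epoch
    mean losses.
    """
    if not instances:
        raise TrainingError("no training instances")
    backend = backend.copy()
    resolved = _resolved_words(verbalizer, backend)
    rng = np.random.default_rng(seed)
    n = len(instances)
    epoch_losses: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        total_loss = 0.0
        for start in range(0, n, config.batch_size):
            batch = [instances[i] for i in order[start:start + config.batch_size]]
            losses = []
            grad_sum: dict[str, np.ndarray] = {}
            for inst in batch:
                loss, dldp = _instance_loss_and_grad(inst, verbalizer, backend, resolved)
                losses.append(loss)
                for name, g in backend.backprop_mask(inst, dldp).items():
                    grad_sum[name] = grad_sum.get(name, 0.0) + g
            batch_loss = float(np.mean(losses))
            if not math.isfinite(batch_loss):
                raise TrainingError(
                    f"non-finite batch loss {batch_loss} "
                    f"(lr={config.learning_rate}, batch of {len(batch)})"
                )
            total_loss += float(np.sum(losses))
            mean_grads = {k: v / len(batch) for k, v in grad_sum.items()}
            backend.apply_gradient_step(mean_grads, config.learning_rate)
        epoch_losses.append(total_loss / n)
    return TrainResult(backend=backend, epoch_losses=tuple(epoch_losses))


@dataclass(frozen=True)
class SeedSummary:
    per_seed: Mapping[int, float]
    mean: float


def run_with_seeds(fn: Callable[[int], float], seeds: Sequence[int]) -> SeedSummary:
    """Run a train+evaluate closure per seed and average the metric."""
    if not seeds:
        raise ValueError("at least one seed is required")
    per_seed = {int(s): float(fn(int(s))) for s in seeds}
    return SeedSummary(per_seed=per_seed, mean=float(np.mean(list(per_seed.values()))))
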