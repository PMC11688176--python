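"""Deterministic stub masked LM with analytically known conditionals.

The stub's vocabulary is partitioned into per-class source-flavored word sets
``A_c``, per-class target-flavored sets ``B_c`` and a filler set ``F``.  For a
prompted instance with context tokens ``ctx`` the affinity score of a
vocabulary word ``w`` of class ``c`` is

    s(w) = alpha * #{t in ctx : t in A_c or B_c}  +  sum_j u[j, c]

where the sum runs over the soft slots present in the instance and ``u`` are
the trainable per-slot, per-class soft-token weights; filler words score 0.
The mask-fill distribution is ``softmax(s)``, computed in log space.  Because
the soft weights enter the logits additively, the class-posterior
cross-entropy used in training is convex in them, which makes recovery of
planted class affinities provable rather than merely plausible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml
from scipy.special import logsumexp

from .mlm import BackendError, BackendVocabulary, MaskDistribution, MLMBackend
from .templating import PromptedInstance

__all__ = ["StubModelSpec", "StubBackend"]


@dataclass(frozen=True)
class StubModelSpec:
    """Vocabulary partition, affinity strength and soft-token weights of a stub LM."""

    classes: tuple[str, ...]
    source_words: Mapping[str, tuple[str, ...]]  # A_c
    target_words: Mapping[str, tuple[str, ...]]  # B_c
    filler: tuple[str, ...]  # F
    alpha: float = 1.0
    n_soft_slots: int = 3
    soft_weights: np.ndarray | None = None  # shape (n_soft_slots, n_classes)

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise BackendError("alpha must be non-negative")
        pools: list[set[str]] = [set(self.filler)]
        for c in self.classes:
            pools.append(set(self.source_words[c]))
            pools.append(set(self.target_words[c]))
        total = sum(len(p) for p in pools)
        if len(set().union(*pools)) != total:
            raise BackendError("A_c, B_c and F word sets must be pairwise disjoint")
        w = self.soft_weights
        if w is None:
            w = np.zeros((self.n_soft_slots, len(self.classes)))
        w = np.asarray(w, dtype=float)
        if w.shape != (self.n_soft_slots, len(self.classes)):
            raise BackendError(
                f"soft_weights shape {w.shape} != ({self.n_soft_slots}, {len(self.classes)})"
            )
        object.__setattr__(self, "soft_weights", w)

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "source_words": {c: list(v) for c, v in self.source_words.items()},
            "target_words": {c: list(v) for c, v in self.target_words.items()},
            "filler": list(self.filler),
            "alpha": float(self.alpha),
            "n_soft_slots": int(self.n_soft_slots),
            "soft_weights": np.asarray(self.soft_weights).tolist(),
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "StubModelSpec":
        return cls(
            classes=tuple(data["classes"]),
            source_words={c: tuple(v) for c, v in data["source_words"].items()},
            target_words={c: tuple(v) for c, v in data["target_words"].items()},
            filler=tuple(data["filler"]),
            alpha=float(data.get("alpha", 1.0)),
            n_soft_slots=int(data.get("n_soft_slots", 3)),
            soft_weights=np.asarray(data["soft_weights"], dtype=float)
            if data.get("soft_weights") is not None
            else None,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False), "utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "StubModelSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text("utf-8")))


class StubBackend(MLMBackend):
    """Masked-LM backend implementing the additive-affinity stub model.

    The vocabulary lists each class's ``A_c`` words (in class order), then
    each class's ``B_c`` words, then the filler words, in the order the spec
    gives them.
    """

    def __init__(self, spec: StubModelSpec):
        self.spec = spec
        words: list[str] = []
        for c in spec.classes:
            words.extend(spec.source_words[c])
        for c in spec.classes:
            words.extend(spec.target_words[c])
        words.extend(spec.filler)
        self.vocabulary = BackendVocabulary(words=tuple(words))
        # class index per vocabulary word; -1 for filler
        cls_index = {c: i for i, c in enumerate(spec.classes)}
        self._word_class = np.full(len(words), -1, dtype=int)
        self._token_class: dict[str, int] = {}
        for c in spec.classes:
            for w in (*spec.source_words[c], *spec.target_words[c]):
                self._word_class[self.vocabulary.index(w)] = cls_index[c]
                self._token_class[w] = cls_index[c]
        self._soft_weights = np.array(spec.soft_weights, dtype=float)

    # -- distribution ------------------------------------------------------

    def _logits(self, instance: PromptedInstance) -> np.ndarray:
        voc = self.vocabulary
        n_soft = len(instance.soft_indices)
        if n_soft > self.spec.n_soft_slots:
            raise BackendError(
                f"instance has {n_soft} soft slots; stub supports {self.spec.n_soft_slots}"
            )
        counts = np.zeros(len(self.spec.classes))
        for i, tok in enumerate(instance.tokens):
            if voc.is_special(tok) or i in instance.soft_indices:
                continue
            c = self._token_class.get(tok)
            if c is not None:
                counts[c] += 1
        class_score = self.spec.alpha * counts
        if n_soft:
            class_score = class_score + self._soft_weights[:n_soft].sum(axis=0)
        s = np.zeros(len(voc))
        indicative = self._word_class >= 0
        s[indicative] = class_score[self._word_class[indicative]]
        return s

    def mask_fill_distribution(self, instance: PromptedInstance) -> MaskDistribution:
        n_masks = sum(1 for t in instance.tokens if t == self.vocabulary.mask_token)
        if n_masks != 1:
            raise BackendError(f"instance must contain exactly one mask slot, found {n_masks}")
        s = self._logits(instance)
        logp = s - logsumexp(s)
        return MaskDistribution(probabilities=np.exp(logp), vocabulary=self.vocabulary)

    # -- training contract -------------------------------------------------

    def trainable_parameters(self) -> dict[str, np.ndarray]:
        return {"soft_weights": self._soft_weights.copy()}

    def apply_gradient_step(
        self, gradients: Mapping[str, np.ndarray], learning_rate: float
    ) -> None:
        for name, grad in gradients.items():
            if name != "soft_weights":
                raise BackendError(f"unknown trainable parameter {name!r}")
            grad = np.asarray(grad, dtype=float)
            if grad.shape != self._soft_weights.shape:
                raise BackendError(
                    f"gradient shape {grad.shape} != parameter shape "
                    f"{self._soft_weights.shape}"
                )
            if learning_rate != 0.0:
                self._soft_weights -= learning_rate * grad
        self.spec = replace(self.spec, soft_weights=self._soft_weights.copy())

    def backprop_mask(
        self, instance: PromptedInstance, dloss_dp: np.ndarray
    ) -> dict[str, np.ndarray]:
        """Chain a loss gradient w.r.t. the mask-fill probabilities into the soft weights.

        With ``p = softmax(s)``, ``dL/ds_v = p_v (dL/dp_v - sum_w dL/dp_w p_w)``;
        a soft slot's weight for class ``c`` collects ``dL/ds`` over class-``c``
        words, identically for every soft slot present (they enter the logits
        symmetrically).
        """
        p = self.mask_fill_distribution(instance).probabilities
        dloss_dp = np.asarray(dloss_dp, dtype=float)
        if dloss_dp.shape != p.shape:
            raise BackendError("dloss_dp shape does not match vocabulary size")
        ds = p * (dloss_dp - float(dloss_dp @ p))
        grad = np.zeros_like(self._soft_weights)
        n_soft = len(instance.soft_indices)
        if n_soft:
            per_class = np.zeros(len(self.spec.classes))
            indicative = self._word_class >= 0
            np.add.at(per_class, self._word_class[indicative], ds[indicative])
            grad[:n_soft] = per_class
        return {"soft_weights": grad}

    def copy(self) -> "StubBackend":
        return StubBackend(replace(self.spec, soft_weights=self._soft_weights.copy()))
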