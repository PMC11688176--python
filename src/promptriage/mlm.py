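"""The masked-language-model backend contract.

Every downstream stage (verbalizer expansion, class scoring, training) talks
to a masked LM only through :class:`MLMBackend`: a vocabulary, a probability
distribution over that vocabulary at the single mask slot of a prompted
instance, a per-position cross-entropy, and a trainable-parameter step.
:mod:`promptriage.stub` provides a deterministic implementation with
analytically known conditionals; :mod:`promptriage.hf` adapts pretrained
transformer checkpoints to the same contract.
"""

from __future__ import annotations

import abc
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "BOS_TOKEN",
    "MASK_TOKEN",
    "SOFT_TOKEN",
    "BackendError",
    "BackendVocabulary",
    "MaskDistribution",
    "MLMBackend",
]

BOS_TOKEN = "[CLS]"
MASK_TOKEN = "[MASK]"
SOFT_TOKEN = "[SOFT]"


class BackendError(ValueError):
    """Contract violation at the masked-LM boundary."""


@dataclass(frozen=True)
class BackendVocabulary:
    """An ordered word list plus the special markers, which are not words."""

    words: tuple[str, ...]
    bos_token: str = BOS_TOKEN
    mask_token: str = MASK_TOKEN
    soft_token: str = SOFT_TOKEN
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.words)) != len(self.words):
            raise BackendError("vocabulary words must be unique")
        specials = {self.bos_token, self.mask_token, self.soft_token}
        if specials & set(self.words):
            raise BackendError("special markers must not appear among vocabulary words")
        object.__setattr__(self, "_index", {w: i for i, w in enumerate(self.words)})

    def __len__(self) -> int:
        return len(self.words)

    def __contains__(self, word: str) -> bool:
        return word in self._index

    def index(self, word: str) -> int:
        try:
            return self._index[word]
        except KeyError:
            raise BackendError(f"word {word!r} not in backend vocabulary") from None

    def is_special(self, token: str) -> bool:
        return token in (self.bos_token, self.mask_token, self.soft_token)


@dataclass(frozen=True)
class MaskDistribution:
    """A probability vector over the backend vocabulary at the mask position."""

    probabilities: np.ndarray
    vocabulary: BackendVocabulary

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", p)
        if p.shape != (len(self.vocabulary),):
            raise BackendError("distribution length does not match vocabulary size")
        if np.any(p < 0):
            raise BackendError("negative probability in mask distribution")
        if abs(float(p.sum()) - 1.0) > 1e-9:
            raise BackendError(f"mask distribution sums to {p.sum()!r}, not 1")

    def p(self, word: str) -> float:
        return float(self.probabilities[self.vocabulary.index(word)])


class MLMBackend(abc.ABC):
    """Contract every masked-LM backend implements."""

    vocabulary: BackendVocabulary

    @abc.abstractmethod
    def mask_fill_distribution(self, instance) -> MaskDistribution:
        """Distribution over the vocabulary at the instance's single mask slot."""

    @abc.abstractmethod
    def trainable_parameters(self) -> dict[str, np.ndarray]:
        """Copies of the parameters a gradient step may change, keyed by name."""

    @abc.abstractmethod
    def apply_gradient_step(
        self, gradients: Mapping[str, np.ndarray], learning_rate: float
    ) -> None:
        """In-place descent step ``theta -= lr * grad`` on declared parameters."""

    @abc.abstractmethod
    def backprop_mask(self, instance, dloss_dp: np.ndarray) -> dict[str, np.ndarray]:
        """Gradient of a scalar loss w.r.t. trainable parameters.

        ``dloss_dp`` is the loss gradient w.r.t. the mask-fill probability
        vector of ``instance``; the backend chains it through its own
        parameterization.
        """

    @abc.abstractmethod
    def copy(self) -> "MLMBackend":
        """Independent deep copy (training never mutates the caller's backend)."""

    def token_cross_entropy(self, instance, position: int) -> float:
        """Cross-entropy of the true token at ``position`` when it is masked.

        The position is masked internally and the mask-fill distribution
        queried; returns ``-log p(true token)``.  Consistency with
        :meth:`mask_fill_distribution` therefore holds by construction.
        """
        tokens = instance.tokens
        if not 0 <= position < len(tokens):
            raise BackendError(f"position {position} out of range for {len(tokens)} tokens")
        token = tokens[position]
        if self.vocabulary.is_special(token):
            raise BackendError(f"cannot mask special token {token!r} at position {position}")
        if self.vocabulary.mask_token in tokens:
            raise BackendError("instance already contains a mask slot")
        if token not in self.vocabulary:
            raise BackendError(f"true token {token!r} not in backend vocabulary")
        masked = instance.with_mask_at(position)
        dist = self.mask_fill_distribution(masked)
        return float(-np.log(dist.p(token)))
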