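"""Class scoring by the mean mask probability of each class's label words.

For a wrapped document the backend yields one distribution over its
vocabulary at the mask slot.  Each class ``c`` with label words
``w_1 .. w_k`` scores

    g_c = (1/k) * sum_i p(mask = w_i | instance)

— every label word contributes equally — and the predicted class is the
argmax of ``g``, ties broken by the declared class order.  A normalized
posterior ``g_c / sum_c' g_c'`` is also reported; it is what the training
loss penalizes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .corpus_io import Document
from .mlm import MLMBackend
from .templating import PromptedInstance, Template, wrap
from .verbalizer import Verbalizer

__all__ = ["ClassificationError", "ClassScores", "score_classes", "predict_corpus",
           "write_predictions", "read_predictions"]

logger = logging.getLogger(__name__)


class ClassificationError(ValueError):
    pass


@dataclass(frozen=True)
class ClassScores:
    """Per-class mean label-word probability, normalized posterior and argmax."""

    g: Mapping[str, float]
    posterior: Mapping[str, float]
    predicted: str


def _resolved_words(verbalizer: Verbalizer, backend: MLMBackend) -> dict[str, list[int]]:
    """Vocabulary indices of each class's label words; missing words dropped with a warning."""
    resolved: dict[str, list[int]] = {}
    for cls in verbalizer.classes:
        idx = []
        for word in verbalizer.words(cls):
            if word in backend.vocabulary:
                idx.append(backend.vocabulary.index(word))
            else:
                logger.warning("label word %r (class %r) not in backend vocabulary; dropped",
                               word, cls)
        if not idx:
            raise ClassificationError(
                f"class {cls!r} has no label word resolvable in the backend vocabulary"
            )
        resolved[cls] = idx
    return resolved


def score_classes(
    instance: PromptedInstance, verbalizer: Verbalizer, backend: MLMBackend
) -> ClassScores:
    """Score every class for one prompted instance and predict the argmax."""
    resolved = _resolved_words(verbalizer, backend)
    p = backend.mask_fill_distribution(instance).probabilities
    g = {cls: float(np.mean(p[idx])) for cls, idx in resolved.items()}
    total = sum(g.values())
    posterior = {cls: v / total for cls, v in g.items()}
    best = max(g.values())
    predicted = next(cls for cls in verbalizer.classes if g[cls] == best)
    return ClassScores(g=g, posterior=posterior, predicted=predicted)


def predict_corpus(
    docs: Sequence[Document],
    template: Template,
    verbalizer: Verbalizer,
    backend: MLMBackend,
    max_length: int = 128,
    batch_size: int = 32,
) -> list[tuple[str, ClassScores]]:
    """Order-preserving per-document predictions.

    Scoring is per-instance and side-effect free, so the result is identical
    for any ``batch_size`` partitioning; the parameter exists for adapter
    backends that batch for throughput.
    """
    del batch_size  # partitioning cannot change per-instance scores
    results: list[tuple[str, ClassScores]] = []
    for doc in docs:
        try:
            scores = score_classes(wrap(doc, template, max_length), verbalizer, backend)
        except Exception as exc:
            raise ClassificationError(f"document {doc.id!r}: {exc}") from exc
        results.append((doc.id, scores))
    return results


def write_predictions(
    predictions: Sequence[tuple[str, ClassScores]], path: str | Path
) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for doc_id, scores in predictions:
            fh.write(json.dumps(
                {"id": doc_id, "predicted": scores.predicted,
                 "scores": {c: scores.g[c] for c in scores.g}},
                ensure_ascii=False) + "\n")


def read_predictions(path: str | Path) -> dict[str, str]:
    """Predicted class per document id."""
    out: dict[str, str] = {}
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                record = json.loads(line)
                out[str(record["id"])] = record["predicted"]
    return out
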