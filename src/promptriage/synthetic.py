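"""Synthetic cross-domain corpora with planted class structure.

Documents are bags of tokens drawn from a token-level mixture: each token is
class-indicative with probability ``pi`` and filler otherwise.  In the source
domain an indicative token of class ``c`` comes from the source-flavored
lexicon ``A_c``; in the target domain it comes from the target-flavored
lexicon ``B_c`` with probability ``delta`` (the domain-shift dial) and from
``A_c`` otherwise.  ``delta = 0`` makes the domains identically distributed;
``delta = 1`` moves every indicative target token into vocabulary the source
never used — emulating sibling clinical sub-disciplines whose wording drifts
apart while the underlying departments stay the same.

The law is simple enough that the Bayes-optimal classifier has a closed form
(:func:`bayes_accuracy`), giving every pipeline evaluation an oracle ceiling,
and each generated corpus ships with a matched stub masked LM sharing the
same lexicons so the whole pipeline runs with no download.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .corpus_io import CorpusPair, Document
from .stub import StubModelSpec
from .verbalizer import WordVectorStore

__all__ = ["GeneratorSpec", "generate_corpus", "bayes_accuracy", "synthetic_vectors"]

DEFAULT_CLASSES = ("pediatrics", "internal", "surgery", "oncology")


@dataclass(frozen=True)
class GeneratorSpec:
    """Lexicons and mixture rates defining a cross-domain generative law."""

    classes: tuple[str, ...]
    source_lexicon: Mapping[str, tuple[str, ...]]  # A_c
    target_lexicon: Mapping[str, tuple[str, ...]]  # B_c
    filler: tuple[str, ...]
    length_range: tuple[int, int] = (5, 15)
    pi: float = 0.3
    delta: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.pi <= 1 or not 0 <= self.delta <= 1:
            raise ValueError("pi and delta must lie in [0, 1]")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValueError(f"bad length range {self.length_range}")
        for c in self.classes:
            if not self.source_lexicon[c] or not self.target_lexicon[c]:
                raise ValueError(f"empty lexicon for class {c!r}")
        if not self.filler:
            raise ValueError("empty filler lexicon")

    @classmethod
    def default(
        cls,
        classes: Sequence[str] = DEFAULT_CLASSES,
        words_per_lexicon: int = 30,
        filler_size: int = 100,
        **overrides,
    ) -> "GeneratorSpec":
        """Standard spec: department-named classes, 30-word lexicons, 100 fillers.

        Each class's source lexicon includes the class name itself, so the
        verbalizer's seed word is a scorable vocabulary word of the matched
        stub backend.
        """
        source = {
            c: (c,) + tuple(f"{c}_src_{i}" for i in range(words_per_lexicon - 1))
            for c in classes
        }
        target = {
            c: tuple(f"{c}_tgt_{i}" for i in range(words_per_lexicon)) for c in classes
        }
        filler = tuple(f"filler_{i}" for i in range(filler_size))
        return cls(classes=tuple(classes), source_lexicon=source,
                   target_lexicon=target, filler=filler, **overrides)

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "source_lexicon": {c: list(v) for c, v in self.source_lexicon.items()},
            "target_lexicon": {c: list(v) for c, v in self.target_lexicon.items()},
            "filler": list(self.filler),
            "length_range": list(self.length_range),
            "pi": float(self.pi),
            "delta": float(self.delta),
            "seed": int(self.seed),
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "GeneratorSpec":
        return cls(
            classes=tuple(data["classes"]),
            source_lexicon={c: tuple(v) for c, v in data["source_lexicon"].items()},
            target_lexicon={c: tuple(v) for c, v in data["target_lexicon"].items()},
            filler=tuple(data["filler"]),
            length_range=tuple(data["length_range"]),
            pi=float(data["pi"]),
            delta=float(data["delta"]),
            seed=int(data["seed"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False), "utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "GeneratorSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text("utf-8")))


def _draw_tokens(spec: GeneratorSpec, cls: str, split: str, rng: np.random.Generator) -> list[str]:
    lo, hi = spec.length_range
    length = int(rng.integers(lo, hi + 1))
    tokens = []
    for _ in range(length):
        if rng.random() < spec.pi:
            if split == "target" and rng.random() < spec.delta:
                pool = spec.target_lexicon[cls]
            else:
                pool = spec.source_lexicon[cls]
        else:
            pool = spec.filler
        tokens.append(pool[int(rng.integers(len(pool)))])
    return tokens


def generate_corpus(
    spec: GeneratorSpec,
    n_per_class: int,
    alpha: float = 1.0,
    n_soft_slots: int = 3,
) -> tuple[CorpusPair, dict[str, str], StubModelSpec]:
    """Generate a corpus pair, the hidden target truth and a matched stub LM.

    Source documents carry their labels; target documents are unlabeled, with
    opaque shuffled ids, and their true classes are returned in a separate
    mapping so the pipeline cannot leak them.  The stub spec shares the
    generator's lexicons (A_c, B_c, F) with ``alpha`` affinity strength and
    zero-initialized soft weights.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(spec.seed)
    source: list[Document] = []
    for c in spec.classes:
        for i in range(n_per_class):
            source.append(Document(
                id=f"src-{c}-{i:05d}",
                text=" ".join(_draw_tokens(spec, c, "source", rng)),
                label=c, domain="source"))
    target_raw: list[tuple[str, str]] = []  # (text, true class)
    for c in spec.classes:
        for _ in range(n_per_class):
            target_raw.append((" ".join(_draw_tokens(spec, c, "target", rng)), c))
    order = rng.permutation(len(target_raw))
    target: list[Document] = []
    truth: dict[str, str] = {}
    for k, j in enumerate(order):
        text, c = target_raw[j]
        doc_id = f"tgt-{k:05d}"
        target.append(Document(id=doc_id, text=text, label=None, domain="target"))
        truth[doc_id] = c
    pair = CorpusPair(source=tuple(source), target=tuple(target), classes=spec.classes)
    stub = StubModelSpec(
        classes=spec.classes,
        source_words=dict(spec.source_lexicon),
        target_words=dict(spec.target_lexicon),
        filler=spec.filler,
        alpha=alpha,
        n_soft_slots=n_soft_slots,
    )
    return pair, truth, stub


def _log_likelihoods(tokens: Sequence[str], spec: GeneratorSpec) -> np.ndarray:
    """Per-class log likelihood of a target-domain token sequence (uniform prior)."""
    a_index = {w: c for c, ws in spec.source_lexicon.items() for w in ws}
    b_index = {w: c for c, ws in spec.target_lexicon.items() for w in ws}
    filler = set(spec.filler)
    ll = np.zeros(len(spec.classes))
    for tok in tokens:
        probs = np.empty(len(spec.classes))
        for i, c in enumerate(spec.classes):
            if tok in filler:
                probs[i] = (1 - spec.pi) / len(spec.filler)
            elif a_index.get(tok) == c:
                probs[i] = spec.pi * (1 - spec.delta) / len(spec.source_lexicon[c])
            elif b_index.get(tok) == c:
                probs[i] = spec.pi * spec.delta / len(spec.target_lexicon[c])
            else:
                probs[i] = 0.0
        with np.errstate(divide="ignore"):
            ll += np.log(probs)
    return ll


def bayes_accuracy(spec: GeneratorSpec, n_docs: int, seed: int) -> float:
    """Oracle accuracy of the exact posterior classifier on fresh target docs.

    Generates ``n_docs`` Monte-Carlo target documents (classes cycled so the
    sample is balanced), classifies each by the exact posterior under the
    generative law, breaking ties by class order, and returns the fraction
    correct.  This is the ceiling any pipeline accuracy is compared against.
    """
    rng = np.random.default_rng(seed)
    correct = 0
    for k in range(n_docs):
        c = spec.classes[k % len(spec.classes)]
        tokens = _draw_tokens(spec, c, "target", rng)
        ll = _log_likelihoods(tokens, spec)
        pred = spec.classes[int(np.argmax(ll))]  # argmax takes the first max: class order
        correct += pred == c
    return correct / n_docs


def synthetic_vectors(
    spec: GeneratorSpec, dim: int = 16, noise: float = 0.25, seed: int = 0
) -> WordVectorStore:
    """Class-clustered static word vectors matched to a generator spec.

    Each class gets a random unit direction; its lexicon words (source and
    target flavored) sit near that direction with Gaussian jitter, filler
    words near directions of their own.  Gives the similarity strategy a
    store in which class-indicative words rank above filler, the structure
    real distributional vectors would show.  Synthetic stand-in: no real
    fastText vectors are involved.
    """
    rng = np.random.default_rng(seed)
    vectors: dict[str, np.ndarray] = {}

    def unit(v: np.ndarray) -> np.ndarray:
        return v / np.linalg.norm(v)

    for c in spec.classes:
        center = unit(rng.normal(size=dim))
        for w in {c, *spec.source_lexicon[c], *spec.target_lexicon[c]}:
            vectors[w] = unit(center + noise * rng.normal(size=dim))
    for w in spec.filler:
        vectors[w] = unit(rng.normal(size=dim))
    return WordVectorStore(vectors)
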