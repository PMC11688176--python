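"""Verbalizer construction: per-class label-word sets from three expansion strategies.

A verbalizer maps mask-slot vocabulary words ("label words") to classes.  Each
class starts from its seed name and is expanded by

* **masked-LM prediction** — wrap each shot of the class, average the
  mask-fill distributions entrywise, take the top-N words;
* **static-vector similarity** — cosine similarity between the class name's
  word vector and each candidate's vector, top-N;
* **context fit** — substitute the candidate at the mask slot, mask each
  surrounding token in turn (left to right), average the cross-entropies;
  lower mean loss ranks better, top-N ascending.

The per-class union of the three lists plus the seed name is the final
verbalizer.  A word proposed for two classes is kept only under the class
where its best strategy rank is better, so every word maps to exactly one
class and the mean-score classifier stays well-posed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .corpus_io import Document
from .mlm import MLMBackend
from .templating import Template, wrap

__all__ = [
    "VerbalizerError",
    "LabelWord",
    "Verbalizer",
    "WordVectorStore",
    "DEFAULT_STOPWORDS",
    "top_n",
    "expand_by_mlm",
    "expand_by_similarity",
    "context_score",
    "expand_by_context",
    "build_verbalizer",
]

logger = logging.getLogger(__name__)

DEFAULT_N = 15

# minimal function-word list for candidate-pool filtering; configurable at call sites
DEFAULT_STOPWORDS: frozenset[str] = frozenset(
    """a an and are as at be but by for from has have i in is it its of on or
    that the this to was were will with what should do if my""".split()
)


class VerbalizerError(ValueError):
    pass


def top_n(
    scores: Mapping[str, float], n: int, order: str = "descending"
) -> list[str]:
    """The ``n`` best-scoring words; ties broken by lexicographic word order.

    Fewer than ``n`` candidates returns all of them; an empty mapping returns
    an empty list.
    """
    if n < 1:
        raise VerbalizerError("n must be >= 1")
    if order == "descending":
        key = lambda kv: (-kv[1], kv[0])
    elif order == "ascending":
        key = lambda kv: (kv[1], kv[0])
    else:
        raise VerbalizerError(f"order must be 'descending' or 'ascending', got {order!r}")
    return [w for w, _ in sorted(scores.items(), key=key)[:n]]


@dataclass(frozen=True)
class LabelWord:
    word: str
    provenance: tuple[str, ...]  # subset of {"seed-name", "mlm", "similarity", "context"}


@dataclass(frozen=True)
class Verbalizer:
    """Ordered per-class label-word sets with per-word provenance."""

    classes: tuple[str, ...]
    entries: Mapping[str, tuple[LabelWord, ...]]
    n: int = DEFAULT_N

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for cls in self.classes:
            words = self.entries[cls]
            if not words:
                raise VerbalizerError(f"class {cls!r} has an empty label-word set")
            for lw in words:
                if lw.word in seen:
                    raise VerbalizerError(
                        f"word {lw.word!r} appears under both {seen[lw.word]!r} and {cls!r}"
                    )
                seen[lw.word] = cls

    def words(self, cls: str) -> tuple[str, ...]:
        return tuple(lw.word for lw in self.entries[cls])

    def to_json(self) -> str:
        payload = {
            cls: [{"word": lw.word, "provenance": list(lw.provenance)} for lw in self.entries[cls]]
            for cls in self.classes
        }
        return json.dumps({"n": self.n, "classes": payload}, ensure_ascii=False, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "Verbalizer":
        data = json.loads(text)
        entries = {
            c: tuple(LabelWord(e["word"], tuple(e["provenance"])) for e in items)
            for c, items in data["classes"].items()
        }
        return cls(classes=tuple(data["classes"]), entries=entries, n=int(data["n"]))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), "utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "Verbalizer":
        return cls.from_json(Path(path).read_text("utf-8"))

    def content_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode("utf-8")).hexdigest()[:16]


class WordVectorStore:
    """Static word vectors in the plain-text ``.vec`` dialect.

    First line is ``<count> <dimension>``; each following line is a word and
    its components, space-separated.  All vectors must share one dimension and
    be non-zero (a zero vector has no direction for a cosine query).
    """

    def __init__(self, vectors: Mapping[str, np.ndarray]):
        if not vectors:
            raise VerbalizerError("empty word-vector store")
        dims = {np.asarray(v).shape for v in vectors.values()}
        if len(dims) != 1 or len(next(iter(dims))) != 1:
            raise VerbalizerError(f"inconsistent vector dimensions: {dims}")
        self._vectors = {w: np.asarray(v, dtype=float) for w, v in vectors.items()}
        for w, v in self._vectors.items():
            if not np.linalg.norm(v) > 0:
                raise VerbalizerError(f"zero vector for word {w!r}")
        self.dim = len(next(iter(self._vectors.values())))

    def __contains__(self, word: str) -> bool:
        return word in self._vectors

    def __len__(self) -> int:
        return len(self._vectors)

    def vector(self, word: str) -> np.ndarray:
        return self._vectors[word]

    @classmethod
    def load(cls, path: str | Path) -> "WordVectorStore":
        vectors: dict[str, np.ndarray] = {}
        with Path(path).open("r", encoding="utf-8") as fh:
            header = fh.readline().split()
            if len(header) != 2:
                raise VerbalizerError(f"{path}: expected '<count> <dim>' header")
            _, dim = (int(x) for x in header)
            for lineno, line in enumerate(fh, start=2):
                parts = line.rstrip("\n").split(" ")
                if len(parts) != dim + 1:
                    raise VerbalizerError(f"{path}:{lineno}: expected word + {dim} components")
                vectors[parts[0]] = np.asarray(parts[1:], dtype=float)
        return cls(vectors)

    def save(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write(f"{len(self._vectors)} {self.dim}\n")
            for w, v in self._vectors.items():
                fh.write(w + " " + " ".join(f"{x:.6f}" for x in v) + "\n")


# -- expansion strategies ---------------------------------------------------


def expand_by_mlm(
    class_name: str,
    shots: Sequence[Document],
    template: Template,
    backend: MLMBackend,
    n: int = DEFAULT_N,
    exclude: Iterable[str] = (),
    max_length: int = 128,
) -> list[str]:
    """Top-N vocabulary words under the shot-averaged mask-fill distribution."""
    if not shots:
        raise VerbalizerError("expand_by_mlm needs at least one shot")
    total = None
    for doc in shots:
        dist = backend.mask_fill_distribution(wrap(doc, template, max_length))
        total = dist.probabilities if total is None else total + dist.probabilities
    mean = total / len(shots)
    skip = set(exclude) | {class_name}
    scores = {
        w: float(mean[i])
        for i, w in enumerate(backend.vocabulary.words)
        if w not in skip
    }
    return top_n(scores, n, "descending")


def expand_by_similarity(
    class_name: str,
    vectors: WordVectorStore,
    candidates: Sequence[str],
    n: int = DEFAULT_N,
) -> list[str]:
    """Top-N candidates by cosine similarity to the class name's vector.

    Candidates absent from the store are skipped; a class name absent from the
    store is an error.
    """
    if class_name not in vectors:
        raise VerbalizerError(f"class name {class_name!r} not in word-vector store")
    ref = vectors.vector(class_name)
    ref = ref / np.linalg.norm(ref)
    scores: dict[str, float] = {}
    for cand in candidates:
        if cand == class_name or cand not in vectors:
            continue
        v = vectors.vector(cand)
        scores[cand] = float(ref @ v / np.linalg.norm(v))
    return top_n(scores, n, "descending")


def _maskable_positions(instance, backend: MLMBackend, skip: int | None) -> list[int]:
    voc = backend.vocabulary
    positions = []
    for i, tok in enumerate(instance.tokens):
        if i == skip or i in instance.soft_indices or voc.is_special(tok):
            continue
        if tok in voc:  # the backend cannot score a token it cannot represent
            positions.append(i)
    return positions


def context_score(
    candidate: str,
    shots: Sequence[Document],
    template: Template,
    backend: MLMBackend,
    max_positions: int | None = None,
    max_length: int = 128,
) -> float:
    """Mean masked cross-entropy of the context around a substituted candidate.

    The candidate replaces the mask slot; each surrounding non-special,
    non-soft token (document and template literals alike) is masked in turn,
    left to right, up to ``max_positions`` per shot, and the cross-entropies
    are averaged over positions and shots.
    """
    total, count = 0.0, 0
    for doc in shots:
        inst = wrap(doc, template, max_length)
        sub = inst.substitute_mask(candidate)
        positions = _maskable_positions(sub, backend, skip=inst.mask_index)
        if max_positions is not None:
            positions = positions[:max_positions]
        for pos in positions:
            total += backend.token_cross_entropy(sub, pos)
            count += 1
    if count == 0:
        raise VerbalizerError("no maskable context token in any shot")
    return total / count


def expand_by_context(
    candidates: Sequence[str],
    shots: Sequence[Document],
    template: Template,
    backend: MLMBackend,
    n: int = DEFAULT_N,
    max_positions: int | None = None,
    max_length: int = 128,
) -> list[str]:
    """Top-N candidates by (ascending) mean context cross-entropy."""
    scores = {
        cand: context_score(cand, shots, template, backend, max_positions, max_length)
        for cand in candidates
    }
    return top_n(scores, n, "ascending")


# -- final assembly ---------------------------------------------------------

_STRATEGIES = ("mlm", "similarity", "context")


def build_verbalizer(
    strategy_words: Mapping[str, Mapping[str, Sequence[str]]],
    classes: Sequence[str],
    n: int = DEFAULT_N,
    seed_names: Mapping[str, str] | None = None,
) -> Verbalizer:
    """Union the three strategies' lists per class into the final verbalizer.

    ``strategy_words[cls][strategy]`` is that strategy's ranked list for the
    class (any may be empty).  The class seed name (the class name itself
    unless overridden) is always included.  A word proposed for two classes is
    assigned to the class where its best (smallest) strategy rank occurs,
    breaking ties by the declared class order.
    """
    seed_names = dict(seed_names or {})
    proposals: dict[str, dict[str, tuple[int, set[str]]]] = {}  # cls -> word -> (rank, prov)
    for cls in classes:
        per_strategy = strategy_words.get(cls, {})
        unknown = set(per_strategy) - set(_STRATEGIES)
        if unknown:
            raise VerbalizerError(f"unknown strategies {sorted(unknown)} for class {cls!r}")
        words: dict[str, tuple[int, set[str]]] = {}
        for strategy in _STRATEGIES:
            ranked = list(per_strategy.get(strategy, ()))
            if len(ranked) > n:
                raise VerbalizerError(
                    f"strategy {strategy!r} proposed {len(ranked)} > N={n} words for {cls!r}"
                )
            for rank, word in enumerate(ranked):
                if word in words:
                    best, prov = words[word]
                    words[word] = (min(best, rank), prov | {strategy})
                else:
                    words[word] = (rank, {strategy})
        proposals[cls] = words

    # cross-class eviction: keep each word only under its best-ranked class;
    # a seed name always belongs to its own class
    seed_owner = {seed_names.get(c, c): c for c in classes}
    owner: dict[str, str] = {}
    class_pos = {c: i for i, c in enumerate(classes)}
    for word in sorted({w for d in proposals.values() for w in d}):
        if word in seed_owner:
            owner[word] = seed_owner[word]
            continue
        holders = [(proposals[c][word][0], class_pos[c], c) for c in classes if word in proposals.get(c, {})]
        holders.sort()
        owner[word] = holders[0][2]

    entries: dict[str, tuple[LabelWord, ...]] = {}
    for cls in classes:
        seed = seed_names.get(cls, cls)
        kept = [
            (rank, word, prov)
            for word, (rank, prov) in proposals[cls].items()
            if owner[word] == cls and word != seed
        ]
        kept.sort(key=lambda t: (t[0], t[1]))
        label_words = [LabelWord(seed, ("seed-name",))]
        label_words.extend(LabelWord(w, tuple(sorted(p))) for _, w, p in kept)
        entries[cls] = tuple(label_words)
    return Verbalizer(classes=tuple(classes), entries=entries, n=n)
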