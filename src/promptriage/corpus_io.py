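"""Reading, writing, validating and sampling document collections.

A corpus is a JSON-lines file, one record per line, UTF-8, with at least a
``text`` field and optionally ``id``, ``label`` and ``domain``.  Labeled
source-domain documents train the prompt model; target-domain documents are
unlabeled at prediction time (their true classes, when known, travel in a
separate mapping so the pipeline cannot see them).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "CorpusError",
    "Document",
    "CorpusPair",
    "tokenize",
    "read_corpus",
    "write_corpus",
    "read_truth",
    "write_truth",
    "few_shot_sample",
]


class CorpusError(ValueError):
    """Malformed corpus file or inconsistent document collection."""


def tokenize(text: str) -> tuple[str, ...]:
    """Whitespace tokenization of raw text, lowercased.

    Used for the deterministic stub pipeline; pretrained adapters apply
    their own subword tokenizer instead.
    """
    return tuple(text.lower().split())


@dataclass(frozen=True)
class Document:
    """One patient text with an optional class label and a domain tag."""

    id: str
    text: str
    label: str | None = None
    domain: str = "source"

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise CorpusError(f"document {self.id!r}: text is empty")

    @property
    def tokens(self) -> tuple[str, ...]:
        return tokenize(self.text)


@dataclass(frozen=True)
class CorpusPair:
    """A labeled source collection, an unlabeled target collection and the class set."""

    source: tuple[Document, ...]
    target: tuple[Document, ...]
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise CorpusError("a corpus pair needs at least 2 classes")
        for name, split in (("source", self.source), ("target", self.target)):
            ids = [d.id for d in split]
            if len(ids) != len(set(ids)):
                dupes = sorted({i for i in ids if ids.count(i) > 1})
                raise CorpusError(f"duplicate document ids in {name} split: {dupes}")
        for doc in self.source:
            if doc.label is not None and doc.label not in self.classes:
                raise CorpusError(
                    f"document {doc.id!r}: label {doc.label!r} not in class set"
                )


def read_corpus(
    path: str | Path,
    split: str = "source",
    classes: Sequence[str] | None = None,
) -> tuple[Document, ...]:
    """Read a JSONL corpus file, returning documents in file order.

    ``split`` sets the domain tag on every document.  When ``classes`` is
    given, any record whose label is not a member fails validation with the
    offending line number.  Records without an ``id`` get one assigned from
    their (1-based) line number.
    """
    path = Path(path)
    docs: list[Document] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                record = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"{path}:{lineno}: malformed JSON ({exc.msg})") from exc
            if not isinstance(record, dict) or "text" not in record:
                raise CorpusError(f"{path}:{lineno}: record has no 'text' field")
            label = record.get("label")
            if label is not None and classes is not None and label not in classes:
                raise CorpusError(
                    f"{path}:{lineno}: label {label!r} not in declared classes {list(classes)}"
                )
            try:
                doc = Document(
                    id=str(record.get("id", lineno)),
                    text=record["text"],
                    label=label,
                    domain=split,
                )
            except CorpusError as exc:
                raise CorpusError(f"{path}:{lineno}: {exc}") from exc
            docs.append(doc)
    return tuple(docs)


def write_corpus(docs: Iterable[Document], path: str | Path) -> None:
    """Write documents as JSONL; label omitted when absent."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for doc in docs:
            record: dict[str, str] = {"id": doc.id, "text": doc.text}
            if doc.label is not None:
                record["label"] = doc.label
            record["domain"] = doc.domain
            fh.write(json.dumps(record, ensure_ascii=False) + "\n")


def read_truth(path: str | Path) -> dict[str, str]:
    """Read a truth-label side file (JSONL with ``id`` and ``label``)."""
    truth: dict[str, str] = {}
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            record = json.loads(line)
            if "id" not in record or "label" not in record:
                raise CorpusError(f"{path}:{lineno}: truth record needs 'id' and 'label'")
            truth[str(record["id"])] = record["label"]
    return truth


def write_truth(truth: Mapping[str, str], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for doc_id, label in truth.items():
            fh.write(json.dumps({"id": doc_id, "label": label}, ensure_ascii=False) + "\n")


def few_shot_sample(
    corpus: Sequence[Document], shots: int, seed: int
) -> tuple[Document, ...]:
    """Sample exactly ``shots`` labeled documents per class, without replacement.

    Classes are visited in first-appearance order; within a class, documents
    are drawn by a NumPy generator seeded with ``seed``, so a fixed seed gives
    an identical sample.  A class with fewer than ``shots`` documents is an
    error naming the class.
    """
    if shots < 1:
        raise CorpusError("shots must be >= 1")
    by_class: dict[str, list[Document]] = {}
    for doc in corpus:
        if doc.label is None:
            raise CorpusError(f"document {doc.id!r} is unlabeled; cannot few-shot sample")
        by_class.setdefault(doc.label, []).append(doc)
    rng = np.random.default_rng(seed)
    sampled: list[Document] = []
    for cls, docs in by_class.items():
        if len(docs) < shots:
            raise CorpusError(
                f"class {cls!r} has only {len(docs)} documents; {shots} shots requested"
            )
        idx = rng.choice(len(docs), size=shots, replace=False)
        sampled.extend(docs[i] for i in sorted(idx))
    return tuple(sampled)
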