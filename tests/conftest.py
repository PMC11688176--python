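import math

import numpy as np
import pytest

from promptriage import (
    Document,
    GeneratorSpec,
    LabelWord,
    StubBackend,
    StubModelSpec,
    Verbalizer,
)


@pytest.fixture
def tiny_spec() -> StubModelSpec:
    """Five-word stub: class A words {a1, a2}, class B words {b1, b2}, filler {f1}."""
    return StubModelSpec(
        classes=("A", "B"),
        source_words={"A": ("a1",), "B": ("b1",)},
        target_words={"A": ("a2",), "B": ("b2",)},
        filler=("f1",),
        alpha=1.0,
    )


@pytest.fixture
def tiny_backend(tiny_spec) -> StubBackend:
    return StubBackend(tiny_spec)


@pytest.fixture
def tiny_verbalizer() -> Verbalizer:
    return Verbalizer(
        classes=("A", "B"),
        entries={
            "A": (LabelWord("a1", ("seed-name",)), LabelWord("a2", ("mlm",))),
            "B": (LabelWord("b1", ("seed-name",)), LabelWord("b2", ("mlm",))),
        },
        n=15,
    )


def make_random_stub_spec(rng: np.random.Generator) -> StubModelSpec:
    """Random small stub spec for fuzzing the MLM contract."""
    n_classes = int(rng.integers(2, 5))
    classes = tuple(f"c{k}" for k in range(n_classes))
    counter = iter(range(10_000))
    source = {c: tuple(f"{c}_a{next(counter)}" for _ in range(int(rng.integers(1, 5))))
              for c in classes}
    target = {c: tuple(f"{c}_b{next(counter)}" for _ in range(int(rng.integers(1, 5))))
              for c in classes}
    filler = tuple(f"f{next(counter)}" for _ in range(int(rng.integers(1, 6))))
    n_soft = int(rng.integers(0, 4))
    return StubModelSpec(
        classes=classes,
        source_words=source,
        target_words=target,
        filler=filler,
        alpha=float(rng.uniform(0, 2)),
        n_soft_slots=max(n_soft, 3),
        soft_weights=rng.normal(scale=0.5, size=(max(n_soft, 3), n_classes)),
    )


def brute_force_stub_distribution(spec: StubModelSpec, context_tokens, n_soft: int):
    """Independent closed-form stub distribution: pure-Python exp / normalize.

    Re-derives the affinity scores from set membership with no shared code
    with StubBackend.
    """
    vocab = []
    for c in spec.classes:
        vocab.extend(spec.source_words[c])
    for c in spec.classes:
        vocab.extend(spec.target_words[c])
    vocab.extend(spec.filler)
    membership = {}
    for c in spec.classes:
        for w in spec.source_words[c]:
            membership[w] = c
        for w in spec.target_words[c]:
            membership[w] = c
    counts = {c: sum(1 for t in context_tokens if membership.get(t) == c)
              for c in spec.classes}
    soft = {c: sum(spec.soft_weights[j][i] for j in range(n_soft))
            for i, c in enumerate(spec.classes)}
    raw = []
    for w in vocab:
        c = membership.get(w)
        raw.append(math.exp(spec.alpha * counts[c] + soft[c]) if c else math.exp(0.0))
    z = sum(raw)
    return vocab, [x / z for x in raw]


def make_docs(texts_and_labels, domain="source"):
    return tuple(
        Document(id=f"d{i}", text=text, label=label, domain=domain)
        for i, (text, label) in enumerate(texts_and_labels)
    )
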