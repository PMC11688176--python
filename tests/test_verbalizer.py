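import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from promptriage import (
    Document,
    StubBackend,
    StubModelSpec,
    VerbalizerError,
    WordVectorStore,
    build_verbalizer,
    context_score,
    expand_by_context,
    expand_by_mlm,
    expand_by_similarity,
    get_template,
    top_n,
)
from conftest import make_docs


def selection_sort_top_n(scores, n, order):
    """Oracle: repeatedly pick the best remaining word by linear scan."""
    remaining = dict(scores)
    out = []
    while remaining and len(out) < n:
        best = None
        for word, score in remaining.items():
            if best is None:
                best = word
                continue
            better = score > remaining[best] if order == "descending" else score < remaining[best]
            if better or (score == remaining[best] and word < best):
                best = word
        out.append(best)
        del remaining[best]
    return out


class TestTopN:
    def test_simple_descending(self):
        assert top_n({"a": 0.5, "b": 0.3, "c": 0.2}, 2) == ["a", "b"]

    def test_lexicographic_tie_rule(self):
        assert top_n({"b": 0.4, "a": 0.4}, 1) == ["a"]

    def test_fewer_candidates_than_n(self):
        assert top_n({"a": 1.0}, 5) == ["a"]

    def test_empty_mapping_is_empty_list(self):
        assert top_n({}, 3) == []

    def test_invalid_n(self):
        with pytest.raises(VerbalizerError):
            top_n({"a": 1.0}, 0)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(seed=st.integers(0, 10_000), order=st.sampled_from(["descending", "ascending"]))
    def test_matches_selection_oracle(self, seed, order):
        rng = np.random.default_rng(seed)
        words = [f"w{i}" for i in range(30)]
        # quantized scores force plenty of ties
        scores = {w: float(rng.integers(0, 5)) / 4 for w in words}
        assert top_n(scores, 15, order) == selection_sort_top_n(scores, 15, order)


class TestExpandByMlm:
    def test_uniform_backend_ties_resolve_lexicographically(self, tiny_spec):
        from dataclasses import replace

        backend = StubBackend(replace(tiny_spec, alpha=0.0))
        shots = make_docs([("a1 b1", "A")])
        words = expand_by_mlm("A", shots, get_template("1"), backend, n=3)
        # all five words tie at 1/5; "a1" (the seed name here is "A", not removed)
        assert words == ["a1", "a2", "b1"]

    def test_average_over_two_shots_matches_hand_average(self, tiny_backend):
        template = get_template("1")
        shots = make_docs([("a1 a1", "A"), ("b1 f1", "A")])
        # hand-averaged distribution of the two closed-form stub distributions
        z1 = 2 * math.exp(2) + 3          # context a1 a1 -> A count 2
        z2 = 2 * math.exp(1) + 3          # context b1 f1 -> B count 1
        mean = {
            "a2": (math.exp(2) / z1 + 1 / z2) / 2,
            "b1": (1 / z1 + math.exp(1) / z2) / 2,
            "b2": (1 / z1 + math.exp(1) / z2) / 2,
            "f1": (1 / z1 + 1 / z2) / 2,
        }
        words = expand_by_mlm("A", shots, template, tiny_backend, n=4, exclude={"a1"})
        expected = selection_sort_top_n(mean, 4, "descending")
        assert words == expected

    def test_n_larger_than_vocabulary(self, tiny_backend):
        words = expand_by_mlm("A", make_docs([("a1", "A")]), get_template("1"),
                              tiny_backend, n=99)
        assert set(words) == {"a1", "a2", "b1", "b2", "f1"} - {"A"}

    def test_empty_shots_error(self, tiny_backend):
        with pytest.raises(VerbalizerError):
            expand_by_mlm("A", [], get_template("1"), tiny_backend, n=3)


class TestExpandBySimilarity:
    def test_hand_computed_cosines(self):
        store = WordVectorStore({
            "cls": np.array([1.0, 0.0]),
            "same": np.array([1.0, 0.0]),
            "mid": np.array([0.6, 0.8]),
            "orth": np.array([0.0, 1.0]),
        })
        words = expand_by_similarity("cls", store, ["same", "mid", "orth"], n=3)
        assert words == ["same", "mid", "orth"]

    def test_absent_candidates_skipped(self):
        store = WordVectorStore({"cls": np.array([1.0, 0.0]), "w": np.array([1.0, 1.0])})
        assert expand_by_similarity("cls", store, ["w", "ghost"], n=5) == ["w"]

    def test_missing_class_name_errors(self):
        store = WordVectorStore({"w": np.array([1.0])})
        with pytest.raises(VerbalizerError, match="'cls'"):
            expand_by_similarity("cls", store, ["w"], n=1)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(seed=st.integers(0, 10_000), scale=st.floats(0.01, 100))
    def test_invariant_to_positive_rescaling(self, seed, scale):
        rng = np.random.default_rng(seed)
        vecs = {f"w{i}": rng.normal(size=4) for i in range(8)}
        vecs["cls"] = rng.normal(size=4)
        base = expand_by_similarity("cls", WordVectorStore(vecs), list(vecs), n=5)
        scaled = {w: (v * scale if w != "cls" else v) for w, v in vecs.items()}
        assert expand_by_similarity("cls", WordVectorStore(scaled), list(vecs), n=5) == base


class TestVecFormat:
    def test_roundtrip(self, tmp_path):
        store = WordVectorStore({"a": np.array([1.0, 2.0]), "b": np.array([-1.0, 0.5])})
        path = tmp_path / "v.vec"
        store.save(path)
        back = WordVectorStore.load(path)
        assert back.dim == 2
        np.testing.assert_allclose(back.vector("b"), [-1.0, 0.5])

    def test_zero_vector_rejected(self):
        with pytest.raises(VerbalizerError, match="zero vector"):
            WordVectorStore({"a": np.array([0.0, 0.0])})


class TestExpandByContext:
    def test_uniform_stub_scores_log_vocab(self, tiny_spec):
        from dataclasses import replace

        backend = StubBackend(replace(tiny_spec, alpha=0.0))
        shots = make_docs([("a1 b1 f1 a2", "A")])
        score = context_score("b2", shots, get_template("1"), backend)
        assert score == pytest.approx(math.log(5), abs=1e-12)

    def test_dominant_class_candidate_scores_lower(self, tiny_backend):
        """A-class shots: an A-word candidate supports the context, a B-word dilutes it."""
        shots = make_docs([("a1 a2 a1", "A"), ("a2 a1 f1", "A")])
        template = get_template("1")
        score_a = context_score("a2", shots, template, tiny_backend)
        score_b = context_score("b1", shots, template, tiny_backend)
        assert score_a < score_b
        ranked = expand_by_context(["b1", "a2"], shots, template, tiny_backend, n=2)
        assert ranked == ["a2", "b1"]

    def test_no_maskable_context_errors(self, tiny_backend):
        # single OOV document token: after substitution nothing remains maskable
        shots = make_docs([("zzz", "A")])
        with pytest.raises(VerbalizerError, match="maskable"):
            context_score("a1", shots, get_template("1"), tiny_backend)

    def test_position_limit_counts_from_the_front(self, tiny_backend):
        shots = make_docs([("a1 b1 a2", "A")])
        template = get_template("1")
        limited = context_score("f1", shots, template, tiny_backend, max_positions=1)
        # only position 1 (token a1) is scored
        inst = shots[0]
        from promptriage import wrap

        sub = wrap(inst, template).substitute_mask("f1")
        assert limited == pytest.approx(tiny_backend.token_cross_entropy(sub, 1))


class TestBuildVerbalizer:
    def test_disjoint_lists_union(self):
        v = build_verbalizer(
            {"A": {"mlm": ["x1", "x2"], "similarity": ["x3", "x4"], "context": ["x5", "x6"]},
             "B": {"mlm": [], "similarity": [], "context": []}},
            classes=["A", "B"], n=15)
        assert len(v.words("A")) == 7  # six expansions + seed
        assert v.words("A")[0] == "A"
        assert v.words("B") == ("B",)

    def test_identical_lists_collapse(self):
        lists = {"mlm": ["w1", "w2"], "similarity": ["w1", "w2"], "context": ["w1", "w2"]}
        v = build_verbalizer({"A": lists, "B": {}}, classes=["A", "B"], n=2)
        assert set(v.words("A")) == {"A", "w1", "w2"}
        (lw,) = [w for w in v.entries["A"] if w.word == "w1"]
        assert set(lw.provenance) == {"mlm", "similarity", "context"}

    def test_cross_class_conflict_goes_to_better_rank(self):
        # "shared" is rank 1 under A but rank 0 under B -> B wins
        v = build_verbalizer(
            {"A": {"mlm": ["ax", "shared"]}, "B": {"mlm": ["shared", "bx"]}},
            classes=["A", "B"], n=5)
        assert "shared" in v.words("B")
        assert "shared" not in v.words("A")

    def test_cross_class_tie_goes_to_first_class_in_order(self):
        v = build_verbalizer(
            {"B": {"mlm": ["shared"]}, "A": {"mlm": ["shared"]}},
            classes=["B", "A"], n=5)
        assert "shared" in v.words("B")

    def test_oversized_strategy_list_rejected(self):
        with pytest.raises(VerbalizerError, match="> N"):
            build_verbalizer({"A": {"mlm": ["a", "b", "c"]}, "B": {}},
                             classes=["A", "B"], n=2)

    def test_json_roundtrip(self):
        v = build_verbalizer({"A": {"mlm": ["x"]}, "B": {"context": ["y"]}},
                             classes=["A", "B"], n=15)
        from promptriage import Verbalizer

        back = Verbalizer.from_json(v.to_json())
        assert back == v
        assert back.content_hash() == v.content_hash()
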