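import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from promptriage import (
    BackendError,
    Document,
    StubBackend,
    StubModelSpec,
    get_template,
    wrap,
)
from conftest import brute_force_stub_distribution, make_random_stub_spec


def instance_for(backend_spec, text, template="1"):
    return wrap(Document(id="d", text=text), get_template(template))


class TestMaskFillDistribution:
    def test_alpha_zero_is_uniform(self, tiny_spec):
        backend = StubBackend(
            StubModelSpec(**{**tiny_spec.__dict__, "alpha": 0.0, "soft_weights": None})
        )
        dist = backend.mask_fill_distribution(instance_for(tiny_spec, "a1 a2"))
        assert np.all(dist.probabilities == dist.probabilities[0])
        np.testing.assert_allclose(dist.probabilities, 1 / 5, atol=1e-15)

    def test_two_class_a_tokens_hand_normalized(self, tiny_backend):
        """Context a1 a2: class-A words get e^2, the rest e^0; normalizer by hand."""
        dist = tiny_backend.mask_fill_distribution(instance_for(None, "a1 a2"))
        z = 2 * math.exp(2) + 3
        expected = {"a1": math.exp(2) / z, "a2": math.exp(2) / z,
                    "b1": 1 / z, "b2": 1 / z, "f1": 1 / z}
        for word, p in expected.items():
            assert dist.p(word) == pytest.approx(p, abs=1e-12)

    def test_multiple_mask_slots_error(self, tiny_backend):
        two_masks = instance_for(None, "a1 a2").with_mask_at(1)  # doc token also masked
        assert two_masks.tokens.count("[MASK]") == 2
        with pytest.raises(BackendError, match="exactly one mask"):
            tiny_backend.mask_fill_distribution(two_masks)

    def test_no_mask_slot_error(self, tiny_backend):
        inst = instance_for(None, "a1").substitute_mask("b1")
        with pytest.raises(BackendError, match="exactly one mask"):
            tiny_backend.mask_fill_distribution(inst)

    def test_matches_brute_force_closed_form(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            spec = make_random_stub_spec(rng)
            backend = StubBackend(spec)
            pool = backend.vocabulary.words
            text = " ".join(rng.choice(pool, size=6))
            inst = wrap(Document(id="d", text=text), get_template("soft"))
            dist = backend.mask_fill_distribution(inst)
            vocab, expected = brute_force_stub_distribution(
                spec, text.split(), n_soft=len(inst.soft_indices))
            assert vocab == list(backend.vocabulary.words)
            np.testing.assert_allclose(dist.probabilities, expected, atol=1e-12)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(seed=st.integers(0, 10_000), n_ctx=st.integers(0, 10))
def test_distribution_sums_to_one(seed, n_ctx):
    rng = np.random.default_rng(seed)
    spec = make_random_stub_spec(rng)
    backend = StubBackend(spec)
    tokens = list(rng.choice(backend.vocabulary.words, size=n_ctx)) or ["x_oov"]
    inst = wrap(Document(id="d", text=" ".join(tokens)), get_template("soft"))
    p = backend.mask_fill_distribution(inst).probabilities
    assert abs(p.sum() - 1) < 1e-9
    assert np.all(p >= 0)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_class_mass_monotone_in_indicative_count(seed):
    """Adding a class-c indicative context token never lowers class-c word mass."""
    rng = np.random.default_rng(seed)
    spec = make_random_stub_spec(rng)
    backend = StubBackend(spec)
    cls = spec.classes[int(rng.integers(len(spec.classes)))]
    cls_words = set(spec.source_words[cls]) | set(spec.target_words[cls])
    base_tokens = list(rng.choice(backend.vocabulary.words, size=4))
    extra = spec.source_words[cls][0]

    def class_mass(tokens):
        inst = wrap(Document(id="d", text=" ".join(tokens)), get_template("1"))
        dist = backend.mask_fill_distribution(inst)
        return sum(dist.p(w) for w in cls_words)

    assert class_mass(base_tokens + [extra]) >= class_mass(base_tokens) - 1e-12


class TestTokenCrossEntropy:
    def test_uniform_stub_gives_log_vocab_size(self, tiny_spec):
        backend = StubBackend(
            StubModelSpec(**{**tiny_spec.__dict__, "alpha": 0.0, "soft_weights": None})
        )
        inst = instance_for(None, "a1 b1").substitute_mask("f1")
        assert backend.token_cross_entropy(inst, 1) == pytest.approx(math.log(5))

    def test_dominant_class_beats_uniform_and_matches_distribution(self, tiny_backend):
        inst = instance_for(None, "a1 a2 a1").substitute_mask("f1")
        ce = tiny_backend.token_cross_entropy(inst, 1)  # true token a1, A-heavy context
        assert ce < math.log(5)
        dist = tiny_backend.mask_fill_distribution(inst.with_mask_at(1))
        assert ce == pytest.approx(-math.log(dist.p("a1")), abs=1e-12)

    def test_special_token_position_error(self, tiny_backend):
        inst = instance_for(None, "a1").substitute_mask("b1")
        with pytest.raises(BackendError, match="special"):
            tiny_backend.token_cross_entropy(inst, 0)  # BOS marker

    def test_out_of_range_position_error(self, tiny_backend):
        inst = instance_for(None, "a1").substitute_mask("b1")
        with pytest.raises(BackendError, match="out of range"):
            tiny_backend.token_cross_entropy(inst, 99)

    def test_existing_mask_slot_error(self, tiny_backend):
        inst = instance_for(None, "a1")  # still has its mask slot
        with pytest.raises(BackendError, match="mask"):
            tiny_backend.token_cross_entropy(inst, 1)


class TestTrainableParameters:
    def test_zero_learning_rate_is_identity(self, tiny_backend):
        before = tiny_backend.trainable_parameters()["soft_weights"]
        grads = {"soft_weights": np.ones_like(before)}
        tiny_backend.apply_gradient_step(grads, learning_rate=0.0)
        after = tiny_backend.trainable_parameters()["soft_weights"]
        assert np.array_equal(before, after)

    def test_shape_mismatch_error(self, tiny_backend):
        with pytest.raises(BackendError, match="shape"):
            tiny_backend.apply_gradient_step({"soft_weights": np.ones((1, 7))}, 0.1)

    def test_identical_steps_are_deterministic(self, tiny_spec):
        grads = {"soft_weights": np.full((3, 2), 0.25)}
        results = []
        for _ in range(2):
            backend = StubBackend(tiny_spec)
            backend.apply_gradient_step(grads, 0.1)
            backend.apply_gradient_step(grads, 0.1)
            results.append(backend.trainable_parameters()["soft_weights"])
        assert np.array_equal(results[0], results[1])

    def test_backprop_matches_central_finite_difference(self):
        """Analytic soft-weight gradient vs a finite-difference oracle, 1e-4 relative."""
        rng = np.random.default_rng(42)
        for _ in range(5):
            spec = make_random_stub_spec(rng)
            backend = StubBackend(spec)
            text = " ".join(rng.choice(backend.vocabulary.words, size=5))
            inst = wrap(Document(id="d", text=text), get_template("soft"))
            dldp = rng.normal(size=len(backend.vocabulary))

            def f(weights):
                b = StubBackend(
                    StubModelSpec(**{**spec.__dict__, "soft_weights": weights}))
                return float(dldp @ b.mask_fill_distribution(inst).probabilities)

            analytic = backend.backprop_mask(inst, dldp)["soft_weights"]
            w0 = np.array(spec.soft_weights)
            eps = 1e-6
            for j in range(w0.shape[0]):
                for c in range(w0.shape[1]):
                    wp, wm = w0.copy(), w0.copy()
                    wp[j, c] += eps
                    wm[j, c] -= eps
                    fd = (f(wp) - f(wm)) / (2 * eps)
                    assert analytic[j, c] == pytest.approx(fd, rel=1e-4, abs=1e-7)
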