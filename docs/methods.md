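# Methods

## Problem setting

A source domain supplies `n_s` labeled documents `(x_i, y_i)` with
`y_i ∈ {1..c}`; a target domain supplies `n_t` unlabeled documents drawn from
a shifted distribution over the same class set. In the motivating
application the domains are sibling clinical sub-disciplines: the same
departments, drifting vocabulary. The classifier is trained on a few shots
per class from the source domain only and evaluated on the target domain.

## Model and procedure

**Templates.** A template is an ordered sequence of literal tokens, one input
slot, exactly one mask slot and, for the soft template, `k` trainable soft
slots (default `k = 3`). Four hard templates ship as built-ins (ids 0–3)
together with the soft template `x, [soft][soft][soft][MASK]`. Wrapping
prepends a begin-of-sequence marker and substitutes the document tokens at
the input slot; when the result exceeds `max_length` (default 128 tokens),
document tokens are truncated from their right end — template tokens, the
mask and soft slots never are, so the cloze structure survives truncation.
Templates are opaque token strings: nothing in the pipeline is
language-specific, and the stub path tokenizes by lowercased whitespace
splitting (pretrained adapters use their own tokenizers).

**Verbalizer.** Per class: the seed name plus the top `N = 15` words from
each of three strategies — shot-averaged mask-distribution ranking,
cosine similarity of static word vectors to the class name, and context fit
(substitute the candidate at the mask, mask each surrounding non-special,
non-soft token left to right, average the cross-entropies; ascending rank).
The candidate pool is the backend vocabulary minus special markers,
stop-words (configurable list) and class seed names, intersected with the
vector store for the similarity strategy. Aggregation across shots
(entrywise mean) and positions (arithmetic mean) uses plain means for
symmetry. Ties in every ranking break lexicographically. A word proposed
for two classes would make the mean-score classifier ill-posed, so it is
kept only under the class where its best strategy rank is better (ties to
the earlier class in declared order); the per-class set size is therefore
bounded by `3N + 1`.

**Scoring and training.** Class score `g_c` is the unweighted mean of the
class's label-word probabilities at the mask; prediction is `argmax g_c`
with ties broken by class order. The training loss is the cross-entropy of
the normalized posterior `g_y / Σ_c g_c` — the standard verbalizer-training
objective, reducing to ordinary cross-entropy when each class has one label
word. The optimizer is plain full-precision gradient descent with per-epoch
reshuffling from a seeded generator, making stub runs bit-reproducible;
adapter backends may substitute an adaptive optimizer, recorded in the run
manifest. The verbalizer is built before training and frozen during it.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| shots | 20 / class | labeled source examples used per class |
| N | 15 | words contributed per expansion strategy |
| learning rate | 3e-5 | gradient-descent step size |
| batch size | 32 | instances per gradient step |
| epochs | 5 | passes over the shots |
| dropout | 0.5 | adapter backends only; the stub has no dropout surface |
| seeds | 3 | independent runs averaged into the reported accuracy |
| max length | 128 | token budget of a wrapped instance |
| k (soft slots) | 3 | trainable template slots |
| context positions | 4 / shot | masked positions scored per candidate by the context strategy, left to right (caps the dominant cost of verbalizer construction) |

## The stub masked LM

The stub's vocabulary is partitioned into per-class source-flavored sets
`A_c`, target-flavored sets `B_c` and filler `F`. For context `ctx`, a word
of class `c` has logit `alpha · #{t ∈ ctx : t ∈ A_c ∪ B_c} + Σ_j u[j, c]`
(soft slots present only), filler words logit 0; the mask distribution is
the softmax, computed in log space. Soft tokens are per-class additive
affinities rather than embeddings: the training loss is then convex in
them, so recovery of planted class priors is a theorem the tests can check,
not a hope. `alpha = 0` gives the exactly uniform distribution; class
probability mass is provably monotone in the indicative-token count. The
per-position cross-entropy is computed by masking the position internally
and reading the same distribution, so its consistency with the mask-fill
query holds by construction. A context token the stub cannot represent
(e.g. a template literal outside the synthetic lexicons) carries no class
evidence, and the context strategy skips positions whose true token is out
of vocabulary — a pretrained backend has a full vocabulary and skips
nothing.

## The synthetic generator

Documents are token-level mixtures: length uniform on [5, 15], each token
class-indicative with probability `pi` (default 0.3), otherwise filler.
Source indicative tokens come from `A_c`; target indicative tokens come from
`B_c` with probability `delta` (default 0.5) and `A_c` otherwise. The default
task has four department-named classes, 30-word lexicons per flavor (the
class name is a member of its source lexicon, so the seed label word is
scorable), 100 filler words, and 1,000 available documents per class per
domain at full scale. Target labels travel in a side mapping, target ids are
opaque and shuffled, so nothing in the prediction path can see them. The
token-level law was chosen over a topic-model law because its Bayes
classifier is closed-form: with disjoint lexicons, any indicative token
identifies the class, so the oracle ceiling is
`1 − (1 − 1/c) · P(document is all filler)` — estimated by Monte Carlo in
`bayes_accuracy`, with ties broken by class order.

What the generator does *not* emulate: correlated tokens, polysemy,
class-overlapping vocabulary, realistic (or Chinese) clinical language, and
label noise. Passing tests therefore demonstrate the correctness of the
machinery — wrapping, expansion, scoring, convex training, the harness — not
clinical-grade triage accuracy; accuracies on these corpora sit near the
Bayes ceiling by design and say nothing about performance on real inquiry
text with a pretrained backend.

## Numerical choices and degenerate inputs

Probabilities are formed in log space (`logits − logsumexp`) and exposed as
plain probabilities summing to 1 within 1e-9. All argmax/top-N ties break
deterministically (lexicographic for words, declared order for classes).
Zero vectors are rejected by the word-vector store since they have no
cosine direction; candidates missing from the store are skipped, a class
name missing from it is an error. A verbalizer word missing from the
backend vocabulary is dropped with a warning; a class losing all words is
an error naming the class. Learning rate 0 freezes training exactly (the
parameter update is skipped, leaving weights bit-identical). Non-finite
losses abort with diagnostics rather than propagate.

## Scale of the shipped experiments

The test suite and the acceptance script run the full pipeline at 50–100
documents per class per domain with 2–4 classes, 2–20 shots, and
3,000-document Monte-Carlo oracle estimates — sizes chosen so the whole
suite re-runs in a couple of minutes while every accuracy estimate carries
a standard error below ~2 percentage points. The generator accepts
arbitrary sizes; the defaults mirror the 1,000-per-domain scale of the
motivating setting.

## Known limitations

- The adapter backend delegates subword tokenization to the checkpoint;
  multi-token label words cannot be scored at a single mask slot and are
  dropped (multi-mask scoring is out of scope).
- Whether prompt-tuning should update all backbone weights or only prompt
  embeddings is checkpoint-dependent; both are exposed (`tune="full"` /
  `"prompt"`, default full) and neither is exercised by the offline test
  suite.
- Accuracy is the primary metric throughout; macro-F1 is available as an
  auxiliary function but not part of the harness tables.
- Posterior scores are normalized means, not calibrated probabilities.
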