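"""Expand the per-class label-word sets by the three strategies and union them.

Each class starts from its seed name and gains up to N = 15 words per
strategy: masked-LM prediction over the shots, cosine similarity of static
word vectors to the class name, and context fit (mean masked cross-entropy
around the substituted candidate).  Provenance records which strategies
proposed each word.
"""

from collections import Counter

from promptriage import (
    GeneratorSpec,
    PipelineConfig,
    StubBackend,
    build_run_verbalizer,
    few_shot_sample,
    generate_corpus,
    get_template,
    synthetic_vectors,
)

spec = GeneratorSpec.default(classes=("cardio", "derm"), pi=0.5, delta=0.0, seed=3)
pair, truth, stub_spec = generate_corpus(spec, n_per_class=50)
backend = StubBackend(stub_spec)
shots = few_shot_sample(pair.source, shots=10, seed=0)
cfg = PipelineConfig()

verbalizer = build_run_verbalizer(pair.classes, shots, get_template(cfg.template_id),
                                  backend, cfg, vectors=synthetic_vectors(spec, seed=3))
for cls in verbalizer.classes:
    entries = verbalizer.entries[cls]
    counts = Counter(s for lw in entries for s in lw.provenance)
    print(f"{cls}: {len(entries)} label words "
          f"(mlm {counts['mlm']}, similarity {counts['similarity']}, "
          f"context {counts['context']}, seed {counts['seed-name']})")
    print("  first words:", ", ".join(lw.word for lw in entries[:6]))
print("per-class sets are disjoint; size is bounded by 3N + 1 = 46")
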