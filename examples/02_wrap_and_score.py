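"""Wrap a document into a cloze template and inspect the mask distribution.

Shows the token sequence a template produces and how the stub masked LM
concentrates mask-slot probability on class-indicative words as the context
contains more of them.
"""

from promptriage import Document, GeneratorSpec, StubBackend, generate_corpus, get_template, wrap

spec = GeneratorSpec.default(classes=("cardio", "derm"), seed=7)
_, _, stub_spec = generate_corpus(spec, n_per_class=1)
backend = StubBackend(stub_spec)

doc = Document(id="demo", text="cardio_src_3 cardio_src_8 filler_2")
for template_id in ("1", "soft"):
    inst = wrap(doc, get_template(template_id), max_length=32)
    print(f"template {template_id!r}: {' '.join(inst.tokens)}")
    print(f"  mask index {inst.mask_index}, soft slots {inst.soft_indices}")
    dist = backend.mask_fill_distribution(inst)
    mass = {
        "cardio words": sum(dist.p(w) for w in stub_spec.source_words["cardio"]),
        "derm words": sum(dist.p(w) for w in stub_spec.source_words["derm"]),
    }
    for name, m in mass.items():
        print(f"  mask-probability mass on {name}: {m:.3f}")
print("two cardio-flavored context tokens pull the mask mass toward cardio words")
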