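"""Score every word of one sentence by leave-one-out embedding dissimilarity.

Each word's informativeness is ln(1 - cos(full sentence, sentence without
that word)): values nearer 0 mean removing the word moves the sentence
meaning more, i.e. the word is more informative. The deterministic reference
embedder keeps this example fully offline; swap the EmbedderSpec name for a
pretrained multilingual sentence encoder to score real corpora.
"""

from wordinfo import EmbedderSpec, Sentence, score_sentence

TEXT = ("even though most of his inventions were not actually built in his "
        "lifetime, many of today’s modern machines can be traced back to "
        "some of his original designs")

spec = EmbedderSpec(name="reference", dim=64, seed=7)
sentence = Sentence.from_text(TEXT, id="example", language="en")
records = score_sentence(sentence, spec)

print(f"{len(records)} word tokens  ({spec.provenance()})")
ranked = sorted(records, key=lambda r: r.informativeness, reverse=True)
print("\nmost informative (scores nearest 0):")
for r in ranked[:3]:
    print(f"  {r.word:12s} cosine={r.cosine_full_vs_partial:.3f} "
          f"dissimilarity={r.raw_dissimilarity:.3f} score={r.informativeness:+.3f}")
print("least informative (most negative scores):")
for r in ranked[-3:]:
    print(f"  {r.word:12s} cosine={r.cosine_full_vs_partial:.3f} "
          f"dissimilarity={r.raw_dissimilarity:.3f} score={r.informativeness:+.3f}")
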