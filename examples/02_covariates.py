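"""Compute the standard psycholinguistic covariates for words in context.

Zipf frequency is log10 of occurrences per billion corpus tokens (6 = one
in a thousand, 3 = one in a million); predictability is the cosine between
a word's static vector and the mean vector of the words before it.
"""

import numpy as np

from wordinfo import FrequencyTable, Sentence, StaticLexicon, zipf
from wordinfo.measures import predictability_for_sentence

table = FrequencyTable("en", {"the": 50_000, "storm": 120, "flooded": 8,
                              "village": 95}, total_tokens=1_000_000)
for word in ("the", "storm", "flooded", "unseen-word"):
    print(f"zipf({word!r:14s}) = {zipf(word, table):.3f}")

rng = np.random.default_rng(0)
lex = StaticLexicon(dim=8)
for w in ("the", "storm", "flooded", "village"):
    v = rng.normal(size=8)
    lex.add(w, v / np.linalg.norm(v))

sentence = Sentence.from_text("the storm flooded the village", id="s0", language="en")
print("\npredictability from preceding context (first word has none):")
for rec in predictability_for_sentence(sentence, lex):
    shown = "missing" if rec.predictability is None else f"{rec.predictability:+.3f}"
    print(f"  {rec.word:10s} n_context={rec.n_context_words} -> {shown}")
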