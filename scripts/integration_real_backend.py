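"""Optional integration workflow: score with the pinned pretrained encoder.

Requires the ``sentence-transformers`` extra and a downloaded copy of the
pinned multilingual model ``distiluse-base-multilingual-cased-v2``; it is
therefore NOT part of the default test suite, which runs fully offline on
the reference embedder. Run it on a machine with the model available:

    python scripts/integration_real_backend.py

It scores the worked example sentence with the pinned backend and compares
every word's log informativeness against the reference values established
for that sentence under the same backend (|delta| <= 0.05 per word; encoder
revision drift can move third decimals). With real interest-area exports and
frequency tables in hand, the same EmbedderSpec drops into
``wordinfo.cli score`` / ``build-table`` to reproduce the full validation
table construction; by-language correlation ranges and mixed-model
coefficients additionally require the multilingual eye-movement corpus
distribution itself.
"""

import sys

from wordinfo import EmbedderSpec, Sentence, score_sentence
from wordinfo.errors import ConfigurationError

BACKEND = "distiluse-base-multilingual-cased-v2"

EXAMPLE_TEXT = ("even though most of his inventions were not actually built in his "
                "lifetime, many of today’s modern machines can be traced back "
                "to some of his original designs")

# Reference per-word log informativeness for the example sentence under the
# pinned backend (word order = token order).
REFERENCE_SCORES = [
    -4.563, -5.150, -4.346, -6.698, -5.329, -3.542, -5.801, -3.745, -4.864,
    -4.833, -6.276, -6.229, -3.692, -5.042, -8.262, -5.041, -4.420, -2.976,
    -4.025, -7.511, -4.747, -4.299, -8.017, -5.489, -7.260, -6.748, -4.139,
    -4.356,
]

TOLERANCE = 0.05


def main() -> int:
    spec = EmbedderSpec(name=BACKEND, dim=512)
    sentence = Sentence.from_text(EXAMPLE_TEXT, id="example", language="en")
    try:
        records = score_sentence(sentence, spec)
    except ConfigurationError as exc:
        print(f"skipped: {exc}", file=sys.stderr)
        return 2
    assert len(records) == len(REFERENCE_SCORES)
    worst = 0.0
    for rec, ref in zip(records, REFERENCE_SCORES):
        delta = abs(rec.informativeness - ref)
        worst = max(worst, delta)
        status = "ok" if delta <= TOLERANCE else "DRIFT"
        print(f"{rec.word:12s} got {rec.informativeness:+7.3f} "
              f"ref {ref:+7.3f} |d|={delta:.3f} {status}")
    print(f"max |delta| = {worst:.3f} (tolerance {TOLERANCE})")
    return 0 if worst <= TOLERANCE else 1


if __name__ == "__main__":
    raise SystemExit(main())
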