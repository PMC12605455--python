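"""Plain-text readers and writers for the pipeline's file formats."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .embedding import EmbedderSpec
from .errors import ParseError
from .measures import InformativenessRecord, PredictabilityRecord
from .text import Sentence


def read_sentences(path: str | Path, language: str = "und") -> list[Sentence]:
    """Read a sentence-per-line UTF-8 file.

    Each line is either the raw sentence text, or ``id<TAB>language<TAB>text``.
    Blank lines are skipped; ids default to the 0-based line position.
    """
    sentences = []
    for i, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines()):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) >= 3:
            sid, lang, text = parts[0], parts[1], "\t".join(parts[2:])
        elif len(parts) == 1:
            sid, lang, text = str(i), language, parts[0]
        else:
            raise ParseError(f"{path}:{i + 1}: expected 1 or >=3 tab-separated fields")
        sentences.append(Sentence.from_text(text, id=sid, language=lang))
    return sentences


def write_tokens(sentences: Iterable[Sentence], path: str | Path) -> None:
    """Dump token tables: one row per word token with punctuation bookkeeping."""
    rows = [
        {"sentence_id": s.id, "token_index": t.index, "surface": t.surface,
         "core": t.core, "leading_punct": t.leading_punct,
         "trailing_punct": t.trailing_punct, "core_length": t.core_length}
        for s in sentences for t in s.tokens
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def scores_to_frame(records: Sequence[InformativenessRecord]) -> pd.DataFrame:
    return pd.DataFrame([
        {"sentence_id": r.sentence_id, "token_index": r.token_index,
         "word": r.word, "cosine": r.cosine_full_vs_partial,
         "dissimilarity": r.raw_dissimilarity,
         "informativeness": r.informativeness,
         "outlier": r.outlier, "clamped": r.clamped}
        for r in records
    ])


def write_scores(records: Sequence[InformativenessRecord], path: str | Path,
                 spec: EmbedderSpec) -> None:
    """Write a score TSV with a header comment recording backend provenance."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# {spec.provenance()}\n")
        scores_to_frame(records).to_csv(fh, sep="\t", index=False)


def read_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def predictability_to_frame(records: Sequence[PredictabilityRecord]) -> pd.DataFrame:
    return pd.DataFrame([
        {"sentence_id": r.sentence_id, "token_index": r.token_index,
         "word": r.word, "predictability": r.predictability,
         "n_context_words": r.n_context_words, "oov": r.oov}
        for r in records
    ])
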