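"""Word informativeness scores and the predictability covariate.

For word *i* in sentence *j*:

    d(i, j)              = 1 - cosine(embed(sentence j), embed(sentence j without word i))
    informativeness(i,j) = ln d(i, j)

Omitting most words barely moves a sentence embedding, so the raw
dissimilarities pile up near 0 with a long right tail; the natural log
spreads them into a usable scale. Extremely negative values (below -10)
reflect numerically degenerate estimates rather than genuinely uninformative
words and are flagged for exclusion before any downstream analysis.

Predictability is a separate covariate: the cosine between a word's static
vector and the mean static vector of the words preceding it in the sentence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .embedding import EmbedderSpec, EmbeddingVector, cosine, embed
from .errors import DegenerateSentenceError
from .lexicon import StaticLexicon
from .text import Sentence, remove_word

#: Default exclusion threshold on the log scale (strict: score < threshold).
OUTLIER_THRESHOLD = -10.0

#: Floor applied to non-positive dissimilarities before the log; ln(1e-12)
#: is ~ -27.6, far below the outlier threshold, so clamped records are always
#: excluded downstream.
CLAMP_FLOOR = 1e-12


@dataclass(frozen=True)
class InformativenessRecord:
    """Informativeness of one word token within one sentence."""

    sentence_id: str
    token_index: int
    word: str
    cosine_full_vs_partial: float
    raw_dissimilarity: float
    informativeness: float
    outlier: bool = False
    clamped: bool = False


@dataclass(frozen=True)
class PredictabilityRecord:
    """Embedding-based predictability of one word token; missing is data, not error."""

    sentence_id: str
    token_index: int
    word: str
    predictability: float | None
    n_context_words: int
    oov: bool


def raw_dissimilarity(cos_sim: float) -> float:
    """1 minus cosine: how much the sentence meaning moves when the word is dropped."""
    if not -1.0 <= cos_sim <= 1.0:
        raise ValueError(f"cosine similarity {cos_sim} outside [-1, 1]")
    return 1.0 - cos_sim


def log_informativeness(d: float, floor: float = CLAMP_FLOOR) -> tuple[float, bool]:
    """Natural log of the dissimilarity, clamped at ``floor`` for d <= floor.

    Cosines that round to >= 1 give d <= 0, where the log is undefined; such
    values are mapped to ln(floor) with ``clamped=True`` so the pipeline
    stays total while the record is guaranteed to fall below the outlier
    threshold. Strictly increasing in d.
    """
    if d < 0 and d > -1e-9:
        d = 0.0  # tolerate float overshoot from 1 - cosine
    if d < 0:
        raise ValueError(f"dissimilarity must be non-negative, got {d}")
    if d <= floor:
        return math.log(floor), True
    return math.log(d), False


def _record_for(sentence: Sentence, index: int, full_vec: EmbeddingVector,
                spec: EmbedderSpec, threshold: float) -> InformativenessRecord:
    partial_text = remove_word(sentence, index)
    partial_vec = embed(partial_text, spec)
    cos = cosine(full_vec, partial_vec)
    d = raw_dissimilarity(cos)
    score, clamped = log_informativeness(d)
    return InformativenessRecord(
        sentence_id=sentence.id,
        token_index=index,
        word=sentence.tokens[index].core,
        cosine_full_vs_partial=cos,
        raw_dissimilarity=max(d, 0.0),
        informativeness=score,
        outlier=score < threshold,
        clamped=clamped,
    )


def score_sentence(sentence: Sentence, spec: EmbedderSpec,
                   outlier_threshold: float = OUTLIER_THRESHOLD,
                   ) -> list[InformativenessRecord]:
    """Score every word token of a sentence.

    The full-sentence embedding is computed once and reused against each
    leave-one-out variant. Records come back ordered by token index.

    Raises
    ------
    DegenerateSentenceError
        For sentences with fewer than two word tokens.
    """
    if len(sentence.tokens) < 2:
        raise DegenerateSentenceError(
            f"sentence {sentence.id!r} has {len(sentence.tokens)} token(s); "
            "informativeness needs at least 2"
        )
    full_vec = embed(sentence.raw_text, spec)
    return [
        _record_for(sentence, i, full_vec, spec, outlier_threshold)
        for i in range(len(sentence.tokens))
    ]


def score_corpus(sentences: Iterable[Sentence], spec: EmbedderSpec,
                 outlier_threshold: float = OUTLIER_THRESHOLD,
                 ) -> list[InformativenessRecord]:
    """Score a corpus sentence by sentence (order of input preserved)."""
    out: list[InformativenessRecord] = []
    for s in sentences:
        out.extend(score_sentence(s, spec, outlier_threshold))
    return out


def flag_outliers(records: Sequence[InformativenessRecord],
                  threshold: float = OUTLIER_THRESHOLD,
                  ) -> tuple[list[InformativenessRecord], int]:
    """Set the outlier flag on every record: strictly ``score < threshold``.

    A value exactly at the threshold is kept. Returns the re-flagged records
    and the count flagged.
    """
    flagged = [replace(r, outlier=r.informativeness < threshold) for r in records]
    return flagged, sum(r.outlier for r in flagged)


def word_sentence_similarity(word: str, sentence: Sentence, spec: EmbedderSpec) -> float:
    """Cosine between a word's own embedding and its full sentence embedding.

    This is the earlier word-in-sentence similarity construct, provided for
    convergent-validity comparisons only; note it is not informativeness
    (a word can be dissimilar to its sentence yet crucial to its message).
    """
    if not word:
        raise ValueError("word must be non-empty")
    return cosine(embed(word, spec), embed(sentence.raw_text, spec))


def context_vector(preceding_cores: Sequence[str],
                   lexicon: StaticLexicon) -> EmbeddingVector | None:
    """Unweighted mean of the in-lexicon static vectors of the preceding words.

    Returns None (missing) when no preceding word is in the lexicon — in
    particular for a sentence-initial word.
    """
    found = [lexicon.lookup(w) for w in preceding_cores]
    found = [v for v in found if v is not None]
    if not found:
        return None
    return EmbeddingVector(np.mean(found, axis=0))


def predictability(word_core: str, preceding_cores: Sequence[str],
                   lexicon: StaticLexicon, sentence_id: str = "",
                   token_index: int = -1) -> PredictabilityRecord:
    """Cosine between the word's static vector and its preceding-context mean.

    Missing (None) when the word is out of lexicon or there is no usable
    context; missingness is recorded, never raised.
    """
    word_vec = lexicon.lookup(word_core)
    ctx = context_vector(preceding_cores, lexicon)
    value: float | None = None
    if word_vec is not None and ctx is not None:
        value = cosine(word_vec, ctx)
    return PredictabilityRecord(
        sentence_id=sentence_id,
        token_index=token_index,
        word=word_core,
        predictability=value,
        n_context_words=len(preceding_cores),
        oov=word_vec is None,
    )


def predictability_for_sentence(sentence: Sentence,
                                lexicon: StaticLexicon) -> list[PredictabilityRecord]:
    """Predictability records for every token of a sentence, in order."""
    cores = [t.core for t in sentence.tokens]
    return [
        predictability(cores[i], cores[:i], lexicon,
                       sentence_id=sentence.id, token_index=i)
        for i in range(len(cores))
    ]
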