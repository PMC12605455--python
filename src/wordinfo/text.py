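"""Orthographic tokenization and leave-one-word-out sentence construction.

Words are whitespace-delimited chunks with edge punctuation stripped but
tracked, so that sentences can be faithfully reconstructed and a single word
removed without losing sentence-level punctuation. Internal punctuation
(apostrophes in contractions, hyphens in compounds) is part of the word and
never stripped. This is deliberately language-agnostic: it covers alphabetic,
space-delimited writing systems and makes no attempt at morphological or
unspaced-script segmentation.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field

from .errors import DegenerateSentenceError, EmptySentenceError

_WS = re.compile(r"\s+")


def _is_punct(ch: str) -> bool:
    return unicodedata.category(ch).startswith("P")


@dataclass(frozen=True)
class WordToken:
    """One orthographic word: a whitespace chunk with edge punctuation split off.

    ``leading_punct + core + trailing_punct`` reconstructs the original chunk.
    ``core_length`` is the printed-character count of the core, the unit used
    for the word-length covariate.
    """

    index: int
    surface: str
    core: str
    leading_punct: str
    trailing_punct: str

    @property
    def core_length(self) -> int:
        return len(self.core)

    def __post_init__(self) -> None:
        if self.leading_punct + self.core + self.trailing_punct != self.surface:
            raise ValueError(
                f"token parts do not reassemble surface: {self.surface!r}"
            )
        if not self.core:
            raise ValueError("word token core must be non-empty")


@dataclass(frozen=True)
class Sentence:
    """A tokenized sentence: opaque id, language code, raw text and its word tokens."""

    id: str
    language: str
    raw_text: str
    tokens: tuple[WordToken, ...] = field(default=())

    @staticmethod
    def from_text(raw_text: str, id: str = "", language: str = "und") -> "Sentence":
        return Sentence(id=id, language=language, raw_text=raw_text,
                        tokens=tuple(segment_words(raw_text)))

    def __len__(self) -> int:
        return len(self.tokens)


def _split_chunk(chunk: str) -> tuple[str, str, str]:
    """Partition a whitespace chunk into (leading_punct, core, trailing_punct)."""
    start, end = 0, len(chunk)
    while start < end and _is_punct(chunk[start]):
        start += 1
    while end > start and _is_punct(chunk[end - 1]):
        end -= 1
    return chunk[:start], chunk[start:end], chunk[end:]


def segment_words(raw_text: str) -> list[WordToken]:
    """Tokenize ``raw_text`` into word tokens.

    Splits on whitespace, strips Unicode punctuation (category P*) from chunk
    edges into ``leading_punct``/``trailing_punct``, and drops chunks that are
    punctuation only. Numerals and symbols with a non-empty core count as
    words. Deterministic: identical input yields an identical token list.

    Raises
    ------
    EmptySentenceError
        If the text is empty or whitespace-only.
    """
    normalized = _WS.sub(" ", raw_text).strip()
    if not normalized:
        raise EmptySentenceError("cannot tokenize empty or whitespace-only text")
    tokens: list[WordToken] = []
    for chunk in normalized.split(" "):
        lead, core, trail = _split_chunk(chunk)
        if not core:
            continue  # pure punctuation is sentence material, not a word
        tokens.append(WordToken(index=len(tokens), surface=chunk, core=core,
                                leading_punct=lead, trailing_punct=trail))
    if not tokens:
        raise EmptySentenceError("text contains no word tokens (punctuation only)")
    return tokens


def detokenize(tokens: list[WordToken] | tuple[WordToken, ...]) -> str:
    """Join token surfaces with single spaces (inverse of :func:`segment_words`
    up to whitespace normalization)."""
    return " ".join(t.surface for t in tokens)


def remove_word(sentence: Sentence, index: int) -> str:
    """Return the sentence text with the word at ``index`` removed.

    Edge punctuation carried by the removed token is re-attached to the
    preceding remaining token, or to the following token when the removed
    token is sentence-initial, so sentence-level punctuation survives the
    removal. The input sentence is not modified.

    Raises
    ------
    IndexError
        If ``index`` is out of range.
    DegenerateSentenceError
        If the sentence has fewer than two word tokens (a score for the sole
        word of a sentence is undefined).
    """
    n = len(sentence.tokens)
    if n < 2:
        raise DegenerateSentenceError(
            f"sentence {sentence.id!r} has {n} token(s); need at least 2"
        )
    if not 0 <= index < n:
        raise IndexError(f"token index {index} out of range for {n} tokens")

    removed = sentence.tokens[index]
    surfaces = [t.surface for t in sentence.tokens]
    carried = removed.leading_punct + removed.trailing_punct
    if carried:
        if index > 0:
            surfaces[index - 1] = surfaces[index - 1] + carried
        else:
            surfaces[index + 1] = carried + surfaces[index + 1]
    del surfaces[index]
    return " ".join(surfaces)


_SENT_END = re.compile(r"(?<=[.!?…])\s+")


def split_sentences(passage: str) -> list[str]:
    """Convenience terminal-punctuation splitter for passages.

    Splitting passages into sentences is ultimately the caller's
    responsibility; this simple splitter (break after ``. ! ? …`` followed by
    whitespace) is offered for quick experiments and is not part of the
    scored contract.
    """
    parts = [p.strip() for p in _SENT_END.split(passage)]
    return [p for p in parts if p]
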