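"""Frequency transforms and per-language descriptive analytics.

Covers the corpus-level questions one asks of informativeness scores: how
they correlate with word length, Zipf-transformed frequency and
predictability within a language, and how mean informativeness relates to
mean word length and passage length across languages. All summaries exclude
outlier-flagged scores first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ParseError, UndefinedStatisticError
from .measures import InformativenessRecord, PredictabilityRecord
from .text import Sentence


@dataclass
class FrequencyTable:
    """Per-language corpus frequency counts.

    ``total_tokens`` is the corpus size used for normalization; it may exceed
    the sum of listed counts (tables are routinely truncated to the top of
    the vocabulary).
    """

    language: str
    counts: dict[str, int]
    total_tokens: int

    def __post_init__(self) -> None:
        if self.total_tokens <= 0:
            raise ValueError("total_tokens must be positive")

    @property
    def vocabulary_size(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class LanguageSummary:
    """Descriptive summary of one language's scored corpus (after outlier exclusion)."""

    language: str
    mean_informativeness: float
    mean_word_length: float
    mean_passage_length_words: float | None
    n_words: int
    r_length: float | None
    r_zipf: float | None
    r_predictability: float | None


def zipf(word_core: str, table: FrequencyTable, smoothing: float = 1.0) -> float:
    """Zipf-transformed frequency: log10 of occurrences per billion tokens.

    With Laplace smoothing ``s`` (default 1) the estimate is
    ``log10((count + s) / (total + s*V) * 1e9)`` where V is the vocabulary
    size, so out-of-vocabulary words get a finite, low value instead of
    -inf. Set ``smoothing=0`` for the raw plug-in transform (defined only
    for attested words).
    """
    count = table.counts.get(word_core, 0)
    s = smoothing
    num = count + s
    if num <= 0:
        raise ValueError(f"word {word_core!r} unattested and smoothing disabled")
    denom = table.total_tokens + s * table.vocabulary_size
    return math.log10(num / denom * 1e9)


def correlate(scores: Sequence[InformativenessRecord],
              covariate: Sequence[float | None],
              method: str = "pearson") -> float:
    """Correlation between informativeness and a per-word covariate.

    Outlier-flagged scores and missing covariate values are dropped
    pairwise. ``method`` is ``"pearson"`` (default, matching the linear
    relations these scores show with length and frequency) or
    ``"spearman"``.

    Raises
    ------
    UndefinedStatisticError
        With fewer than 3 complete pairs or a zero-variance margin.
    """
    if len(scores) != len(covariate):
        raise ValueError("scores and covariate must align one-to-one")
    xs, ys = [], []
    for rec, c in zip(scores, covariate):
        if rec.outlier or c is None or (isinstance(c, float) and math.isnan(c)):
            continue
        xs.append(rec.informativeness)
        ys.append(float(c))
    if len(xs) < 3:
        raise UndefinedStatisticError(f"only {len(xs)} complete pairs; need >= 3")
    x, y = np.asarray(xs), np.asarray(ys)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("zero variance in one of the margins")
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")


def _maybe_correlate(scores, covariate, method) -> float | None:
    try:
        return correlate(scores, covariate, method=method)
    except UndefinedStatisticError:
        return None


def summarize_language(
    scores: Sequence[InformativenessRecord],
    sentences: Sequence[Sentence],
    passages: Sequence[Sequence[str]] | None = None,
    freq_table: FrequencyTable | None = None,
    predictability_records: Sequence[PredictabilityRecord] | None = None,
    language: str | None = None,
    method: str = "pearson",
) -> LanguageSummary:
    """Per-language means and covariate correlations.

    ``passages`` optionally groups sentence ids into passages; passage length
    is the word-token count of a passage, averaged over passages. Undefined
    correlations (constant covariate, too few pairs) come back as None.

    Raises
    ------
    ValueError
        If no scores survive outlier exclusion.
    """
    sent_by_id: Mapping[str, Sentence] = {s.id: s for s in sentences}
    kept = [r for r in scores if not r.outlier]
    if not kept:
        raise ValueError("no scores remain after outlier exclusion")

    lengths: list[float] = []
    zipfs: list[float | None] = []
    for r in kept:
        tok = sent_by_id[r.sentence_id].tokens[r.token_index]
        lengths.append(float(tok.core_length))
        zipfs.append(zipf(tok.core, freq_table) if freq_table is not None else None)

    preds: list[float | None]
    if predictability_records is not None:
        by_key = {(p.sentence_id, p.token_index): p.predictability
                  for p in predictability_records}
        preds = [by_key.get((r.sentence_id, r.token_index)) for r in kept]
    else:
        preds = [None] * len(kept)

    mean_passage_len: float | None = None
    if passages is not None and len(passages) > 0:
        counts = [sum(len(sent_by_id[sid].tokens) for sid in group) for group in passages]
        mean_passage_len = float(np.mean(counts))

    lang = language
    if lang is None:
        lang = sentences[0].language if sentences else "und"

    return LanguageSummary(
        language=lang,
        mean_informativeness=float(np.mean([r.informativeness for r in kept])),
        mean_word_length=float(np.mean(lengths)),
        mean_passage_length_words=mean_passage_len,
        n_words=len(kept),
        r_length=_maybe_correlate(kept, lengths, method),
        r_zipf=_maybe_correlate(kept, zipfs, method) if freq_table is not None else None,
        r_predictability=(_maybe_correlate(kept, preds, method)
                          if predictability_records is not None else None),
    )


def read_frequency_table(path: str | Path, language: str = "und") -> FrequencyTable:
    """Read a two-column (word, count) TSV with a ``#total_tokens=N`` header line."""
    path = Path(path)
    counts: dict[str, int] = {}
    total: int | None = None
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#total_tokens="):
                    total = int(line.split("=", 1)[1])
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 'word<TAB>count'")
            try:
                counts[parts[0]] = int(parts[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer count {parts[1]!r}") from exc
    if total is None:
        total = sum(counts.values())
    return FrequencyTable(language=language, counts=counts, total_tokens=total)


def write_frequency_table(table: FrequencyTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"#total_tokens={table.total_tokens}\n")
        for word, count in sorted(table.counts.items()):
            fh.write(f"{word}\t{count}\n")
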