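"""Deterministic synthetic corpora and eye-movement data with known truth.

Every stage of the package is testable offline against data whose generating
model is known exactly. The generator emulates the statistical structure the
validation pipeline assumes, not the surface realism of any real corpus:

* ``make_corpus`` builds per-language vocabularies with Zipfian frequencies
  and configurable word lengths, and packs passages into sentences. Across
  languages the passages are "translation equivalents": a fixed
  character-budget of meaning per passage, so languages with longer words
  carry fewer tokens per passage.
* ``make_scores`` plants informativeness values directly: a base level of
  ``offset − ln(sentence token count)`` (removing one of fewer words moves
  the meaning more — the packing rule) plus linear couplings to word length
  and Zipf frequency plus noise, with a small rate of degenerate outliers
  below −10.
* ``make_eye_data`` simulates one row per (subject, word token): log total
  fixation duration linear in the centered/scaled covariates with subject
  and word random intercepts and Gaussian noise; first-run skipping and
  rereading from logistic models (skipping with negative length and
  informativeness coefficients by default, the direction reading studies
  report); gaze and first-fixation durations carved out of the total so that
  ffd <= gaze <= tfd always holds after integer-millisecond rounding.

Identical configs give bitwise-identical outputs; every config field enters
the config hash.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .corpus_stats import FrequencyTable, zipf as zipf_transform
from .errors import ConfigurationError
from .lexicon import StaticLexicon
from .text import Sentence

_ALPHABET = "abcdefghijklmnopqrstuvwxyz"


@dataclass(frozen=True)
class SynthConfig:
    """Ground-truth configuration of the synthetic generator.

    Eye-model coefficients are on the scale of centered/scaled covariates
    (log-ms change per covariate SD for durational outcomes, logit change
    per SD for binary ones). ``word_length_growth`` controls how much longer
    words are in each successive language, which via the fixed per-passage
    character budget makes later languages pack fewer tokens per passage.
    """

    seed: int = 0
    n_languages: int = 1
    n_passages: int = 10
    tokens_per_passage: int = 30
    vocabulary_size: int = 150
    mean_word_length: float = 5.0
    word_length_growth: float = 0.25
    sentence_tokens_mean: int = 10

    # planted couplings in the score model
    coupling_length: float = 0.15
    coupling_zipf: float = -0.20
    score_offset: float = -2.0
    score_noise_sd: float = 0.30
    planted_outlier_rate: float = 0.001

    # eye model: durational (log-ms) coefficients
    intercept: float = 5.35
    b_len: float = 0.10
    b_zipf: float = -0.06
    b_pred: float = -0.02
    b_info: float = 0.05
    b_skill: float = -0.10
    b_skill_info: float = -0.03
    sd_subject: float = 0.15
    sd_word: float = 0.08
    sd_resid: float = 0.35

    # logistic DVs
    skip_intercept: float = -1.2
    skip_b_len: float = -0.5
    skip_b_info: float = -0.1
    reread_intercept: float = -1.5
    reread_b_info: float = 0.15

    n_subjects: int = 40

    def __post_init__(self) -> None:
        if self.sd_resid <= 0:
            raise ConfigurationError("residual SD must be positive")
        if self.n_subjects < 2:
            raise ConfigurationError("need at least 2 subjects")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SynthCorpus:
    """Generated corpus bundle: one entry per language."""

    sentences: dict[str, list[Sentence]]
    freq_tables: dict[str, FrequencyTable]
    lexicon: StaticLexicon
    passages: dict[str, list[list[str]]] = field(default_factory=dict)

    def all_sentences(self) -> list[Sentence]:
        return [s for lang in sorted(self.sentences) for s in self.sentences[lang]]


def _rng(config: SynthConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed & 0x7FFFFFFF, stream])


def _make_vocabulary(config: SynthConfig, lang_idx: int,
                     rng: np.random.Generator) -> tuple[list[str], np.ndarray]:
    """Vocabulary with Zipfian probabilities; longer words sit at rarer ranks."""
    mean_len = config.mean_word_length * (1.0 + config.word_length_growth * lang_idx)
    words: set[str] = set()
    attempts = 0
    while len(words) < config.vocabulary_size:
        length = max(2, 2 + rng.poisson(max(mean_len - 2.0, 0.1)))
        w = "".join(rng.choice(list(_ALPHABET), size=length))
        words.add(w)
        attempts += 1
        if attempts > 50 * config.vocabulary_size:
            raise ConfigurationError("vocabulary too large for requested word lengths")
    # rank by length with noise so frequency and length are realistically coupled
    wlist = sorted(words)
    noise = rng.normal(0, 1.5, size=len(wlist))
    order = np.argsort([len(w) + e for w, e in zip(wlist, noise)])
    ranked = [wlist[i] for i in order]
    probs = 1.0 / np.arange(1, len(ranked) + 1)
    probs /= probs.sum()
    return ranked, probs


def make_corpus(config: SynthConfig) -> SynthCorpus:
    """Generate the multilingual corpus, frequency tables, and a toy lexicon.

    Raises :class:`ConfigurationError` when a passage asks for more tokens
    than the vocabulary supports.
    """
    if config.vocabulary_size < 2:
        raise ConfigurationError("vocabulary_size must be >= 2")
    if config.vocabulary_size < config.tokens_per_passage:
        raise ConfigurationError(
            f"vocabulary_size {config.vocabulary_size} smaller than "
            f"tokens_per_passage {config.tokens_per_passage}")
    sentences: dict[str, list[Sentence]] = {}
    freq_tables: dict[str, FrequencyTable] = {}
    passages: dict[str, list[list[str]]] = {}
    lex = StaticLexicon(dim=16)
    lex_rng = _rng(config, 900)

    char_budget = config.tokens_per_passage * config.mean_word_length
    for li in range(config.n_languages):
        lang = f"L{li + 1}"
        rng = _rng(config, 100 + li)
        vocab, probs = _make_vocabulary(config, li, rng)
        mean_len_li = config.mean_word_length * (1.0 + config.word_length_growth * li)
        tokens_per_passage = max(4, int(round(char_budget / mean_len_li)))

        counts: dict[str, int] = {}
        sentences[lang] = []
        passages[lang] = []
        for pj in range(config.n_passages):
            toks = list(rng.choice(vocab, size=tokens_per_passage, p=probs))
            for t in toks:
                counts[t] = counts.get(t, 0) + 1
            group: list[str] = []
            k = 0
            si = 0
            while k < len(toks):
                n = int(np.clip(rng.poisson(config.sentence_tokens_mean),
                                2, len(toks) - k))
                if len(toks) - (k + n) == 1:
                    n += 1  # never leave a one-token remainder
                chunk = toks[k:k + n]
                k += n
                sid = f"{lang}_p{pj}_s{si}"
                si += 1
                text = " ".join(chunk) + "."
                sentences[lang].append(Sentence.from_text(text, id=sid, language=lang))
                group.append(sid)
            passages[lang].append(group)
        freq_tables[lang] = FrequencyTable(language=lang, counts=counts,
                                           total_tokens=sum(counts.values()))
        for w in vocab:
            v = lex_rng.normal(size=16)
            lex.add(w, v / np.linalg.norm(v))
    return SynthCorpus(sentences=sentences, freq_tables=freq_tables,
                       lexicon=lex, passages=passages)


def make_scores(config: SynthConfig, corpus: SynthCorpus) -> pd.DataFrame:
    """Plant per-token informativeness and covariates with known couplings.

    Returns one row per word token with columns: language, trial (sentence
    id), ia_index, word, length, zipf, predictability, informativeness,
    outlier. Informativeness is ``score_offset − ln(sentence length) +
    coupling_length·z(length) + coupling_zipf·z(zipf) + noise``, capped at
    ln 2; a ``planted_outlier_rate`` fraction is replaced by degenerate
    values below −10.
    """
    rng = _rng(config, 200)
    rows = []
    for lang in sorted(corpus.sentences):
        table = corpus.freq_tables[lang]
        for sent in corpus.sentences[lang]:
            for tok in sent.tokens:
                rows.append({
                    "language": lang,
                    "trial": sent.id,
                    "ia_index": tok.index,
                    "word": tok.core,
                    "length": float(tok.core_length),
                    "zipf": zipf_transform(tok.core, table),
                    "n_tokens": len(sent.tokens),
                })
    df = pd.DataFrame(rows)
    len_z = _zscore(df["length"].to_numpy())
    zipf_z = _zscore(df["zipf"].to_numpy())
    noise = rng.normal(0, config.score_noise_sd, size=len(df))
    info = (config.score_offset - np.log(df["n_tokens"].to_numpy())
            + config.coupling_length * len_z
            + config.coupling_zipf * zipf_z
            + noise)
    info = np.minimum(info, math.log(2.0))
    degenerate = rng.random(len(df)) < config.planted_outlier_rate
    info = np.where(degenerate, rng.uniform(-30.0, -10.5, size=len(df)), info)
    df["informativeness"] = info
    df["outlier"] = info < -10.0
    df["predictability"] = np.tanh(0.4 * zipf_z + rng.normal(0, 0.5, size=len(df)))
    return df.drop(columns="n_tokens")


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


_SKILL_TESTS = {
    "towre_word": (75.0, 12.0),
    "towre_nonword": (45.0, 10.0),
    "spelling": (60.0, 15.0),
    "lextale": (0.75, 0.12),
    "vocabulary": (80.0, 14.0),
}


def make_eye_data(config: SynthConfig, covariates: pd.DataFrame,
                  ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate interest-area records and skill scores over scored tokens.

    ``covariates`` is the output of :func:`make_scores` (or real scores in
    the same shape); outlier rows are excluded from the generating model the
    way the analysis excludes them. Returns (ia, skills, truth): the IA
    table in the column contract of :func:`wordinfo.eyetrack.read_ia_report`,
    a five-test skill table, and the full generating truth.
    """
    rng = _rng(config, 300)
    cov = covariates.loc[~covariates["outlier"]].reset_index(drop=True)
    n_words = len(cov)
    n_subj = config.n_subjects

    len_z = _zscore(cov["length"].to_numpy())
    zipf_z = _zscore(cov["zipf"].to_numpy())
    pred_z = _zscore(cov["predictability"].to_numpy())
    info_z = _zscore(cov["informativeness"].to_numpy())

    skill = rng.normal(0, 1, size=n_subj)
    u_subj = rng.normal(0, config.sd_subject, size=n_subj)
    word_key = (cov["language"] + ":" + cov["word"]).to_numpy()
    uniq = pd.unique(word_key)
    w_int = dict(zip(uniq, rng.normal(0, config.sd_word, size=len(uniq))))
    u_word = np.array([w_int[k] for k in word_key])

    rows = []
    for s in range(n_subj):
        subj = f"S{s + 1:03d}"
        mu = (config.intercept
              + config.b_len * len_z + config.b_zipf * zipf_z
              + config.b_pred * pred_z + config.b_info * info_z
              + config.b_skill * skill[s]
              + config.b_skill_info * skill[s] * info_z
              + u_subj[s] + u_word)
        log_tfd = mu + rng.normal(0, config.sd_resid, size=n_words)
        tfd = np.maximum(np.rint(np.exp(log_tfd)).astype(int), 2)

        p_skip = _sigmoid(config.skip_intercept + config.skip_b_len * len_z
                          + config.skip_b_info * info_z)
        skip = rng.random(n_words) < p_skip
        p_reread = _sigmoid(config.reread_intercept + config.reread_b_info * info_z)
        reread = rng.random(n_words) < p_reread

        gaze_frac = rng.uniform(0.45, 0.85, size=n_words)
        single_fix = rng.random(n_words) < 0.4
        ffd_frac = np.where(single_fix, 1.0, rng.uniform(0.5, 1.0, size=n_words))

        gaze = np.where(reread,
                        np.minimum(np.rint(tfd * gaze_frac).astype(int), tfd - 1),
                        tfd)
        gaze = np.maximum(gaze, 1)
        ffd = np.maximum(np.minimum(np.rint(gaze * ffd_frac).astype(int), gaze), 1)

        ffd_out = ffd.astype(float)
        gaze_out = gaze.astype(float)
        tfd_out = tfd.astype(float)
        # first-pass skip: no FFD/gaze; if never reread, no fixation at all
        ffd_out[skip] = np.nan
        gaze_out[skip] = np.nan
        tfd_out[skip & ~reread] = np.nan

        rows.append(pd.DataFrame({
            "subject": subj,
            "language": cov["language"],
            "trial": cov["trial"],
            "ia_index": cov["ia_index"],
            "word": cov["word"],
            "ffd": ffd_out,
            "gaze": gaze_out,
            "tfd": tfd_out,
        }))
    ia = pd.concat(rows, ignore_index=True)

    test_rng = _rng(config, 400)
    skills = {"subject": [f"S{s + 1:03d}" for s in range(n_subj)]}
    for test, (mean, sd) in _SKILL_TESTS.items():
        latent = 0.85 * skill + math.sqrt(1 - 0.85 ** 2) * test_rng.normal(0, 1, n_subj)
        skills[test] = mean + sd * latent
    skills_df = pd.DataFrame(skills)

    truth = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "true_skill": skill.tolist(),
        **{k: getattr(config, k) for k in (
            "intercept", "b_len", "b_zipf", "b_pred", "b_info", "b_skill",
            "b_skill_info", "sd_subject", "sd_word", "sd_resid",
            "skip_intercept", "skip_b_len", "skip_b_info",
            "reread_intercept", "reread_b_info")},
    }
    return ia, skills_df, truth


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))
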