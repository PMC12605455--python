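"""Text-to-vector contract, deterministic reference embedder, and cosine.

The scoring pipeline only assumes a function from text to a fixed-dimension
vector. Production scoring uses a pretrained multilingual sentence encoder
through the optional adapter in :mod:`wordinfo.backends`; every test and all
offline work uses the reference embedder below, which is a fast, seeded,
order-sensitive hashing encoder with the structural properties the scores
rely on (determinism, sensitivity to any single word, unit norm).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, DegenerateVectorError, EmptyInputError

_NGRAM = 3          # character n-gram size of the reference embedder
_DECAY = 0.9        # positional decay factor per token index
_REFERENCE_NAMES = {"reference", "ref"}


@dataclass(frozen=True)
class EmbeddingVector:
    """A finite, fixed-dimension semantic vector."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("embedding must be one-dimensional")
        if not np.all(np.isfinite(v)):
            raise ValueError("embedding contains non-finite entries")
        object.__setattr__(self, "values", v)

    @property
    def dim(self) -> int:
        return self.values.shape[0]

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.values))


@dataclass(frozen=True)
class EmbedderSpec:
    """Identifies a backend so that scores are reproducible.

    ``name`` is either ``"reference"`` (the built-in seeded embedder) or the
    identifier of a pretrained sentence-encoder model handled by the optional
    adapter. The same (name, seed, text) always yields an identical vector;
    for the reference backend this is bitwise. Backend name and seed are
    recorded in every output file header, because scores from different
    backends are not comparable.
    """

    name: str = "reference"
    dim: int = 64
    seed: int = 0
    order_sensitive: bool = True

    @property
    def is_reference(self) -> bool:
        return self.name.lower() in _REFERENCE_NAMES

    def provenance(self) -> str:
        return f"backend={self.name} dim={self.dim} seed={self.seed}"


def load_embedder_spec(path: str | Path) -> EmbedderSpec:
    """Read an EmbedderSpec from a YAML or JSON key-value config file."""
    text = Path(path).read_text(encoding="utf-8")
    try:
        data = json.loads(text)
    except json.JSONDecodeError:
        import yaml

        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigurationError(f"config file {path} is not a key-value mapping")
    known = {k: data[k] for k in ("name", "dim", "seed", "order_sensitive") if k in data}
    return EmbedderSpec(**known)


def _token_weight(index: int, order_sensitive: bool) -> float:
    return _DECAY ** index if order_sensitive else 1.0


def _hash64(s: str) -> int:
    return int.from_bytes(hashlib.blake2b(s.encode("utf-8"), digest_size=8).digest(), "big")


@lru_cache(maxsize=200_000)
def _ngram_vector(h: int, seed: int, dim: int) -> np.ndarray:
    rng = np.random.default_rng((seed & 0x7FFFFFFF, h))
    v = rng.standard_normal(dim)
    v.setflags(write=False)
    return v


def reference_embed(text: str, seed: int = 0, dim: int = 64,
                    order_sensitive: bool = True) -> EmbeddingVector:
    """Deterministic hashing sentence embedder.

    Each whitespace token is padded with boundary markers and decomposed into
    character trigrams; every trigram is hashed to 64 bits and mapped through
    a seeded Gaussian random projection; trigram vectors are summed with a
    positional decay of 0.9 per token index (making the encoding sensitive to
    word order) and the total is L2-normalized. Removing any token changes
    the vector, because it removes that token's trigram mass and shifts the
    positional weights of everything after it.
    """
    if dim < 8:
        raise ConfigurationError(f"reference embedder needs dim >= 8, got {dim}")
    tokens = text.split()
    if not tokens:
        raise EmptyInputError("cannot embed empty text")
    acc = np.zeros(dim)
    for i, tok in enumerate(tokens):
        w = _token_weight(i, order_sensitive)
        padded = f"\x02{tok}\x03"
        grams = [padded] if len(padded) < _NGRAM else [
            padded[j:j + _NGRAM] for j in range(len(padded) - _NGRAM + 1)
        ]
        for g in grams:
            acc += w * _ngram_vector(_hash64(g), seed, dim)
    n = np.linalg.norm(acc)
    if n == 0.0:  # astronomically unlikely; guard anyway
        raise DegenerateVectorError("reference embedding collapsed to zero")
    return EmbeddingVector(acc / n)


def embed(text: str, spec: EmbedderSpec) -> EmbeddingVector:
    """Embed ``text`` under ``spec``, dispatching to the configured backend."""
    if not text or not text.strip():
        raise EmptyInputError("cannot embed empty text")
    if spec.is_reference:
        return reference_embed(text, seed=spec.seed, dim=spec.dim,
                               order_sensitive=spec.order_sensitive)
    from . import backends

    return backends.pretrained_embed(text, spec)


def cosine(u: EmbeddingVector | np.ndarray, v: EmbeddingVector | np.ndarray) -> float:
    """Cosine similarity u·v / (‖u‖‖v‖), clipped into [−1, 1].

    Raises for zero-norm input or mismatched dimensions; the clip only guards
    against floating-point overshoot at the boundaries.
    """
    a = u.values if isinstance(u, EmbeddingVector) else np.asarray(u, dtype=float)
    b = v.values if isinstance(v, EmbeddingVector) else np.asarray(v, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise DegenerateVectorError("cosine undefined for zero-norm vector")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))
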