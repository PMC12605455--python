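"""Static word-vector lexicons in word2vec text format.

Used for the embedding-based predictability covariate: each word has one
static vector (fastText-style), and a word's predictability in context is
the cosine between its vector and the mean vector of the preceding words.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ParseError


@dataclass
class StaticLexicon:
    """word -> vector mapping with case-folded fallback lookup.

    Lookup tries the exact-cased form first, then the case-folded form;
    static lexicons are typically lowercased while running text is not.
    """

    dim: int
    vectors: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._folded: dict[str, str] = {}
        for w in self.vectors:
            self._folded.setdefault(w.casefold(), w)

    def add(self, word: str, vector: np.ndarray) -> None:
        v = np.asarray(vector, dtype=float)
        if v.shape != (self.dim,):
            raise ValueError(f"vector for {word!r} has shape {v.shape}, expected ({self.dim},)")
        self.vectors[word] = v
        self._folded.setdefault(word.casefold(), word)

    def lookup(self, word: str) -> np.ndarray | None:
        v = self.vectors.get(word)
        if v is not None:
            return v
        key = self._folded.get(word.casefold())
        return self.vectors[key] if key is not None else None

    def __contains__(self, word: str) -> bool:
        return self.lookup(word) is not None

    def __len__(self) -> int:
        return len(self.vectors)


def read_word2vec_text(path: str | Path) -> StaticLexicon:
    """Read a lexicon in word2vec text format.

    First line: ``<count> <dim>``; each following line: ``word v1 ... vdim``
    separated by spaces. Surplus declared count is tolerated; a malformed
    vector line raises :class:`ParseError` with its line number.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ParseError(f"{path}: header must be '<count> <dim>'")
        try:
            _count, dim = int(header[0]), int(header[1])
        except ValueError as exc:
            raise ParseError(f"{path}: non-integer header {header!r}") from exc
        lex = StaticLexicon(dim=dim)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split(" ")
            if len(parts) != dim + 1:
                raise ParseError(
                    f"{path}:{lineno}: expected word + {dim} floats, got {len(parts)} fields"
                )
            try:
                vec = np.array([float(x) for x in parts[1:]])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric vector entry") from exc
            lex.add(parts[0], vec)
    return lex


def write_word2vec_text(lex: StaticLexicon, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"{len(lex)} {lex.dim}\n")
        for word, vec in lex.vectors.items():
            fh.write(word + " " + " ".join(f"{x:.6g}" for x in vec) + "\n")
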