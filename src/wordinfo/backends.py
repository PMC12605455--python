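"""Optional pretrained sentence-encoder adapter.

Never imported unless a non-reference backend is requested, so the core
library and its tests run fully offline. Scoring a real corpus the way the
validation studies do means pointing ``EmbedderSpec.name`` at a pinned
multilingual sentence-BERT model (``distiluse-base-multilingual-cased-v2``)
with the ``sentence-transformers`` extra installed.
"""

from __future__ import annotations

from .embedding import EmbedderSpec, EmbeddingVector
from .errors import BackendError, ConfigurationError

_models: dict[str, object] = {}


def pretrained_embed(text: str, spec: EmbedderSpec) -> EmbeddingVector:
    try:
        from sentence_transformers import SentenceTransformer
    except ImportError as exc:
        raise ConfigurationError(
            f"backend {spec.name!r} needs the optional 'sentence-transformers' "
            "dependency (pip install wordinfo[transformers]); the built-in "
            "'reference' backend runs without it"
        ) from exc
    model = _models.get(spec.name)
    if model is None:
        model = SentenceTransformer(spec.name)
        _models[spec.name] = model
    try:
        vec = model.encode([text], normalize_embeddings=True)[0]
    except Exception as exc:  # pragma: no cover - network/model failures
        raise BackendError(f"backend {spec.name!r} failed on text: {text[:60]!r}") from exc
    return EmbeddingVector(vec)
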