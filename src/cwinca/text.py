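"""Text cleaning and embedding frontend.

A corpus (texts + labels) is cleaned with simple, reproducible rules and
turned into a numeric feature matrix by an embedding backend.  Two kinds
of backend exist: thin adapters around pre-trained transformer encoders
(optional, loaded lazily) and a dependency-free hashing backend that maps
token hashes into a fixed-width signed-count vector.  The hashing
backend is fully deterministic, which makes it the workhorse for tests
and synthetic experiments; matrices from several backends can be
concatenated column-wise into one combined feature vector.
"""

from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass

import numpy as np

from .data import LabeledMatrix

__all__ = [
    "Corpus",
    "DEFAULT_STOPWORDS",
    "clean_text",
    "HashingBackend",
    "TransformerBackend",
    "embed_texts",
    "concat_features",
]

logger = logging.getLogger(__name__)

# Compact English function-word list; an explicit input so runs are pinned.
DEFAULT_STOPWORDS = frozenset(
    """a about after again all am an and any are as at be because been before
    being but by can could did do does doing down for from had has have having
    he her here hers him his how i if in into is it its just me more most my
    no nor not of off on once only or other our ours out over own s so some
    such t than that the their theirs them then there these they this those
    through to too under until up very was we were what when where which while
    who whom why will with you your yours""".split()
)

_RE_NONALNUM = re.compile(r"[^a-z0-9\s]+")
_RE_REPEAT = re.compile(r"(.)\1{2,}")


@dataclass
class Corpus:
    """Raw labeled texts."""

    texts: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if len(self.texts) != self.labels.size:
            raise ValueError("texts and labels must have equal length")
        if len(self.texts) == 0:
            raise ValueError("corpus is empty")


def clean_text(raw: str, stopwords: frozenset[str] | set[str] = DEFAULT_STOPWORDS) -> str:
    """Normalize one text: lowercase, strip punctuation and symbols,
    collapse runs of three or more identical characters to two, drop
    stopwords, rejoin with single spaces.  Idempotent; may return "".
    """
    s = raw.lower()
    s = _RE_NONALNUM.sub(" ", s)
    s = _RE_REPEAT.sub(r"\1\1", s)
    tokens = [t for t in s.split() if t not in stopwords]
    return " ".join(tokens)


class HashingBackend:
    """Deterministic signed hashing embedder.

    Each token is hashed (BLAKE2b, unsalted) to a bucket in ``[0, dim)``
    and a sign in {-1, +1}; a text's vector is the signed token-count
    histogram.  No vocabulary, no fit step, identical output for
    identical cleaned text.
    """

    kind = "hashing_test_backend"

    def __init__(self, dimension: int = 64, name: str = "hash"):
        if dimension < 1:
            raise ValueError("dimension must be positive")
        self.dimension = dimension
        self.name = name

    def embed(self, cleaned: str) -> np.ndarray:
        vec = np.zeros(self.dimension)
        for token in cleaned.split():
            digest = hashlib.blake2b(token.encode("utf-8"), digest_size=8).digest()
            h = int.from_bytes(digest, "big")
            vec[(h >> 1) % self.dimension] += 1.0 if h & 1 else -1.0
        return vec


class TransformerBackend:
    """Thin adapter around a pre-trained transformer encoder.

    Pools the final hidden layer over tokens (mean by default, CLS
    optional).  The heavy dependencies are imported lazily; when they are
    not installed a clear error points at the hashing backend instead.
    """

    kind = "transformer_adapter"

    def __init__(self, model_name: str, pooling: str = "mean"):
        if pooling not in {"mean", "cls"}:
            raise ValueError("pooling must be 'mean' or 'cls'")
        self.name = model_name
        self.pooling = pooling
        try:
            from transformers import AutoModel, AutoTokenizer  # noqa: PLC0415
            import torch  # noqa: F401, PLC0415
        except ImportError as exc:
            raise RuntimeError(
                f"transformer backend {model_name!r} needs the optional "
                "'transformers' and 'torch' packages; use HashingBackend "
                "for a dependency-free deterministic embedder"
            ) from exc
        self._tokenizer = AutoTokenizer.from_pretrained(model_name)
        self._model = AutoModel.from_pretrained(model_name)
        self._model.eval()
        self.dimension = int(self._model.config.hidden_size)

    def embed(self, cleaned: str) -> np.ndarray:
        import torch  # noqa: PLC0415

        with torch.no_grad():
            enc = self._tokenizer(cleaned, return_tensors="pt", truncation=True)
            hidden = self._model(**enc).last_hidden_state[0]
            pooled = hidden[0] if self.pooling == "cls" else hidden.mean(dim=0)
        return pooled.numpy().astype(float)


def embed_texts(
    corpus: Corpus,
    backend,
    stopwords: frozenset[str] | set[str] = DEFAULT_STOPWORDS,
) -> LabeledMatrix:
    """Clean every text and stack backend vectors into a LabeledMatrix.

    Texts that clean to the empty string are dropped (never silently: the
    count is logged).  Feature names are ``<backend>_0 .. <backend>_{dim-1}``.
    """
    cleaned = [clean_text(t, stopwords) for t in corpus.texts]
    keep = [i for i, c in enumerate(cleaned) if c]
    dropped = len(cleaned) - len(keep)
    if dropped:
        logger.warning("dropped %d text(s) that were empty after cleaning", dropped)
    if not keep:
        raise ValueError("every text was empty after cleaning")
    rows = np.stack([backend.embed(cleaned[i]) for i in keep])
    names = [f"{backend.name}_{j}" for j in range(backend.dimension)]
    return LabeledMatrix(rows, corpus.labels[keep], names)


def concat_features(matrices: list[LabeledMatrix]) -> LabeledMatrix:
    """Column-wise concatenation of per-backend matrices.

    All inputs must share the sample count and the exact label vector
    (no silent row alignment).  A single input passes through unchanged.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    first = matrices[0]
    if len(matrices) == 1:
        return first
    for m in matrices[1:]:
        if m.n_samples != first.n_samples or (m.labels != first.labels).any():
            raise ValueError("label vectors differ between matrices")
    values = np.hstack([m.values for m in matrices])
    names = [name for m in matrices for name in m.feature_names]
    return LabeledMatrix(values, first.labels, names)
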