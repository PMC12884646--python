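"""Semantic sentence similarity via pluggable embedding backends.

A backend maps a list of texts to fixed-dimension vectors; pairwise cosine
similarity over a corpus gives the semantic layer's similarity matrix, and
rank (Spearman) correlation over the upper-triangle entries compares how
two backends order the same sentence pairs.

Three backends are registered: two published sentence-transformer models
(the biomedical model ``pritamdeka/S-Biomed-Roberta-snli-multinli-stsb``
used as the clinical reference, and the general-purpose
``all-mpnet-base-v2``), both loaded lazily and requiring the optional
``transformers`` extra; and the deterministic offline stub from
:mod:`symscreen.fixtures`, which is the default for testing and pipelines
that must run without model downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence, runtime_checkable

import numpy as np
from scipy import stats

from .corpus import Corpus

REFERENCE_CLINICAL_MODEL = "pritamdeka/S-Biomed-Roberta-snli-multinli-stsb"
GENERAL_PURPOSE_MODEL = "all-mpnet-base-v2"


@runtime_checkable
class EmbeddingBackend(Protocol):
    """Deterministic text-to-vector contract: identical text, identical vector."""

    name: str
    dim: int

    def embed(self, texts: Sequence[str]) -> np.ndarray:  # (len(texts), dim)
        ...


@dataclass
class CachedBackend:
    """Wrap a backend with a per-text embedding cache keyed by (name, text)."""

    backend: EmbeddingBackend
    _cache: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def name(self) -> str:
        return self.backend.name

    @property
    def dim(self) -> int:
        return self.backend.dim

    def embed(self, texts: Sequence[str]) -> np.ndarray:
        missing = [t for t in dict.fromkeys(texts) if t not in self._cache]
        if missing:
            vecs = self.backend.embed(missing)
            for t, v in zip(missing, np.asarray(vecs)):
                self._cache[t] = v
        return np.stack([self._cache[t] for t in texts])


@dataclass
class TransformerBackend:
    """Sentence-transformer model backend (requires the ``transformers`` extra)."""

    model_name: str = REFERENCE_CLINICAL_MODEL
    dim: int = 768

    def __post_init__(self) -> None:
        try:
            from sentence_transformers import SentenceTransformer
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "sentence-transformers is required for transformer backends; "
                "install symscreen[transformers] or use the 'stub' backend"
            ) from exc
        self._model = SentenceTransformer(self.model_name)

    @property
    def name(self) -> str:
        return self.model_name

    def embed(self, texts: Sequence[str]) -> np.ndarray:  # pragma: no cover
        return np.asarray(self._model.encode(list(texts)))


def get_backend(key: str, seed: int = 0) -> EmbeddingBackend:
    """Resolve a backend by config key: ``stub``, ``clinical`` or ``general``."""
    from .fixtures import StubEmbedder

    if key == "stub":
        return StubEmbedder(seed=seed)
    if key == "clinical":
        return TransformerBackend(REFERENCE_CLINICAL_MODEL)
    if key == "general":
        return TransformerBackend(GENERAL_PURPOSE_MODEL)
    raise KeyError(f"unknown backend {key!r}; valid keys: stub, clinical, general")


@dataclass(frozen=True)
class SimilarityMatrix:
    labels: tuple[str, ...]
    M: np.ndarray

    def __post_init__(self) -> None:
        M = np.asarray(self.M, dtype=float)
        object.__setattr__(self, "M", M)
        if M.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape must match label count")
        if not np.allclose(M, M.T, atol=1e-9):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(M), 1.0, atol=1e-9):
            raise ValueError("similarity matrix diagonal must be 1")

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.M[iu]

    def pair_scores(self) -> dict[tuple[str, str], float]:
        n = len(self.labels)
        return {
            (self.labels[i], self.labels[j]): float(self.M[i, j])
            for i in range(n)
            for j in range(i + 1, n)
        }

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.M, index=self.labels, columns=self.labels).to_csv(path)


def cosine_pairwise(backend: EmbeddingBackend, corpus: Corpus) -> SimilarityMatrix:
    """Pairwise cosine similarity matrix over a corpus under one backend."""
    if len(corpus) == 0:
        raise ValueError("corpus is empty")
    E = np.asarray(backend.embed(corpus.texts), dtype=float)
    norms = np.linalg.norm(E, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ValueError(f"zero-norm embedding for item {corpus.ids[zero[0]]!r}")
    En = E / norms[:, None]
    M = En @ En.T
    np.fill_diagonal(M, 1.0)
    M = np.clip((M + M.T) / 2.0, -1.0, 1.0)
    return SimilarityMatrix(tuple(corpus.ids), M)


def compare_backends(
    simA: SimilarityMatrix, simB: SimilarityMatrix
) -> tuple[float, float]:
    """Spearman rank correlation between two backends' pair scores.

    Uses the upper-triangle (i < j) entries only; labels must agree in
    content and order.  Returns (rho, two-sided p-value).
    """
    if simA.labels != simB.labels:
        raise ValueError("similarity matrices carry different labels")
    res = stats.spearmanr(simA.upper_triangle(), simB.upper_triangle())
    return float(res.statistic), float(res.pvalue)
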