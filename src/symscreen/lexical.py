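"""Lexical sentence similarity: hybrid word scores, greedy alignment, length penalty.

For each token pair across two preprocessed sentences a hybrid word
similarity is computed: taxonomy path similarity (maximum over sense
pairs) when a path exists and clears a minimum threshold, otherwise a
normalized Levenshtein similarity 1 - dist/max(len).  The resulting
word-level matrix is aggregated by greedy alignment — repeatedly take the
global maximum, retire its row and column, average over the iterations —
and a length penalty |la - lb| * sim / max(la, lb) is subtracted to
discount asymmetric sentence lengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np

from .taxonomy import Taxonomy, default_taxonomy
from .textproc import EmptyTokenSeqError, TokenSeq, lexical_preprocess

MIN_PATH_SIM = 0.1


@dataclass(frozen=True)
class LexicalScore:
    word_sim: float
    len_a: int
    len_b: int
    penalty: float
    final: float
    empty_input: bool = False  # warning flag: one side had no content tokens


def levenshtein_similarity(a: str, b: str) -> float:
    """1 - editdistance(a, b) / max(|a|, |b|); 1.0 for two empty strings."""
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    dist = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def word_similarity(
    a: str,
    b: str,
    pos_a: str = "noun",
    pos_b: str = "noun",
    taxonomy: Taxonomy | None = None,
    min_path_sim: float = MIN_PATH_SIM,
) -> float:
    """Hybrid word-to-word similarity in [0, 1], symmetric in its arguments.

    Taxonomy path similarity (max over sense pairs) is used when defined
    and >= ``min_path_sim``; otherwise the normalized Levenshtein
    similarity of the surface lemmas.
    """
    if not a or not b:
        raise ValueError("lemmas must be non-empty")
    if a == b:
        return 1.0
    tax = taxonomy if taxonomy is not None else default_taxonomy()
    path = tax.word_path_similarity(a, pos_a, b, pos_b)
    if path is None or path < min_path_sim:
        return levenshtein_similarity(a, b)
    return path


def greedy_align(S: np.ndarray) -> float:
    """Greedy alignment score of a word/triple similarity matrix.

    Repeatedly selects the global maximum entry (ties broken by smallest
    (row, col) in lexicographic order), accumulates it, and removes its row
    and column; runs for min(n_rows, n_cols) iterations and returns the
    accumulated total divided by the iteration count.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.size == 0:
        raise ValueError("alignment matrix must be non-empty and 2-D")
    work = S.copy()
    iters = min(work.shape)
    total = 0.0
    for _ in range(iters):
        # argmax on the flattened array scans row-major, so the first
        # occurrence of the maximum is the lexicographically smallest (r, c)
        r, c = np.unravel_index(np.argmax(work), work.shape)
        total += work[r, c]
        work = np.delete(np.delete(work, r, axis=0), c, axis=1)
    return total / iters


def word_similarity_matrix(
    a: TokenSeq, b: TokenSeq, taxonomy: Taxonomy | None = None,
    min_path_sim: float = MIN_PATH_SIM,
) -> np.ndarray:
    S = np.empty((len(a), len(b)))
    for i, ta in enumerate(a):
        for j, tb in enumerate(b):
            S[i, j] = word_similarity(
                ta.lemma, tb.lemma, ta.coarse_pos, tb.coarse_pos,
                taxonomy=taxonomy, min_path_sim=min_path_sim,
            )
    return S


def lexical_similarity(
    a: str, b: str, taxonomy: Taxonomy | None = None,
    min_path_sim: float = MIN_PATH_SIM,
) -> LexicalScore:
    """Length-penalized lexical similarity between two sentences.

    Symmetric; a sentence with no content tokens yields a defined 0.0
    result with the ``empty_input`` flag set.
    """
    try:
        ta, tb = lexical_preprocess(a), lexical_preprocess(b)
    except EmptyTokenSeqError:
        return LexicalScore(0.0, 0, 0, 0.0, 0.0, empty_input=True)
    S = word_similarity_matrix(ta, tb, taxonomy=taxonomy, min_path_sim=min_path_sim)
    word_sim = greedy_align(S)
    la, lb = len(ta), len(tb)
    penalty = abs(la - lb) * word_sim / max(la, lb)
    return LexicalScore(word_sim, la, lb, penalty, word_sim - penalty)
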