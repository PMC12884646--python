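"""Syntactic sentence similarity over filtered dependency triples.

Sentences are reduced to RDF-style triples (head, relation, dependent)
with lemmatized vertices, keeping only a fixed set of structurally
informative relations (subjects, objects, adverbial/adjectival modifiers,
auxiliaries, prepositions, negation, conjunctions, clausal complements);
determiners and punctuation never surface.  Triples are extracted by a
deterministic pattern grammar over the POS-tagged token sequence — a
lightweight parser sized for the short, subject-less behavioural
sentences this package analyses.

Triple-to-triple similarity averages a direct vertex alignment
(head-head, dependent-dependent) with a cross-wise one (head-dependent,
dependent-head), each vertex pair scored by the same hybrid
taxonomy/edit-distance word similarity as the lexical layer; relation
labels do not enter the score.  Sentence-level similarity aggregates the
triple-pair matrix with the same greedy alignment as the lexical layer;
no length penalty is applied by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .lexical import MIN_PATH_SIM, greedy_align, levenshtein_similarity
from .taxonomy import Taxonomy, default_taxonomy
from .textproc import coarse_pos, lemmatize, pos_tag, tokenize

RETAINED_RELATIONS = frozenset({
    "nsubj", "nsubjpass", "dobj", "iobj", "dative", "advmod", "prep", "pobj",
    "aux", "auxpass", "amod", "xcomp", "ccomp", "conj", "neg", "acomp",
})

_AUX_LEMMAS = {"be", "have", "do"}


@dataclass(frozen=True)
class DepTriple:
    head: str
    relation: str
    dependent: str

    def __post_init__(self) -> None:
        if self.relation not in RETAINED_RELATIONS:
            raise ValueError(f"relation {self.relation!r} not in retained set")


@dataclass(frozen=True)
class _Tok:
    i: int
    surface: str
    tag: str
    lemma: str

    @property
    def is_verb(self) -> bool:
        return self.tag.startswith("VB")

    @property
    def is_noun(self) -> bool:
        return self.tag.startswith("NN")


def _prepare(text: str) -> list[_Tok]:
    raw = [t for t in tokenize(text.lower()) if t.isalpha()]
    tagged = pos_tag(raw)
    return [
        _Tok(i, surface, tag, lemmatize(surface, coarse_pos(tag)))
        for i, (surface, tag) in enumerate(tagged)
    ]


def _classify_aux(toks: list[_Tok]) -> dict[int, int]:
    """Map aux-verb token index -> index of the main verb it supports."""
    aux: dict[int, int] = {}
    for t in toks:
        if t.tag == "MD" or (t.is_verb and t.lemma in _AUX_LEMMAS):
            for j in range(t.i + 1, min(t.i + 4, len(toks))):
                nxt = toks[j]
                if nxt.is_verb and not (nxt.lemma in _AUX_LEMMAS or nxt.tag == "MD"):
                    aux[t.i] = j
                    break
                if nxt.tag not in {"RB", "TO"} and not nxt.is_verb:
                    break
    return aux


def extract_triples(text: str) -> list[DepTriple]:
    """Extract filtered, lemmatized dependency triples from a sentence.

    Punctuation is stripped, tokens lowercased and lemmatized; only
    relations in :data:`RETAINED_RELATIONS` are emitted, ordered by the
    token position of the head (then of the dependent).  An empty or
    unparseable sentence yields an empty list.
    """
    toks = _prepare(text)
    if not toks:
        return []
    aux_of = _classify_aux(toks)
    main_verbs = [t for t in toks if t.is_verb and t.i not in aux_of]

    def main(i: int) -> _Tok:
        return toks[aux_of[i]] if i in aux_of else toks[i]

    def nearest_main_verb_left(i: int) -> _Tok | None:
        cands = [v for v in main_verbs if v.i < i]
        return cands[-1] if cands else None

    def chunk_head(start: int) -> _Tok | None:
        """Head (last noun) of a contiguous modifier+noun chunk at start."""
        j = start
        while j < len(toks) and toks[j].tag in {"DT", "PRP$", "JJ", "JJR", "JJS"}:
            j += 1
        if j >= len(toks) or not toks[j].is_noun:
            return None
        while j + 1 < len(toks) and toks[j + 1].is_noun:
            j += 1
        return toks[j]

    out: list[tuple[int, int, DepTriple]] = []

    def emit(head: _Tok, rel: str, dep: _Tok) -> None:
        out.append((head.i, dep.i, DepTriple(head.lemma, rel, dep.lemma)))

    for t in toks:
        # --- auxiliaries -------------------------------------------------
        if t.i in aux_of:
            m = toks[aux_of[t.i]]
            rel = "auxpass" if t.lemma == "be" and m.tag == "VBN" else "aux"
            emit(m, rel, t)
        if t.tag == "TO" and t.i + 1 < len(toks) and toks[t.i + 1].is_verb:
            v = toks[t.i + 1]
            emit(v, "aux", t)
            gov = nearest_main_verb_left(t.i)
            if gov is None:
                adjs = [a for a in toks if a.tag.startswith("JJ") and a.i < t.i]
                gov = adjs[-1] if adjs else None
            if gov is not None and gov.lemma != v.lemma:
                emit(gov, "xcomp", v)
        # --- adverbs and negation ---------------------------------------
        if t.tag in {"RB", "RBR", "RBS", "WRB"}:
            rel = "neg" if t.surface in {"not", "never"} else "advmod"
            target: _Tok | None = None
            if t.i > 0 and toks[t.i - 1].is_verb:
                target = main(t.i - 1)
            else:
                for j in range(t.i + 1, min(t.i + 4, len(toks))):
                    if toks[j].is_verb:
                        target = main(j)
                        break
                if target is None:
                    left = [v for v in toks if v.is_verb and v.i < t.i]
                    if left:
                        target = main(left[-1].i)
            if target is not None:
                emit(target, rel, t)
        # --- adjectival modifiers ---------------------------------------
        if t.tag.startswith("JJ"):
            j = t.i + 1
            while j < len(toks) and toks[j].tag.startswith("JJ"):
                j += 1
            if j < len(toks) and toks[j].is_noun:
                head = chunk_head(t.i + 1)
                if head is not None:
                    emit(head, "amod", t)
        # --- direct objects ---------------------------------------------
        if t.is_verb and t.i not in aux_of:
            j = t.i + 1
            while j < len(toks) and toks[j].tag in {"RP", "RB"}:
                j += 1
            head = chunk_head(j) if j < len(toks) else None
            if head is not None:
                emit(t, "dobj", head)
        # --- prepositions ------------------------------------------------
        if t.tag == "IN" and t.surface not in {"if", "that", "because", "while", "as"}:
            if t.i + 1 < len(toks) and toks[t.i + 1].tag == "IN":
                pass  # particle-like first element of a compound ("through on")
            else:
                obj = chunk_head(t.i + 1) if t.i + 1 < len(toks) else None
                if obj is not None:
                    gov = nearest_main_verb_left(t.i)
                    if gov is not None:
                        emit(gov, "prep", t)
                    emit(t, "pobj", obj)
        if t.tag == "TO" and not (t.i + 1 < len(toks) and toks[t.i + 1].is_verb):
            obj = chunk_head(t.i + 1) if t.i + 1 < len(toks) else None
            if obj is not None:
                emit(t, "pobj", obj)
        # --- subjects ----------------------------------------------------
        if t.is_noun:
            j = t.i + 1
            if j < len(toks) and toks[j].is_noun:
                pass  # not the chunk head
            else:
                k = j
                while k < len(toks) and toks[k].tag in {"RB"}:
                    k += 1
                if k < len(toks) and toks[k].is_verb:
                    m = main(k)
                    rel = (
                        "nsubjpass"
                        if m.tag == "VBN" and any(
                            a for a, mi in aux_of.items()
                            if mi == m.i and toks[a].lemma == "be"
                        )
                        else "nsubj"
                    )
                    emit(m, rel, t)
        # --- conjunctions -------------------------------------------------
        if t.tag == "CC":
            right: _Tok | None = None
            for j in range(t.i + 1, len(toks)):
                if toks[j].is_verb and toks[j].i not in aux_of:
                    right = toks[j]
                    break
                if toks[j].is_noun:
                    right = chunk_head(j) or toks[j]
                    break
                if toks[j].tag not in {"RB", "DT", "JJ", "PRP$", "TO"}:
                    break
            if right is not None:
                if right.is_verb:
                    left = nearest_main_verb_left(t.i)
                else:
                    nouns = [n for n in toks if n.is_noun and n.i < t.i]
                    left = nouns[-1] if nouns else nearest_main_verb_left(t.i)
                if left is not None and left.lemma != right.lemma:
                    emit(left, "conj", right)

    out.sort(key=lambda item: (item[0], item[1]))
    seen: set[DepTriple] = set()
    triples: list[DepTriple] = []
    for _, _, tr in out:
        if tr not in seen:
            seen.add(tr)
            triples.append(tr)
    return triples


def _vertex_similarity(a: str, b: str, taxonomy: Taxonomy) -> float:
    """Hybrid word similarity for triple vertices (POS unknown: best of
    noun/verb senses, Levenshtein fallback as in the lexical layer)."""
    if a == b:
        return 1.0
    best = None
    for pa in ("noun", "verb"):
        for pb in ("noun", "verb"):
            sim = taxonomy.word_path_similarity(a, pa, b, pb)
            if sim is not None and (best is None or sim > best):
                best = sim
    if best is None or best < MIN_PATH_SIM:
        return levenshtein_similarity(a, b)
    return best


def triple_similarity(
    t1: DepTriple, t2: DepTriple, taxonomy: Taxonomy | None = None
) -> float:
    """Mean of direct (head-head, dep-dep) and cross-wise (head-dep,
    dep-head) vertex alignments; relation labels are ignored; symmetric."""
    tax = taxonomy if taxonomy is not None else default_taxonomy()
    direct = 0.5 * (
        _vertex_similarity(t1.head, t2.head, tax)
        + _vertex_similarity(t1.dependent, t2.dependent, tax)
    )
    cross = 0.5 * (
        _vertex_similarity(t1.head, t2.dependent, tax)
        + _vertex_similarity(t1.dependent, t2.head, tax)
    )
    return 0.5 * (direct + cross)


def triple_similarity_matrix(
    ta: list[DepTriple], tb: list[DepTriple], taxonomy: Taxonomy | None = None
) -> np.ndarray:
    tax = taxonomy if taxonomy is not None else default_taxonomy()
    S = np.empty((len(ta), len(tb)))
    for i, x in enumerate(ta):
        for j, y in enumerate(tb):
            S[i, j] = triple_similarity(x, y, taxonomy=tax)
    return S


def syntactic_similarity(
    a: str,
    b: str,
    taxonomy: Taxonomy | None = None,
    length_penalty: bool = False,
) -> float:
    """Greedy-aligned triple-set similarity between two sentences.

    ``length_penalty`` optionally applies the lexical layer's asymmetry
    penalty to the triple counts (off by default).  If either sentence
    yields no retained triples the result is 0.0 and a warning is issued.
    """
    ta, tb = extract_triples(a), extract_triples(b)
    if not ta or not tb:
        warnings.warn("sentence yielded no retained dependency triples; score 0.0")
        return 0.0
    score = greedy_align(triple_similarity_matrix(ta, tb, taxonomy=taxonomy))
    if length_penalty:
        la, lb = len(ta), len(tb)
        score -= abs(la - lb) * score / max(la, lb)
    return score
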