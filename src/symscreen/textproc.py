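"""Deterministic text preprocessing: tokenization, POS tagging, lemmatization.

The package ships a self-contained, fully deterministic preprocessing stack
sized for short behavioural sentences: a regex word tokenizer, a standard
English stopword list, a lexicon-plus-suffix-rule Penn Treebank tagger and a
rule-based lemmatizer in the style of WordNet's morphy (suffix-stripping
candidates validated against the package vocabulary, with an irregular-form
exception table).  Penn tags are mapped onto the four coarse categories
(noun, verb, adjective, adverb) that drive POS-aware lemmatization and
taxonomy lookup; unmappable tags default to noun.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Iterable

__all__ = [
    "Token",
    "TokenSeq",
    "EmptyTokenSeqError",
    "tokenize",
    "stopwords",
    "pos_tag",
    "lemmatize",
    "coarse_pos",
    "lexical_preprocess",
]

_WORD_RE = re.compile(r"[A-Za-z]+(?:'[A-Za-z]+)?|\d+|[^\w\s]")
# curly quotes/dashes normalized before tokenization; storage keeps originals
_PUNCT_MAP = str.maketrans({"“": '"', "”": '"', "‘": "'", "’": "'", "–": "-", "—": "-"})

NOUN, VERB, ADJ, ADV = "noun", "verb", "adjective", "adverb"

_COARSE = {
    "NN": NOUN, "NNS": NOUN, "NNP": NOUN, "NNPS": NOUN,
    "VB": VERB, "VBD": VERB, "VBG": VERB, "VBN": VERB, "VBP": VERB, "VBZ": VERB,
    "JJ": ADJ, "JJR": ADJ, "JJS": ADJ,
    "RB": ADV, "RBR": ADV, "RBS": ADV, "WRB": ADV,
}

_DETERMINERS = {"the", "a", "an", "this", "that", "these", "those"}
_POSSESSIVES = {"their", "his", "her", "my", "your", "our", "its"}

_FUNCTION_TAGS = {
    "to": "TO", "of": "IN", "in": "IN", "on": "IN", "by": "IN", "with": "IN",
    "for": "IN", "at": "IN", "from": "IN", "before": "IN", "after": "IN",
    "during": "IN", "as": "IN", "if": "IN", "when": "WRB", "while": "IN",
    "because": "IN", "that": "IN", "than": "IN", "and": "CC", "or": "CC",
    "but": "CC", "nor": "CC", "not": "RB", "no": "DT", "the": "DT", "a": "DT",
    "an": "DT", "this": "DT", "these": "DT", "those": "DT", "is": "VBZ",
    "are": "VBP", "was": "VBD", "were": "VBD", "be": "VB", "been": "VBN",
    "being": "VBG", "has": "VBZ", "have": "VBP", "had": "VBD", "having": "VBG",
    "do": "VB", "does": "VBZ", "did": "VBD", "doing": "VBG", "will": "MD",
    "would": "MD", "can": "MD", "could": "MD", "may": "MD", "must": "MD",
    "should": "MD", "it": "PRP", "he": "PRP", "she": "PRP", "they": "PRP",
    "them": "PRP", "him": "PRP", "her": "PRP$", "their": "PRP$", "his": "PRP$",
    "my": "PRP$", "your": "PRP$", "our": "PRP$", "its": "PRP$", "who": "WP",
    "what": "WP", "which": "WDT", "most": "JJS", "more": "JJR", "all": "DT",
    "some": "DT", "any": "DT", "each": "DT", "both": "DT", "very": "RB",
    "too": "RB", "so": "RB", "up": "RP", "down": "RP", "out": "RP", "off": "RP",
    "over": "IN", "there": "EX", "seems": "VBZ",
}

# irregular inflections that suffix rules cannot recover
_LEMMA_EXCEPTIONS = {
    VERB: {
        "is": "be", "are": "be", "was": "be", "were": "be", "been": "be",
        "being": "be", "am": "be", "has": "have", "had": "have",
        "having": "have", "does": "do", "did": "do", "done": "do",
        "driven": "drive", "drove": "drive", "spoken": "speak",
        "spoke": "speak", "ran": "run", "left": "leave", "lost": "lose",
        "made": "make", "gave": "give", "given": "give", "went": "go",
        "gone": "go", "sat": "sit", "felt": "feel", "broke": "break",
        "broken": "break", "slept": "sleep", "hit": "hit", "bit": "bite",
        "bitten": "bite", "lay": "lie", "lied": "lie", "kept": "keep",
        "got": "get", "gotten": "get", "said": "say", "heard": "hear",
        "thought": "think", "forgot": "forget", "forgotten": "forget",
    },
    NOUN: {
        "feet": "foot", "children": "child", "people": "people",
        "stimuli": "stimulus", "men": "man", "women": "woman",
        "teeth": "tooth", "mice": "mouse", "lives": "life",
        "belongings": "belongings",
    },
    ADJ: {"better": "good", "best": "good", "worse": "bad", "worst": "bad"},
    ADV: {},
}

# (suffix, replacements-in-priority-order)
_SUFFIX_RULES = {
    NOUN: [
        ("ies", ["y"]),
        ("ves", ["f", "fe"]),
        ("ches", ["ch"]),
        ("shes", ["sh"]),
        ("sses", ["ss"]),
        ("xes", ["x"]),
        ("zes", ["z"]),
        ("ses", ["s"]),
        ("s", [""]),
    ],
    VERB: [
        ("ies", ["y"]),
        ("ches", ["ch"]),
        ("shes", ["sh"]),
        ("sses", ["ss"]),
        ("es", ["e", ""]),
        ("s", [""]),
        ("ing", ["", "e"]),
        ("ed", ["", "e"]),
    ],
    ADJ: [("er", ["", "e"]), ("est", ["", "e"])],
    ADV: [],
}


class EmptyTokenSeqError(ValueError):
    """Sentence reduced to zero content tokens after preprocessing."""


@dataclass(frozen=True)
class Token:
    surface: str
    penn_pos: str
    coarse_pos: str
    lemma: str


@dataclass(frozen=True)
class TokenSeq:
    tokens: tuple[Token, ...]

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)

    @property
    def lemmas(self) -> list[str]:
        return [t.lemma for t in self.tokens]


@lru_cache(maxsize=1)
def stopwords() -> frozenset[str]:
    text = resources.files("symscreen.data").joinpath("stopwords.txt").read_text()
    return frozenset(w.strip() for w in text.splitlines() if w.strip())


@lru_cache(maxsize=1)
def _lexicon() -> dict[str, str]:
    text = resources.files("symscreen.data").joinpath("tag_lexicon.tsv").read_text()
    lex: dict[str, str] = {}
    for line in text.splitlines():
        if line.strip():
            word, tag = line.split("\t")
            lex[word] = tag
    return lex


def tokenize(text: str) -> list[str]:
    """Split a sentence into word/punctuation tokens (case preserved)."""
    return _WORD_RE.findall(text.translate(_PUNCT_MAP))


def coarse_pos(penn_tag: str) -> str:
    """Map a Penn Treebank tag to noun/verb/adjective/adverb (default noun)."""
    return _COARSE.get(penn_tag, NOUN)


def _suffix_guess(word: str) -> str:
    if word.endswith("ly"):
        return "RB"
    if word.endswith("ing"):
        return "VBG"
    if word.endswith("ed"):
        return "VBD"
    if word.endswith(("ful", "ous", "ive", "able", "ible", "al", "ish", "less")):
        return "JJ"
    if word.endswith("s") and not word.endswith(("ss", "us", "is")):
        stem = word[:-1]
        if _lexicon().get(stem) == "VB":
            return "VBZ"
        return "NNS"
    return "NN"


def pos_tag(tokens: list[str]) -> list[tuple[str, str]]:
    """Tag lowercase word tokens with Penn Treebank tags.

    Lookup order: function-word table, context adjustments (a verb reading
    after a determiner/possessive becomes nominal; a nominal reading right
    after "to" or a modal becomes a base verb), bundled content lexicon,
    then suffix heuristics for out-of-vocabulary words.
    """
    tags: list[tuple[str, str]] = []
    prev_surface = ""
    for tok in tokens:
        w = tok.lower()
        if not w.isalpha():
            tags.append((tok, "." if not w.isdigit() else "CD"))
            prev_surface = w
            continue
        tag = _FUNCTION_TAGS.get(w) or _lexicon().get(w) or _suffix_guess(w)
        if tag.startswith("VB") and prev_surface in _DETERMINERS | _POSSESSIVES:
            tag = "NNS" if w.endswith("s") and not w.endswith("ss") else "NN"
        elif tag in {"NN", "NNS"} and prev_surface in {"to"}:
            base = w[:-1] if w.endswith("s") else w
            if _lexicon().get(base, "").startswith("VB") or _lexicon().get(w, "") == "VB":
                tag = "VB"
        tags.append((tok, tag))
        prev_surface = w
    return tags


def _known(word: str, pos: str) -> bool:
    from . import taxonomy  # local import to avoid cycle at module load

    if word in _lexicon():
        return True
    return taxonomy.default_taxonomy().has_lemma(word, pos)


def lemmatize(word: str, pos: str = NOUN) -> str:
    """Reduce a lowercase word to its base form for the given coarse POS.

    Tries the irregular-form table, then suffix-stripping candidates in rule
    order, preferring the first candidate found in the package vocabulary
    (tag lexicon or taxonomy); falls back to the first raw candidate, then
    the word itself.
    """
    w = word.lower()
    exc = _LEMMA_EXCEPTIONS.get(pos, {})
    if w in exc:
        return exc[w]
    candidates: list[str] = []
    for suffix, replacements in _SUFFIX_RULES.get(pos, []):
        if w.endswith(suffix) and len(w) > len(suffix) + 1:
            stem = w[: -len(suffix)]
            for rep in replacements:
                candidates.append(stem + rep)
                # undouble a final consonant (running -> run, tapping -> tap)
                if not rep and len(stem) >= 2 and stem[-1] == stem[-2]:
                    candidates.append(stem[:-1])
    if _known(w, pos):
        # an in-vocabulary surface form may still be inflected (e.g. "fails")
        for cand in candidates:
            if cand != w and _known(cand, pos):
                return cand
        return w
    for cand in candidates:
        if _known(cand, pos):
            return cand
    return candidates[0] if candidates else w


def lexical_preprocess(text: str) -> TokenSeq:
    """Full lexical-layer preprocessing pipeline.

    Order: lowercase, tokenize, drop stopwords, keep alphabetic-only tokens,
    POS-tag, map tags to coarse categories, lemmatize with the coarse POS.
    Raises :class:`EmptyTokenSeqError` when nothing survives.
    """
    if not text or not text.strip():
        raise EmptyTokenSeqError("empty input text")
    raw = tokenize(text.lower())
    sw = stopwords()
    content = [t for t in raw if t.isalpha() and t not in sw]
    if not content:
        raise EmptyTokenSeqError(f"no content tokens in {text!r}")
    tagged = pos_tag(content)
    tokens = []
    for surface, penn in tagged:
        cp = coarse_pos(penn)
        tokens.append(Token(surface, penn, cp, lemmatize(surface, cp)))
    return TokenSeq(tuple(tokens))
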