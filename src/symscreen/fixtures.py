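"""Deterministic synthetic data: stub embedder and questionnaire generator.

Everything downstream of the embedding backend must be testable offline,
so this module provides (a) a seeded, hash-based stub embedding backend
whose vectors are pure functions of the text, and (b) a generator of
synthetic questionnaire corpora: paraphrases of a labelled base corpus
(inheriting the source item's domain label) mixed with templated
non-ADHD behavioural distractor items.

The stub embedder is compositional: each token hashes to a fixed
pseudo-random Gaussian direction and a sentence embeds as the unit-
normalized sum of its token vectors.  Identical texts embed identically;
unrelated texts are near-orthogonal in 768 dimensions; paraphrases that
share most of their vocabulary stay close — the geometry (not the
semantics) that makes the synthetic suite separable by construction.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np

from .corpus import Corpus, SymptomStatement

PERTURBATION_OPS = ("synonym_swap", "clause_reorder", "filler_insert", "verbatim_copy")

_FILLERS = (
    "at home or in school",
    "during daily routines",
    "according to caregivers",
    "in most settings",
)

# templated non-ADHD behavioural sentences (conduct / oppositional /
# depressive language) used as distractors; synthetic, not drawn from any
# copyrighted instrument
_DISTRACTOR_TEMPLATES = (
    "Often argues with adults and refuses to comply with requests",
    "Often deliberately annoys people and blames others for misbehavior",
    "Often feels sad empty or hopeless for most of the day",
    "Has lost interest or pleasure in most daily routines",
    "Often starts physical fights and bullies or threatens peers",
    "Often destroys property or breaks belongings on purpose",
    "Often defies rules at school and is spiteful or vindictive",
    "Sleeps too little or too much on most nights",
    "Often feels worthless with excessive guilt and low energy",
    "Often cries easily and complains of headaches or stomach aches",
    "Shows marked fatigue and loss of appetite on most days",
    "Often loses temper and has tantrums over minor requests",
)


def _token_vector(token: str, dim: int, seed: int) -> np.ndarray:
    digest = hashlib.sha256(f"{seed}:{token}".encode()).digest()
    rng = np.random.default_rng(int.from_bytes(digest[:8], "little"))
    return rng.standard_normal(dim)


@dataclass
class StubEmbedder:
    """Offline deterministic embedding backend (hash-based, unit-norm)."""

    seed: int = 0
    dim: int = 768
    _token_cache: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def name(self) -> str:
        return f"stub-{self.seed}-{self.dim}"

    def _tokens(self, text: str) -> list[str]:
        return re.findall(r"[a-z]+", text.lower())

    def embed(self, texts: Sequence[str]) -> np.ndarray:
        out = np.empty((len(texts), self.dim))
        for i, text in enumerate(texts):
            tokens = self._tokens(text) or ["<empty>"]
            vec = np.zeros(self.dim)
            for tok in tokens:
                if tok not in self._token_cache:
                    self._token_cache[tok] = _token_vector(tok, self.dim, self.seed)
                vec += self._token_cache[tok]
            norm = np.linalg.norm(vec)
            out[i] = vec / norm if norm > 0 else vec
        return out


def stub_embed(texts: Sequence[str], seed: int = 0, dim: int = 768) -> np.ndarray:
    """Convenience wrapper: embed texts with a fresh :class:`StubEmbedder`."""
    return StubEmbedder(seed=seed, dim=dim).embed(texts)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic questionnaire corpus.

    ``n_adhd_paraphrases`` items are generated per ADHD domain present in
    the base corpus, each a perturbation of a base statement and labelled
    with the source's domain; ``n_distractors`` templated non-ADHD items
    are appended.  Fully reproducible from ``seed``.
    """

    n_adhd_paraphrases: int = 5
    n_distractors: int = 10
    perturbations: tuple[str, ...] = ("synonym_swap",)
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.perturbations) - set(PERTURBATION_OPS)
        if unknown:
            raise ValueError(f"unknown perturbation ops: {sorted(unknown)}")
        if self.n_adhd_paraphrases < 0 or self.n_distractors < 0:
            raise ValueError("counts must be non-negative")
        if self.n_adhd_paraphrases + self.n_distractors == 0:
            raise ValueError("spec generates zero items")


def _synonym_table() -> dict[str, str]:
    text = resources.files("symscreen.data").joinpath("synonyms.json").read_text()
    table = json.loads(text)
    table.pop("_comment", None)
    return table


def _apply_synonym_swap(text: str, rng: np.random.Generator) -> str:
    table = _synonym_table()
    words = text.split()
    hits = [i for i, w in enumerate(words) if w.lower() in table]
    if not hits:
        return text
    # swap a random subset (at least one) of the swappable words
    n_swap = 1 + int(rng.integers(0, len(hits)))
    for i in rng.choice(hits, size=n_swap, replace=False):
        w = words[i]
        rep = table[w.lower()]
        words[i] = rep.capitalize() if w[0].isupper() else rep
    return " ".join(words)


def _apply_clause_reorder(text: str, rng: np.random.Generator) -> str:
    for sep in (" or ", " and "):
        if sep in text:
            left, right = text.split(sep, 1)
            return f"{right[0].upper()}{right[1:]}{sep}{left[0].lower()}{left[1:]}"
    return text


def _apply_filler_insert(text: str, rng: np.random.Generator) -> str:
    filler = _FILLERS[int(rng.integers(len(_FILLERS)))]
    return f"{text} {filler}"


_PERTURB_FUNCS = {
    "synonym_swap": _apply_synonym_swap,
    "clause_reorder": _apply_clause_reorder,
    "filler_insert": _apply_filler_insert,
    "verbatim_copy": lambda text, rng: text,
}


def generate_questionnaire(spec: SyntheticSpec, base: Corpus) -> Corpus:
    """Generate a labelled synthetic questionnaire corpus from a base corpus.

    Paraphrase items carry the source statement's domain label and a
    ``source`` field naming the base item; distractors are labelled
    ``non_adhd``.  Byte-identical output for identical (spec, base).
    """
    rng = np.random.default_rng(spec.seed)
    items: list[SymptomStatement] = []
    domains = [d for d in ("inattention", "hyperactivity_impulsivity")
               if len(base.subset(d)) > 0]
    for domain in domains:
        pool = base.subset(domain)
        for j in range(spec.n_adhd_paraphrases):
            src = pool[int(rng.integers(len(pool)))]
            op = spec.perturbations[int(rng.integers(len(spec.perturbations)))]
            text = _PERTURB_FUNCS[op](src.text, rng)
            items.append(
                SymptomStatement(
                    id=f"syn-{domain[:2]}-{j:03d}",
                    text=text,
                    domain=domain,
                    source=f"synthetic:{op}:{src.id}",
                )
            )
    for j in range(spec.n_distractors):
        tpl = _DISTRACTOR_TEMPLATES[j % len(_DISTRACTOR_TEMPLATES)]
        if j >= len(_DISTRACTOR_TEMPLATES):
            tpl = _apply_filler_insert(tpl, rng)
        items.append(
            SymptomStatement(
                id=f"syn-nd-{j:03d}",
                text=tpl,
                domain="non_adhd",
                source="synthetic:distractor",
            )
        )
    return Corpus(tuple(items))
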