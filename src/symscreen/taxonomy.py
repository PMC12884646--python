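"""Hypernym taxonomy and taxonomy path similarity.

A WordNet-style resource: lemmas map to one or more synsets, synsets carry
hypernym links forming a DAG.  Nouns are rooted at a single top synset;
verb sub-hierarchies are joined by a virtual root (mirroring how verb
taxonomies are handled in standard lexical databases) so a path exists
between any two synsets of the same part of speech.  Path similarity
between two synsets is 1 / (1 + d) with d the shortest path length through
the (undirected) hypernym graph; word-level similarity takes the maximum
over all sense pairs.

The bundled taxonomy is hand-curated for the vocabulary of the DSM-5 ADHD
statements and the synthetic fixtures; its version string is recorded in
outputs because layer scores shift with the resource.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import networkx as nx

_VIRTUAL_ROOTS = {"n": "*root*.n", "v": "*root*.v"}
_POS_ALIASES = {"noun": "n", "verb": "v", "n": "n", "v": "v"}

TAXONOMY_VERSION = "symscreen-minitax-1"


@dataclass(frozen=True)
class Taxonomy:
    graph: nx.Graph                       # undirected hypernym edges + virtual roots
    lemmas: dict[str, tuple[str, ...]]    # "lemma|pos" -> synset ids
    version: str = TAXONOMY_VERSION
    _dist_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def _distances_from(self, source: str) -> dict[str, int]:
        if source not in self._dist_cache:
            self._dist_cache[source] = nx.single_source_shortest_path_length(
                self.graph, source
            )
        return self._dist_cache[source]

    def has_lemma(self, lemma: str, pos: str) -> bool:
        p = _POS_ALIASES.get(pos)
        return p is not None and f"{lemma}|{p}" in self.lemmas

    def senses(self, lemma: str, pos: str) -> tuple[str, ...]:
        p = _POS_ALIASES.get(pos)
        if p is None:
            return ()
        return self.lemmas.get(f"{lemma}|{p}", ())

    def path_similarity(self, s1: str, s2: str) -> float | None:
        """1/(1+shortest path) between two synsets, None if disconnected."""
        if s1 == s2:
            return 1.0
        if s1 not in self.graph or s2 not in self.graph:
            return None
        d = self._distances_from(s1).get(s2)
        if d is None:
            return None
        return 1.0 / (1.0 + d)

    def word_path_similarity(self, a: str, pos_a: str, b: str, pos_b: str) -> float | None:
        """Maximum path similarity over all sense pairs; None when either
        word lacks senses or no sense pair is connected."""
        sa, sb = self.senses(a, pos_a), self.senses(b, pos_b)
        if not sa or not sb:
            return None
        best = None
        for x in sa:
            for y in sb:
                sim = self.path_similarity(x, y)
                if sim is not None and (best is None or sim > best):
                    best = sim
        return best


def _build(synsets: dict[str, list[str]], lemmas: dict[str, list[str]], version: str) -> Taxonomy:
    g = nx.Graph()
    g.add_nodes_from(synsets)
    for sid, hypernyms in synsets.items():
        for h in hypernyms:
            if h not in synsets:
                raise ValueError(f"synset {sid} names unknown hypernym {h}")
            g.add_edge(sid, h)
    # join each POS's root synsets under a virtual root so every same-POS
    # pair is connected (nouns typically have one real root already)
    for sid, hypernyms in synsets.items():
        if not hypernyms:
            pos = sid.rsplit(".", 1)[-1]
            root = _VIRTUAL_ROOTS.get(pos)
            if root is not None:
                g.add_edge(root, sid)
    for key, sids in lemmas.items():
        for s in sids:
            if s not in synsets:
                raise ValueError(f"lemma {key} names unknown synset {s}")
    return Taxonomy(g, {k: tuple(v) for k, v in lemmas.items()}, version)


def load_taxonomy(path=None) -> Taxonomy:
    """Load a taxonomy from a JSON file (bundled resource by default)."""
    if path is None:
        text = resources.files("symscreen.data").joinpath("taxonomy.json").read_text()
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    data = json.loads(text)
    return _build(data["synsets"], data["lemmas"], data.get("version", TAXONOMY_VERSION))


@lru_cache(maxsize=1)
def default_taxonomy() -> Taxonomy:
    return load_taxonomy()
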