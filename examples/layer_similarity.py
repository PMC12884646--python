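"""Score one sentence pair on all three similarity layers.

Lexical: POS-aware lemmas, hybrid taxonomy/edit-distance word scores,
greedy alignment, length penalty.  Syntactic: greedy alignment of filtered
dependency triples.  Semantic: embedding cosine (deterministic stub
backend here; swap in a sentence-transformer backend for published-model
scores).
"""

import symscreen as ss

dsm5 = ss.load_bundled("dsm5_adhd")
a = dsm5.get("inattention", 2).text   # sustaining attention in tasks/play
b = dsm5.get("inattention", 5).text   # organizing tasks and activities
print("A:", a)
print("B:", b)

lex = ss.lexical_similarity(a, b)
print(f"lexical  : {lex.final:.3f} "
      f"(word alignment {lex.word_sim:.3f}, length penalty {lex.penalty:.3f})")
print(f"syntactic: {ss.syntactic_similarity(a, b):.3f}")

backend = ss.StubEmbedder(seed=1)
pair_corpus = ss.Corpus((dsm5.get("inattention", 2), dsm5.get("inattention", 5)))
sem = ss.cosine_pairwise(backend, pair_corpus).M[0, 1]
print(f"semantic : {sem:.3f}  (stub backend)")

print("\ntriples of A:")
for t in ss.extract_triples(a):
    print(f"  ({t.head}, {t.relation}, {t.dependent})")

# Each layer sees a different facet of the pair: shared vocabulary
# (lexical), shared grammatical structure (syntactic) and shared overall
# meaning (semantic).  This pair is among the most similar in its domain.
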