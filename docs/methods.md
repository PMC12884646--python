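# Methods

## Scope and data model

`symscreen` analyses short clinical sentences: the 18 core DSM-5 ADHD
symptom statements (bundled verbatim, including the source's
typographical quirks, with curly quotes preserved in storage) and
questionnaire-style items. Two 36-row layer-score tables — one per
symptom domain, rows = unordered symptom pairs (1-based indices, stored
as (low, high)), columns = lexical/syntactic/semantic scores plus a
reference combined column — are bundled as package data and are the
substrate for the weighting and statistics modules.

## Lexical layer

Pipeline order is fixed: lowercase → tokenize → drop stopwords → keep
alphabetic tokens → Penn-Treebank POS tag → map to
noun/verb/adjective/adverb (unmappable tags default to noun) → lemmatize
with the coarse POS. POS-aware lemmatization matters: "leaves" in
"often leaves seat…" is a verb and must become "leave", not the
noun-default "leaf".

The preprocessing stack is self-contained and deterministic: a bundled
standard English stopword list; a tagger that consults a function-word
table, a content-word lexicon sized for this vocabulary, two context
adjustments (nominal reading after a determiner/possessive, base-verb
reading after "to") and suffix heuristics; and a rule lemmatizer in the
morphy style (irregular-form table, then suffix-stripping candidates
validated against the package vocabulary, with final-consonant
undoubling). This stack is a first-class component of the package, sized
deliberately for short behavioural sentences rather than open-domain
text; its tag lexicon and exception tables are data files a user can
extend.

Word similarity is hybrid: taxonomy path similarity `1/(1 + d)` (d =
shortest hypernym-path length), maximized over all sense pairs, when
both words have same-POS senses and the best path scores ≥ 0.1 (the
`min_path_sim` floor); otherwise normalized Levenshtein similarity
`1 − dist/max(len)` (edit distance via edlib). Max-over-senses was
chosen over first-sense because it is deterministic and standard when no
sense-disambiguation step exists. The bundled taxonomy is hand-curated
(~200 synsets) for the DSM-5 ADHD vocabulary plus the synthetic-fixture
vocabulary: nouns root at a single top synset; verb sub-hierarchies are
joined by a virtual root so same-POS paths always exist; adjectives and
adverbs have no hypernym structure and always use the edit-distance
fallback, mirroring how adjective/adverb similarity is undefined in
standard lexical databases. The taxonomy version string is recorded in
run manifests because layer scores move with the resource.

Greedy alignment: repeatedly select the global maximum of the word-pair
matrix (ties broken by smallest (row, col) lexicographically — row-major
argmax gives this for free), retire its row and column, stop after
`min(rows, cols)` iterations, return the accumulated sum divided by the
iteration count. This is greedy, not the optimal assignment, by design;
the test suite pins the distinction ([[0.9, 0.8], [0.85, 0.1]] → 0.5,
not 0.825). The length penalty `|lₐ − l_b|·sim/max(lₐ, l_b)` is
subtracted last; equal-length sentences are never penalized, and the
penalty can never push the score below zero.

A sentence that preprocesses to zero content tokens yields a defined
0.0 score with an `empty_input` flag rather than an exception, so batch
computations over messy questionnaires do not abort.

## Syntactic layer

Preprocessing here only strips punctuation, lowercases and lemmatizes —
function words are needed for structure. Sentences are reduced to
(head, relation, dependent) triples by a deterministic pattern grammar
over the tagged token sequence (auxiliary chains, "to"-infinitives with
xcomp to the governing verb or adjective, adverb/negation attachment,
adjectival modifiers, direct objects through particle/modifier chunks,
prepositional phrases with their objects, noun and verb conjunction).
Only a fixed relation set is retained — nsubj, nsubjpass, dobj, iobj,
dative, advmod, prep, pobj, aux, auxpass, amod, xcomp, ccomp, conj, neg,
acomp — so determiners and punctuation never surface. The retained set
is the closed union of relations observed in the reference triple
inventories plus the subject/object relations those inventories imply.
On the first inattention statement the extractor reproduces the full
nine-triple reference parse, including ('fail','advmod','often') and
('make','dobj','mistake').

Triple similarity averages a direct (head–head, dependent–dependent) and
a cross-wise (head–dependent, dependent–head) vertex alignment, each
vertex pair scored by the lexical layer's hybrid word measure with POS
unknown (best of noun/verb senses). Relation labels never enter the
score, which makes the measure invariant under a simultaneous
head/dependent swap of both triples — asserted as a property test. A
triple compared with itself scores below 1 whenever its own head and
dependent are dissimilar (the cross terms see to that); this is a
property of the formula, not a bug.

Sentence-level syntactic similarity greedy-aligns the triple-pair matrix
exactly as the lexical layer aligns words. No length penalty is applied
by default; a `length_penalty` switch exists because the aggregation
could defensibly discount asymmetric triple counts, but the default
follows the narrower reading that the penalty belongs to the lexical
layer only. A sentence yielding no retained triples scores 0.0 with a
warning.

## Semantic layer

Backends implement a minimal contract (name, dim, `embed`), must be
deterministic, and are wrapped in an embedding cache keyed by text. The
registry exposes the biomedical sentence-transformer
`pritamdeka/S-Biomed-Roberta-snli-multinli-stsb` (the clinical reference,
768-d), the general-purpose `all-mpnet-base-v2`, and the offline stub.
The transformer backends import `sentence-transformers` lazily behind
the optional `transformers` extra; every test and default pipeline runs
on the stub. Pairwise cosine matrices are validated (symmetry, unit
diagonal, entries in [−1, 1]) and backend agreement is measured by
Spearman rank correlation over the 36 upper-triangle entries — rank,
not value, because absolute cosine scales differ across embedding
spaces.

The stub embedder hashes each token to a fixed pseudo-random Gaussian
direction (SHA-256 of seed:token seeding a generator) and embeds a
sentence as the unit-normalized sum of its token vectors. The design is
compositional on purpose: identical texts embed identically; unrelated
texts are near-orthogonal in 768 dimensions (|cos| < 0.2 for ≥ 95% of
random pairs); paraphrases that share most vocabulary stay close. That
geometry is what makes the synthetic test suite separable by
construction — it exercises the pipeline's code paths, not the
semantics of any trained model.

## Entropy-weight fusion and thresholds

The Entropy Weight Method steps are implemented exactly as stated in the
package docstrings: column normalization to probabilities, zero
replacement at 1e-10, k = 1/ln(m), entropy, divergence, weight
normalization, natural logarithms throughout. Combined scores multiply
the *original* (not normalized) layer values by the weights, so each
combined score is a convex combination bounded by the row's extremes.
Properties pinned by tests: weights sum to 1, a uniform column gets
entropy 1 and weight 0, rescaling a column leaves all weights unchanged,
and a `math.fsum`-based independent re-evaluation agrees to 1e-12.

On the bundled tables the weights are (0.35, 0.16, 0.49) for inattention
and (0.21, 0.04, 0.75) for hyperactivity/impulsivity (two decimals), and
the flagged pairs are inattention (2,5) at 0.62 and (5,7) at 0.58, and
hyperactivity (1,2) at 0.49.

Redundancy selection uses the 99th percentile ("top 1st percentile") by
linear interpolation (rank position p/100·(n−1) on the ascending sort),
relaxed downward by 0.03 on the 0–1 similarity scale; the relaxation is
applied on the lower side only. The "±3" relaxation is interpreted as
0.03 because that is the only reading that reproduces both the
published pair counts (4 semantic-layer inattention pairs; 2
combined-score pairs) and the printed cutoffs. One known discrepancy: the
99th percentile of the hyperactivity combined column is 0.46, while the
reference analysis quotes 0.47 for that domain (matching its semantic
column instead); pair selection is identical under either cutoff with
the 0.03 relaxation, so the package reports what it computes.

## Layer-validation statistics

- Wilcoxon signed-rank, two-sided, zero differences dropped before
  ranking, statistic = min of positive/negative rank sums, normal
  approximation for n > 25 and the exact distribution otherwise. This
  combination recomputes the reference statistics from the bundled
  tables (141, 79, 88, 86). With n = 36 the approximate two-sided p for
  the semantic-vs-lexical comparison is 0.0026 (the exact value is
  0.002); tests assert the statistic exactly and the p to 1e-3.
- Mutual information via the k-nearest-neighbour (Kraskov-family)
  estimator with k = 3, seeded noise, negative estimates clipped to 0.
  On the bundled hyperactivity table the syntactic–semantic MI is
  exactly 0 (statistical independence); property tests check near-zero
  MI under simulated independence and monotone growth with dependence
  strength.
- Class-imbalance chi-square: one-degree-of-freedom goodness of fit
  against equal counts, algebraically (a−b)²/(a+b); (18, 32) gives
  3.920, p = 0.048.

No multiple-testing correction is applied across the four layer
comparisons.

## Screening pipeline

Filter: logistic regression (max_iter = 1000, otherwise defaults) on
backend embeddings, positive class = ADHD. ADASYN oversampling is
implemented in-package: each minority sample's share of majority points
among its k = 5 nearest neighbours (in the full embedding space) sets
its synthetic-sample allocation, synthetic points interpolate toward
random minority neighbours, the generator is seeded, and allocation
remainders are distributed deterministically by weight rank; when the
minority class is isolated the allocation falls back to uniform. Post-
resampling class counts land within ±2 of equal.

Subtype features: for each layer, mean similarity of the item to all
inattention exemplars minus mean similarity to all hyperactivity/
impulsivity exemplars (positive = inattention-leaning; the sign
convention is the package's choice). The means run over *all* exemplars
— including the item itself when it appears verbatim among them — so
that training items (drawn from the exemplar set) and test items
(paraphrases whose near-duplicate source sits in the exemplar set) live
on the same feature scale. An `exclude_self` switch provides the
alternative; with it, training features lose the own-domain boost that
test paraphrases retain, a train/test distribution shift that measurably
degrades forest generalization on the synthetic suite.

Subtype classifiers: random forest (100 trees, random_state 42),
RBF-kernel SVC with probability estimates, logistic regression — all at
fixed defaults, no hyper-parameter search, so performance differences
reflect model character. Evaluation reports accuracy, precision, recall,
F1, specificity and rank-statistic AUC with class 1
(hyperactivity/impulsivity) positive, plus the 2×2 confusion counts and
a per-class table; every scalar is recomputable from the confusion
counts, and AUC is reported absent for single-class truth.

## Leakage control and bootstrap

Overlap exclusion removes a test item when its embedding cosine with ANY
training statement reaches the cutoff (default 0.90 — near-duplicate or
paraphrase-equivalent territory, well above topical relatedness);
training items are never removed. Lowering the cutoff can only shrink
the retained set (monotonicity is property-tested).

Bootstrap: 30 iterations by default, each resampling the test items with
replacement at full size; the fitted model is not refit. Iteration i
uses seed + i, so two conditions evaluated with the same base seed share
resample indices and are paired by iteration; permuting iterations
identically in both conditions leaves the paired t unchanged. The 95%
CI on a mean accuracy difference uses the Student-t quantile with B − 1
degrees of freedom. Zero-variance differences (e.g., two identical
accuracy vectors) make t undefined; the comparison then reports the mean
difference with a degenerate CI rather than a spurious statistic. A
coverage property test (200 seeded replications of binomially simulated
correctness at p = 0.8, n = 40, B = 30, CI = mean ± t·SD of the
bootstrap distribution) requires ≥ 85% coverage of the true accuracy.

## Synthetic data

The generator emulates the role questionnaire items play — ADHD
paraphrases plus non-ADHD behavioural distractors — without claiming
clinical realism. Perturbation operators: `synonym_swap` (hand-curated
surface synonyms within the package vocabulary, no external thesaurus),
`clause_reorder` (swap around the first "or"/"and"), `filler_insert`
(append a contextual filler phrase), `verbatim_copy`. Paraphrases
inherit the source statement's domain label and carry a provenance tag
naming the source; distractors are templated conduct/oppositional/
depressive-language sentences labelled non-ADHD. Output is byte-identical
for identical (spec, seed).

Defaults (5 paraphrases per domain, 10 distractors, synonym-swap only)
represent the mild-perturbation regime; the end-to-end property — filter
accuracy ≥ 0.9 and subtype accuracy ≥ 0.9 with the stub backend — holds
in that regime by construction (paraphrases share most vocabulary with
their sources; distractors use disjoint vocabulary). What passing shows:
the pipeline's stages compose correctly and its decision boundaries
behave as designed on separable data. What it does not show: performance
on real questionnaires under trained embeddings, which depends on model
weights and instrument texts outside this package. Published reference
points from the original analysis (filter 97% on Vanderbilt, forest
94%→92% before/after overlap exclusion, 26%/24% overlap rates, Spearman
0.54/0.63 backend agreement) are documented here for orientation and are
not recomputed.

## Problem sizes and runtime

All bundled-table computations are O(36 × 3) and instantaneous. Property
suites use matrices up to 6×6 (greedy oracle), n ≤ 8 (exact Wilcoxon
enumeration), n = 200–300 samples (MI), 200 × 30 bootstrap replications,
and a 20-item synthetic test corpus for the end-to-end check; the full
test suite completes in well under a minute on one CPU.

## Known limitations

- The lexical/syntactic layer *values* depend on the preprocessing
  resources (stopword list, tagger lexicon, taxonomy, parser rules);
  scores from other resource stacks (e.g., a full WordNet and a
  statistical parser) will differ in the second or third decimal while
  preserving the layer semantics. The bundled score tables, not live
  layer computation, are the basis for all reproduced numbers.
- The pattern-grammar parser targets short, subject-light behavioural
  sentences; long multi-clause sentences will yield partial parses
  (deterministically, and only over the retained relation set).
- The taxonomy's coverage is intentionally narrow; out-of-vocabulary
  content words fall back to edit distance, which under-scores true
  synonyms it has never seen.
- The stub backend measures vocabulary overlap, not meaning; semantic
  conclusions about real instruments require a trained backend.
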