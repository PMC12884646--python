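# symscreen

Multi-layer sentence-similarity analysis of DSM-5 ADHD symptom statements,
plus a two-stage pipeline for checking how well ADHD screening
questionnaires align with the DSM-5 symptom domains.

The DSM-5 defines ADHD by 9 inattention and 9 hyperactivity/impulsivity
symptoms, but several of the 18 statements arguably describe overlapping
behaviours. `symscreen` is for researchers in clinical NLP and
psychometrics who want to (a) quantify that wording-level redundancy and
(b) audit whether a screening instrument's items map cleanly onto the two
diagnostic domains.

## Method

**Three similarity layers.** For a sentence pair (A, B):

- *Lexical* — preprocess (lowercase, tokenize, drop stopwords, POS-tag,
  lemmatize with the coarse POS), score every word pair with a hybrid
  measure (taxonomy path similarity `1/(1+d)` maximized over sense pairs;
  normalized Levenshtein `1 − dist/max(|a|,|b|)` as fallback when no path
  exists or the path score is < 0.1), aggregate the word matrix by greedy
  alignment (repeatedly take the global maximum, delete its row and
  column, average over `min(|A|,|B|)` picks), then subtract the length
  penalty `|lₐ − l_b|·sim / max(lₐ, l_b)`.
- *Syntactic* — extract filtered dependency triples (head, relation,
  dependent); score triple pairs as the mean of a direct (head–head,
  dep–dep) and a cross-wise (head–dep, dep–head) vertex alignment;
  aggregate with the same greedy alignment.
- *Semantic* — cosine similarity of sentence embeddings from a pluggable
  backend (sentence-transformer models, or the bundled deterministic
  offline stub).

**Entropy-weighted fusion.** With the m = 36 within-domain pair scores as
rows and the n = 3 layers as columns x_ij: normalize each column to
p_ij = x_ij / Σᵢ x_ij (zeros → 1e-10), compute H_j = −k Σᵢ p_ij ln p_ij
with k = 1/ln(m), divergence d_j = 1 − H_j, weights w_j = d_j / Σ d_j.
Combined pair scores are Σ_j w_j x_ij over the *original* values. Pairs at
or above the 99th-percentile cutoff (linear interpolation, relaxed by
0.03) are flagged as redundant.

**Screening pipeline.** Stage 1: a logistic-regression filter on sentence
embeddings (trained ADHD vs non-ADHD statements, classes balanced by
ADASYN oversampling in embedding space) keeps only ADHD-consistent items.
Stage 2: each surviving item becomes a 3-vector — per layer, mean
similarity to the 9 inattention exemplars minus mean similarity to the 9
hyperactivity/impulsivity exemplars — classified by a random forest
(100 trees, seed 42), an RBF-kernel SVM, or logistic regression.
Leakage control excludes test items with embedding cosine ≥ 0.90 to any
training statement; robustness is assessed by 30-iteration bootstrap
resampling of the test set with paired t-tests and Student-t 95% CIs.

## Worked example

```bash
python examples/redundancy_analysis.py
```

prints

```
--- inattention ---
layer weights: {'lexical': 0.35, 'syntactic': 0.16, 'semantic': 0.49}
99th-percentile cutoff: 0.61 (relaxed by 0.03)
  redundant pair (2, 5): combined similarity 0.62
  redundant pair (5, 7): combined similarity 0.58
--- hyperactivity/impulsivity ---
layer weights: {'lexical': 0.21, 'syntactic': 0.04, 'semantic': 0.75}
99th-percentile cutoff: 0.46 (relaxed by 0.03)
  redundant pair (1, 2): combined similarity 0.49
```

Reading: the semantic layer is the most informative in both domains (it
carries the largest entropy weight). Inattention symptoms 2 and 5
("sustaining attention in tasks or play" vs "organizing tasks and
activities", combined similarity 0.62) and 5 and 7 ("organizing tasks"
vs "loses things necessary for tasks", 0.58) overlap enough in wording to
question their distinctiveness; in the hyperactivity/impulsivity domain
only the fidgeting/leaves-seat pair (1, 2) crosses the relaxed threshold,
and its lower score (0.49) reflects clearly distinct behaviours.

Other examples: `layer_similarity.py` (one pair, all three layers, with
the extracted dependency triples), `layer_validation.py` (Wilcoxon and
mutual-information layer checks, chi-square imbalance test),
`screening_pipeline.py` (filter + subtype classification on synthetic
questionnaire items), `leakage_bootstrap.py` (overlap exclusion and
bootstrap comparison). A thin CLI wraps the same functionality:
`symscreen --help`.

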