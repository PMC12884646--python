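"""Lexical layer: preprocessing, hybrid word similarity, greedy alignment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import symscreen as ss
from symscreen.textproc import EmptyTokenSeqError, lexical_preprocess
from symscreen.taxonomy import default_taxonomy


class TestPreprocess:
    def test_verb_leaves_lemmatizes_to_leave_not_leaf(self):
        seq = lexical_preprocess(
            "Often leaves seat in situations when remaining seated is expected"
        )
        assert "leave" in seq.lemmas
        assert "leaf" not in seq.lemmas
        (tok,) = [t for t in seq if t.surface == "leaves"]
        assert tok.coarse_pos == "verb"

    @pytest.mark.parametrize("text", ["", "   ", "the of and", "to a the"])
    def test_stopword_only_input_raises(self, text):
        with pytest.raises(EmptyTokenSeqError):
            lexical_preprocess(text)

    def test_morphological_variants_collapse_to_one_lemma(self):
        # hand-tagged oracle: running/VBG, runs/VBZ, ran/VBD -> lemma "run"
        expected = {"running": ("VBG", "run"), "runs": ("VBZ", "run"),
                    "ran": ("VBD", "run")}
        seq = lexical_preprocess("Running!! runs, ran.")
        assert len(seq) == 3
        for tok in seq:
            tag, lemma = expected[tok.surface]
            assert (tok.penn_pos, tok.lemma) == (tag, lemma)

    def test_no_stopwords_or_nonalpha_survive(self, dsm5):
        from symscreen.textproc import stopwords

        sw = stopwords()
        for s in dsm5:
            seq = lexical_preprocess(s.text)
            assert all(t.surface.isalpha() and t.surface not in sw for t in seq)


class TestWordSimilarity:
    def test_identical_word_scores_one(self):
        assert ss.word_similarity("task", "task", "noun", "noun") == 1.0

    def test_out_of_vocabulary_falls_back_to_edit_distance(self):
        # editdistance("attention","attendtion") = 1, max length 10
        assert ss.word_similarity("attention", "attendtion") == pytest.approx(0.9)

    def test_symmetry(self):
        pairs = [("task", "chore"), ("organize", "lose"), ("often", "motor")]
        for a, b in pairs:
            for pos in ("noun", "verb"):
                assert ss.word_similarity(a, b, pos, pos) == ss.word_similarity(
                    b, a, pos, pos
                )

    def test_matches_exhaustive_sense_pair_oracle(self):
        tax = default_taxonomy()
        for a, b in [("organize", "lose"), ("run", "climb"), ("task", "play")]:
            pos = "verb" if (a, b) != ("task", "play") else "noun"
            best = None
            for sa in tax.senses(a, pos):
                for sb in tax.senses(b, pos):
                    d = tax.path_similarity(sa, sb)
                    if d is not None and (best is None or d > best):
                        best = d
            assert best is not None and best >= 0.1
            assert ss.word_similarity(a, b, pos, pos) == pytest.approx(best)

    def test_empty_lemma_rejected(self):
        with pytest.raises(ValueError):
            ss.word_similarity("", "task")


def _greedy_oracle(S):
    """Independent re-implementation: sort all entries, simulate deletion."""
    entries = sorted(
        ((S[i, j], i, j) for i in range(S.shape[0]) for j in range(S.shape[1])),
        key=lambda e: (-e[0], e[1], e[2]),
    )
    used_r, used_c = set(), set()
    total, count = 0.0, min(S.shape)
    for v, i, j in entries:
        if i not in used_r and j not in used_c:
            used_r.add(i)
            used_c.add(j)
            total += v
            if len(used_r) == count:
                break
    return total / count


class TestGreedyAlign:
    @pytest.mark.parametrize("n", [1, 3, 5])
    def test_identity_matrix_scores_one(self, n):
        assert ss.greedy_align(np.eye(n)) == pytest.approx(1.0)

    def test_greedy_is_not_optimal_assignment(self):
        # greedy takes 0.9 then is forced to 0.1; optimal pairing is 0.825
        assert ss.greedy_align(np.array([[0.9, 0.8], [0.85, 0.1]])) == pytest.approx(0.5)

    def test_single_row_takes_global_max(self):
        assert ss.greedy_align(np.array([[0.2, 0.7, 0.4]])) == pytest.approx(0.7)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            ss.greedy_align(np.empty((0, 0)))

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.integers(1, 6), st.integers(1, 6), st.integers(0, 2**31 - 1)
    )
    def test_agrees_with_sort_and_delete_oracle(self, nr, nc, seed):
        S = np.random.default_rng(seed).random((nr, nc)).round(3)
        assert ss.greedy_align(S) == pytest.approx(_greedy_oracle(S), abs=1e-12)


class TestLexicalSimilarity:
    def test_identical_sentences_score_one(self, dsm5):
        text = dsm5.get("inattention", 5).text
        score = ss.lexical_similarity(text, text)
        assert score.word_sim == pytest.approx(1.0)
        assert score.penalty == 0.0
        assert score.final == pytest.approx(1.0)

    def test_symmetry_and_range_over_statement_pairs(self, dsm5):
        texts = dsm5.texts[::4]
        for a in texts:
            for b in texts:
                fa = ss.lexical_similarity(a, b)
                fb = ss.lexical_similarity(b, a)
                assert fa.final == pytest.approx(fb.final)
                assert 0.0 <= fa.final <= fa.word_sim <= 1.0

    def test_penalty_formula_for_length_4_vs_2(self):
        score = ss.lexical_similarity(
            "organize tasks carefully today", "organize tasks"
        )
        assert (score.len_a, score.len_b) == (4, 2)
        assert score.penalty == pytest.approx(2 * score.word_sim / 4)
        assert score.final == pytest.approx(score.word_sim / 2)

    def test_equal_length_sentences_have_zero_penalty(self):
        score = ss.lexical_similarity("loses things daily", "organize tasks quietly")
        assert score.len_a == score.len_b
        assert score.penalty == 0.0
        assert score.final == pytest.approx(score.word_sim)

    def test_stopword_only_side_yields_flagged_zero(self):
        score = ss.lexical_similarity("the of and", "organize tasks")
        assert score.final == 0.0
        assert score.empty_input
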