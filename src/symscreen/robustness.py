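"""Leakage control and bootstrap robustness machinery.

Screening questionnaires frequently paraphrase the diagnostic manual, so
near-verbatim overlap between training statements and test items can
inflate apparent performance.  ``overlap_exclude`` flags and removes test
items whose embedding cosine with ANY training statement reaches a
conservative cutoff (default 0.90, near-duplicate territory).
``bootstrap_accuracy`` resamples a labelled test set with replacement —
the fitted model is NOT refit — and ``paired_t_compare`` compares two
bootstrap accuracy vectors that share iteration seeds, with a Student-t
95% confidence interval on the mean difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .corpus import Corpus
from .semantic import EmbeddingBackend


@dataclass(frozen=True)
class OverlapReport:
    flagged_pairs: tuple[tuple[str, str, float], ...]  # (train id, test id, cosine)
    excluded_test_ids: tuple[str, ...]
    retained: Corpus
    cutoff: float


@dataclass(frozen=True)
class BootstrapComparison:
    acc_a: np.ndarray
    acc_b: np.ndarray
    mean_diff: float
    ci95: tuple[float, float]
    t: float | None
    p: float | None


def overlap_exclude(
    train: Corpus,
    test: Corpus,
    backend: EmbeddingBackend,
    cutoff: float = 0.90,
) -> OverlapReport:
    """Exclude test items that near-duplicate any training statement.

    A test item is excluded iff its embedding cosine similarity with at
    least one training item is >= ``cutoff``.  The report lists every
    flagged (train, test, cosine) pair and the retained sub-corpus.
    """
    if not 0.0 < cutoff <= 1.0:
        raise ValueError("cutoff must lie in (0, 1]")
    if len(train) == 0 or len(test) == 0:
        raise ValueError("train and test corpora must be non-empty")
    Et = np.asarray(backend.embed(train.texts), dtype=float)
    Es = np.asarray(backend.embed(test.texts), dtype=float)
    Et = Et / np.linalg.norm(Et, axis=1, keepdims=True)
    Es = Es / np.linalg.norm(Es, axis=1, keepdims=True)
    C = Et @ Es.T
    flagged = []
    excluded = set()
    for i, tid in enumerate(train.ids):
        for j, sid in enumerate(test.ids):
            if C[i, j] >= cutoff - 1e-12:
                flagged.append((tid, sid, float(C[i, j])))
                excluded.add(sid)
    retained = Corpus(tuple(s for s in test if s.id not in excluded))
    return OverlapReport(
        flagged_pairs=tuple(flagged),
        excluded_test_ids=tuple(s.id for s in test if s.id in excluded),
        retained=retained,
        cutoff=cutoff,
    )


def bootstrap_accuracy(
    predict: Callable[[Corpus], Sequence[int]],
    corpus: Corpus,
    B: int = 30,
    seed: int = 0,
) -> np.ndarray:
    """Accuracy of a fitted model over B bootstrap resamples of a test set.

    Each iteration i draws len(corpus) items with replacement using seed
    ``seed + i``, so two conditions evaluated with the same seed share
    resample indices and are paired by iteration.  Items must carry known
    labels; class 1 = hyperactivity/impulsivity, 0 otherwise.
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap iterations")
    if any(s.domain == "unknown" for s in corpus):
        raise ValueError("bootstrap requires a fully labelled corpus")
    truth = np.array(
        [1 if s.domain == "hyperactivity_impulsivity" else 0 for s in corpus]
    )
    pred = np.asarray(predict(corpus), int)
    if pred.shape != truth.shape:
        raise ValueError("predict must return one label per item")
    correct = (pred == truth).astype(float)
    n = len(corpus)
    accs = np.empty(B)
    for i in range(B):
        rng = np.random.default_rng(seed + i)
        idx = rng.integers(0, n, size=n)
        accs[i] = correct[idx].mean()
    return accs


def paired_t_compare(acc_a, acc_b) -> BootstrapComparison:
    """Two-sided paired t-test on per-iteration accuracy differences.

    The 95% CI is mean_diff +/- t_{0.975, B-1} * SE.  Zero-variance
    differences make t undefined; the comparison then reports the mean
    difference with a degenerate CI and t = p = None.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length vectors of >= 2 accuracies")
    d = a - b
    mean_diff = float(d.mean())
    if np.allclose(d.std(ddof=1), 0.0):
        return BootstrapComparison(a, b, mean_diff, (mean_diff, mean_diff), None, None)
    res = stats.ttest_rel(a, b)
    se = d.std(ddof=1) / np.sqrt(d.size)
    tq = stats.t.ppf(0.975, d.size - 1)
    ci = (mean_diff - tq * se, mean_diff + tq * se)
    return BootstrapComparison(
        a, b, mean_diff, (float(ci[0]), float(ci[1])),
        float(res.statistic), float(res.pvalue),
    )
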