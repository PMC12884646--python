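"""Entropy Weight Method score fusion and percentile redundancy thresholds.

The Entropy Weight Method (EWM) assigns each similarity layer an objective
weight from the dispersion of its values: each layer column is normalized
to a probability distribution p_ij = x_ij / sum_i x_ij (zeros replaced by a
small constant), its Shannon entropy H_j = -k sum_i p_ij ln p_ij is scaled
by k = 1/ln(m) into [0, 1], and the divergences d_j = 1 - H_j are
normalized into weights w_j summing to one.  A layer whose values are
nearly uniform carries no information (H ~ 1) and receives weight ~ 0.

Combined per-pair scores are the weighted sums of the ORIGINAL layer
values, so each combined score is a convex combination bounded by the
pair's smallest and largest layer scores.  Redundant pairs are selected by
an upper-percentile cutoff (linear interpolation) relaxed downward by a
small margin on the 0-1 similarity scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus import LayerScoreTable

ZERO_EPS = 1e-10
DEFAULT_PERCENTILE = 99.0
DEFAULT_RELAXATION = 0.03


@dataclass(frozen=True)
class EntropyWeights:
    k: float
    H: np.ndarray  # per-layer entropy, in [0, 1]
    d: np.ndarray  # per-layer divergence 1 - H
    w: np.ndarray  # normalized weights, sum to 1
    layer_names: tuple[str, ...] = ("lexical", "syntactic", "semantic")

    def __post_init__(self) -> None:
        for name in ("H", "d", "w"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        if not np.isclose(self.w.sum(), 1.0, atol=1e-9):
            raise ValueError("weights must sum to 1")
        if np.any(self.w < -1e-12) or np.any(self.w > 1 + 1e-12):
            raise ValueError("weights must lie in [0, 1]")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.layer_names, map(float, self.w)))


@dataclass(frozen=True)
class ThresholdResult:
    percentile: float
    cutoff: float
    relaxation: float
    selected: tuple


def entropy_weights(table: LayerScoreTable, zero_eps: float = ZERO_EPS) -> EntropyWeights:
    """Objective per-layer weights from the dispersion of each score column."""
    x = table.x
    m = table.m
    if m < 2:
        raise ValueError("entropy weights need at least 2 rows (ln(1) = 0)")
    if np.any(x < 0):
        raise ValueError("layer scores must be non-negative")
    colsum = x.sum(axis=0)
    if np.any(colsum == 0):
        raise ValueError("all-zero layer column")
    p = x / colsum
    p = np.where(p == 0, zero_eps, p)
    k = 1.0 / np.log(m)
    H = -k * (p * np.log(p)).sum(axis=0)
    d = 1.0 - H
    w = d / d.sum()
    return EntropyWeights(k=k, H=H, d=d, w=w, layer_names=table.layer_names)


def combined_scores(table: LayerScoreTable, weights: EntropyWeights) -> np.ndarray:
    """Per-pair weighted sum of the original (unnormalized) layer scores."""
    if weights.w.shape[0] != table.n:
        raise ValueError("weight/layer dimension mismatch")
    return table.x @ weights.w


def percentile_cutoff(
    scores,
    percentile: float = DEFAULT_PERCENTILE,
    relaxation: float = DEFAULT_RELAXATION,
    labels=None,
) -> ThresholdResult:
    """Select high-similarity items at an upper-percentile cutoff.

    The cutoff is the linear-interpolation percentile of the scores (rank
    position p/100 * (n-1) on the ascending sort); items with score >=
    cutoff - relaxation are selected.  Labels default to positional
    indices.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise ValueError("need at least 2 scores")
    if not 0.0 < percentile < 100.0:
        raise ValueError("percentile must lie in (0, 100)")
    cutoff = float(np.percentile(scores, percentile, method="linear"))
    if labels is None:
        labels = list(range(scores.size))
    if len(labels) != scores.size:
        raise ValueError("labels length must match scores")
    selected = tuple(
        lab for lab, s in zip(labels, scores) if s >= cutoff - relaxation
    )
    return ThresholdResult(percentile, cutoff, relaxation, selected)


def redundant_pairs(
    table: LayerScoreTable,
    percentile: float = DEFAULT_PERCENTILE,
    relaxation: float = DEFAULT_RELAXATION,
) -> tuple[EntropyWeights, np.ndarray, ThresholdResult]:
    """Full fusion pipeline: EWM weights, combined scores, thresholded pairs."""
    w = entropy_weights(table)
    combined = combined_scores(table, w)
    thr = percentile_cutoff(combined, percentile, relaxation, labels=table.pair_labels)
    return w, combined, thr
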