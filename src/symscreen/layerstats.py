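"""Statistical validation that the similarity layers are non-redundant.

Three checks: a paired Wilcoxon signed-rank test (do two layers differ in
location over the same symptom pairs), a k-nearest-neighbour mutual-
information estimate (does one layer's score carry information about
another's), and a one-degree-of-freedom chi-square goodness-of-fit test
for class imbalance in the filter-stage training data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.feature_selection import mutual_info_regression


@dataclass(frozen=True)
class PairedTestResult:
    statistic: float
    p_value: float
    n: int
    method: str


class DegenerateSampleError(ValueError):
    """All paired differences are zero; the signed-rank test is undefined."""


def wilcoxon_paired(x, y) -> PairedTestResult:
    """Two-sided Wilcoxon signed-rank test on paired score lists.

    Zero differences are dropped before ranking (Wilcoxon's original
    treatment); the statistic is the smaller of the positive- and
    negative-difference rank sums; the p-value uses the normal
    approximation for n > 25 and the exact distribution otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D score lists")
    if x.size < 5:
        raise ValueError("need at least 5 paired samples")
    d = x - y
    nz = d[d != 0]
    if nz.size == 0:
        raise DegenerateSampleError("all paired differences are zero")
    method = "approx" if nz.size > 25 else "exact"
    try:
        res = stats.wilcoxon(
            x, y, zero_method="wilcox", correction=False, method=method
        )
    except ValueError:
        # exact mode refuses ties; fall back to the normal approximation
        res = stats.wilcoxon(x, y, zero_method="wilcox", correction=False,
                             method="approx")
        method = "approx"
    return PairedTestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=int(nz.size),
        method=f"wilcoxon-signed-rank/{method}",
    )


def mutual_info(x, y, seed: int = 0, n_neighbors: int = 3) -> float:
    """k-NN (Kraskov-family) estimate of the mutual information I(x; y).

    Nonparametric, captures non-linear dependence; the estimator's noise
    injection is seeded for reproducibility and negative estimates are
    clipped to zero (zero indicates independence).  Constant inputs carry
    no information and return 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D score lists")
    if x.size < 10:
        raise ValueError("need at least 10 samples for a stable MI estimate")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    mi = mutual_info_regression(
        x[:, None], y, n_neighbors=n_neighbors, random_state=seed
    )
    return float(max(mi[0], 0.0))


def chi_square_balance(n_pos: int, n_neg: int) -> tuple[float, float]:
    """Goodness-of-fit chi-square of two class counts against a 50/50 split.

    One degree of freedom, expected count (n_pos + n_neg) / 2 per class;
    algebraically the statistic equals (n_pos - n_neg)^2 / (n_pos + n_neg).
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("counts must be non-negative")
    if n_pos + n_neg == 0:
        raise ValueError("both class counts are zero")
    res = stats.chisquare([n_pos, n_neg])
    return float(res.statistic), float(res.pvalue)


def layer_comparison_report(tables: dict[str, "LayerScoreTable"], seed: int = 0) -> dict:
    """Wilcoxon + MI comparison of the semantic layer against the lexical
    and syntactic layers, per domain, as a JSON-ready dict."""
    report: dict[str, dict] = {}
    for domain, table in tables.items():
        sem = table.column("semantic")
        rows = {}
        for other in ("lexical", "syntactic"):
            w = wilcoxon_paired(sem, table.column(other))
            mi = mutual_info(table.column(other), sem, seed=seed)
            rows[f"semantic_vs_{other}"] = {
                "wilcoxon_statistic": w.statistic,
                "wilcoxon_p": w.p_value,
                "mutual_information": mi,
            }
        report[domain] = rows
    return report
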