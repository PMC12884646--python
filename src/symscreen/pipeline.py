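"""Two-stage screening pipeline: ADHD/non-ADHD filter, then subtype classifier.

Stage one embeds every statement with the configured backend and fits a
logistic-regression filter separating ADHD-consistent from non-ADHD
diagnostic language, after balancing the training classes with adaptive
synthetic oversampling (ADASYN) in embedding space.  Stage two represents
each surviving item by a three-dimensional similarity-difference feature
vector — for each layer, mean similarity to the inattention exemplars
minus mean similarity to the hyperactivity/impulsivity exemplars
(positive = inattention-leaning) — and classifies the symptom domain with
a random forest, an RBF-kernel max-margin classifier, or logistic
regression, all at fixed default hyper-parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

from .corpus import Corpus
from .lexical import lexical_similarity
from .semantic import EmbeddingBackend
from .syntactic import syntactic_similarity

LAYERS = ("lexical", "syntactic", "semantic")


@dataclass(frozen=True)
class PipelineConfig:
    """Fixed pipeline constants; defaults mirror the reference analysis."""

    filter_max_iter: int = 1000
    forest_trees: int = 100
    forest_seed: int = 42
    overlap_cutoff: float = 0.90
    bootstrap_iters: int = 30
    embed_dim: int = 768
    min_path_sim: float = 0.1
    zero_eps: float = 1e-10
    percentile: float = 99.0
    relaxation: float = 0.03
    adasyn_neighbors: int = 5
    global_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.overlap_cutoff <= 1.0:
            raise ValueError("overlap_cutoff must lie in (0, 1]")
        for name in ("filter_max_iter", "forest_trees", "bootstrap_iters",
                     "embed_dim", "adasyn_neighbors"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class FeatureVector:
    d_lex: float
    d_syn: float
    d_sem: float

    def as_array(self) -> np.ndarray:
        return np.array([self.d_lex, self.d_syn, self.d_sem])


def extract_features(
    item: str,
    inatt: Corpus,
    hyper: Corpus,
    backend: EmbeddingBackend,
    exclude_self: bool = False,
) -> FeatureVector:
    """Similarity-difference features for one sentence.

    For each layer, the mean similarity of ``item`` to all inattention
    exemplars minus its mean similarity to all hyperactivity/impulsivity
    exemplars.  The averages run over ALL exemplars, including a literal
    occurrence of the item itself, keeping training and test items on the
    same feature scale; set ``exclude_self`` to drop exact text matches
    from their own mean instead.
    """
    if len(inatt) == 0 or len(hyper) == 0:
        raise ValueError("both exemplar corpora must be non-empty")

    def keep_texts(corpus: Corpus) -> list[str]:
        if exclude_self:
            return [t for t in corpus.texts if t != item] or corpus.texts
        return corpus.texts

    def domain_means(corpus: Corpus) -> tuple[float, float]:
        texts = keep_texts(corpus)
        lex = [lexical_similarity(item, t).final for t in texts]
        syn = [syntactic_similarity(item, t) for t in texts]
        return float(np.mean(lex)), float(np.mean(syn))

    lex_i, syn_i = domain_means(inatt)
    lex_h, syn_h = domain_means(hyper)

    all_texts = [item] + keep_texts(inatt) + keep_texts(hyper)
    E = np.asarray(backend.embed(all_texts), dtype=float)
    v = E[0]
    n_i = len(keep_texts(inatt))
    Ei = E[1 : 1 + n_i]
    Eh = E[1 + n_i :]

    def sem_mean(sub: np.ndarray) -> float:
        sims = (sub @ v) / (np.linalg.norm(sub, axis=1) * np.linalg.norm(v))
        return float(np.mean(sims))

    return FeatureVector(
        lex_i - lex_h, syn_i - syn_h, sem_mean(Ei) - sem_mean(Eh)
    )


def feature_matrix(
    corpus: Corpus,
    inatt: Corpus,
    hyper: Corpus,
    backend: EmbeddingBackend,
    exclude_self: bool = False,
) -> np.ndarray:
    return np.vstack(
        [
            extract_features(
                s.text, inatt, hyper, backend, exclude_self=exclude_self
            ).as_array()
            for s in corpus
        ]
    )


def adasyn_oversample(
    X: np.ndarray,
    y: np.ndarray,
    n_neighbors: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Adaptive synthetic oversampling of the minority class.

    For each minority sample, the share of majority points among its k
    nearest neighbours decides how many synthetic points it spawns
    (boundary-heavy generation); each synthetic point interpolates between
    the sample and a random minority neighbour.  Falls back to uniform
    allocation when the minority class is isolated.  Classes already
    balanced are returned unchanged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("adasyn expects a binary label vector")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 samples")
    minority = classes[np.argmin(counts)]
    n_new = int(counts.max() - counts.min())
    if n_new == 0:
        return X, y
    rng = np.random.default_rng(seed)
    Xmin = X[y == minority]
    k = min(n_neighbors, len(X) - 1)
    nn_all = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn_all.kneighbors(Xmin)
    # ratio of majority points among each minority sample's neighbours
    ratios = np.array(
        [np.mean(y[row[1:]] != minority) for row in idx], dtype=float
    )
    if ratios.sum() == 0:
        weights = np.full(len(Xmin), 1.0 / len(Xmin))
    else:
        weights = ratios / ratios.sum()
    alloc = np.floor(weights * n_new).astype(int)
    # distribute the remainder by largest weight, deterministically
    for j in np.argsort(-weights)[: n_new - alloc.sum()]:
        alloc[j] += 1
    kmin = min(n_neighbors, len(Xmin) - 1)
    nn_min = NearestNeighbors(n_neighbors=kmin + 1).fit(Xmin)
    _, min_idx = nn_min.kneighbors(Xmin)
    synth = []
    for i, gi in enumerate(alloc):
        for _ in range(gi):
            j = min_idx[i][1:][rng.integers(kmin)]
            lam = rng.random()
            synth.append(Xmin[i] + lam * (Xmin[j] - Xmin[i]))
    if not synth:
        return X, y
    Xs = np.vstack([X, np.vstack(synth)])
    ys = np.concatenate([y, np.full(len(synth), minority, dtype=y.dtype)])
    return Xs, ys


@dataclass
class FilterModel:
    classifier: LogisticRegression
    backend_name: str
    resampled_counts: dict
    config: PipelineConfig


def train_filter(
    adhd: Corpus,
    non_adhd: Corpus,
    backend: EmbeddingBackend,
    cfg: PipelineConfig | None = None,
) -> FilterModel:
    """Fit the stage-one ADHD/non-ADHD filter (positive class = ADHD).

    Embeds all statements, balances classes with ADASYN in embedding
    space, then fits a logistic-regression classifier with the configured
    iteration cap.
    """
    cfg = cfg or PipelineConfig()
    if len(adhd) < 2 or len(non_adhd) < 2:
        raise ValueError("each class needs at least 2 statements for oversampling")
    X = np.asarray(backend.embed(adhd.texts + non_adhd.texts), dtype=float)
    y = np.concatenate([np.ones(len(adhd), int), np.zeros(len(non_adhd), int)])
    Xr, yr = adasyn_oversample(
        X, y, n_neighbors=cfg.adasyn_neighbors, seed=cfg.global_seed
    )
    clf = LogisticRegression(max_iter=cfg.filter_max_iter)
    clf.fit(Xr, yr)
    counts = {int(c): int(n) for c, n in zip(*np.unique(yr, return_counts=True))}
    return FilterModel(clf, backend.name, counts, cfg)


def apply_filter(
    model: FilterModel,
    corpus: Corpus,
    backend: EmbeddingBackend,
) -> tuple[Corpus, Corpus, "ClassificationReport | None"]:
    """Partition a corpus into ADHD-consistent (passed) and rejected items.

    Order is preserved and passed + rejected recompose the input.  When
    every item carries a known domain label, a classification report for
    the filter decision (ADHD = positive) is attached.
    """
    if backend.name != model.backend_name:
        raise ValueError(
            f"filter was trained with backend {model.backend_name!r}, "
            f"got {backend.name!r}"
        )
    if len(corpus) == 0:
        return Corpus(()), Corpus(()), None
    E = np.asarray(backend.embed(corpus.texts), dtype=float)
    pred = model.classifier.predict(E)
    prob = model.classifier.predict_proba(E)[:, 1]
    passed = Corpus(tuple(s for s, p in zip(corpus, pred) if p == 1))
    rejected = Corpus(tuple(s for s, p in zip(corpus, pred) if p == 0))
    report = None
    if all(s.domain != "unknown" for s in corpus):
        truth = np.array([0 if s.domain == "non_adhd" else 1 for s in corpus])
        report = evaluate(pred, prob, truth)
    return passed, rejected, report


SUBTYPE_KINDS = ("forest", "rbf_margin", "linear_logodds")


@dataclass
class SubtypeModel:
    kind: str
    classifier: object


def train_subtype(kind: str, X: np.ndarray, y: np.ndarray,
                  cfg: PipelineConfig | None = None) -> SubtypeModel:
    """Fit a stage-two symptom-domain classifier on similarity features.

    Labels: 0 = inattention, 1 = hyperactivity/impulsivity.  No
    hyper-parameter search: the forest uses its fixed tree count and seed,
    the RBF margin classifier and logistic regression their defaults.
    """
    cfg = cfg or PipelineConfig()
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")
    if kind == "forest":
        clf = RandomForestClassifier(
            n_estimators=cfg.forest_trees, random_state=cfg.forest_seed
        )
    elif kind == "rbf_margin":
        clf = SVC(kernel="rbf", probability=True, random_state=cfg.forest_seed)
    elif kind == "linear_logodds":
        clf = LogisticRegression()
    else:
        raise KeyError(f"unknown subtype classifier {kind!r}; valid: {SUBTYPE_KINDS}")
    clf.fit(np.asarray(X, float), y)
    return SubtypeModel(kind, clf)


@dataclass(frozen=True)
class ClassificationReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    specificity: float
    auc: float | None
    confusion: tuple[tuple[int, int], tuple[int, int]]  # rows = truth 0/1
    per_class: dict

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "specificity": self.specificity,
            "auc": self.auc,
            "confusion": [list(r) for r in self.confusion],
            "per_class": self.per_class,
        }


def evaluate(pred, prob, truth) -> ClassificationReport:
    """Binary classification metrics with class 1 as positive.

    All scalar metrics are recomputable from the confusion counts; AUC is
    the rank statistic over ``prob`` and is reported as None when the
    truth is single-class.
    """
    pred = np.asarray(pred, int)
    truth = np.asarray(truth, int)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    cm = confusion_matrix(truth, pred, labels=[0, 1])
    (tn, fp), (fn, tp) = cm
    total = cm.sum()
    acc = (tp + tn) / total
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    auc = None
    if prob is not None and np.unique(truth).size == 2:
        auc = float(roc_auc_score(truth, np.asarray(prob, float)))
    per_class = {}
    for cls, (tpc, fpc, fnc) in {0: (tn, fn, fp), 1: (tp, fp, fn)}.items():
        p = tpc / (tpc + fpc) if tpc + fpc else 0.0
        r = tpc / (tpc + fnc) if tpc + fnc else 0.0
        per_class[cls] = {
            "precision": p,
            "recall": r,
            "f1": 2 * p * r / (p + r) if p + r else 0.0,
        }
    return ClassificationReport(
        accuracy=float(acc),
        precision=float(prec),
        recall=float(rec),
        f1=float(f1),
        specificity=float(spec),
        auc=auc,
        confusion=((int(tn), int(fp)), (int(fn), int(tp))),
        per_class=per_class,
    )
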