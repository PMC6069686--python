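"""Relation detection, relation classification and the retraining loop.

The detector is a binary classifier (random forest by default) over a
fixed, versioned feature schema with three families:

* statistical — termhood scores and lengths of the three mentions;
* lexical — token distances, predicate position relative to the entity
  pair, a small hashed bag-of-words of the tokens between subject and
  object, sentence length;
* semantic — kind flags and the predicate's best match against the
  relation-class lexicon.

A candidate triple becomes an :class:`Assertion` when the model's
positive-class probability reaches the confidence threshold λ (default
0.94).  Accepted assertions are normalized to one of 13 relation classes
(12 named classes + a mandatory ``"other"`` catch-all) either by lexicon
lookup or by a trained multi-class model.

The retraining loop rebuilds the training set from crowd feedback:
crowd-validated triples are positives, triples never selected by any
worker are negatives, either all of them (imbalanced, with balanced class
weights) or a seeded without-replacement sample (balanced).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (auc, precision_recall_fscore_support, roc_curve)
from sklearn.model_selection import StratifiedKFold, cross_val_predict

from ._text import tokenize, tokenize_spans
from .extraction import CandidateTriple, Sentence

__all__ = [
    "FEATURE_SCHEMA",
    "DetectionConfig",
    "Assertion",
    "EvalReport",
    "RelationClassInventory",
    "DEFAULT_INVENTORY",
    "featurize",
    "featurize_batch",
    "RelationDetector",
    "train_detector",
    "detect",
    "classify_relation",
    "LexiconClassifier",
    "train_multiclass",
    "evaluate",
    "build_retraining_set",
]

_BOW_DIM = 8

FEATURE_SCHEMA: tuple[str, ...] = (
    # statistical
    "subj_score", "pred_score", "obj_score",
    "subj_n_tokens", "pred_n_tokens", "obj_n_tokens",
    "subj_n_chars", "obj_n_chars",
    # lexical
    "token_dist_subj_obj", "tokens_between_count",
    "pred_between_pair", "pred_before_pair", "pred_after_pair",
    "subj_position_frac", "sentence_n_tokens",
    *(f"between_bow_h{i}" for i in range(_BOW_DIM)),
    # semantic
    "pred_is_multiword", "pred_lexicon_class_idx", "pred_lexicon_overlap",
)

SCHEMA_VERSION = "1"


@dataclass(frozen=True)
class DetectionConfig:
    """Detector hyper-parameters.

    ``lambda_threshold`` is the minimum positive-class probability for a
    candidate to be asserted into the KB (default 0.94).
    """

    algorithm: str = "random_forest"
    n_trees: int = 500
    rng_seed: int = 0
    lambda_threshold: float = 0.94
    class_weight: str | None = "balanced"
    n_cv_folds: int = 5

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_threshold <= 1.0:
            raise ValueError("lambda_threshold must be in [0, 1]")


@dataclass(frozen=True)
class Assertion:
    triple: CandidateTriple
    confidence: float
    relation_class: str = "other"


@dataclass
class EvalReport:
    classes: list[str]
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    support: dict[str, int]
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    roc_points: list[tuple[float, float]] | None = None
    auroc: float | None = None


# -- relation-class inventory -------------------------------------------------

@dataclass(frozen=True)
class RelationClassInventory:
    """13 relation classes: 12 named + mandatory ``other``.

    ``lexicon`` maps each named class to predicate phrases that evidence
    it; a predicate with no lexicon overlap falls back to ``other``.
    """

    classes: tuple[str, ...]
    lexicon: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "other" not in self.classes:
            raise ValueError('inventory must include the "other" class')

    def best_match(self, predicate_surface: str) -> tuple[str, float]:
        """(class, token-overlap score) of the best lexicon hit; ``other``
        with score 0 when nothing overlaps."""
        ptoks = set(tokenize(predicate_surface.lower()))
        best, best_score = "other", 0.0
        for cls in self.classes:
            for phrase in self.lexicon.get(cls, ()):
                if phrase == predicate_surface.lower():
                    return cls, 1.0
                otoks = set(tokenize(phrase))
                if not otoks:
                    continue
                ov = len(ptoks & otoks) / len(ptoks | otoks)
                if ov > best_score:
                    best, best_score = cls, ov
        return best, best_score

    def index(self, cls: str) -> int:
        return self.classes.index(cls)


DEFAULT_INVENTORY = RelationClassInventory(
    classes=(
        "associated with", "inversely associated with", "is a", "part of",
        "causes", "increases", "decreases", "regulates", "located in",
        "participates in", "precedes", "has role", "other",
    ),
    lexicon={
        "associated with": ("associated with", "is associated with",
                            "correlates with", "is linked to", "related to"),
        "inversely associated with": ("inversely associated with",
                                      "negatively associated with"),
        "is a": ("is a", "is an", "is"),
        "part of": ("part of", "is part of"),
        "causes": ("causes", "cause", "induces", "leads to", "results in",
                   "triggers"),
        "increases": ("increases", "raises", "elevates", "promotes",
                      "enhances", "increases the risk of"),
        "decreases": ("decreases", "reduces", "lowers", "inhibits",
                      "suppresses"),
        "regulates": ("regulates", "modulates", "mediates", "controls"),
        "located in": ("located in", "found in", "occurs in"),
        "participates in": ("participates in", "involved in",
                            "contributes to"),
        "precedes": ("precedes", "occurs before"),
        "has role": ("has role", "plays a role in", "acts as"),
    },
)


# -- featurization ------------------------------------------------------------

def _token_index_of_span(spans: list[tuple[int, int]], char_span: tuple[int, int]
                         ) -> tuple[int, int]:
    """First/last token index overlapping a character span."""
    first = last = -1
    for k, (a, b) in enumerate(spans):
        if b > char_span[0] and a < char_span[1]:
            if first < 0:
                first = k
            last = k
    return first, last


def featurize(triple: CandidateTriple, sentence: Sentence,
              inventory: RelationClassInventory = DEFAULT_INVENTORY,
              ) -> np.ndarray:
    """Deterministic feature vector of length ``len(FEATURE_SCHEMA)``.

    Raises ``ValueError`` if the triple is not anchored to ``sentence``.
    """
    if triple.sentence_key != sentence.key:
        raise ValueError("triple does not belong to this sentence")
    text = sentence.text
    spans = tokenize_spans(text)
    toks = [text[a:b] for a, b in spans]
    n_tok = len(toks)

    s, p, o = triple.subject, triple.predicate, triple.object
    s_first, s_last = _token_index_of_span(spans, s.span)
    o_first, o_last = _token_index_of_span(spans, o.span)
    p_first, _ = _token_index_of_span(spans, p.span)

    between = toks[s_last + 1:o_first] if o_first > s_last else []
    token_dist = max(o_first - s_last, 0)

    bow = np.zeros(_BOW_DIM)
    for t in between:
        # crc32, not hash(): stable across interpreter runs
        bow[zlib.crc32(t.lower().encode("utf-8")) % _BOW_DIM] += 1.0

    pred_between = float(s_last < p_first < o_first)
    pred_before = float(p_first <= s_last)
    pred_after = float(p_first >= o_first)

    cls, overlap = inventory.best_match(p.surface)

    vec = np.array([
        s.score, p.score, o.score,
        len(s.surface.split()), len(p.surface.split()), len(o.surface.split()),
        len(s.surface), len(o.surface),
        float(token_dist), float(len(between)),
        pred_between, pred_before, pred_after,
        (s_first / n_tok) if n_tok else 0.0, float(n_tok),
        *bow,
        float(len(p.surface.split()) > 1),
        float(inventory.index(cls)), overlap,
    ])
    assert len(vec) == len(FEATURE_SCHEMA)
    return vec


def featurize_batch(triples: Sequence[CandidateTriple],
                    sentences: dict[str, Sentence],
                    inventory: RelationClassInventory = DEFAULT_INVENTORY,
                    ) -> np.ndarray:
    return np.array([featurize(t, sentences[t.sentence_key], inventory)
                     for t in triples]).reshape(len(triples), len(FEATURE_SCHEMA))


# -- detection ----------------------------------------------------------------

@dataclass
class RelationDetector:
    model: RandomForestClassifier
    config: DetectionConfig
    schema: tuple[str, ...] = FEATURE_SCHEMA
    schema_version: str = SCHEMA_VERSION

    def predict_proba_positive(self, X: np.ndarray) -> np.ndarray:
        if X.shape[1] != len(self.schema):
            raise ValueError(
                f"feature schema mismatch: model expects {len(self.schema)} "
                f"features, got {X.shape[1]}")
        pos_col = list(self.model.classes_).index(1)
        return self.model.predict_proba(X)[:, pos_col]


def _make_forest(config: DetectionConfig) -> RandomForestClassifier:
    if config.algorithm != "random_forest":
        raise ValueError(f"unsupported algorithm: {config.algorithm!r}")
    return RandomForestClassifier(
        n_estimators=config.n_trees, max_features="sqrt",
        class_weight=config.class_weight, random_state=config.rng_seed,
        n_jobs=1)


def train_detector(X: np.ndarray, y: Sequence[int] | np.ndarray,
                   config: DetectionConfig = DetectionConfig(),
                   ) -> tuple[RelationDetector, EvalReport]:
    """Fit the detector and report seeded stratified cross-validation
    metrics.  Raises ``ValueError`` on single-class training data."""
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")

    cv = StratifiedKFold(n_splits=config.n_cv_folds, shuffle=True,
                         random_state=config.rng_seed)
    est = _make_forest(config)
    proba = cross_val_predict(est, X, y, cv=cv, method="predict_proba")
    pos_col = 1  # classes_ sorted, labels are {0, 1}
    pred = (proba[:, pos_col] >= 0.5).astype(int)
    report = evaluate(pred.tolist(), y.tolist(),
                      scores=proba[:, pos_col].tolist())

    model = _make_forest(config).fit(X, y)
    return RelationDetector(model, config), report


def detect(detector: RelationDetector,
           candidates: Sequence[CandidateTriple],
           sentences: dict[str, Sentence],
           lambda_threshold: float | None = None,
           inventory: RelationClassInventory = DEFAULT_INVENTORY,
           ) -> list[Assertion]:
    """Assert every candidate whose positive-class probability ≥ λ.

    Monotone in λ: the accepted set at a larger λ is a subset of the
    accepted set at a smaller one.
    """
    lam = (detector.config.lambda_threshold
           if lambda_threshold is None else lambda_threshold)
    if not candidates:
        return []
    X = featurize_batch(candidates, sentences, inventory)
    proba = detector.predict_proba_positive(X)
    return [Assertion(t, float(c)) for t, c in zip(candidates, proba)
            if c >= lam]


# -- relation classification --------------------------------------------------

class LexiconClassifier:
    """1-nearest-lexicon relation classifier: the class whose lexicon best
    overlaps the predicate surface; ``other`` when nothing overlaps."""

    def __init__(self, inventory: RelationClassInventory = DEFAULT_INVENTORY):
        self.inventory = inventory

    def predict(self, predicate_surface: str) -> str:
        cls, score = self.inventory.best_match(predicate_surface)
        return cls if score > 0 else "other"


def classify_relation(classifier, assertion: Assertion,
                      sentence: Sentence | None = None) -> Assertion:
    """Attach a relation class to an assertion.

    ``classifier`` is either a :class:`LexiconClassifier` or a trained
    multi-class model from :func:`train_multiclass` (then ``sentence`` is
    required for featurization).
    """
    if isinstance(classifier, LexiconClassifier):
        cls = classifier.predict(assertion.triple.predicate.surface)
    else:
        if sentence is None:
            raise ValueError("sentence context required for a trained model")
        X = featurize(assertion.triple, sentence).reshape(1, -1)
        cls = str(classifier.predict(X)[0])
    return Assertion(assertion.triple, assertion.confidence, cls)


def train_multiclass(X: np.ndarray, labels: Sequence[str],
                     config: DetectionConfig = DetectionConfig(),
                     ) -> RandomForestClassifier:
    """Random-forest multi-class relation classifier over the same schema."""
    return _make_forest(config).fit(X, np.asarray(labels))


# -- evaluation ---------------------------------------------------------------

def evaluate(predicted: Sequence, gold: Sequence,
             scores: Sequence[float] | None = None) -> EvalReport:
    """Per-class and support-weighted precision/recall/F; ROC + AUROC when
    confidences are supplied (binary labels only)."""
    if len(predicted) != len(gold):
        raise ValueError("predicted and gold must have equal length")
    classes = sorted(set(gold) | set(predicted), key=str)
    p, r, f, s = precision_recall_fscore_support(
        gold, predicted, labels=classes, zero_division=0)
    wp, wr, wf, _ = precision_recall_fscore_support(
        gold, predicted, labels=classes, average="weighted", zero_division=0)
    report = EvalReport(
        classes=[str(c) for c in classes],
        precision={str(c): float(v) for c, v in zip(classes, p)},
        recall={str(c): float(v) for c, v in zip(classes, r)},
        f1={str(c): float(v) for c, v in zip(classes, f)},
        support={str(c): int(v) for c, v in zip(classes, s)},
        weighted_precision=float(wp), weighted_recall=float(wr),
        weighted_f1=float(wf))
    if scores is not None and set(gold) <= {0, 1}:
        fpr, tpr, _ = roc_curve(gold, scores)
        report.roc_points = list(zip(fpr.tolist(), tpr.tolist()))
        report.auroc = float(auc(fpr, tpr))
    return report


# -- retraining ---------------------------------------------------------------

def build_retraining_set(validated: Iterable[CandidateTriple],
                         never_selected: Iterable[CandidateTriple],
                         strategy: str = "imbalanced",
                         n_balance: int | None = None,
                         rng_seed: int = 0,
                         ) -> list[tuple[CandidateTriple, int]]:
    """Labeled dataset from crowd feedback.

    Positives are the crowd-validated triples; negatives are triples never
    selected by any worker — all of them (``imbalanced``) or ``n_balance``
    sampled without replacement under ``rng_seed`` (``balanced``).
    """
    pos = list(validated)
    neg = list(never_selected)
    if not pos:
        raise ValueError("validated set must be non-empty")
    pos_keys = {t.key for t in pos}
    if any(t.key in pos_keys for t in neg):
        raise ValueError("validated and never-selected sets must be disjoint")

    if strategy == "imbalanced":
        chosen_neg = neg
    elif strategy == "balanced":
        if n_balance is None:
            n_balance = len(pos)
        if n_balance > len(neg):
            raise ValueError(
                f"n_balance={n_balance} exceeds the {len(neg)} available "
                "never-selected triples")
        rng = np.random.default_rng(rng_seed)
        idx = rng.choice(len(neg), size=n_balance, replace=False)
        chosen_neg = [neg[i] for i in sorted(idx)]
    else:
        raise ValueError(f"unknown strategy: {strategy!r}")

    return [(t, 1) for t in pos] + [(t, 0) for t in chosen_neg]
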