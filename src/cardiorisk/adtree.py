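"""Alternating decision tree (ADTree) classifier with probability output.

An ADTree is a boosted ensemble of decision rules arranged as a tree of
alternating splitter and prediction nodes.  The classifier starts from a
root prediction value and, at each boosting iteration, adds one rule
(precondition c1, threshold condition c2 on one feature) chosen to minimize

    Z = 2·[√(W₊(c1∧c2)·W₋(c1∧c2)) + √(W₊(c1∧¬c2)·W₋(c1∧¬c2))] + W(¬c1)

over all existing prediction nodes (preconditions) and all candidate
thresholds (midpoints of consecutive sorted unique feature values).  The
two new prediction values are a = ½·ln((W₊(c1∧c2)+ε)/(W₋(c1∧c2)+ε)) and the
analogous b for ¬c2, and instance weights update multiplicatively,
w ← w·exp(−y·r(x)).  An instance's margin is the sum of the prediction
values along every path it satisfies; the class probability is
logistic(2·margin).

The estimator follows the scikit-learn API (``fit`` / ``predict`` /
``predict_proba`` / ``decision_function``) and composes with sklearn model
selection.  By the TdP convention used here, the class mapped to margin > 0
is TdP(−) and the reported probability is that of lacking TdP association;
a probability ≥ threshold (default 0.5) classifies as negative.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.multiclass import unique_labels
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "Rule",
    "ADTreeClassifier",
    "Classification",
    "cross_validate",
    "roc_analysis",
]


@dataclass(frozen=True)
class Rule:
    """One boosting rule: split ``feature < threshold`` under a precondition.

    ``precondition`` is the index of the prediction node that must be
    reached (0 = root); rule k creates prediction nodes 2k+1 (condition
    true) and 2k+2 (condition false).
    """

    precondition: int
    feature: int
    threshold: float
    score_true: float
    score_false: float


@dataclass(frozen=True)
class Classification:
    """Prediction for one instance under the TdP sign convention."""

    p_negative: float
    margin: float
    label: str


class DegenerateModelError(ValueError):
    """Training set contains a single class."""


def _margin_to_probability(margin: np.ndarray) -> np.ndarray:
    """Map an additive margin to the positive-node class probability."""
    return 1.0 / (1.0 + np.exp(-2.0 * margin))


class ADTreeClassifier(ClassifierMixin, BaseEstimator):
    """Alternating decision tree for binary classification.

    Parameters
    ----------
    n_iterations : int
        Number of boosting rules to add (0 gives the root-only model).
    epsilon : float
        Laplace-style smoothing inside the prediction values.
    positive_class : object, optional
        The class mapped to margin > 0 (and to ``predict_proba``'s reported
        event); defaults to ``classes_[1]``.  For TdP use pass
        ``"negative"`` so margins > 0 mean lacking TdP association.
    threshold : float
        Probability cut for ``predict``; p(positive_class) ≥ threshold
        predicts ``positive_class`` (the ≥ convention keeps a margin of
        exactly 0 on the positive_class side).

    Attributes
    ----------
    root_score_ : float
        Prediction value of the root node.
    rules_ : list of Rule
        Boosting rules in insertion order.
    classes_ : ndarray
        The two class labels.
    """

    def __init__(
        self,
        n_iterations: int = 10,
        epsilon: float = 1.0,
        positive_class=None,
        threshold: float = 0.5,
    ):
        self.n_iterations = n_iterations
        self.epsilon = epsilon
        self.positive_class = positive_class
        self.threshold = threshold

    # ------------------------------------------------------------------ fit
    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        if self.n_iterations < 0:
            raise ValueError("n_iterations must be >= 0")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must be in (0, 1)")
        self.classes_ = unique_labels(y)
        if len(self.classes_) != 2:
            raise DegenerateModelError(
                f"need exactly 2 classes, got {list(self.classes_)}"
            )
        if self.positive_class is None:
            pos = self.classes_[1]
        else:
            pos = self.positive_class
            if pos not in self.classes_:
                raise ValueError(f"positive_class {pos!r} not among {list(self.classes_)}")
        self._pos_class_ = pos
        ysign = np.where(y == pos, 1.0, -1.0)
        n, p = X.shape
        self.n_features_in_ = p

        eps = float(self.epsilon)
        w = np.ones(n)
        wp = float(w[ysign > 0].sum())
        wm = float(w[ysign < 0].sum())
        self.root_score_ = 0.5 * math.log((wp + eps) / (wm + eps))
        w = w * np.exp(-ysign * self.root_score_)

        rules: list[Rule] = []
        # reach[:, node]: does each training instance reach this prediction node
        reach = np.ones((n, 1), dtype=bool)
        # candidate thresholds per feature: midpoints of consecutive unique values
        thr_by_feature = []
        for f in range(p):
            u = np.unique(X[:, f])
            thr_by_feature.append((u[:-1] + u[1:]) / 2.0 if len(u) > 1 else np.empty(0))

        for _ in range(self.n_iterations):
            total_w = float(w.sum())
            best = None  # (Z, feature, threshold, precondition, a, b, cond_mask, pre_mask)
            for pre in range(reach.shape[1]):
                mask = reach[:, pre]
                w_not_c1 = total_w - float(w[mask].sum())
                if not np.any(mask):
                    continue
                for f in range(p):
                    thrs = thr_by_feature[f]
                    if thrs.size == 0:
                        continue
                    xv = X[mask, f]
                    wv = w[mask]
                    yv = ysign[mask]
                    order = np.argsort(xv, kind="mergesort")
                    xs = xv[order]
                    wpos = np.where(yv[order] > 0, wv[order], 0.0)
                    wneg = np.where(yv[order] <= 0, wv[order], 0.0)
                    cpos = np.concatenate([[0.0], np.cumsum(wpos)])
                    cneg = np.concatenate([[0.0], np.cumsum(wneg)])
                    # position of each candidate threshold within sorted values
                    cuts = np.searchsorted(xs, thrs, side="left")
                    wp_lt = cpos[cuts]
                    wm_lt = cneg[cuts]
                    wp_ge = cpos[-1] - wp_lt
                    wm_ge = cneg[-1] - wm_lt
                    z = (
                        2.0 * (np.sqrt(wp_lt * wm_lt) + np.sqrt(wp_ge * wm_ge))
                        + w_not_c1
                    )
                    k = int(np.argmin(z))
                    zk = float(z[k])
                    cand_key = (zk, f, float(thrs[k]), pre)
                    if best is None or _better(cand_key, best[0]):
                        a = 0.5 * math.log((wp_lt[k] + eps) / (wm_lt[k] + eps))
                        b = 0.5 * math.log((wp_ge[k] + eps) / (wm_ge[k] + eps))
                        best = (cand_key, a, b)
            if best is None:
                break
            (zk, f, thr, pre), a, b = best
            rules.append(Rule(pre, f, thr, a, b))
            pre_mask = reach[:, pre]
            cond = X[:, f] < thr
            m_true = pre_mask & cond
            m_false = pre_mask & ~cond
            w[m_true] *= np.exp(-ysign[m_true] * a)
            w[m_false] *= np.exp(-ysign[m_false] * b)
            reach = np.hstack([reach, m_true[:, None], m_false[:, None]])

        self.rules_ = rules
        return self

    # ------------------------------------------------------------ predict
    def decision_function(self, X) -> np.ndarray:
        """Additive classification margin (root + satisfied rule scores)."""
        check_is_fitted(self, "rules_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}"
            )
        n = X.shape[0]
        margin = np.full(n, self.root_score_)
        reach = np.ones((n, 1 + 2 * len(self.rules_)), dtype=bool)
        for k, rule in enumerate(self.rules_):
            sat = reach[:, rule.precondition]
            cond = X[:, rule.feature] < rule.threshold
            m_true = sat & cond
            m_false = sat & ~cond
            reach[:, 2 * k + 1] = m_true
            reach[:, 2 * k + 2] = m_false
            margin += np.where(m_true, rule.score_true, 0.0)
            margin += np.where(m_false, rule.score_false, 0.0)
        return margin

    def predict_proba(self, X) -> np.ndarray:
        """Class probabilities, columns ordered as ``classes_``."""
        margin = self.decision_function(X)
        p_pos = _margin_to_probability(margin)
        proba = np.empty((len(p_pos), 2))
        for j, c in enumerate(self.classes_):
            proba[:, j] = p_pos if c == self._pos_class_ else 1.0 - p_pos
        return proba

    def predict(self, X) -> np.ndarray:
        margin = self.decision_function(X)
        p_pos = _margin_to_probability(margin)
        other = self.classes_[self.classes_ != self._pos_class_][0]
        return np.where(p_pos >= self.threshold, self._pos_class_, other)

    def classify(self, X) -> list[Classification]:
        """Domain-convention report: probability of lacking TdP association."""
        margin = self.decision_function(X)
        p = _margin_to_probability(margin)
        labels = self.predict(X)
        return [
            Classification(p_negative=float(pi), margin=float(mi), label=str(li))
            for pi, mi, li in zip(p, margin, labels)
        ]

    # ------------------------------------------------------- serialization
    def to_dict(self) -> dict:
        check_is_fitted(self, "rules_")
        return {
            "root_score": self.root_score_,
            "rules": [asdict(r) for r in self.rules_],
            "classes": [str(c) for c in self.classes_],
            "positive_class": str(self._pos_class_),
            "n_iterations": self.n_iterations,
            "epsilon": self.epsilon,
            "threshold": self.threshold,
            "n_features": self.n_features_in_,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "ADTreeClassifier":
        model = cls(
            n_iterations=d["n_iterations"],
            epsilon=d["epsilon"],
            positive_class=d["positive_class"],
            threshold=d["threshold"],
        )
        model.classes_ = np.array(d["classes"])
        model._pos_class_ = d["positive_class"]
        model.root_score_ = float(d["root_score"])
        model.rules_ = [Rule(**r) for r in d["rules"]]
        model.n_features_in_ = int(d["n_features"])
        return model

    @classmethod
    def from_json(cls, path) -> "ADTreeClassifier":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _better(cand: tuple, best: tuple) -> bool:
    """Tie-break Z comparisons: lowest Z, then feature, threshold, precondition."""
    if cand[0] < best[0] - 1e-12:
        return True
    if cand[0] > best[0] + 1e-12:
        return False
    return cand[1:] < best[1:]


def cross_validate(
    X,
    y,
    folds: int = 10,
    seed: int = 0,
    **model_params,
) -> dict:
    """Stratified k-fold cross-validation of the ADTree.

    Every instance is predicted exactly once by a model not trained on its
    fold.  Returns per-fold and pooled accuracy plus the out-of-fold
    predictions and probabilities (of the model's positive-node class).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if folds > n:
        raise ValueError(f"folds={folds} exceeds n={n}")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    predictions = np.empty(n, dtype=y.dtype)
    p_pos = np.empty(n)
    fold_of = np.empty(n, dtype=int)
    fold_accuracies = []
    for fold, (train, test) in enumerate(skf.split(X, y)):
        model = ADTreeClassifier(**model_params).fit(X[train], y[train])
        pred = model.predict(X[test])
        proba = model.predict_proba(X[test])
        pos_col = int(np.nonzero(model.classes_ == model._pos_class_)[0][0])
        predictions[test] = pred
        p_pos[test] = proba[:, pos_col]
        fold_of[test] = fold
        fold_accuracies.append(float(np.mean(pred == y[test])))
    return {
        "fold_accuracies": fold_accuracies,
        "pooled_accuracy": float(np.mean(predictions == y)),
        "predictions": predictions,
        "p_positive_class": p_pos,
        "fold_of": fold_of,
        "seed": seed,
        "folds": folds,
    }


def roc_analysis(labels, scores, event_label) -> dict:
    """ROC curve by threshold sweep plus trapezoidal AUC.

    ``scores`` are probabilities (or any monotone score) for the event
    class ``event_label``; thresholds sweep the unique scores.  Returns the
    ordered (threshold, sensitivity, specificity) points and the AUC.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    is_event = labels == event_label
    n_pos = int(is_event.sum())
    n_neg = int((~is_event).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for ROC analysis")
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    points = []
    for thr in thresholds:
        called = scores >= thr
        sens = float((called & is_event).sum()) / n_pos
        spec = float((~called & ~is_event).sum()) / n_neg
        points.append((float(thr), sens, spec))
    fpr = np.array([1.0 - p[2] for p in points])
    tpr = np.array([p[1] for p in points])
    auc = float(np.trapezoid(tpr, fpr))
    return {"points": points, "auc": auc}
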