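"""Penalized binomial logistic regression over ER features.

The classifier is

    F(x) = 1 / (1 + exp(-(b0 + b1 . x)))

with x the sparse vector of significant-pair enrichment ratios,
F(x) read as the probability that the regulation is an activation, and
1 - F(x) the probability of inhibition.  Training minimizes the total
negative log-likelihood plus lambda * ||b1||_1 (L1, the default, drives
b1 sparse over the large pair universe) or lambda/2-style L2; the
intercept is never penalized.  Fitting is delegated to scikit-learn's
saga solver with C = 1/lambda, which optimizes exactly this objective.

Evaluation is stratified k-fold cross-validation (5 folds by default)
reporting per-fold and pooled accuracy plus per-class precision and
recall, so L1 and L2 runs on the same folds can be compared directly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold

from .features import NO_FEATURE, FeatureIndex, FeatureVector, to_sparse_matrix
from .io_formats import ACTIVATION, INHIBITION

PENALTIES = ("l1", "l2")

POSITIVE_CLASS = ACTIVATION  # ties at p = 0.5 predict activation

DEFAULT_LAMBDA_GRID = tuple(float(x) for x in np.logspace(-1.0, 3.0, 9))


def _encode_labels(labels) -> np.ndarray:
    y = np.empty(len(labels), dtype=np.int8)
    for i, lab in enumerate(labels):
        if lab == ACTIVATION:
            y[i] = 1
        elif lab == INHIBITION:
            y[i] = 0
        else:
            raise ValueError(f"label {lab!r} is not activation/inhibition")
    return y


@dataclass
class LogisticModel:
    """Fitted coefficients tied to a specific feature index."""

    intercept: float
    coefficients: np.ndarray  # dense, aligned with the feature index order
    penalty: str
    lambda_: float
    namespace: str
    feature_index_digest: str = ""
    pairs: list = field(default_factory=list)  # TermPair order for serialization

    def __len__(self) -> int:
        return len(self.coefficients)

    def nonzero_pairs(self, tol: float = 1e-9) -> list:
        return [p for p, c in zip(self.pairs, self.coefficients) if abs(c) > tol]

    def n_nonzero(self, tol: float = 1e-9) -> int:
        return int(np.sum(np.abs(self.coefficients) > tol))


def _prior_model(y: np.ndarray, dim: int, penalty: str, lambda_: float,
                 index: FeatureIndex | None) -> LogisticModel:
    # degenerate single-class contract: predict the (smoothed) class prior
    p = (float(np.sum(y)) + 0.5) / (len(y) + 1.0)
    return LogisticModel(
        intercept=math.log(p / (1 - p)),
        coefficients=np.zeros(dim),
        penalty=penalty,
        lambda_=lambda_,
        namespace=index.namespace if index else "go",
        feature_index_digest=index.digest() if index else "",
        pairs=list(index.pairs) if index else [],
    )


def _refine_intercept(Xs, y: np.ndarray, coef: np.ndarray, b0: float) -> float:
    # the intercept is unpenalized, so given the coefficients its optimum
    # solves a 1-D convex problem; Newton iterations fix the saga solver's
    # tendency to leave the intercept under-converged at strong penalty
    margin = Xs @ coef
    for _ in range(100):
        p = 1.0 / (1.0 + np.exp(-(b0 + margin)))
        grad = float(np.sum(p - y))
        hess = float(np.sum(p * (1.0 - p)))
        if hess <= 0:
            break
        step = grad / hess
        b0 -= step
        if abs(step) < 1e-14:
            break
    return b0


def _column_scales(X: sparse.csr_matrix) -> np.ndarray:
    # population std per column, computed sparsely (no centering of X);
    # zero-variance columns are left unscaled
    n = X.shape[0]
    mean = np.asarray(X.mean(axis=0)).ravel()
    mean_sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    var = np.maximum(mean_sq - mean**2, 0.0)
    s = np.sqrt(var)
    s[s == 0] = 1.0
    return s


def train(
    features: list[FeatureVector],
    labels,
    penalty: str = "l1",
    lambda_: float = 1.0,
    tol: float = 1e-6,
    seed: int = 0,
    index: FeatureIndex | None = None,
    max_iter: int = 50_000,
    standardize: bool = True,
) -> LogisticModel:
    """Fit the penalized logistic model.

    The objective is the *total* negative log-likelihood plus
    ``lambda_ * ||diag(s) . b1||_1`` (or the squared L2 analogue),
    where ``s`` holds the per-feature standard deviations — i.e. the
    penalty acts on standardized coefficients, as in glmnet, so
    features on different ER scales are shrunk comparably
    (``standardize=False`` uses ``s = 1``).  The intercept is never
    penalized; ``lambda_ = 0`` is the unpenalized MLE.  Deterministic
    given ``seed``.  A single-class input returns the class-prior
    model (all coefficients zero) rather than failing.
    """
    if penalty not in PENALTIES:
        raise ValueError(f"unknown penalty {penalty!r}")
    if lambda_ < 0:
        raise ValueError("lambda must be nonnegative")
    if len(features) == 0:
        raise ValueError("cannot train on an empty feature list")
    if len(features) != len(labels):
        raise ValueError("features and labels length mismatch")
    y = _encode_labels(labels)
    X = to_sparse_matrix(features)
    if len(np.unique(y)) < 2:
        return _prior_model(y, X.shape[1], penalty, lambda_, index)
    scales = _column_scales(X) if standardize else np.ones(X.shape[1])
    Xs = X @ sparse.diags(1.0 / scales)
    if lambda_ == 0:
        clf = LogisticRegression(
            C=np.inf, solver="lbfgs", tol=tol, max_iter=max_iter,
        )
    else:
        clf = LogisticRegression(
            C=1.0 / lambda_, l1_ratio=1.0 if penalty == "l1" else 0.0,
            solver="saga", tol=tol, max_iter=max_iter, random_state=seed,
        )
    clf.fit(Xs, y)
    if clf.n_iter_[0] >= max_iter:
        raise RuntimeError(
            f"logistic solver did not converge within {max_iter} iterations "
            f"(penalty={penalty}, lambda={lambda_})"
        )
    coef_s = np.asarray(clf.coef_[0], dtype=float)
    return LogisticModel(
        intercept=_refine_intercept(Xs, y, coef_s, float(clf.intercept_[0])),
        coefficients=coef_s / scales,
        penalty=penalty,
        lambda_=lambda_,
        namespace=index.namespace if index else "go",
        feature_index_digest=index.digest() if index else "",
        pairs=list(index.pairs) if index else [],
    )


def predict_proba(model: LogisticModel, x: FeatureVector) -> tuple[float, float, str]:
    """(p_activation, p_inhibition, label) for one feature vector."""
    if x.dimension != len(model.coefficients):
        raise ValueError(
            f"dimension mismatch: vector {x.dimension} vs model {len(model.coefficients)}"
        )
    z = model.intercept + sum(model.coefficients[i] * v for i, v in x.entries)
    p_act = 1.0 / (1.0 + math.exp(-z))
    label = ACTIVATION if p_act >= 0.5 else INHIBITION
    return p_act, 1.0 - p_act, label


def predict_labels(model: LogisticModel, features: list[FeatureVector]) -> list[str]:
    return [predict_proba(model, x)[2] for x in features]


# ---------------------------------------------------------------------------
# lambda selection and cross-validation
# ---------------------------------------------------------------------------

def select_lambda(
    features: list[FeatureVector],
    labels,
    penalty: str = "l1",
    grid=DEFAULT_LAMBDA_GRID,
    k: int = 5,
    seed: int = 0,
    tol: float = 1e-4,
) -> float:
    """Pick lambda by inner stratified k-fold CV over a log grid.

    Uses the one-standard-error rule: among all lambdas whose mean
    fold accuracy is within one standard error of the best, the
    largest (sparsest) wins — the usual guard against the tendency of
    plain CV to overselect features.
    """
    y = _encode_labels(labels)
    k_eff = min(k, int(np.min(np.bincount(y, minlength=2))))
    if k_eff < 2:
        return float(grid[len(grid) // 2])
    splitter = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
    feats = np.array(features, dtype=object)
    labs = np.array(labels, dtype=object)
    folds = list(splitter.split(np.zeros(len(y)), y))
    mean_acc, se_acc = {}, {}
    for lam in grid:
        accs = []
        for tr, te in folds:
            m = train(list(feats[tr]), list(labs[tr]), penalty, lam, tol, seed)
            pred = predict_labels(m, list(feats[te]))
            accs.append(float(np.mean([p == t for p, t in zip(pred, labs[te])])))
        mean_acc[lam] = float(np.mean(accs))
        se_acc[lam] = float(np.std(accs, ddof=1) / np.sqrt(len(accs)))
    best = max(grid, key=lambda lam: (mean_acc[lam], lam))
    threshold = mean_acc[best] - se_acc[best]
    return max(lam for lam in grid if mean_acc[lam] >= threshold)


@dataclass
class EvalReport:
    """Cross-validation metrics: per-fold and pooled over held-out folds."""

    k: int
    seed: int
    penalty: str
    lambda_: float | None
    fold_metrics: list[dict]
    pooled: dict
    class_counts: dict

    def to_tsv(self, path: str) -> None:
        cols = ["fold", "n", "accuracy",
                "precision_activation", "recall_activation",
                "precision_inhibition", "recall_inhibition"]
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(cols) + "\n")
            for i, fm in enumerate(self.fold_metrics):
                fh.write("\t".join([str(i)] + [f"{fm[c]:.6g}" for c in cols[1:]]) + "\n")
            fh.write("\t".join(["pooled"] + [f"{self.pooled[c]:.6g}" for c in cols[1:]]) + "\n")


def _metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    def prf(cls):
        tp = int(np.sum((y_pred == cls) & (y_true == cls)))
        fp = int(np.sum((y_pred == cls) & (y_true != cls)))
        fn = int(np.sum((y_pred != cls) & (y_true == cls)))
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        return prec, rec

    pa, ra = prf(1)
    pi, ri = prf(0)
    return {
        "n": int(len(y_true)),
        "accuracy": float(np.mean(y_true == y_pred)),
        "precision_activation": pa,
        "recall_activation": ra,
        "precision_inhibition": pi,
        "recall_inhibition": ri,
    }


def crossvalidate(
    features: list[FeatureVector],
    labels,
    k: int = 5,
    penalty: str = "l1",
    lambda_: float | None = None,
    seed: int = 0,
    tol: float = 1e-6,
    stratified: bool = True,
) -> EvalReport:
    """Stratified (by default) k-fold CV on fixed feature vectors.

    ``lambda_ = None`` triggers nested selection by ``select_lambda``
    within each training fold.  Same seed => same folds => identical
    report, so L1 vs L2 comparisons share splits.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(features) < k:
        raise ValueError(f"need at least k={k} samples, got {len(features)}")
    y = _encode_labels(labels)
    feats = np.array(features, dtype=object)
    labs = np.array(labels, dtype=object)
    if stratified:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    fold_metrics = []
    pooled_true, pooled_pred = [], []
    for tr, te in splitter.split(np.zeros(len(y)), y):
        lam = lambda_
        if lam is None:
            lam = select_lambda(list(feats[tr]), list(labs[tr]), penalty, seed=seed)
        m = train(list(feats[tr]), list(labs[tr]), penalty, lam, tol, seed)
        pred = _encode_labels(predict_labels(m, list(feats[te])))
        fold_metrics.append(_metrics(y[te], pred))
        pooled_true.append(y[te])
        pooled_pred.append(pred)
    pooled = _metrics(np.concatenate(pooled_true), np.concatenate(pooled_pred))
    return EvalReport(
        k=k, seed=seed, penalty=penalty, lambda_=lambda_,
        fold_metrics=fold_metrics, pooled=pooled,
        class_counts={
            ACTIVATION: int(np.sum(y == 1)),
            INHIBITION: int(np.sum(y == 0)),
        },
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

MODEL_FORMAT_VERSION = 1


def save_model(model: LogisticModel, path: str) -> None:
    """Versioned JSON: intercept, sparse coefficients keyed by pair."""
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "intercept": model.intercept,
        "penalty": model.penalty,
        "lambda": model.lambda_,
        "namespace": model.namespace,
        "feature_index_digest": model.feature_index_digest,
        "pairs": [[p.left, p.right] for p in model.pairs],
        "coefficients": {
            str(i): c for i, c in enumerate(model.coefficients) if c != 0.0
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)


def load_model(path: str) -> LogisticModel:
    from .enrichment import TermPair

    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {doc.get('format_version')}")
    pairs = [TermPair(l, r, doc["namespace"]) for l, r in doc["pairs"]]
    coef = np.zeros(len(pairs))
    for i, c in doc["coefficients"].items():
        coef[int(i)] = c
    return LogisticModel(
        intercept=float(doc["intercept"]),
        coefficients=coef,
        penalty=doc["penalty"],
        lambda_=float(doc["lambda"]),
        namespace=doc["namespace"],
        feature_index_digest=doc["feature_index_digest"],
        pairs=pairs,
    )
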