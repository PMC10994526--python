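"""Multiclass linear discriminant analysis on eigenbrain scores.

The classifier models each diagnostic class as a Gaussian with its own
mean and a shared (pooled within-class) covariance, assigns subjects to
the class maximizing the linear discriminant score, and embeds subjects
on at most ``n_classes - 1`` discriminant axes (three for the four
diagnostic groups).  Reported accuracy is resubstitution (training-set)
accuracy by default; an optional stratified k-fold mode is available and
clearly an extension of the core report.

Two variants address heteroscedastic, non-normal score distributions:

* ``log``   — a signed log transform sign(x) * ln(1 + |x|) of the scores
  (scores can be negative, so the plain log is not defined) before a
  standard fit;
* ``robust`` — class locations/scatters from high-breakdown minimum
  covariance determinant (MCD) estimates, pooled by class size.  MCD
  needs more subjects than features per class and errors loudly when a
  class is too small.

:func:`analytic_gaussian_accuracy` is a closed-form oracle for the
single-feature case (used for the age-only baseline): the equal-variance
decision regions are resolved exactly from pairwise boundaries and the
expected accuracy integrates each class's own normal over its region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.stats import norm
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.covariance import MinCovDet
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "EigenvalueLDA",
    "LDAReport",
    "confusion_matrix",
    "overall_accuracy",
    "signed_log_transform",
    "fit_lda",
    "fit_robust_lda",
    "predict_report",
    "analytic_gaussian_accuracy",
    "monte_carlo_gaussian_accuracy",
]


def signed_log_transform(scores: np.ndarray) -> np.ndarray:
    """Odd, monotone log compression: y = sign(x) * ln(1 + |x|)."""
    x = np.asarray(scores, dtype=float)
    return np.sign(x) * np.log1p(np.abs(x))


def confusion_matrix(y_true, y_pred, labels=None) -> pd.DataFrame:
    """True-by-predicted count table (rows sum to the class sizes)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if labels is None:
        labels = list(np.unique(np.concatenate([y_true, y_pred])))
    table = pd.DataFrame(0, index=list(labels), columns=list(labels), dtype=int)
    for t, p in zip(y_true, y_pred):
        table.loc[t, p] += 1
    return table


def overall_accuracy(confusion: pd.DataFrame) -> float:
    """Trace over total of a confusion matrix."""
    total = int(confusion.to_numpy().sum())
    return float(np.trace(confusion.to_numpy()) / total)


@dataclass(frozen=True)
class LDAReport:
    predictions: np.ndarray
    embedding: np.ndarray  # subjects x (<= 3) discriminant axes
    confusion: pd.DataFrame  # true (rows) x predicted (columns)
    overall_accuracy: float
    per_class_accuracy: dict


class EigenvalueLDA(BaseEstimator, ClassifierMixin):
    """Gaussian LDA with shared covariance on eigenbrain scores.

    Parameters
    ----------
    variant : {"standard", "log", "robust"}
        "log" applies :func:`signed_log_transform` to the features before
        fitting and before prediction; "robust" replaces class means and
        pooled covariance with per-class MCD estimates.
    priors : array-like or None
        Class priors; class proportions when None.
    support_fraction : float
        MCD support fraction per class (robust variant only).
    random_state : int
        Seeds the MCD subsampling; the fit is deterministic given it.
    """

    def __init__(self, variant: str = "standard", priors=None,
                 support_fraction: float = 0.75, random_state: int = 0):
        self.variant = variant
        self.priors = priors
        self.support_fraction = support_fraction
        self.random_state = random_state

    # -- fitting ----------------------------------------------------------
    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim == 1:
            X = X[:, None]
        if self.variant not in ("standard", "log", "robust"):
            raise ValueError("variant must be standard, log or robust")
        if self.variant == "log":
            X = signed_log_transform(X)
        classes, y_idx = np.unique(y, return_inverse=True)
        n, p = X.shape
        C = len(classes)
        if C < 2:
            raise ValueError("need >= 2 classes")
        counts = np.bincount(y_idx, minlength=C)
        if np.any(counts < 2):
            raise ValueError(f"classes with < 2 subjects: {list(classes[counts < 2])}")
        if n <= C:
            raise ValueError("need more subjects than classes")

        if self.variant == "robust":
            means = np.empty((C, p))
            pooled = np.zeros((p, p))
            for k in range(C):
                Xk = X[y_idx == k]
                if len(Xk) < p + 1:
                    raise ValueError(
                        f"class {classes[k]!r} has {len(Xk)} subjects but robust "
                        f"scatter estimation needs more than {p} features' worth "
                        f"(n_k > p); reduce the feature count first"
                    )
                mcd = MinCovDet(support_fraction=self.support_fraction,
                                random_state=self.random_state).fit(Xk)
                means[k] = mcd.location_
                pooled += (len(Xk) - 1) * mcd.covariance_
            pooled /= n - C
        else:
            means = np.stack([X[y_idx == k].mean(axis=0) for k in range(C)])
            pooled = np.zeros((p, p))
            for k in range(C):
                d = X[y_idx == k] - means[k]
                pooled += d.T @ d
            pooled /= n - C

        # discriminant axes from the generalized eigenproblem Sb w = lambda Sw w
        overall = (counts[:, None] * means).sum(axis=0) / n
        Sb = np.zeros((p, p))
        for k in range(C):
            d = (means[k] - overall)[:, None]
            Sb += counts[k] * (d @ d.T)
        Sw = pooled * (n - C)
        try:
            evals, evecs = linalg.eigh(Sb, Sw)
        except linalg.LinAlgError as exc:
            raise ValueError(
                "singular within-class scatter (collinear or duplicated features); "
                "reduce the feature set"
            ) from exc
        if not np.all(np.isfinite(evals)):
            raise ValueError(
                "singular within-class scatter (collinear or duplicated features); "
                "reduce the feature set"
            )
        order = np.argsort(evals)[::-1]
        rank = min(C - 1, int(np.linalg.matrix_rank(Sb, tol=1e-10)))
        self.scalings_ = evecs[:, order[:rank]]
        self.explained_ratios_ = (
            evals[order[:rank]] / evals[order[:rank]].sum()
            if rank > 0 and evals[order[:rank]].sum() > 0
            else np.array([])
        )

        pri = (counts / n if self.priors is None
               else np.asarray(self.priors, dtype=float))
        if len(pri) != C or not np.isclose(pri.sum(), 1.0):
            raise ValueError("priors must have one entry per class and sum to 1")
        cov_inv = linalg.pinvh(pooled)
        if not np.all(np.isfinite(cov_inv)):
            raise ValueError("singular pooled covariance")

        self.classes_ = classes
        self.means_ = means
        self.covariance_ = pooled
        self.priors_ = pri
        self._cov_inv = cov_inv
        self.n_features_in_ = p
        self.n_axes_ = rank
        return self

    # -- prediction -------------------------------------------------------
    def _features(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature count {X.shape[1]} does not match model ({self.n_features_in_})"
            )
        if self.variant == "log":
            X = signed_log_transform(X)
        return X

    def decision_scores(self, X) -> np.ndarray:
        """Linear discriminant score per class (shared-covariance Gaussian)."""
        check_is_fitted(self, "classes_")
        X = self._features(X)
        A = self.means_ @ self._cov_inv  # C x p
        const = -0.5 * np.einsum("ij,ij->i", A, self.means_) + np.log(self.priors_)
        return X @ A.T + const

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_scores(X), axis=1)]

    def transform(self, X) -> np.ndarray:
        """Embedding on the discriminant axes (at most C - 1, here <= 3)."""
        check_is_fitted(self, "scalings_")
        return self._features(X) @ self.scalings_

    # -- reporting --------------------------------------------------------
    def report(self, X, y, cv: int | None = None) -> LDAReport:
        """Confusion matrix, overall and per-class accuracy, 3-D embedding.

        Resubstitution by default; ``cv=k`` switches to stratified k-fold
        cross-validated predictions (an extension beyond the core report).
        """
        check_is_fitted(self, "classes_")
        y = np.asarray(y)
        if cv is None:
            pred = self.predict(X)
        else:
            X_arr = np.asarray(X, dtype=float)
            pred = np.empty(len(y), dtype=y.dtype)
            skf = StratifiedKFold(n_splits=cv, shuffle=True,
                                  random_state=self.random_state)
            for tr, te in skf.split(X_arr, y):
                fold = EigenvalueLDA(**self.get_params()).fit(X_arr[tr], y[tr])
                pred[te] = fold.predict(X_arr[te])
        labels = list(self.classes_)
        confusion = confusion_matrix(y, pred, labels=labels)
        overall = overall_accuracy(confusion)
        per_class = {
            g: float(confusion.loc[g, g] / confusion.loc[g].sum()) for g in labels
        }
        emb = self.transform(X)[:, :3]
        return LDAReport(predictions=pred, embedding=emb, confusion=confusion,
                         overall_accuracy=overall, per_class_accuracy=per_class)


# -- functional wrappers ----------------------------------------------------

def fit_lda(scores, labels, priors=None) -> EigenvalueLDA:
    return EigenvalueLDA(variant="standard", priors=priors).fit(scores, labels)


def fit_robust_lda(scores, labels, support_fraction: float = 0.75,
                   random_state: int = 0) -> EigenvalueLDA:
    return EigenvalueLDA(variant="robust", support_fraction=support_fraction,
                         random_state=random_state).fit(scores, labels)


def predict_report(model: EigenvalueLDA, scores, labels, cv: int | None = None) -> LDAReport:
    return model.report(scores, labels, cv=cv)


# -- analytic single-feature oracle -----------------------------------------

def _lda_lines(class_means, class_sds, class_ns):
    mu = np.asarray(class_means, dtype=float)
    sd = np.asarray(class_sds, dtype=float)
    n = np.asarray(class_ns, dtype=float)
    if len(mu) < 2 and len(mu) != 1:
        raise ValueError("need >= 1 class")
    if np.any(sd <= 0):
        raise ValueError("class SDs must be positive")
    if len(np.unique(mu)) != len(mu):
        raise ValueError("duplicate class means: degenerate decision boundaries")
    pooled = float(((n - 1) * sd**2).sum() / (n.sum() - len(mu)))
    pri = n / n.sum()
    a = mu / pooled
    b = -(mu**2) / (2 * pooled) + np.log(pri)
    return mu, sd, pri, a, b


def _decision_regions(a, b):
    """Exact argmax regions of linear discriminants a_k x + b_k.

    The winner can only change where two lines intersect, so evaluating
    midpoints between consecutive intersection abscissae resolves the
    regions exactly.  Returns (edges, winners) with len(edges) =
    len(winners) + 1.
    """
    C = len(a)
    if C == 1:
        return np.array([-np.inf, np.inf]), np.array([0])
    pts = []
    for i in range(C):
        for j in range(i + 1, C):
            if a[i] != a[j]:
                pts.append((b[j] - b[i]) / (a[i] - a[j]))
    pts = np.unique(np.asarray(pts, dtype=float))
    probes = np.concatenate([[pts[0] - 1.0], (pts[:-1] + pts[1:]) / 2.0, [pts[-1] + 1.0]])
    winners = np.argmax(a[:, None] * probes[None, :] + b[:, None], axis=0)
    edges = [-np.inf]
    merged = [winners[0]]
    for cut, w in zip(pts, winners[1:]):
        if w != merged[-1]:
            edges.append(cut)
            merged.append(w)
    edges.append(np.inf)
    return np.asarray(edges), np.asarray(merged)


def analytic_gaussian_accuracy(class_means, class_sds, class_ns) -> float:
    """Expected accuracy of the univariate equal-variance LDA rule.

    The rule pools variance from the class SDs (n-1 weights) and uses
    priors proportional to class sizes; the truth keeps each class's own
    normal (its printed mean and SD).  Expected accuracy is the
    prior-weighted probability that a draw from class k lands in class k's
    decision region, computed from normal CDFs over the exact regions.
    """
    mu, sd, pri, a, b = _lda_lines(class_means, class_sds, class_ns)
    if len(mu) == 1:
        return 1.0
    edges, winners = _decision_regions(a, b)
    acc = 0.0
    for lo, hi, k in zip(edges[:-1], edges[1:], winners):
        acc += pri[k] * (norm.cdf(hi, mu[k], sd[k]) - norm.cdf(lo, mu[k], sd[k]))
    return float(acc)


def monte_carlo_gaussian_accuracy(class_means, class_sds, class_ns,
                                  n_draws: int = 1_000_000, seed: int = 0) -> float:
    """Simulation oracle for :func:`analytic_gaussian_accuracy`."""
    mu, sd, pri, a, b = _lda_lines(class_means, class_sds, class_ns)
    if len(mu) == 1:
        return 1.0
    rng = np.random.default_rng(seed)
    ks = rng.choice(len(mu), size=n_draws, p=pri)
    x = rng.normal(mu[ks], sd[ks])
    pred = np.argmax(a[:, None] * x[None, :] + b[:, None], axis=0)
    return float(np.mean(pred == ks))
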