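"""Core estimators and metrics.

* NIPALS partial least squares (regression and one-hot discriminant form)
  with nested-component prediction — prediction at any number of components
  ``a <= A`` comes from the same fit, which the elimination ladder in
  :mod:`flavorlink.rdcv_selection` relies on for speed;
* VIP (variable importance in projection), normalized so the squared scores
  average to one;
* a bagged regression forest with out-of-bag permutation importance (mean
  decrease in accuracy), built over scikit-learn decision trees with
  explicitly tracked bootstrap indices so the OOB sets are known;
* balanced accuracy (mean of per-class TPR and TNR), cross-validated Q2 and
  RMSEP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

logger = logging.getLogger(__name__)

__all__ = [
    "PLSModel",
    "fit_pls",
    "vip",
    "plsda_predict",
    "one_hot",
    "ConfusionSummary",
    "confusion_summary",
    "balanced_accuracy",
    "q_squared",
    "rmsep",
    "RandomForestMDA",
    "rf_rank",
    "rank_from_importance",
]

_NIPALS_TOL = 1e-10  # rank/degeneracy threshold
_NIPALS_CONV = 1e-13  # weight-vector convergence threshold
_NIPALS_MAX_ITER = 1000


@dataclass
class PLSModel:
    """Fitted NIPALS PLS model.

    Arrays follow the usual chemometrics notation: X-weights ``W`` (p x A),
    X-loadings ``P`` (p x A), Y-loadings ``Q`` (m x A), X-scores ``T``
    (n x A).  ``ss_y`` holds the Y sum of squares captured by each component
    (used by VIP).  Coefficients for any truncation a <= A are available via
    :meth:`coef` / :meth:`predict`.
    """

    n_components: int
    W: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    T: np.ndarray
    ss_y: np.ndarray
    x_mean: np.ndarray
    y_mean: np.ndarray

    def coef(self, n_components: int | None = None) -> np.ndarray:
        """Regression coefficient matrix B (p x m) for the first ``a``
        components: B = W_a (P_a' W_a)^{-1} Q_a'."""
        a = self.n_components if n_components is None else n_components
        if not 1 <= a <= self.n_components:
            raise ValueError(f"n_components must be in 1..{self.n_components}")
        W, P, Q = self.W[:, :a], self.P[:, :a], self.Q[:, :a]
        return W @ np.linalg.solve(P.T @ W, Q.T)

    def predict(self, X: np.ndarray, n_components: int | None = None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.x_mean) @ self.coef(n_components) + self.y_mean

    def predict_all_components(self, X: np.ndarray) -> list[np.ndarray]:
        """Predictions at every truncation 1..A (one pass per size)."""
        return [self.predict(X, a) for a in range(1, self.n_components + 1)]

    def to_dict(self) -> dict:
        """JSON-serializable structure + arrays, for reproducible storage."""
        return {
            "n_components": self.n_components,
            **{
                k: getattr(self, k).tolist()
                for k in ("W", "P", "Q", "T", "ss_y", "x_mean", "y_mean")
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PLSModel":
        return cls(
            n_components=int(d["n_components"]),
            **{
                k: np.asarray(d[k], dtype=float)
                for k in ("W", "P", "Q", "T", "ss_y", "x_mean", "y_mean")
            },
        )


def fit_pls(X: np.ndarray, Y: np.ndarray, n_components: int) -> PLSModel:
    """Fit a PLS model by NIPALS with standard deflation.

    X and Y are centered internally (no scaling: the pipeline autoscales
    upstream).  The requested component count is reduced with a warning when
    the X residual collapses first.  Deterministic: no randomness is
    involved.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    m = Y.shape[1]
    if n < 2:
        raise ValueError("need at least 2 samples")
    if Y.shape[0] != n:
        raise ValueError("X and Y row counts differ")
    if np.isnan(X).any() or np.isnan(Y).any():
        raise ValueError("missing values are not supported; impute upstream")
    max_a = min(n - 1, p)
    if n_components > max_a:
        logger.warning(
            "reducing n_components from %d to rank limit %d", n_components, max_a
        )
        n_components = max_a
    if n_components < 1:
        raise ValueError("n_components must be >= 1")

    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    Yc = Y - y_mean
    x_scale = np.abs(Xc).max(initial=0.0)
    if x_scale == 0:
        raise ValueError("X has no variance")

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros((m, n_components))
    T = np.zeros((n, n_components))
    ss_y = np.zeros(n_components)
    a_done = 0
    for a in range(n_components):
        if np.abs(Xc).max(initial=0.0) < _NIPALS_TOL * x_scale:
            logger.warning("X residual exhausted after %d components", a_done)
            break
        # initialize u with the largest-variance Y residual column
        u = Yc[:, int(np.argmax((Yc**2).sum(axis=0)))].copy()
        if (u**2).sum() < _NIPALS_TOL:
            break
        w = np.zeros(p)
        for _ in range(_NIPALS_MAX_ITER):
            w_new = Xc.T @ u
            norm = np.linalg.norm(w_new)
            if norm < _NIPALS_TOL * x_scale:
                break
            w_new /= norm
            t = Xc @ w_new
            tt = t @ t
            if tt < _NIPALS_TOL:
                break
            q = Yc.T @ t / tt
            qq = q @ q
            if qq < _NIPALS_TOL**2 or m == 1:
                u_new = t if m == 1 else u
                w = w_new
                if m == 1:
                    # single-response NIPALS converges in one pass
                    u = Yc[:, 0]
                break
            u_new = Yc @ q / qq
            if np.linalg.norm(w_new - w) < _NIPALS_CONV:
                w = w_new
                u = u_new
                break
            w = w_new
            u = u_new
        t = Xc @ w
        tt = t @ t
        if tt < _NIPALS_TOL:
            break
        pvec = Xc.T @ t / tt
        q = Yc.T @ t / tt
        Xc = Xc - np.outer(t, pvec)
        Yc = Yc - np.outer(t, q)
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, pvec, q, t
        ss_y[a] = tt * (q @ q)
        a_done += 1
    if a_done == 0:
        raise ValueError("no PLS component could be extracted (Y constant?)")
    return PLSModel(
        n_components=a_done,
        W=W[:, :a_done],
        P=P[:, :a_done],
        Q=Q[:, :a_done],
        T=T[:, :a_done],
        ss_y=ss_y[:a_done],
        x_mean=x_mean,
        y_mean=y_mean,
    )


def vip(model: PLSModel, n_components: int | None = None) -> np.ndarray:
    """Variable importance in projection.

    VIP_f = sqrt( p * sum_a SS_a (w_af / ||w_a||)^2 / sum_a SS_a ), with
    SS_a the Y sum of squares explained by component a; by construction the
    squared scores sum to p.  For multi-response Y the SS_a are summed over
    responses (Y-variance-weighted).
    """
    a = model.n_components if n_components is None else n_components
    W = model.W[:, :a]
    ss = model.ss_y[:a]
    total = ss.sum()
    if total <= 0:
        raise ValueError("model explains no Y variance; VIP undefined")
    wnorm2 = (W**2).sum(axis=0)
    wnorm2[wnorm2 == 0] = 1.0
    p = W.shape[0]
    return np.sqrt(p * ((W**2 / wnorm2) @ ss) / total)


def one_hot(labels: np.ndarray, classes: list | None = None) -> tuple[np.ndarray, list]:
    """Dummy-code labels into an n x L indicator matrix.

    Class order is first-appearance order in the training labels (this order
    also breaks prediction ties)."""
    labels = np.asarray(labels)
    if classes is None:
        classes = list(dict.fromkeys(labels.tolist()))
    idx = {c: i for i, c in enumerate(classes)}
    Y = np.zeros((len(labels), len(classes)))
    for r, lab in enumerate(labels):
        Y[r, idx[lab]] = 1.0
    return Y, classes


def plsda_predict(
    model: PLSModel, X_new: np.ndarray, class_labels: list, n_components: int | None = None
) -> np.ndarray:
    """Decode PLS-DA dummy predictions by argmax; ties go to the earliest
    training label (np.argmax's first-maximum rule)."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.shape[1] != model.W.shape[0]:
        raise ValueError(
            f"feature count mismatch: model has {model.W.shape[0]}, X has {X_new.shape[1]}"
        )
    scores = model.predict(X_new, n_components)
    if scores.shape[1] != len(class_labels):
        raise ValueError("class_labels length does not match model responses")
    return np.asarray(class_labels, dtype=object)[scores.argmax(axis=1)]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


@dataclass
class ConfusionSummary:
    """Per-class true-positive and true-negative rates."""

    classes: list
    tpr: np.ndarray
    tnr: np.ndarray
    counts: np.ndarray  # per-class true counts


def confusion_summary(y_true, y_pred, classes: list | None = None) -> ConfusionSummary:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if classes is None:
        classes = sorted(set(y_true.tolist()))
    tpr = np.zeros(len(classes))
    tnr = np.zeros(len(classes))
    counts = np.zeros(len(classes), dtype=int)
    for i, c in enumerate(classes):
        pos = y_true == c
        neg = ~pos
        counts[i] = pos.sum()
        if pos.sum() == 0:
            raise ValueError(f"class {c!r} has no true members; TPR undefined")
        if neg.sum() == 0:
            raise ValueError(f"class {c!r} covers all samples; TNR undefined")
        tpr[i] = np.mean(y_pred[pos] == c)
        tnr[i] = np.mean(y_pred[neg] != c)
    return ConfusionSummary(classes=list(classes), tpr=tpr, tnr=tnr, counts=counts)


def balanced_accuracy(c: ConfusionSummary) -> float:
    """BACC = sum_i (TPR_i + TNR_i) / (2L); 0.5 is the random baseline for
    balanced binary problems."""
    L = len(c.classes)
    if L < 2:
        raise ValueError("balanced accuracy needs >= 2 classes")
    return float((c.tpr + c.tnr).sum() / (2 * L))


def q_squared(y: np.ndarray, yhat_cv: np.ndarray) -> float:
    """Cross-validated coefficient of prediction: 1 - PRESS/TSS, with yhat
    the out-of-fold predictions.  Negative values mean worse than the mean."""
    y = np.asarray(y, dtype=float)
    yhat_cv = np.asarray(yhat_cv, dtype=float)
    if y.shape != yhat_cv.shape:
        raise ValueError("y and yhat_cv must have equal shapes")
    if len(y) < 2:
        raise ValueError("need at least 2 observations")
    tss = ((y - y.mean()) ** 2).sum()
    if tss == 0:
        raise ValueError("constant y: Q2 undefined")
    return float(1.0 - ((y - yhat_cv) ** 2).sum() / tss)


def rmsep(y: np.ndarray, yhat_cv: np.ndarray) -> float:
    """Root-mean-squared error of (out-of-fold) prediction."""
    y = np.asarray(y, dtype=float)
    yhat_cv = np.asarray(yhat_cv, dtype=float)
    if y.shape != yhat_cv.shape:
        raise ValueError("y and yhat_cv must have equal shapes")
    return float(np.sqrt(np.mean((y - yhat_cv) ** 2)))


# ---------------------------------------------------------------------------
# random forest with OOB permutation importance
# ---------------------------------------------------------------------------


@dataclass
class RandomForestMDA:
    """Bagged regression trees with explicit bootstrap bookkeeping."""

    trees: list = field(default_factory=list)
    oob_indices: list = field(default_factory=list)
    n_features: int = 0
    importance: np.ndarray | None = None  # OOB mean decrease in accuracy

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        preds = np.zeros(len(X))
        for tree in self.trees:
            preds += tree.predict(X)
        return preds / len(self.trees)


def rf_fit(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 500,
    seed: int = 0,
    compute_importance: bool = True,
) -> RandomForestMDA:
    """Fit a bagged regression forest and compute OOB permutation importance.

    Per tree: a bootstrap of n samples, a scikit-learn regression tree with
    mtry = ceil(p/3) candidate features per split, unlimited depth.
    Importance of feature f = mean over trees of the increase in OOB mean
    squared error after permuting column f within the tree's OOB rows
    (mean decrease in accuracy, regression form).  Deterministic under seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 5:
        raise ValueError("need at least 5 samples for a forest")
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    rng = np.random.RandomState(seed)
    mtry = int(np.ceil(p / 3))
    forest = RandomForestMDA(n_features=p)
    mda = np.zeros(p)
    n_oob_trees = np.zeros(p)
    for _ in range(n_trees):
        boot = rng.randint(0, n, n)
        oob = np.setdiff1d(np.arange(n), boot)
        tree = DecisionTreeRegressor(
            max_features=mtry, random_state=rng.randint(0, 2**31 - 1)
        )
        tree.fit(X[boot], y[boot])
        forest.trees.append(tree)
        forest.oob_indices.append(oob)
        if compute_importance and len(oob) >= 2:
            Xo = X[oob]
            base = np.mean((tree.predict(Xo) - y[oob]) ** 2)
            perm = rng.permutation(len(oob))
            for f in range(p):
                Xp = Xo.copy()
                Xp[:, f] = Xo[perm, f]
                err = np.mean((tree.predict(Xp) - y[oob]) ** 2)
                mda[f] += err - base
                n_oob_trees[f] += 1
    if compute_importance:
        with np.errstate(invalid="ignore"):
            forest.importance = np.where(n_oob_trees > 0, mda / np.maximum(n_oob_trees, 1), 0.0)
    return forest


def rank_from_importance(importance: np.ndarray) -> np.ndarray:
    """Ranks 1..p, 1 = most important; ties broken by feature position."""
    order = np.lexsort((np.arange(len(importance)), -np.asarray(importance)))
    ranks = np.empty(len(importance), dtype=int)
    ranks[order] = np.arange(1, len(importance) + 1)
    return ranks


def rf_rank(
    X: np.ndarray, y: np.ndarray, n_trees: int = 500, seed: int = 0
) -> tuple[RandomForestMDA, np.ndarray]:
    """Fit a forest and return it with the MDA-based rank vector."""
    forest = rf_fit(X, y, n_trees=n_trees, seed=seed, compute_importance=True)
    return forest, rank_from_importance(forest.importance)
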