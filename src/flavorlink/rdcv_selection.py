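"""Repeated double cross-validation feature selection.

The engine eliminates features iteratively inside a nested cross-validation
and ranks them by importance, in the style of the MUVR framework:

per repetition (reshuffled folds each time):

1. split the samples into ``n_outer`` stratified folds (by class for
   classification, by response quantile for regression);
2. holding out each outer fold in turn, run an ``n_inner``-fold inner CV on
   the remaining samples over a descending feature ladder — at every ladder
   step fit the engine (PLS or random forest), rank the current features by
   importance (VIP or OOB mean decrease in accuracy averaged over the inner
   folds), record the inner validation error (misclassification count for
   classification, RMSEP for regression), and drop the worst
   ``elimination_fraction`` of features;
3. read the per-fold validation curve: ``n_min`` is the smallest ladder size
   whose inner error is within ``(1 + tolerance)`` of the minimum, ``n_max``
   the largest such size, ``n_mid`` their rounded geometric mean;
4. refit on the full outer-training set at each of the three sizes (top
   features by the fold's fused ranks) and predict the held-out fold;
5. fuse per-feature ranks over ladder steps (arithmetic mean; a feature
   absent from a step scores ``step size + 1``).

Across repetitions, ranks are averaged, the three set sizes are medians, and
performance — balanced accuracy for classification, Q2 for regression — is
computed from the pooled out-of-fold outer predictions only, so there is no
leakage from the inner selection loop into the reported performance.

For PLS, the component count at each ladder step is chosen as the argmin of
the inner validation error over ``1..max_components``; the classification
fitness minimized during elimination is the raw misclassification count,
with balanced accuracy used only for final reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from .design_io import StudyDesign, FACTOR_NAMES
from .feature_processing import ProcessedTable
from .models import (
    balanced_accuracy,
    confusion_summary,
    fit_pls,
    one_hot,
    plsda_predict,
    q_squared,
    rank_from_importance,
    rf_fit,
    vip,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionConfig",
    "SelectionResult",
    "rdcv_select",
    "classify_composition",
    "predict_attribute",
]


@dataclass
class SelectionConfig:
    """Knobs of the rdCV engine.

    Defaults mirror the study-scale protocol (4 outer folds / 500
    repetitions for classification, 9 folds / 200 repetitions for
    regression); pass smaller ``n_repetitions`` for desk-scale runs.
    ``None`` fields are resolved per task by :meth:`resolved`.
    """

    task: str = "classification"  # or "regression"
    engine: str = "pls"  # or "rf"
    n_outer: int | None = None
    n_repetitions: int | None = None
    n_inner: int | None = None
    elimination_fraction: float = 0.10
    max_components: int = 5
    tolerance: float = 0.05
    n_trees: int = 300  # rf engine only
    performance_pooling: str = "pooled"  # or "per_repetition"
    seed: int = 0

    def resolved(self) -> "SelectionConfig":
        cfg = dc_replace(self)
        if cfg.task not in ("classification", "regression"):
            raise ValueError(f"unknown task {cfg.task!r}")
        if cfg.engine not in ("pls", "rf"):
            raise ValueError(f"unknown engine {cfg.engine!r}")
        if cfg.n_outer is None:
            cfg.n_outer = 4 if cfg.task == "classification" else 9
        if cfg.n_repetitions is None:
            cfg.n_repetitions = 500 if cfg.task == "classification" else 200
        if cfg.n_inner is None:
            cfg.n_inner = max(cfg.n_outer - 1, 2)
        if not 0 < cfg.elimination_fraction < 1:
            raise ValueError("elimination_fraction must be in (0, 1)")
        if cfg.performance_pooling not in ("pooled", "per_repetition"):
            raise ValueError(
                f"unknown performance_pooling {cfg.performance_pooling!r}"
            )
        if cfg.n_outer < 2:
            raise ValueError("n_outer must be >= 2")
        return cfg


@dataclass
class SelectionResult:
    """Aggregated output of :func:`rdcv_select`."""

    feature_ids: list[str]
    rank_table: pd.Series  # average fused rank per feature (lower = better)
    ranks: pd.Series  # integer 1..p ranks derived from rank_table
    n_min: int
    n_mid: int
    n_max: int
    set_min: list[str]
    set_mid: list[str]
    set_max: list[str]
    validation_curve: pd.DataFrame  # ladder size -> mean inner error
    performance: float  # BACC or Q2 at the mid set size, pooled outer preds
    performance_per_size: dict[str, float]
    task: str
    engine: str
    config: SelectionConfig
    outer_predictions: pd.DataFrame | None = None
    input_digest: str = ""  # sha256 over (X, y), for report provenance

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return {
            "task": self.task,
            "engine": self.engine,
            "input_digest": self.input_digest,
            "n_min": self.n_min,
            "n_mid": self.n_mid,
            "n_max": self.n_max,
            "set_min": self.set_min,
            "set_mid": self.set_mid,
            "set_max": self.set_max,
            "performance": self.performance,
            "performance_per_size": self.performance_per_size,
            "rank_table": {f: float(v) for f, v in self.rank_table.items()},
            "validation_curve": {
                int(k): float(v)
                for k, v in self.validation_curve["error"].items()
            },
            "config": asdict(self.config),
        }


def _ladder(p: int, fraction: float) -> list[int]:
    """Descending geometric feature ladder: p, p*(1-fraction), ..., floor 2."""
    sizes = [p]
    size = p
    while size > 2:
        size = min(size - 1, int(np.floor(size * (1.0 - fraction))))
        size = max(size, 2)
        sizes.append(size)
    return sizes


def _stratified_folds(
    y: np.ndarray, n_folds: int, task: str, rng: np.random.Generator
) -> np.ndarray:
    """Fold assignment per sample; stratified by class or response quantile."""
    n = len(y)
    fold = np.full(n, -1, dtype=int)
    if task == "classification":
        for c in np.unique(y):
            idx = np.flatnonzero(y == c)
            rng.shuffle(idx)
            fold[idx] = np.arange(len(idx)) % n_folds
    else:
        order = np.argsort(np.asarray(y, dtype=float), kind="stable")
        for start in range(0, n, n_folds):
            block = order[start : start + n_folds].copy()
            rng.shuffle(block)
            fold[block] = np.arange(len(block))
    # rotate fold labels so fold sizes are balanced across strata blocks
    return fold


def _inner_error_and_importance(
    X: np.ndarray,
    y: np.ndarray,
    classes: list | None,
    cfg: SelectionConfig,
    rng: np.random.Generator,
):
    """One inner CV at the current feature set.

    Returns (best inner error, importance vector averaged over inner folds,
    best component count for PLS or None).  Errors: misclassification count
    (classification) or RMSEP (regression) on pooled inner out-of-fold
    predictions.
    """
    n, p = X.shape
    n_inner = min(cfg.n_inner, n)
    folds = _stratified_folds(
        y if cfg.task == "classification" else y.astype(float),
        n_inner,
        cfg.task,
        rng,
    )
    if cfg.engine == "pls":
        max_a = min(cfg.max_components, p, n - int(np.ceil(n / n_inner)) - 1)
        max_a = max(max_a, 1)
        if cfg.task == "classification":
            Y, _ = one_hot(y, classes)
        else:
            Y = y.astype(float)[:, None]
        err_per_a = np.zeros(max_a)
        imp_per_a = np.zeros((max_a, p))
        n_models = 0
        sq_err_per_a = np.zeros(max_a)
        for f in range(n_inner):
            tr = folds != f
            te = folds == f
            if te.sum() == 0 or tr.sum() < 2:
                continue
            try:
                model = fit_pls(X[tr], Y[tr], max_a)
            except ValueError:
                continue
            n_models += 1
            fold_err = np.zeros(max_a)
            fold_sq = np.zeros(max_a)
            fold_imp = np.zeros((max_a, p))
            for a in range(1, max_a + 1):
                # truncations beyond this fold's extractable components reuse
                # the deepest available model
                a_eff = min(a, model.n_components)
                pred = model.predict(X[te], a_eff)
                if cfg.task == "classification":
                    lab = np.asarray(classes, dtype=object)[pred.argmax(axis=1)]
                    fold_err[a - 1] = np.sum(lab != y[te])
                else:
                    fold_sq[a - 1] = np.sum((pred[:, 0] - y[te].astype(float)) ** 2)
                try:
                    fold_imp[a - 1] = vip(model, a_eff)
                except ValueError:
                    pass
            err_per_a += fold_err
            sq_err_per_a += fold_sq
            imp_per_a += fold_imp
        if n_models == 0:
            raise RuntimeError("no inner PLS model could be fitted")
        if cfg.task == "classification":
            errors = err_per_a
        else:
            errors = np.sqrt(sq_err_per_a / n)
        best_a = int(np.argmin(errors)) + 1
        importance = imp_per_a[best_a - 1] / n_models
        return float(errors[best_a - 1]), importance, best_a
    else:  # rf, regression only
        preds = np.zeros(n)
        importance = np.zeros(p)
        n_models = 0
        for f in range(n_inner):
            tr = folds != f
            te = folds == f
            if te.sum() == 0 or tr.sum() < 5:
                continue
            forest = rf_fit(
                X[tr],
                y[tr].astype(float),
                n_trees=cfg.n_trees,
                seed=int(rng.integers(2**31 - 1)),
                compute_importance=True,
            )
            preds[te] = forest.predict(X[te])
            importance += forest.importance
            n_models += 1
        if n_models == 0:
            raise RuntimeError("no inner forest could be fitted")
        err = float(np.sqrt(np.mean((preds - y.astype(float)) ** 2)))
        return err, importance / n_models, None


def _refit_predict(
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    X_te: np.ndarray,
    classes: list | None,
    cfg: SelectionConfig,
    best_a: int | None,
    rng: np.random.Generator,
) -> np.ndarray:
    if cfg.engine == "pls":
        if cfg.task == "classification":
            Y, _ = one_hot(y_tr, classes)
            a = min(best_a or cfg.max_components, X_tr.shape[1], X_tr.shape[0] - 1)
            model = fit_pls(X_tr, Y, max(a, 1))
            return plsda_predict(model, X_te, classes)
        a = min(best_a or cfg.max_components, X_tr.shape[1], X_tr.shape[0] - 1)
        model = fit_pls(X_tr, y_tr.astype(float), max(a, 1))
        return model.predict(X_te)[:, 0]
    forest = rf_fit(
        X_tr,
        y_tr.astype(float),
        n_trees=cfg.n_trees,
        seed=int(rng.integers(2**31 - 1)),
        compute_importance=False,
    )
    return forest.predict(X_te)


def rdcv_select(
    X: pd.DataFrame | np.ndarray,
    y,
    cfg: SelectionConfig,
    feature_ids: list[str] | None = None,
) -> SelectionResult:
    """Run the repeated double cross-validation selection (see module doc).

    ``X`` should be preprocessed (autoscaled) samples x features; ``y`` class
    labels or a numeric response.  Deterministic under ``cfg.seed``.
    """
    cfg = cfg.resolved()
    if isinstance(X, pd.DataFrame):
        feature_ids = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if feature_ids is None:
            feature_ids = [f"f{i + 1}" for i in range(X.shape[1])]
    y = np.asarray(y)
    n, p = X.shape
    if len(y) != n:
        raise ValueError("X and y lengths differ")
    if np.all(np.std(X, axis=0) == 0):
        raise ValueError("all features are constant")
    classes = None
    if cfg.task == "classification":
        classes = list(dict.fromkeys(y.tolist()))
        counts = {c: int(np.sum(y == c)) for c in classes}
        too_small = {c: k for c, k in counts.items() if k < cfg.n_outer}
        if too_small:
            raise ValueError(
                f"classes with fewer members than n_outer={cfg.n_outer}: {too_small}"
            )
    else:
        y = y.astype(float)
        if np.std(y) == 0:
            raise ValueError("constant response")

    import hashlib

    digest = hashlib.sha256()
    digest.update(np.ascontiguousarray(X).tobytes())
    digest.update(np.asarray(y).astype(str).tobytes() if y.dtype == object
                  else np.ascontiguousarray(y).tobytes())
    input_digest = digest.hexdigest()[:16]

    master = np.random.SeedSequence(cfg.seed)
    rep_seeds = master.spawn(cfg.n_repetitions)

    rank_score_sum = np.zeros(p)
    rank_score_n = 0
    curve_sum: dict[int, float] = {}
    curve_n: dict[int, int] = {}
    n_min_reps: list[float] = []
    n_mid_reps: list[float] = []
    n_max_reps: list[float] = []
    pooled: dict[str, dict[str, list]] = {
        s: {"true": [], "pred": [], "rep": [], "sample": []}
        for s in ("min", "mid", "max")
    }

    for r in range(cfg.n_repetitions):
        rng = np.random.default_rng(rep_seeds[r])
        outer = _stratified_folds(y, cfg.n_outer, cfg.task, rng)
        fold_mins, fold_mids, fold_maxs = [], [], []
        for o in range(cfg.n_outer):
            te = outer == o
            tr = ~te
            if te.sum() == 0:
                continue
            X_tr, y_tr = X[tr], y[tr]
            feats = np.arange(p)
            fused = np.zeros(p)
            n_steps = 0
            curve: dict[int, tuple[float, int | None]] = {}
            for size in _ladder(p, cfg.elimination_fraction):
                if size < len(feats):
                    # keep the most important features from the previous step
                    keep = np.argsort(step_ranks, kind="stable")[:size]
                    feats = feats[np.sort(keep)]
                try:
                    err, importance, best_a = _inner_error_and_importance(
                        X_tr[:, feats], y_tr, classes, cfg, rng
                    )
                except RuntimeError:
                    break
                step_ranks = rank_from_importance(importance)
                curve[len(feats)] = (err, best_a)
                # fused rank: in-step rank, absent features score size + 1
                step_score = np.full(p, len(feats) + 1, dtype=float)
                step_score[feats] = step_ranks
                fused += step_score
                n_steps += 1
                if len(feats) <= 2:
                    break
            if not curve:
                continue
            fused /= max(n_steps, 1)
            sizes = np.array(sorted(curve))
            errs = np.array([curve[s][0] for s in sizes])
            emin = errs.min()
            ok = errs <= (1.0 + cfg.tolerance) * emin + 1e-12
            n_min_f = int(sizes[ok].min())
            n_max_f = int(sizes[ok].max())
            n_mid_f = int(round(float(np.sqrt(n_min_f * n_max_f))))
            fold_mins.append(n_min_f)
            fold_mids.append(n_mid_f)
            fold_maxs.append(n_max_f)
            for s, nsel in (("min", n_min_f), ("mid", n_mid_f), ("max", n_max_f)):
                top = np.argsort(fused, kind="stable")[:nsel]
                best_a = curve[min(curve, key=lambda k: abs(k - nsel))][1]
                pred = _refit_predict(
                    X_tr[:, top], y_tr, X[te][:, top], classes, cfg, best_a, rng
                )
                pooled[s]["true"].extend(y[te].tolist())
                pooled[s]["pred"].extend(np.asarray(pred).tolist())
                pooled[s]["rep"].extend([r] * int(te.sum()))
                pooled[s]["sample"].extend(np.flatnonzero(te).tolist())
            rank_score_sum += fused
            rank_score_n += 1
            for s, e in zip(sizes, errs):
                curve_sum[int(s)] = curve_sum.get(int(s), 0.0) + float(e)
                curve_n[int(s)] = curve_n.get(int(s), 0) + 1
        if fold_mins:
            n_min_reps.append(float(np.median(fold_mins)))
            n_mid_reps.append(float(np.median(fold_mids)))
            n_max_reps.append(float(np.median(fold_maxs)))

    if rank_score_n == 0:
        raise RuntimeError("rdCV produced no successful outer folds")
    avg_rank = pd.Series(rank_score_sum / rank_score_n, index=feature_ids)
    ranks = pd.Series(
        rank_from_importance(-avg_rank.to_numpy()), index=feature_ids
    )
    n_min = int(round(float(np.median(n_min_reps))))
    n_max = int(round(float(np.median(n_max_reps))))
    n_mid = int(round(float(np.median(n_mid_reps))))
    n_min, n_mid, n_max = sorted((n_min, n_mid, n_max))
    ordered = ranks.sort_values(kind="stable").index.tolist()
    set_min, set_mid, set_max = ordered[:n_min], ordered[:n_mid], ordered[:n_max]

    def _score(yt: np.ndarray, yp: np.ndarray) -> float:
        if cfg.task == "classification":
            return balanced_accuracy(confusion_summary(yt, yp, classes))
        return q_squared(yt.astype(float), yp.astype(float))

    perf: dict[str, float] = {}
    for s in ("min", "mid", "max"):
        yt = np.asarray(pooled[s]["true"])
        yp = np.asarray(pooled[s]["pred"])
        if cfg.performance_pooling == "pooled":
            perf[s] = _score(yt, yp)
        else:  # average the metric computed within each repetition
            reps = np.asarray(pooled[s]["rep"])
            perf[s] = float(
                np.mean([_score(yt[reps == r], yp[reps == r])
                         for r in np.unique(reps)])
            )
    curve_df = pd.DataFrame(
        {
            "n_features": sorted(curve_sum),
            "error": [curve_sum[s] / curve_n[s] for s in sorted(curve_sum)],
        }
    ).set_index("n_features")
    outer_preds = pd.DataFrame(
        {
            "repetition": pooled["mid"]["rep"],
            "sample_index": pooled["mid"]["sample"],
            "y_true": pooled["mid"]["true"],
            "y_pred": pooled["mid"]["pred"],
        }
    )
    return SelectionResult(
        feature_ids=list(feature_ids),
        rank_table=avg_rank,
        ranks=ranks,
        n_min=n_min,
        n_mid=n_mid,
        n_max=n_max,
        set_min=set_min,
        set_mid=set_mid,
        set_max=set_max,
        validation_curve=curve_df,
        performance=perf["mid"],
        performance_per_size=perf,
        task=cfg.task,
        engine=cfg.engine,
        config=cfg,
        outer_predictions=outer_preds,
        input_digest=input_digest,
    )


# ---------------------------------------------------------------------------
# study-level drivers
# ---------------------------------------------------------------------------


def classify_composition(
    tables: dict[str, pd.DataFrame],
    design: StudyDesign,
    factor: str,
    cfg: SelectionConfig | None = None,
) -> dict[str, SelectionResult]:
    """Per-platform PLS-DA rdCV for one compositional factor.

    ``tables`` maps platform name to a product-level (autoscaled) matrix
    indexed by product_id.  The outer fold count is capped at the smallest
    class size.  Single-level factors are skipped with a warning (empty
    result)."""
    if factor not in FACTOR_NAMES:
        raise KeyError(f"unknown factor {factor!r}")
    cfg = (cfg or SelectionConfig(task="classification", engine="pls")).resolved()
    results: dict[str, SelectionResult] = {}
    for platform, matrix in tables.items():
        y = np.array(
            [design.factor_level(p, factor) for p in matrix.index], dtype=object
        )
        levels = sorted(set(y.tolist()))
        if len(levels) < 2:
            logger.warning(
                "factor %s has a single level on platform %s; skipped", factor, platform
            )
            continue
        min_class = min(int(np.sum(y == c)) for c in levels)
        run_cfg = dc_replace(cfg, n_outer=min(cfg.n_outer, min_class), n_inner=None)
        run_cfg = run_cfg.resolved()
        results[platform] = rdcv_select(matrix, y, run_cfg)
    return results


def bacc_grid(
    tables: dict[str, pd.DataFrame],
    design: StudyDesign,
    cfg: SelectionConfig | None = None,
    factors: list[str] | None = None,
) -> pd.DataFrame:
    """Platform x factor balanced-accuracy grid over all compositional
    factors (the classification-performance summary surface)."""
    factors = list(factors or FACTOR_NAMES)
    rows = {}
    for factor in factors:
        res = classify_composition(tables, design, factor, cfg)
        for platform, r in res.items():
            rows.setdefault(platform, {})[factor] = r.performance
    return pd.DataFrame(rows).T


def predict_attribute(
    table: ProcessedTable | pd.DataFrame,
    response: pd.DataFrame,
    attribute: str,
    cfg: SelectionConfig | None = None,
) -> SelectionResult:
    """Regression rdCV predicting one sensory attribute from a platform's
    product-level matrix.  Engine default: PLS; pass an rf config for
    GC-MS-style condensed tables."""
    matrix = table.matrix if isinstance(table, ProcessedTable) else table
    if attribute not in response.columns:
        raise KeyError(f"attribute {attribute!r} absent from the response table")
    shared = [p for p in matrix.index if p in response.index]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared products")
    y = response.loc[shared, attribute].to_numpy(dtype=float)
    if np.std(y) == 0:
        raise ValueError(f"attribute {attribute!r} is constant")
    cfg = (cfg or SelectionConfig(task="regression", engine="pls")).resolved()
    if cfg.task != "regression":
        raise ValueError("predict_attribute requires a regression config")
    cfg = dc_replace(cfg, n_outer=min(cfg.n_outer, len(shared)), n_inner=None).resolved()
    return rdcv_select(matrix.loc[shared], y, cfg)
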