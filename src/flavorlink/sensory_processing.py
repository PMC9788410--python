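"""Trained-panel score standardization and product-effect F statistics.

Quantitative descriptive analysis panels differ systematically in how
assessors use the 0–100 line scale: each assessor has an offset and a
scaling of their own.  The standardization implemented here removes both by
z-scoring each (assessor, attribute) slice across products,

    y~_ijk = (y_ijk - ybar_ik) / s_ik ,

then back-transforms to interpretable score units,

    y~*_ijk = ybar_k + y~_ijk * sp_k ,

where ybar_k is the overall attribute mean and sp_k a pooled per-attribute
standard deviation.  Two pooling modes are offered:

* ``conventional`` (default): sp_k = sqrt( sum_i s_ik^2 / I ), the
  root-mean-variance pooled SD, which actually restores the original spread;
* ``literal``: sp_k = sum_i s_ik / (I * (J - 1)), a historical form kept for
  fidelity with prior descriptions of the procedure even though it shrinks
  the back-transformed spread by roughly 1/(J-1).

Sensory responses nu_jk are the across-assessor means of the
back-transformed scores; they are the regression targets downstream.

The product-effect F value per attribute comes from a linear mixed model
with product as fixed effect and assessor as random intercept (REML fit,
Wald F on the product terms).  On complete balanced data this equals the
classical two-way (product + assessor blocks) ANOVA F.  Sessions are
averaged out before modeling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design_io import PanelScores, ScoreTensor

logger = logging.getLogger(__name__)

__all__ = [
    "StandardizationStats",
    "AttributeFResult",
    "standardize",
    "pooled_sd",
    "back_transform",
    "sensory_response",
    "standardize_panel",
    "product_f_values",
]


@dataclass
class StandardizationStats:
    """Per-slice moments used by the standardize/back-transform pair.

    ``assessor_mean``/``assessor_sd`` are I x K arrays (NaN where a slice was
    dropped); ``attribute_mean`` is the overall per-attribute mean ybar_k and
    ``pooled`` the per-attribute pooled SD sp_k (filled by
    :func:`pooled_sd`).
    """

    assessors: list[str]
    attributes: list[str]
    assessor_mean: np.ndarray
    assessor_sd: np.ndarray
    attribute_mean: np.ndarray
    pooled: np.ndarray | None = None
    pooled_mode: str | None = None
    dropped_slices: list[tuple[str, str]] = field(default_factory=list)


def standardize(
    tensor: ScoreTensor, on_constant: str = "drop"
) -> tuple[ScoreTensor, StandardizationStats]:
    """Z-score every (assessor, attribute) slice across products.

    Slices with zero variance carry no ranking information; they are dropped
    (set to NaN) with a warning naming the assessor and attribute, or raise
    when ``on_constant='error'``.  Slices with fewer than two scored products
    are likewise dropped.  SDs use the sample (n-1) denominator.
    """
    if on_constant not in ("drop", "error"):
        raise ValueError("on_constant must be 'drop' or 'error'")
    y = tensor.values.astype(float).copy()
    I, J, K = y.shape
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean_ik = np.nanmean(y, axis=1)  # I x K
        sd_ik = np.nanstd(y, axis=1, ddof=1)
        n_ik = np.sum(~np.isnan(y), axis=1)

    dropped: list[tuple[str, str]] = []
    bad = (n_ik < 2) | ~np.isfinite(sd_ik) | (sd_ik <= 0)
    for i, k in zip(*np.nonzero(bad)):
        pair = (tensor.assessors[i], tensor.attributes[k])
        if n_ik[i, k] >= 2 and sd_ik[i, k] == 0:
            if on_constant == "error":
                raise ValueError(
                    f"constant score slice for assessor {pair[0]!r}, "
                    f"attribute {pair[1]!r}"
                )
            logger.warning(
                "dropping constant slice: assessor %s, attribute %s", *pair
            )
        dropped.append(pair)
    sd_safe = np.where(bad, np.nan, sd_ik)
    z = (y - mean_ik[:, None, :]) / sd_safe[:, None, :]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        attr_mean = np.nanmean(np.where(bad[:, None, :].repeat(J, 1), np.nan, y), axis=(0, 1))
    stats_ = StandardizationStats(
        assessors=list(tensor.assessors),
        attributes=list(tensor.attributes),
        assessor_mean=np.where(bad, np.nan, mean_ik),
        assessor_sd=sd_safe,
        attribute_mean=attr_mean,
        dropped_slices=dropped,
    )
    return (
        ScoreTensor(z, list(tensor.assessors), list(tensor.products), list(tensor.attributes)),
        stats_,
    )


def pooled_sd(
    stats_: StandardizationStats, n_products: int, mode: str = "conventional"
) -> np.ndarray:
    """Pooled per-attribute SD sp_k over retained assessors.

    ``conventional``: sqrt(mean of s_ik^2); ``literal``: mean s_ik scaled by
    1/(J-1) (see module docstring).  Stores the result on ``stats_``.
    """
    s = stats_.assessor_sd
    n_retained = np.sum(np.isfinite(s), axis=0)
    if np.any(n_retained == 0):
        k = int(np.argmax(n_retained == 0))
        raise ValueError(
            f"no retained assessor slices for attribute {stats_.attributes[k]!r}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        if mode == "conventional":
            sp = np.sqrt(np.nanmean(s**2, axis=0))
        elif mode == "literal":
            if n_products < 2:
                raise ValueError("literal pooling requires J >= 2 products")
            sp = np.nansum(s, axis=0) / (n_retained * (n_products - 1))
        else:
            raise ValueError(f"unknown pooling mode {mode!r}")
    stats_.pooled = sp
    stats_.pooled_mode = mode
    return sp


def back_transform(z: ScoreTensor, stats_: StandardizationStats) -> ScoreTensor:
    """Map standardized scores back to score units: ybar_k + z * sp_k."""
    if stats_.pooled is None:
        raise ValueError("call pooled_sd() before back_transform()")
    vals = stats_.attribute_mean[None, None, :] + z.values * stats_.pooled[None, None, :]
    return ScoreTensor(vals, list(z.assessors), list(z.products), list(z.attributes))


def sensory_response(bt: ScoreTensor) -> pd.DataFrame:
    """Across-assessor mean per (product, attribute): the sensory responses
    nu_jk.  Cells with no contributing assessor are NaN with a warning."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        nu = np.nanmean(bt.values, axis=0)
    if np.isnan(nu).any():
        jj, kk = np.nonzero(np.isnan(nu))
        logger.warning(
            "sensory response undefined for %d (product, attribute) cells, "
            "e.g. (%s, %s)",
            len(jj),
            bt.products[jj[0]],
            bt.attributes[kk[0]],
        )
    return pd.DataFrame(nu, index=bt.products, columns=bt.attributes)


def standardize_panel(
    scores: PanelScores | ScoreTensor,
    pooled_mode: str = "conventional",
    on_constant: str = "drop",
) -> tuple[ScoreTensor, pd.DataFrame, StandardizationStats]:
    """Convenience chain: standardize -> pooled SD -> back-transform ->
    sensory responses.  Returns (back-transformed tensor, nu table, stats)."""
    tensor = scores.to_tensor() if isinstance(scores, PanelScores) else scores
    z, st = standardize(tensor, on_constant=on_constant)
    pooled_sd(st, n_products=len(tensor.products), mode=pooled_mode)
    bt = back_transform(z, st)
    return bt, sensory_response(bt), st


# ---------------------------------------------------------------------------
# product-effect F
# ---------------------------------------------------------------------------


@dataclass
class AttributeFResult:
    attribute: str
    f_value: float
    df_num: int
    df_den: int
    critical_f: float
    p_value: float


def _reml_random_intercept(
    y: np.ndarray, X: np.ndarray, groups: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Exact REML fit of y = X b + u_g + e with a single random intercept.

    The variance ratio lambda = var(u)/var(e) is profiled out: for fixed
    lambda the GLS solution is closed-form (V = I + lambda Z Z' inverts
    group-wise), and the scalar REML criterion is minimized over log-lambda
    by bounded scalar search.  Returns (beta, cov_beta, sigma2_e, lambda).
    """
    from scipy.optimize import minimize_scalar

    n, p = X.shape
    group_ids = np.unique(groups)
    group_rows = [np.flatnonzero(groups == g) for g in group_ids]
    Xg_sum = np.stack([X[r].sum(axis=0) for r in group_rows])  # G x p
    yg_sum = np.array([y[r].sum() for r in group_rows])
    ng = np.array([len(r) for r in group_rows], dtype=float)
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    def gls(lam: float):
        c = lam / (1.0 + lam * ng)  # per-group shrinkage
        A = XtX - (Xg_sum.T * c) @ Xg_sum
        rhs = Xty - Xg_sum.T @ (c * yg_sum)
        beta = np.linalg.solve(A, rhs)
        # weighted RSS: (y - Xb)' V^-1 (y - Xb)
        quad_y = yty - float((c * yg_sum) @ yg_sum)
        rss = quad_y - 2 * float(beta @ rhs) + float(beta @ (A @ beta))
        # V^-1 is positive definite but roundoff can graze zero
        rss = max(rss, 1e-300)
        return A, beta, rss

    def crit(log_lam: float) -> float:
        lam = np.exp(log_lam)
        A, _, rss = gls(lam)
        logdet_v = float(np.sum(np.log1p(lam * ng)))
        sign, logdet_a = np.linalg.slogdet(A)
        return (n - p) * np.log(rss) + logdet_v + logdet_a

    res = minimize_scalar(
        crit, bounds=(-15.0, 15.0), method="bounded", options={"xatol": 1e-10}
    )
    best_log_lam = float(res.x)
    # compare against the lambda -> 0 boundary (no assessor variance)
    lam = np.exp(best_log_lam)
    if crit(-15.0) < res.fun:
        lam = np.exp(-15.0)
    A, beta, rss = gls(lam)
    sigma2 = rss / (n - p)
    cov = sigma2 * np.linalg.inv(A)
    return beta, cov, sigma2, lam


def _mixed_f_one_attribute(df: pd.DataFrame) -> tuple[float, int, int]:
    """Wald F of the product fixed effect from the REML random-intercept fit.

    Denominator df is the residual count n - (J - 1) - 1 - (I - 1), which
    reduces to (I-1)(J-1) on complete data.
    """
    products = sorted(df["product"].unique())
    assessors = df["assessor"].to_numpy()
    J = len(products)
    I = df["assessor"].nunique()
    n = len(df)
    # treatment coding: intercept + J-1 product dummies
    X = np.ones((n, J))
    pidx = {p: j for j, p in enumerate(products)}
    for r, prod in enumerate(df["product"]):
        j = pidx[prod]
        X[r, 1:] = 0.0
        if j > 0:
            X[r, j] = 1.0
    y = df["score"].to_numpy(dtype=float)
    beta, cov, _sigma2, _lam = _reml_random_intercept(y, X, assessors)
    b = beta[1:]
    cov_b = cov[1:, 1:]
    wald = float(b @ np.linalg.solve(cov_b, b))
    q = J - 1
    df_den = max(n - J - I + 1, 1)
    return wald / q, q, df_den


def product_f_values(
    tensor: ScoreTensor, alpha: float = 0.05
) -> list[AttributeFResult]:
    """Per-attribute product-effect F from the mixed model, with the
    upper-``alpha`` critical F of the matching F distribution.

    Works on raw or standardized/back-transformed tensors alike (the model
    is refit per attribute on the session-averaged scores).  Attributes with
    insufficient replication (fewer than two products or assessors observed)
    are skipped with a warning.
    """
    results: list[AttributeFResult] = []
    I, J, K = tensor.shape
    if J < 2 or I < 2:
        raise ValueError("need at least 2 products and 2 assessors")
    for k, attr in enumerate(tensor.attributes):
        y = tensor.values[:, :, k]
        ii, jj = np.nonzero(~np.isnan(y))
        if len(ii) == 0 or len(set(jj)) < 2 or len(set(ii)) < 2:
            logger.warning("skipping attribute %s: insufficient replication", attr)
            continue
        df = pd.DataFrame(
            {
                "score": y[ii, jj],
                "assessor": [tensor.assessors[i] for i in ii],
                "product": [tensor.products[j] for j in jj],
            }
        )
        try:
            f, q, df_den = _mixed_f_one_attribute(df)
        except Exception as exc:  # singular fits on degenerate slices
            logger.warning("skipping attribute %s: mixed model failed (%s)", attr, exc)
            continue
        crit = float(stats.f.ppf(1 - alpha, q, df_den))
        p = float(stats.f.sf(f, q, df_den))
        results.append(
            AttributeFResult(
                attribute=attr,
                f_value=float(f),
                df_num=q,
                df_den=df_den,
                critical_f=crit,
                p_value=p,
            )
        )
    return results


def f_table(results: list[AttributeFResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "attribute": r.attribute,
                "f_value": r.f_value,
                "df_num": r.df_num,
                "df_den": r.df_den,
                "critical_f": r.critical_f,
                "p_value": r.p_value,
            }
            for r in results
        ]
    )
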