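"""Result surfaces: attribute F-vs-Q2 summary, top-marker tables,
cross-platform marker correlations, and marker-vs-score scatter data.

Everything here is a join or a Pearson/Spearman correlation over objects
computed upstream; no new estimation happens in this module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .rdcv_selection import SelectionResult
from .sensory_processing import AttributeFResult

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerLink",
    "attribute_summary",
    "top_features",
    "cross_platform_correlation",
    "marker_scatter",
]


def attribute_summary(
    f_results: list[AttributeFResult],
    selection_results: dict[str, dict[str, SelectionResult]],
    q2_threshold: float = 0.3,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Join per-attribute F values with per-platform Q2 values.

    ``selection_results`` maps platform -> attribute -> SelectionResult.
    Returns the joined table (one row per attribute; missing cells where an
    attribute is absent from a source, with a warning) and the Spearman
    rho between F and Q2 per platform (NaN when fewer than 2 complete
    pairs).  The ``selected`` flag is F > critical F and max Q2 over
    platforms >= ``q2_threshold``.
    """
    f_map = {r.attribute: r for r in f_results}
    platforms = list(selection_results)
    attrs = list(
        dict.fromkeys(
            list(f_map) + [a for pl in platforms for a in selection_results[pl]]
        )
    )
    rows = []
    for attr in attrs:
        row: dict = {"attribute": attr}
        fr = f_map.get(attr)
        if fr is None:
            logger.warning("attribute %s missing from the F-value results", attr)
        row["f_value"] = fr.f_value if fr else np.nan
        row["critical_f"] = fr.critical_f if fr else np.nan
        q2s = []
        for pl in platforms:
            res = selection_results[pl].get(attr)
            if res is None:
                logger.warning("attribute %s missing from platform %s", attr, pl)
                row[f"q2_{pl}"] = np.nan
            else:
                row[f"q2_{pl}"] = res.performance
                q2s.append(res.performance)
        row["selected"] = bool(
            fr is not None
            and fr.f_value > fr.critical_f
            and q2s
            and max(q2s) >= q2_threshold
        )
        rows.append(row)
    table = pd.DataFrame(rows).set_index("attribute")
    rho: dict[str, float] = {}
    for pl in platforms:
        pair = table[["f_value", f"q2_{pl}"]].dropna()
        if len(pair) < 2:
            rho[pl] = float("nan")
        else:
            rho[pl] = float(
                stats.spearmanr(pair["f_value"], pair[f"q2_{pl}"]).statistic
            )
    return table, rho


def top_features(result: SelectionResult, n: int) -> pd.DataFrame:
    """The ``n`` features with the smallest average rank (ties by id)."""
    df = pd.DataFrame(
        {
            "feature_id": result.rank_table.index,
            "average_rank": result.rank_table.to_numpy(),
            "rank": result.ranks.to_numpy(),
        }
    ).sort_values(["rank"], kind="stable")
    return df.head(n).reset_index(drop=True)


@dataclass
class MarkerLink:
    """A cross-platform feature pair with its product-level correlation."""

    feature_a: str
    platform_a: str
    rank_a: int
    feature_b: str
    platform_b: str
    rank_b: int
    pearson_r: float
    n: int


def cross_platform_correlation(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    set_a: list[str],
    set_b: list[str],
    min_abs_r: float = 0.9,
    platform_a: str = "lcms",
    platform_b: str = "gcms",
    ranks_a: pd.Series | None = None,
    ranks_b: pd.Series | None = None,
) -> list[MarkerLink]:
    """All pairs from ``set_a x set_b`` with |Pearson r| >= ``min_abs_r``.

    Tables must be product-level log-scale matrices (one row per product);
    correlation is computed on the shared products, sorted by |r|
    descending.  Correlation being affine-invariant, the pre-autoscaling log
    intensities are the natural input.
    """
    shared = [p for p in table_a.index if p in set(table_b.index)]
    if len(shared) < 3:
        raise ValueError(f"need at least 3 shared products, got {len(shared)}")
    A = table_a.loc[shared, list(set_a)].to_numpy(dtype=float)
    B = table_b.loc[shared, list(set_b)].to_numpy(dtype=float)
    Az = A - A.mean(axis=0)
    Bz = B - B.mean(axis=0)
    sa = np.sqrt((Az**2).sum(axis=0))
    sb = np.sqrt((Bz**2).sum(axis=0))
    sa[sa == 0] = np.nan
    sb[sb == 0] = np.nan
    corr = (Az.T @ Bz) / np.outer(sa, sb)
    links = []
    for i, fa in enumerate(set_a):
        for j, fb in enumerate(set_b):
            r = corr[i, j]
            if np.isfinite(r) and abs(r) >= min_abs_r:
                links.append(
                    MarkerLink(
                        feature_a=fa,
                        platform_a=platform_a,
                        rank_a=int(ranks_a[fa]) if ranks_a is not None else 0,
                        feature_b=fb,
                        platform_b=platform_b,
                        rank_b=int(ranks_b[fb]) if ranks_b is not None else 0,
                        pearson_r=float(r),
                        n=len(shared),
                    )
                )
    links.sort(key=lambda l: -abs(l.pearson_r))
    return links


def marker_scatter(
    feature_id: str,
    table: pd.DataFrame,
    response: pd.DataFrame,
    attribute: str,
    exclude_products: list[str] | None = None,
) -> tuple[pd.DataFrame, float]:
    """Paired (log peak area, sensory score) values for one marker.

    ``table`` is a product-level log matrix; ``exclude_products`` removes a
    flagged product group (e.g. an outlying yeast arm) before recomputing r.
    Degenerate two-point correlations are flagged with a warning.
    """
    if feature_id not in table.columns:
        raise KeyError(f"unknown feature {feature_id!r}")
    if attribute not in response.columns:
        raise KeyError(f"unknown attribute {attribute!r}")
    shared = [p for p in table.index if p in set(response.index)]
    unmatched = [p for p in table.index if p not in set(response.index)]
    if unmatched:
        raise ValueError(f"products missing from the response table: {unmatched[:5]}")
    exclude = set(exclude_products or [])
    kept = [p for p in shared if p not in exclude]
    if len(kept) < 2:
        raise ValueError("fewer than 2 products after exclusion")
    pairs = pd.DataFrame(
        {
            "product_id": kept,
            "log_intensity": table.loc[kept, feature_id].to_numpy(dtype=float),
            "score": response.loc[kept, attribute].to_numpy(dtype=float),
        }
    )
    if len(kept) == 2:
        logger.warning("only 2 products: correlation is degenerate (+-1)")
    r = float(np.corrcoef(pairs["log_intensity"], pairs["score"])[0, 1])
    return pairs, r
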