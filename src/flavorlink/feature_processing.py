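"""Post-peak-picking preprocessing of untargeted feature tables.

Fixed step order: blank filter -> QC relative-SD filter -> natural-log
transform -> technical-replicate averaging -> autoscaling.  Every step
appends a replayable entry to the table's processing log, so a processed
table can be reconstructed bit-for-bit from the raw table plus its log.

Threshold defaults (blank ratio 5, QC RSD 0.30) are common untargeted-
metabolomics conventions; both are explicit parameters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design_io import FeatureTable

logger = logging.getLogger(__name__)

__all__ = [
    "ProcessedTable",
    "blank_filter",
    "qc_rsd_filter",
    "log_transform",
    "average_replicates",
    "autoscale",
    "pca",
    "preprocess",
    "replay",
]


def blank_filter(table: FeatureTable, ratio: float = 5.0) -> FeatureTable:
    """Drop features not sufficiently enriched in study samples over blanks.

    A feature is removed when mean(study) < ratio * mean(blank).  Features
    absent from blanks (blank mean 0) are always retained.  With no blank
    rows the table passes through unchanged with a warning.
    """
    blanks = table.rows_of_type("blank")
    if blanks.empty:
        logger.warning("blank_filter: no blank samples; table passed through")
        return table.replace(
            log_entry={"step": "blank_filter", "ratio": ratio, "removed": []}
        )
    study = table.rows_of_type("study")
    blank_mean = blanks.mean(axis=0, skipna=True).fillna(0.0)
    study_mean = study.mean(axis=0, skipna=True).fillna(0.0)
    removed = list(table.intensities.columns[study_mean < ratio * blank_mean])
    if removed:
        logger.info("blank_filter removed %d features", len(removed))
    return table.replace(
        intensities=table.intensities.drop(columns=removed),
        log_entry={"step": "blank_filter", "ratio": ratio, "removed": removed},
    )


def qc_rsd_filter(table: FeatureTable, max_rsd: float = 0.30) -> FeatureTable:
    """Drop features whose relative SD over QC injections exceeds ``max_rsd``.

    The QC RSD measures pure instrument/technical variability; features that
    are unstable on the pooled QC cannot be trusted on the study samples.
    Requires >= 3 QC rows (otherwise a warned no-op).
    """
    qc = table.rows_of_type("qc")
    if len(qc) < 3:
        logger.warning("qc_rsd_filter: fewer than 3 QC samples; table passed through")
        return table.replace(
            log_entry={"step": "qc_rsd_filter", "max_rsd": max_rsd, "removed": []}
        )
    mean = qc.mean(axis=0, skipna=True)
    sd = qc.std(axis=0, ddof=1, skipna=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = (sd / mean).where(mean > 0, np.inf)
    removed = list(table.intensities.columns[rsd > max_rsd])
    if removed:
        logger.info("qc_rsd_filter removed %d features", len(removed))
    return table.replace(
        intensities=table.intensities.drop(columns=removed),
        log_entry={"step": "qc_rsd_filter", "max_rsd": max_rsd, "removed": removed},
    )


def log_transform(table: FeatureTable, pseudo_policy: str = "half_min") -> FeatureTable:
    """Natural-log transform with a per-feature zero-replacement policy.

    ``half_min``: zeros become half the smallest positive value observed for
    that feature.  All-zero features carry no information and are dropped
    with a warning.  Missing cells stay missing.
    """
    if pseudo_policy != "half_min":
        raise ValueError(f"unknown pseudo_policy {pseudo_policy!r}")
    x = table.intensities.astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        min_pos = x.where(x > 0).min(axis=0)
    all_zero = list(x.columns[min_pos.isna() & x.notna().any(axis=0)])
    if all_zero:
        logger.warning("log_transform dropping %d all-zero features", len(all_zero))
        x = x.drop(columns=all_zero)
        min_pos = min_pos.drop(all_zero)
    filled = x.where(x > 0, min_pos / 2.0, axis=1)
    out = np.log(filled)
    return table.replace(
        intensities=out,
        log_entry={
            "step": "log_transform",
            "pseudo_policy": pseudo_policy,
            "removed": all_zero,
        },
    )


def average_replicates(table: FeatureTable, keep_special: bool = False) -> FeatureTable:
    """Average technical replicates: one row per product for study samples.

    Averaging is arithmetic on the current (typically log) scale.  QC and
    blank rows are dropped by default or passed through untouched with
    ``keep_special=True``.
    """
    meta = table.sample_meta
    study_mask = (meta["sample_type"] == "study").to_numpy()
    study = table.intensities.loc[study_mask]
    products = meta.loc[study_mask, "product_id"].astype(str).to_numpy()
    averaged = study.groupby(products, sort=False).mean()
    new_meta_rows = [
        {
            "sample_id": pid,
            "product_id": pid,
            "sample_type": "study",
            "replicate_id": 1,
            "batch": 1,
            "injection_order": i + 1,
        }
        for i, pid in enumerate(averaged.index)
    ]
    if keep_special:
        special_mask = ~study_mask
        special = table.intensities.loc[special_mask]
        averaged = pd.concat([averaged, special])
        offset = len(new_meta_rows)
        for t, row in enumerate(meta.loc[special_mask].itertuples(index=False)):
            new_meta_rows.append(
                {
                    "sample_id": row.sample_id,
                    "product_id": None,
                    "sample_type": row.sample_type,
                    "replicate_id": row.replicate_id,
                    "batch": 1,
                    "injection_order": offset + t + 1,
                }
            )
    return table.replace(
        intensities=averaged,
        sample_meta=pd.DataFrame(new_meta_rows),
        log_entry={"step": "average_replicates", "keep_special": keep_special},
    )


def autoscale(table: FeatureTable) -> FeatureTable:
    """Per-feature center + unit-variance scale (sample SD, n-1).

    Constant features are dropped with a warning; after autoscaling every
    retained column has mean 0 and SD 1.
    """
    x = table.intensities.astype(float)
    if len(x) < 2:
        raise ValueError("autoscale requires at least 2 rows")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    constant = list(x.columns[(sd == 0) | sd.isna()])
    if constant:
        logger.warning("autoscale dropping %d constant features", len(constant))
        x = x.drop(columns=constant)
        mean = mean.drop(constant)
        sd = sd.drop(constant)
    return table.replace(
        intensities=(x - mean) / sd,
        log_entry={"step": "autoscale", "removed": constant},
    )


_STEP_FUNCS = {
    "blank_filter": lambda t, e: blank_filter(t, ratio=e["ratio"]),
    "qc_rsd_filter": lambda t, e: qc_rsd_filter(t, max_rsd=e["max_rsd"]),
    "log_transform": lambda t, e: log_transform(t, pseudo_policy=e["pseudo_policy"]),
    "average_replicates": lambda t, e: average_replicates(
        t, keep_special=e["keep_special"]
    ),
    "autoscale": lambda t, e: autoscale(t),
}


def replay(raw: FeatureTable, log: list[dict]) -> FeatureTable:
    """Re-apply a processing log to a raw table (bit-for-bit reproduction)."""
    t = raw
    for entry in log:
        t = _STEP_FUNCS[entry["step"]](t, entry)
    return t


@dataclass
class ProcessedTable:
    """Product-level processed matrix plus the log that produced it."""

    matrix: pd.DataFrame  # index: product_id
    platform: str
    processing_log: list[dict] = field(default_factory=list)
    log_matrix: pd.DataFrame | None = None  # pre-autoscaling log intensities

    @property
    def products(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.matrix.columns)


def preprocess(
    table: FeatureTable,
    blank_ratio: float = 5.0,
    qc_max_rsd: float = 0.30,
    pseudo_policy: str = "half_min",
) -> ProcessedTable:
    """Full pipeline: blank filter, QC RSD filter, log, replicate averaging,
    autoscale.  Also retains the pre-autoscaling product-level log matrix,
    which cross-platform correlation works on (correlation is
    scale-invariant, so the unscaled log values are the natural input)."""
    t = blank_filter(table, ratio=blank_ratio)
    t = qc_rsd_filter(t, max_rsd=qc_max_rsd)
    t = log_transform(t, pseudo_policy=pseudo_policy)
    t = average_replicates(t)
    log_matrix = t.intensities.copy()
    t = autoscale(t)
    return ProcessedTable(
        matrix=t.intensities,
        platform=t.platform,
        processing_log=t.processing_log,
        log_matrix=log_matrix,
    )


def pca(
    matrix: pd.DataFrame, n_components: int = 2
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """SVD-based principal component analysis of a preprocessed matrix.

    Input is assumed centered per feature (autoscaled or at least
    log-scaled); columns are centered defensively.  Components beyond the
    matrix rank are truncated with a warning.  Sign convention: the
    largest-magnitude loading of each component is positive.

    Returns (scores, loadings, explained-variance fractions).
    """
    x = matrix.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    tol = s.max(initial=0.0) * max(x.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    if n_components > rank:
        logger.warning(
            "pca: requested %d components but rank is %d; truncating",
            n_components,
            rank,
        )
        n_components = rank
    u, s, vt = u[:, :n_components], s[:n_components], vt[:n_components]
    # fix signs so the largest-|loading| entry of each component is positive
    flip = np.sign(vt[np.arange(n_components), np.abs(vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    u = u * flip[None, :]
    scores = u * s
    total_var = (x**2).sum()
    explained = (s**2) / total_var if total_var > 0 else np.zeros(n_components)
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        pd.DataFrame(vt.T, index=matrix.columns, columns=comp_names),
        explained,
    )
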