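"""Coupled synthetic sensory-panel and dual-platform feature-table generator.

The generator emulates the statistical structure the downstream analysis
assumes: a trained panel whose assessors differ in offset and scaling but
observe the same true product effects, and two mass-spectrometry-style
feature tables in which a small set of marker features carries those same
product effects on the log-intensity scale, embedded among uninformative
features, correlated adduct/isotope-like blocks, blank-background
contaminants, interleaved QC injections and blank injections.

Every generator is deterministic under a fixed seed, and returns the ground
truth (marker map, assessor biases, true responses) needed for recovery
tests.

Panel model, per assessor ``i``, product ``j``, attribute ``k``::

    y_ijk = clip( a_i + b_i * mu_jk + eps_ijk , 0, 100 )

with ``a_i ~ N(0, offset_sd^2)``, ``log b_i ~ N(0, scale_sd^2)``,
``eps ~ N(0, noise_sd^2)`` drawn independently per session, and ``mu_jk``
the true product effect encoded by an :class:`EffectMap`.

Feature model, log scale, for marker feature ``f`` of attribute ``k``::

    log x_fs = baseline_f + beta_f * c_{j(s),k} + technical noise

where ``c_jk`` is the unit-variance standardized true response of product
``j`` on attribute ``k``.  Non-markers carry baseline plus noise only;
correlated blocks share a per-injection latent factor sized so that the
pairwise log-scale correlation is >= 0.9 by construction.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design_io import (
    DEFAULT_ATTRIBUTES,
    FACTOR_NAMES,
    FeatureTable,
    PanelScores,
    StudyDesign,
    default_design,
    write_design,
    write_feature_table,
    write_panel_scores,
)

__all__ = [
    "PanelSimConfig",
    "PlatformSimConfig",
    "StudySimConfig",
    "EffectMap",
    "GroundTruth",
    "default_effect_map",
    "simulate_panel",
    "simulate_feature_table",
    "simulate_study",
]

#: Feature-id prefixes per platform, mirroring the usual naming of
#: electrospray LC-MS features (X...) and SPME GC-MS features (SPME...).
_PLATFORM_PREFIX = {"lcms": "X", "gcms": "SPME"}

# ratio of block-latent SD to residual SD inside a correlated block;
# 3.2 gives pairwise correlation 3.2^2/(3.2^2+1) ~ 0.911 >= 0.9.
_BLOCK_LATENT_RATIO = 3.2

# blanks sit this many natural-log units below the study baseline for
# ordinary features (~0.25% relative intensity); background contaminants sit
# at the study baseline in blanks and study samples alike.
_BLANK_LOG_DROP = 6.0


@dataclass
class PanelSimConfig:
    """Panel-simulation knobs; defaults follow the 14-assessor, 4-session
    study layout, with noise magnitudes chosen as plausible trained-panel
    variability (they are free parameters, not estimates of any dataset)."""

    n_assessors: int = 14
    n_sessions: int = 4
    assessor_offset_sd: float = 8.0
    assessor_scale_sd: float = 0.15
    noise_sd: float = 6.0
    design_coverage: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_assessors < 2:
            raise ValueError("n_assessors must be >= 2")
        if not 0 < self.design_coverage <= 1:
            raise ValueError("design_coverage must be in (0, 1]")


@dataclass
class PlatformSimConfig:
    """Feature-table simulation knobs for one platform."""

    platform: str = "lcms"
    n_features: int = 500
    n_markers_per_attribute: int = 5
    marker_effect: float = 1.0
    baseline_log_mean: float = 10.0
    baseline_log_sd: float = 1.0
    technical_cv: float = 0.05
    n_tech_replicates: int = 4
    n_replicated_products: int = 12
    n_qc: int | None = None
    n_blank: int = 3
    qc_spacing: int = 10
    correlated_block_size: int = 3
    n_background_features: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.platform not in _PLATFORM_PREFIX:
            raise ValueError(f"unknown platform {self.platform!r}")
        if self.technical_cv < 0:
            raise ValueError("technical_cv must be >= 0")
        if self.qc_spacing < 1:
            raise ValueError("qc_spacing must be >= 1")


@dataclass
class EffectMap:
    """True product effects: per-attribute baseline plus additive factor
    contributions ``(factor, level, effect)`` in score units."""

    baseline: dict[str, float]
    effects: dict[str, list[tuple[str, str, float]]] = field(default_factory=dict)

    @property
    def attributes(self) -> list[str]:
        return list(self.baseline)

    def validate(self, design: StudyDesign) -> None:
        for attr, terms in self.effects.items():
            if attr not in self.baseline:
                raise ValueError(f"effects reference unknown attribute {attr!r}")
            for factor, level, _ in terms:
                if factor not in FACTOR_NAMES:
                    raise ValueError(f"unknown factor {factor!r} in attribute {attr!r}")
                if level not in design.factor_levels(factor):
                    raise ValueError(
                        f"level {level!r} of factor {factor!r} not observed in design"
                    )

    def true_response(self, design: StudyDesign) -> pd.DataFrame:
        """Products x attributes matrix of mu_jk implied by the map."""
        self.validate(design)
        data = {}
        for attr in self.attributes:
            col = np.full(len(design), self.baseline[attr], dtype=float)
            for factor, level, effect in self.effects.get(attr, []):
                hit = np.array(
                    [getattr(p, factor) == level for p in design.products], dtype=float
                )
                col += effect * hit
            data[attr] = col
        return pd.DataFrame(data, index=design.product_ids)


def default_effect_map(attributes: Sequence[str] = DEFAULT_ATTRIBUTES) -> EffectMap:
    """A graded, plausible effect map over the default 26 attributes.

    Tomato dosage dominates (as the strongest compositional driver), the
    yeast codes G28/O31/YPr carry garlic/onion/bitter notes, and the oil and
    heat factors contribute only weakly — giving a wide spread of true
    product-effect sizes across attributes.
    """
    table: dict[str, list[tuple[str, str, float]]] = {
        "intensity.od": [("tomato_dose", "high", 10), ("yeast_dose", "high", 6)],
        "tomato.od": [("tomato_dose", "high", 15)],
        "onion.od": [("yeast_product", "O31", 12)],
        "garlic.od": [("yeast_product", "G28", 12)],
        "yeast.od": [("yeast_dose", "high", 8), ("yeast_dose", "low", 4)],
        "sweet.od": [("tomato_dose", "high", 5)],
        "intensity.fl": [("tomato_dose", "high", 10), ("yeast_dose", "high", 8)],
        "tomato.fl": [("tomato_dose", "high", 16)],
        "onion.fl": [("yeast_product", "O31", 14)],
        "garlic.fl": [("yeast_product", "G28", 16)],
        "umami.fl": [
            ("yeast_dose", "high", 10),
            ("yeast_dose", "low", 5),
            ("tomato_dose", "high", 4),
        ],
        "sweet.fl": [("tomato_dose", "high", 8)],
        "bitter.fl": [("yeast_product", "YPr", 8)],
        "salty.fl": [("yeast_dose", "high", 5)],
        "sour.fl": [("tomato_dose", "high", 6)],
        "yeast.fl": [("yeast_dose", "high", 9), ("yeast_dose", "low", 4)],
        "thickness.mf": [("tomato_dose", "high", 10)],
        "fattiness.mf": [("oil_type", "olive", 4)],
        "mouthfullness.mf": [("yeast_dose", "high", 6), ("tomato_dose", "high", 4)],
        "graininess.mf": [("tomato_dose", "high", 3)],
        "intensity.at": [("yeast_dose", "high", 6), ("tomato_dose", "high", 5)],
        "umami.at": [("yeast_dose", "high", 7)],
        "bitter.at": [("yeast_product", "YPr", 6)],
        "dryness.af": [("heat", "long", 3)],
        "coating.af": [("oil_type", "olive", 3)],
        "pungency.af": [("yeast_product", "G28", 5)],
    }
    baseline = {a: 50.0 for a in attributes}
    effects = {a: table[a] for a in attributes if a in table}
    return EffectMap(baseline=baseline, effects=effects)


@dataclass
class GroundTruth:
    """What the generators actually planted, for recovery testing."""

    true_response: pd.DataFrame
    assessor_bias: dict[str, tuple[float, float]] = field(default_factory=dict)
    marker_map: dict[str, dict[str, float]] = field(default_factory=dict)
    background_features: list[str] = field(default_factory=list)
    correlated_blocks: list[list[str]] = field(default_factory=list)
    clip_fraction: float = 0.0

    def markers_for(self, attribute: str) -> set[str]:
        return set(self.marker_map.get(attribute, {}))

    def to_dict(self) -> dict:
        return {
            "true_response": {
                "index": list(self.true_response.index),
                "columns": list(self.true_response.columns),
                "values": self.true_response.to_numpy().tolist(),
            },
            "assessor_bias": {
                a: [float(o), float(s)] for a, (o, s) in self.assessor_bias.items()
            },
            "marker_map": self.marker_map,
            "background_features": self.background_features,
            "correlated_blocks": self.correlated_blocks,
            "clip_fraction": self.clip_fraction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        tr = pd.DataFrame(
            np.asarray(d["true_response"]["values"], dtype=float),
            index=d["true_response"]["index"],
            columns=d["true_response"]["columns"],
        )
        return cls(
            true_response=tr,
            assessor_bias={a: (v[0], v[1]) for a, v in d["assessor_bias"].items()},
            marker_map={
                k: {f: float(b) for f, b in v.items()}
                for k, v in d["marker_map"].items()
            },
            background_features=list(d["background_features"]),
            correlated_blocks=[list(b) for b in d["correlated_blocks"]],
            clip_fraction=float(d.get("clip_fraction", 0.0)),
        )


# ---------------------------------------------------------------------------
# panel
# ---------------------------------------------------------------------------


def _session_allocation(
    n_assessors: int, n_products: int, coverage: float, session: int
) -> list[list[int]]:
    """Cyclic balanced-incomplete allocation: assessor ``i`` in a session
    scores a contiguous cyclic block of products whose start rotates with the
    assessor and session, so every product is assessed in every session
    whenever ``block * n_assessors >= n_products``."""
    block = max(1, int(round(coverage * n_products)))
    alloc = []
    for i in range(n_assessors):
        start = (int(round(i * n_products / n_assessors)) + session) % n_products
        alloc.append([(start + t) % n_products for t in range(block)])
    return alloc


def simulate_panel(
    design: StudyDesign, effects: EffectMap, cfg: PanelSimConfig
) -> tuple[PanelScores, GroundTruth]:
    """Draw panel scores under the offset/scale assessor-bias model."""
    mu = effects.true_response(design)  # J x K
    rng = np.random.default_rng(cfg.seed)
    offsets = rng.normal(0.0, cfg.assessor_offset_sd, cfg.n_assessors)
    scales = np.exp(rng.normal(0.0, cfg.assessor_scale_sd, cfg.n_assessors))

    assessor_ids = [f"A{i + 1:02d}" for i in range(cfg.n_assessors)]
    products = design.product_ids
    attributes = mu.columns.tolist()
    mu_arr = mu.to_numpy()

    rows = []
    n_clipped = 0
    n_total = 0
    for s in range(cfg.n_sessions):
        alloc = _session_allocation(
            cfg.n_assessors, len(products), cfg.design_coverage, s
        )
        for i, prod_idx in enumerate(alloc):
            for j in prod_idx:
                eps = rng.normal(0.0, cfg.noise_sd, len(attributes))
                raw = offsets[i] + scales[i] * mu_arr[j] + eps
                clipped = np.clip(raw, 0.0, 100.0)
                n_clipped += int((raw != clipped).sum())
                n_total += len(attributes)
                for k, attr in enumerate(attributes):
                    rows.append(
                        (assessor_ids[i], s + 1, products[j], attr, clipped[k])
                    )
    long = pd.DataFrame(
        rows, columns=["assessor_id", "session", "product_id", "attribute", "score"]
    )
    truth = GroundTruth(
        true_response=mu,
        assessor_bias={
            a: (float(offsets[i]), float(scales[i]))
            for i, a in enumerate(assessor_ids)
        },
        clip_fraction=n_clipped / max(n_total, 1),
    )
    return PanelScores(long=long), truth


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------


def _standardized_contrasts(mu: pd.DataFrame) -> pd.DataFrame:
    """Per-attribute unit-variance, zero-mean product contrasts c_jk
    (all-zero when an attribute has no product variation)."""
    c = mu - mu.mean(axis=0)
    sd = c.std(axis=0, ddof=1)
    sd = sd.replace(0.0, 1.0)
    return c / sd


def simulate_feature_table(
    design: StudyDesign, effects: EffectMap, cfg: PlatformSimConfig
) -> tuple[FeatureTable, GroundTruth]:
    """Draw one platform's samples x features table plus ground truth.

    Sample layout: blanks first in the injection sequence, then the study
    samples in randomized order with a pooled-QC injection inserted after
    every ``qc_spacing`` study injections.  The first
    ``n_replicated_products`` products (in design order) are injected in
    ``n_tech_replicates``-fold technical replication; the rest once.
    """
    mu = effects.true_response(design)
    attributes = mu.columns.tolist()
    n_markers = cfg.n_markers_per_attribute * len(attributes)
    if n_markers + cfg.n_background_features > cfg.n_features:
        raise ValueError(
            f"marker budget ({n_markers}) + background features "
            f"({cfg.n_background_features}) exceed n_features ({cfg.n_features})"
        )
    rng = np.random.default_rng(cfg.seed)
    prefix = _PLATFORM_PREFIX[cfg.platform]
    feature_ids = [f"{prefix}{i + 1:04d}" for i in range(cfg.n_features)]

    # feature roles: markers first, then background contaminants, the rest
    # plain features grouped into correlated blocks
    marker_map: dict[str, dict[str, float]] = {}
    pos = 0
    for k, attr in enumerate(attributes):
        betas = {}
        for m in range(cfg.n_markers_per_attribute):
            sign = 1.0 if m % 2 == 0 else -1.0
            betas[feature_ids[pos]] = sign * cfg.marker_effect
            pos += 1
        marker_map[attr] = betas
    background = feature_ids[pos : pos + cfg.n_background_features]
    plain = feature_ids[pos + cfg.n_background_features :]
    blocks = [
        plain[i : i + cfg.correlated_block_size]
        for i in range(0, len(plain), cfg.correlated_block_size)
        if cfg.correlated_block_size >= 2
        and len(plain[i : i + cfg.correlated_block_size]) >= 2
    ]

    baselines = rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, cfg.n_features)
    baseline_of = dict(zip(feature_ids, baselines))
    sigma_t = float(np.sqrt(np.log1p(cfg.technical_cv**2)))
    sigma_block = _BLOCK_LATENT_RATIO * sigma_t

    # study injection list (product per injection), randomized order
    study_products: list[str] = []
    for j, pid in enumerate(design.product_ids):
        reps = cfg.n_tech_replicates if j < cfg.n_replicated_products else 1
        study_products.extend([pid] * reps)
    order = rng.permutation(len(study_products))
    study_products = [study_products[t] for t in order]

    contrasts = _standardized_contrasts(mu)

    # signed effect per feature column, per product
    beta_vec = np.zeros(cfg.n_features)
    contrast_col = np.zeros((len(design), cfg.n_features))
    fidx = {f: i for i, f in enumerate(feature_ids)}
    for attr, betas in marker_map.items():
        for f, b in betas.items():
            beta_vec[fidx[f]] = b
            contrast_col[:, fidx[f]] = contrasts[attr].to_numpy()
    prod_idx = {p: j for j, p in enumerate(design.product_ids)}

    block_member = np.full(cfg.n_features, -1)
    for bi, blk in enumerate(blocks):
        for f in blk:
            block_member[fidx[f]] = bi

    def draw_noise() -> np.ndarray:
        """Per-injection technical noise with shared block latents."""
        e = rng.normal(0.0, sigma_t, cfg.n_features) if sigma_t > 0 else np.zeros(
            cfg.n_features
        )
        if blocks and sigma_block > 0:
            z = rng.normal(0.0, sigma_block, len(blocks))
            e = e + np.where(block_member >= 0, z[np.clip(block_member, 0, None)], 0.0)
        elif blocks:
            # keep the rng call sequence stable even in the noiseless limit
            rng.normal(0.0, 1.0, len(blocks))
        return e

    rows = []
    meta_rows = []
    injection = 0

    def add_row(sample_id, product_id, sample_type, replicate_id, log_vals):
        nonlocal injection
        injection += 1
        rows.append(np.exp(log_vals))
        meta_rows.append(
            {
                "sample_id": sample_id,
                "product_id": product_id,
                "sample_type": sample_type,
                "replicate_id": replicate_id,
                "batch": 1,
                "injection_order": injection,
            }
        )

    blank_base = np.where(
        np.isin(feature_ids, background), baselines, baselines - _BLANK_LOG_DROP
    )
    for b in range(cfg.n_blank):
        add_row(f"{cfg.platform}_blank{b + 1}", None, "blank", b + 1, blank_base + draw_noise())

    study_log_mean = baselines + contrast_col.mean(axis=0) * beta_vec  # pooled target
    rep_counter: dict[str, int] = {}
    qc_counter = 0
    n_study_done = 0
    max_qc = cfg.n_qc if cfg.n_qc is not None else np.inf
    for pid in study_products:
        j = prod_idx[pid]
        log_vals = baselines + beta_vec * contrast_col[j] + draw_noise()
        rep_counter[pid] = rep_counter.get(pid, 0) + 1
        add_row(f"{pid}_r{rep_counter[pid]}", pid, "study", rep_counter[pid], log_vals)
        n_study_done += 1
        if n_study_done % cfg.qc_spacing == 0 and qc_counter < max_qc:
            qc_counter += 1
            add_row(
                f"{cfg.platform}_qc{qc_counter}",
                None,
                "qc",
                qc_counter,
                study_log_mean + draw_noise(),
            )

    intens = pd.DataFrame(
        np.vstack(rows), index=[m["sample_id"] for m in meta_rows], columns=feature_ids
    )
    meta = pd.DataFrame(meta_rows)
    table = FeatureTable(
        intensities=intens, sample_meta=meta, platform=cfg.platform
    )
    truth = GroundTruth(
        true_response=mu,
        marker_map=marker_map,
        background_features=list(background),
        correlated_blocks=[list(b) for b in blocks],
    )
    return table, truth


# ---------------------------------------------------------------------------
# full-study bundle
# ---------------------------------------------------------------------------


@dataclass
class StudySimConfig:
    """Bundle configuration for a full coupled simulation.

    The master ``seed`` deterministically spawns per-component seeds in the
    fixed order (panel, lcms, gcms); the per-component ``seed`` fields of the
    nested configs are overridden.
    """

    seed: int = 0
    panel: PanelSimConfig = field(default_factory=PanelSimConfig)
    lcms: PlatformSimConfig = field(
        default_factory=lambda: PlatformSimConfig(platform="lcms", n_features=500)
    )
    gcms: PlatformSimConfig = field(
        default_factory=lambda: PlatformSimConfig(platform="gcms", n_features=300)
    )

    def component_seeds(self) -> dict[str, int]:
        state = np.random.SeedSequence(self.seed).generate_state(3)
        return {
            name: int(s % (2**31))
            for name, s in zip(("panel", "lcms", "gcms"), state)
        }


def simulate_study(
    out_dir: str | Path,
    cfg: StudySimConfig | None = None,
    design: StudyDesign | None = None,
    effects: EffectMap | None = None,
) -> dict[str, Path]:
    """Simulate and write a complete on-disk bundle loadable by design_io.

    Writes ``design.csv``, ``panel_scores.csv``, ``features_{lcms,gcms}.csv``
    + ``samples_{lcms,gcms}.csv``, ``ground_truth.json`` and
    ``manifest.json``; returns the path of each artifact.
    """
    cfg = cfg or StudySimConfig()
    design = design or default_design()
    effects = effects or default_effect_map()
    seeds = cfg.component_seeds()

    panel_cfg = PanelSimConfig(**{**asdict(cfg.panel), "seed": seeds["panel"]})
    lcms_cfg = PlatformSimConfig(**{**asdict(cfg.lcms), "seed": seeds["lcms"]})
    gcms_cfg = PlatformSimConfig(**{**asdict(cfg.gcms), "seed": seeds["gcms"]})

    panel, panel_truth = simulate_panel(design, effects, panel_cfg)
    lcms, lcms_truth = simulate_feature_table(design, effects, lcms_cfg)
    gcms, gcms_truth = simulate_feature_table(design, effects, gcms_cfg)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "design": out / "design.csv",
        "panel_scores": out / "panel_scores.csv",
        "features_lcms": out / "features_lcms.csv",
        "samples_lcms": out / "samples_lcms.csv",
        "features_gcms": out / "features_gcms.csv",
        "samples_gcms": out / "samples_gcms.csv",
        "ground_truth": out / "ground_truth.json",
        "manifest": out / "manifest.json",
    }
    write_design(design, paths["design"])
    write_panel_scores(panel, paths["panel_scores"])
    write_feature_table(lcms, paths["features_lcms"], paths["samples_lcms"])
    write_feature_table(gcms, paths["features_gcms"], paths["samples_gcms"])

    truth = {
        "panel": panel_truth.to_dict(),
        "lcms": lcms_truth.to_dict(),
        "gcms": gcms_truth.to_dict(),
    }
    with open(paths["ground_truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    manifest = {
        "master_seed": cfg.seed,
        "component_seeds": seeds,
        "panel": asdict(panel_cfg),
        "lcms": asdict(lcms_cfg),
        "gcms": asdict(gcms_cfg),
        "n_products": len(design),
        "n_attributes": len(effects.attributes),
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return paths


def load_ground_truth(path: str | Path) -> dict[str, GroundTruth]:
    with open(path) as fh:
        d = json.load(fh)
    return {k: GroundTruth.from_dict(v) for k, v in d.items()}
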