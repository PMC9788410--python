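"""Study-design data model and tabular IO.

All tables are plain CSV: comma-delimited, UTF-8, ``.`` decimal separator,
mandatory header row.  Missing values are written as empty cells and read back
as missing (never as zero — zero is a meaningful intensity).

Three input families are handled:

* the product-composition design (one row per soup product, five factors),
* long-format trained-panel scores (assessor, session, product, attribute,
  score on the 0–100 line scale),
* post-peak-picking feature tables (samples x features intensity matrix plus
  per-sample metadata: product, sample type, replicate, batch, injection
  order).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "ValidationError",
    "ProductSpec",
    "StudyDesign",
    "PanelScores",
    "ScoreTensor",
    "FeatureTable",
    "FACTOR_NAMES",
    "FIXED_FACTOR_LEVELS",
    "DEFAULT_YEAST_PRODUCTS",
    "DEFAULT_ATTRIBUTES",
    "default_design",
    "load_design",
    "write_design",
    "load_panel_scores",
    "write_panel_scores",
    "load_feature_table",
    "write_feature_table",
]


class SchemaError(ValueError):
    """A file does not match the expected CSV schema."""


class ValidationError(ValueError):
    """A table is schema-conformant but violates a domain invariant."""


#: The five compositional factors, in canonical column order.
FACTOR_NAMES = ("oil_type", "tomato_dose", "yeast_product", "yeast_dose", "heat")

#: Closed level sets for the factors whose levels are fixed by the study frame.
#: ``yeast_product`` is open-ended: ``none`` plus any configured product codes.
FIXED_FACTOR_LEVELS = {
    "oil_type": ("corn", "olive"),
    "tomato_dose": ("high", "low"),
    "yeast_dose": ("none", "low", "high"),
    "heat": ("short", "long"),
}

#: Yeast-derived flavor-product codes used by the default fixture.
DEFAULT_YEAST_PRODUCTS = ("S99", "G28", "O31", "YPr")

#: Default 26-attribute vocabulary over the five sensory categories
#: (odor ``.od``, flavor ``.fl``, mouthfeel ``.mf``, aftertaste ``.at``,
#: afterfeel ``.af``).  Names are package placeholders; the count and the
#: category suffixes are the anchored structure.
DEFAULT_ATTRIBUTES = (
    "intensity.od",
    "tomato.od",
    "onion.od",
    "garlic.od",
    "yeast.od",
    "sweet.od",
    "intensity.fl",
    "tomato.fl",
    "onion.fl",
    "garlic.fl",
    "umami.fl",
    "sweet.fl",
    "bitter.fl",
    "salty.fl",
    "sour.fl",
    "yeast.fl",
    "thickness.mf",
    "fattiness.mf",
    "mouthfullness.mf",
    "graininess.mf",
    "intensity.at",
    "umami.at",
    "bitter.at",
    "dryness.af",
    "coating.af",
    "pungency.af",
)

_SAMPLE_TYPES = ("study", "qc", "blank")


@dataclass(frozen=True)
class ProductSpec:
    """One soup product: an id plus its five compositional factor levels."""

    product_id: str
    oil_type: str
    tomato_dose: str
    yeast_product: str
    yeast_dose: str
    heat: str

    def __post_init__(self) -> None:
        if not self.product_id:
            raise ValidationError("product_id must be nonempty")
        for factor, levels in FIXED_FACTOR_LEVELS.items():
            value = getattr(self, factor)
            if value not in levels:
                raise SchemaError(
                    f"product {self.product_id!r}: unknown level {value!r} "
                    f"for factor {factor!r} (expected one of {levels})"
                )
        if (self.yeast_product == "none") != (self.yeast_dose == "none"):
            raise ValidationError(
                f"product {self.product_id!r}: yeast_product={self.yeast_product!r} "
                f"inconsistent with yeast_dose={self.yeast_dose!r} "
                "(exactly one is 'none')"
            )


@dataclass
class StudyDesign:
    """Ordered collection of products; the backbone every table joins on."""

    products: list[ProductSpec]

    def __post_init__(self) -> None:
        ids = [p.product_id for p in self.products]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise SchemaError(f"duplicate product_id values: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.products)

    @property
    def product_ids(self) -> list[str]:
        return [p.product_id for p in self.products]

    def factor_levels(self, factor: str) -> list[str]:
        """Observed levels of *factor*, in first-appearance order."""
        if factor not in FACTOR_NAMES:
            raise KeyError(f"unknown factor {factor!r}")
        seen: list[str] = []
        for p in self.products:
            level = getattr(p, factor)
            if level not in seen:
                seen.append(level)
        return seen

    def factor_level(self, product_id: str, factor: str) -> str:
        for p in self.products:
            if p.product_id == product_id:
                return getattr(p, factor)
        raise KeyError(f"unknown product {product_id!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "product_id": p.product_id,
                    **{f: getattr(p, f) for f in FACTOR_NAMES},
                }
                for p in self.products
            ],
            columns=["product_id", *FACTOR_NAMES],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "StudyDesign":
        missing = {"product_id", *FACTOR_NAMES} - set(df.columns)
        if missing:
            raise SchemaError(f"design table missing columns: {sorted(missing)}")
        products = []
        for row_no, row in enumerate(df.itertuples(index=False), start=2):
            try:
                products.append(
                    ProductSpec(
                        product_id=str(row.product_id),
                        **{f: str(getattr(row, f)) for f in FACTOR_NAMES},
                    )
                )
            except (SchemaError, ValidationError) as exc:
                raise type(exc)(f"design row {row_no}: {exc}") from exc
        return cls(products=products)


def load_design(path: str | Path) -> StudyDesign:
    """Read a product-composition CSV into a validated :class:`StudyDesign`.

    Row order is preserved.  An empty file (header only) yields a design with
    zero products and logs a warning.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    design = StudyDesign.from_frame(df)
    if len(design) == 0:
        logger.warning("design file %s contains no products", path)
    return design


def write_design(design: StudyDesign, path: str | Path) -> None:
    design.to_frame().to_csv(path, index=False)


def default_design() -> StudyDesign:
    """The packaged 27-product fixture (4 yeast codes x 2 doses in three
    tomato/oil/heat contexts, plus a 3-product no-yeast arm)."""
    ref = resources.files("flavorlink").joinpath("data/design.csv")
    with resources.as_file(ref) as p:
        return load_design(p)


# ---------------------------------------------------------------------------
# panel scores
# ---------------------------------------------------------------------------

_PANEL_COLUMNS = ["assessor_id", "session", "product_id", "attribute", "score"]


@dataclass
class ScoreTensor:
    """Dense (assessor, product, attribute) array with NaN for missing cells."""

    values: np.ndarray
    assessors: list[str]
    products: list[str]
    attributes: list[str]

    def __post_init__(self) -> None:
        expected = (len(self.assessors), len(self.products), len(self.attributes))
        if self.values.shape != expected:
            raise ValueError(
                f"tensor shape {self.values.shape} does not match axis labels {expected}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def copy(self) -> "ScoreTensor":
        return ScoreTensor(
            self.values.copy(),
            list(self.assessors),
            list(self.products),
            list(self.attributes),
        )


@dataclass
class PanelScores:
    """Long-format trained-panel scores with 0–100 range validation."""

    long: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(_PANEL_COLUMNS) - set(self.long.columns)
        if missing:
            raise SchemaError(f"panel table missing columns: {sorted(missing)}")
        scores = pd.to_numeric(self.long["score"], errors="raise")
        bad = self.long.index[(scores < 0) | (scores > 100)]
        if len(bad):
            raise ValidationError(
                f"scores outside [0, 100] at rows {list(bad[:5])}"
                + ("..." if len(bad) > 5 else "")
            )
        key = ["assessor_id", "session", "product_id", "attribute"]
        dup = self.long.duplicated(subset=key)
        if dup.any():
            first = self.long.loc[dup].iloc[0]
            raise ValidationError(
                "duplicate (assessor, session, product, attribute) entry: "
                f"{tuple(first[k] for k in key)}"
            )

    @property
    def assessors(self) -> list[str]:
        return sorted(self.long["assessor_id"].astype(str).unique())

    @property
    def products(self) -> list[str]:
        return sorted(self.long["product_id"].astype(str).unique())

    @property
    def attributes(self) -> list[str]:
        return sorted(self.long["attribute"].astype(str).unique())

    def to_tensor(
        self,
        products: Sequence[str] | None = None,
        attributes: Sequence[str] | None = None,
    ) -> ScoreTensor:
        """Session-averaged (assessor, product, attribute) tensor.

        Scores are averaged over sessions per cell; cells never assessed are
        NaN.  Axis orders default to sorted unique labels but can be pinned.
        """
        assessors = self.assessors
        products = list(products) if products is not None else self.products
        attributes = list(attributes) if attributes is not None else self.attributes
        ai = {a: i for i, a in enumerate(assessors)}
        pj = {p: j for j, p in enumerate(products)}
        ak = {a: k for k, a in enumerate(attributes)}

        sums = np.zeros((len(assessors), len(products), len(attributes)))
        counts = np.zeros_like(sums)
        for row in self.long.itertuples(index=False):
            i = ai[str(row.assessor_id)]
            j = pj[str(row.product_id)]
            k = ak[str(row.attribute)]
            sums[i, j, k] += float(row.score)
            counts[i, j, k] += 1
        with np.errstate(invalid="ignore"):
            values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        n_missing = int((counts == 0).sum())
        if n_missing:
            logger.info(
                "panel tensor has %d missing (assessor, product, attribute) cells",
                n_missing,
            )
        return ScoreTensor(values, assessors, products, attributes)

    def missing_cells(self) -> int:
        t = self.to_tensor()
        return int(np.isnan(t.values).sum())


def load_panel_scores(path: str | Path) -> PanelScores:
    """Read a long-format panel-score CSV; scores validated to [0, 100]."""
    df = pd.read_csv(path, float_precision="round_trip")
    return PanelScores(long=df)


def write_panel_scores(scores: PanelScores, path: str | Path) -> None:
    # repr(float) is the shortest exactly-round-tripping representation
    scores.long.to_csv(path, index=False, float_format=lambda x: repr(float(x)))


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

_META_COLUMNS = [
    "sample_id",
    "product_id",
    "sample_type",
    "replicate_id",
    "batch",
    "injection_order",
]


def _validate_sample_meta(meta: pd.DataFrame) -> pd.DataFrame:
    missing = set(_META_COLUMNS) - set(meta.columns)
    if missing:
        raise SchemaError(f"sample metadata missing columns: {sorted(missing)}")
    meta = meta.copy()
    meta["sample_id"] = meta["sample_id"].astype(str)
    if meta["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in metadata")
    bad_type = ~meta["sample_type"].isin(_SAMPLE_TYPES)
    if bad_type.any():
        raise SchemaError(
            f"unknown sample_type values: {sorted(meta.loc[bad_type, 'sample_type'].unique())}"
        )
    study = meta["sample_type"] == "study"
    if meta.loc[study, "product_id"].isna().any():
        raise ValidationError("study samples must reference a product_id")
    for col in ("replicate_id", "batch", "injection_order"):
        vals = pd.to_numeric(meta[col], errors="raise")
        if (vals < 1).any():
            raise ValidationError(f"{col} must be >= 1")
        meta[col] = vals.astype(int)
    dup = meta.duplicated(subset=["batch", "injection_order"])
    if dup.any():
        pair = meta.loc[dup, ["batch", "injection_order"]].iloc[0]
        raise ValidationError(
            f"injection_order {pair.injection_order} duplicated within batch {pair.batch}"
        )
    return meta


@dataclass
class FeatureTable:
    """Samples x features intensity matrix joined with sample metadata.

    ``intensities`` is indexed by sample_id with one column per feature id;
    ``sample_meta`` is row-aligned on the same index.  ``processing_log``
    records every preprocessing step applied (see
    :mod:`flavorlink.feature_processing`).
    """

    intensities: pd.DataFrame
    sample_meta: pd.DataFrame
    platform: str = "lcms"
    processing_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sample_meta = _validate_sample_meta(self.sample_meta.reset_index(drop=True))
        self.intensities = self.intensities.copy()
        self.intensities.index = self.intensities.index.astype(str)
        meta_ids = set(self.sample_meta["sample_id"])
        unknown = [s for s in self.intensities.index if s not in meta_ids]
        if unknown:
            raise ValidationError(
                f"samples absent from metadata: {unknown[:5]}"
                + ("..." if len(unknown) > 5 else "")
            )
        # align metadata to the intensity row order
        self.sample_meta = (
            self.sample_meta.set_index("sample_id")
            .loc[self.intensities.index]
            .rename_axis("sample_id")
            .reset_index()
        )
        if self.intensities.columns.duplicated().any():
            raise ValidationError("duplicate feature ids")
        if not self.processing_log:  # raw intensities only; log scale may be negative
            vals = self.intensities.to_numpy(dtype=float)
            if np.nanmin(vals, initial=0.0) < 0:
                raise ValidationError("negative intensity values are not allowed")
        all_missing = self.intensities.columns[self.intensities.isna().all(axis=0)]
        if len(all_missing):
            logger.warning(
                "dropping %d all-missing feature columns: %s",
                len(all_missing),
                list(all_missing[:5]),
            )
            self.intensities = self.intensities.drop(columns=all_missing)

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.intensities.columns)

    def rows_of_type(self, sample_type: str) -> pd.DataFrame:
        mask = (self.sample_meta["sample_type"] == sample_type).to_numpy()
        return self.intensities.loc[mask]

    def replace(
        self,
        intensities: pd.DataFrame | None = None,
        sample_meta: pd.DataFrame | None = None,
        log_entry: dict | None = None,
    ) -> "FeatureTable":
        """Functional update helper used by the preprocessing steps."""
        new_log = list(self.processing_log)
        if log_entry is not None:
            new_log.append(log_entry)
        return FeatureTable(
            intensities=intensities if intensities is not None else self.intensities,
            sample_meta=sample_meta if sample_meta is not None else self.sample_meta,
            platform=self.platform,
            processing_log=new_log,
        )


def load_feature_table(
    path: str | Path, meta_path: str | Path, platform: str = "lcms"
) -> FeatureTable:
    """Read an intensity CSV (first column ``sample_id``) plus its metadata CSV.

    Every intensity row must appear in the metadata; all-missing feature
    columns are dropped with a warning; negative intensities are rejected.
    """
    intens = pd.read_csv(path, index_col=0, float_precision="round_trip")
    intens.index.name = "sample_id"
    meta = pd.read_csv(meta_path)
    return FeatureTable(intensities=intens, sample_meta=meta, platform=platform)


def write_feature_table(
    table: FeatureTable, path: str | Path, meta_path: str | Path
) -> None:
    table.intensities.to_csv(
        path, index=True, index_label="sample_id",
        float_format=lambda x: repr(float(x)),
    )
    table.sample_meta.to_csv(meta_path, index=False)
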