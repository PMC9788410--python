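import numpy as np
import pytest

import flavorlink as fl
from flavorlink import synthetic_data as sd


@pytest.fixture(scope="session")
def design():
    return fl.design_io.default_design()


@pytest.fixture(scope="session")
def effect_map():
    return sd.default_effect_map()


@pytest.fixture(scope="session")
def small_panel(design, effect_map):
    """Default-size panel draw used by several read-only tests."""
    panel, truth = sd.simulate_panel(
        design, effect_map, sd.PanelSimConfig(seed=42)
    )
    return panel, truth


@pytest.fixture(scope="session")
def small_feature_bundle(design):
    """One-attribute platform table with 6 planted markers among 80 features."""
    em = sd.EffectMap(
        baseline={"tomato.fl": 50.0},
        effects={"tomato.fl": [("tomato_dose", "high", 16)]},
    )
    cfg = sd.PlatformSimConfig(
        platform="lcms",
        n_features=80,
        n_markers_per_attribute=6,
        marker_effect=1.0,
        technical_cv=0.05,
        n_background_features=10,
        seed=7,
    )
    table, truth = sd.simulate_feature_table(design, em, cfg)
    return em, table, truth


def two_way_anova_f(y: np.ndarray) -> float:
    """Closed-form balanced two-way ANOVA (product + assessor blocks) F for
    the product effect; the independent oracle for the mixed-model F."""
    I, J = y.shape
    gm = y.mean()
    pm = y.mean(axis=0)
    am = y.mean(axis=1)
    ss_p = I * ((pm - gm) ** 2).sum()
    ss_e = ((y - pm[None, :] - am[:, None] + gm) ** 2).sum()
    return (ss_p / (J - 1)) / (ss_e / ((I - 1) * (J - 1)))
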