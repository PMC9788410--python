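import warnings

import numpy as np
import pandas as pd
import pytest

from flavorlink.design_io import ScoreTensor
from flavorlink import sensory_processing as sp
from flavorlink import synthetic_data as sd

from conftest import two_way_anova_f


def _tensor(values):
    values = np.asarray(values, dtype=float)
    I, J, K = values.shape
    return ScoreTensor(
        values,
        [f"A{i}" for i in range(I)],
        [f"P{j}" for j in range(J)],
        [f"attr{k}" for k in range(K)],
    )


class TestStandardize:
    def test_hand_example_two_products(self):
        z, _ = sp.standardize(_tensor([[[40.0], [60.0]]]))
        np.testing.assert_allclose(
            z.values[0, :, 0], [-1 / np.sqrt(2), 1 / np.sqrt(2)], atol=1e-10
        )

    def test_slice_moments_zero_one(self):
        rng = np.random.default_rng(0)
        z, _ = sp.standardize(_tensor(rng.uniform(0, 100, (4, 9, 3))))
        np.testing.assert_allclose(np.nanmean(z.values, axis=1), 0, atol=1e-10)
        np.testing.assert_allclose(np.nanstd(z.values, axis=1, ddof=1), 1, atol=1e-10)

    def test_idempotent_on_standardized_input(self):
        rng = np.random.default_rng(1)
        z, _ = sp.standardize(_tensor(rng.uniform(0, 100, (3, 8, 2))))
        z2, _ = sp.standardize(z)
        np.testing.assert_allclose(z2.values, z.values, atol=1e-10)

    def test_constant_slice_dropped_with_named_warning(self, caplog):
        vals = np.array([[[50.0, 10.0], [50.0, 20.0]], [[30.0, 30.0], [60.0, 40.0]]])
        with caplog.at_level("WARNING"):
            z, stats = sp.standardize(_tensor(vals))
        assert ("A0", "attr0") in stats.dropped_slices
        assert "A0" in caplog.text and "attr0" in caplog.text
        assert np.isnan(z.values[0, :, 0]).all()
        with pytest.raises(ValueError, match="constant"):
            sp.standardize(_tensor(vals), on_constant="error")


class TestPooledSD:
    def test_conventional_root_mean_variance(self):
        _, stats = sp.standardize(_tensor(np.random.default_rng(0).uniform(0, 100, (2, 4, 1))))
        stats.assessor_sd = np.array([[2.0], [4.0]])
        sp.pooled_sd(stats, n_products=4, mode="conventional")
        np.testing.assert_allclose(stats.pooled, [np.sqrt(10.0)], atol=1e-12)

    def test_literal_mode_as_printed(self):
        _, stats = sp.standardize(_tensor(np.random.default_rng(0).uniform(0, 100, (2, 3, 1))))
        stats.assessor_sd = np.array([[2.0], [4.0]])
        sp.pooled_sd(stats, n_products=3, mode="literal")
        np.testing.assert_allclose(stats.pooled, [1.5], atol=1e-12)

    def test_modes_differ_and_equal_sds_pass_through(self):
        _, stats = sp.standardize(_tensor(np.random.default_rng(0).uniform(0, 100, (3, 5, 1))))
        stats.assessor_sd = np.array([[3.0], [3.0], [3.0]])
        conv = sp.pooled_sd(stats, n_products=5, mode="conventional").copy()
        lit = sp.pooled_sd(stats, n_products=5, mode="literal").copy()
        np.testing.assert_allclose(conv, [3.0], atol=1e-12)
        # the literal form shrinks by roughly 1/(J-1)
        np.testing.assert_allclose(lit, [3.0 / 4.0], atol=1e-12)
        assert not np.allclose(conv, lit)


class TestBackTransform:
    def test_zero_scores_map_to_attribute_mean(self):
        t = _tensor(np.random.default_rng(2).uniform(20, 80, (3, 6, 2)))
        z, stats = sp.standardize(t)
        sp.pooled_sd(stats, 6)
        zero = ScoreTensor(np.zeros_like(z.values), z.assessors, z.products, z.attributes)
        bt = sp.back_transform(zero, stats)
        for k in range(2):
            np.testing.assert_allclose(bt.values[:, :, k], stats.attribute_mean[k])

    def test_round_trip_restores_grand_mean_and_ranking(self):
        t = _tensor(np.random.default_rng(3).uniform(0, 100, (4, 7, 3)))
        bt, _, stats = sp.standardize_panel(t)
        np.testing.assert_allclose(
            np.nanmean(bt.values, axis=(0, 1)), stats.attribute_mean, atol=1e-10
        )
        # a monotone affine map preserves within-assessor product ranking
        for i in range(4):
            for k in range(3):
                assert (
                    np.argsort(bt.values[i, :, k]).tolist()
                    == np.argsort(t.values[i, :, k]).tolist()
                )

    def test_per_attribute_sd_equals_pooled_sd(self):
        """When every assessor slice has SD 1, the back-transformed spread
        per assessor equals sp_k exactly (affine-scaling identity)."""
        t = _tensor(np.random.default_rng(4).uniform(0, 100, (2, 6, 1)))
        z, stats = sp.standardize(t)
        sp.pooled_sd(stats, 6)
        bt = sp.back_transform(z, stats)
        for i in range(2):
            np.testing.assert_allclose(
                np.std(bt.values[i, :, 0], ddof=1), stats.pooled[0], atol=1e-10
            )


class TestSensoryResponse:
    def test_mean_across_assessors(self):
        t = _tensor([[[30.0]], [[50.0]]])
        nu = sp.sensory_response(t)
        assert nu.iloc[0, 0] == 40.0

    def test_single_assessor_passthrough(self):
        t = _tensor([[[33.0], [44.0]]])
        nu = sp.sensory_response(t)
        np.testing.assert_allclose(nu.to_numpy()[:, 0], [33.0, 44.0])

    def test_noiseless_panel_recovers_true_ordering(self, design):
        em = sd.EffectMap(
            baseline={"a": 50.0, "b": 40.0},
            effects={"a": [("tomato_dose", "high", 12)],
                     "b": [("yeast_dose", "high", 9), ("yeast_dose", "low", 4)]},
        )
        cfg = sd.PanelSimConfig(n_assessors=3, n_sessions=1, assessor_offset_sd=5,
                                assessor_scale_sd=0.1, noise_sd=0, seed=0)
        panel, truth = sd.simulate_panel(design, em, cfg)
        _, nu, _ = sp.standardize_panel(panel)
        for attr in ("a", "b"):
            got = nu[attr].loc[truth.true_response.index]
            rho = pd.Series(got).corr(truth.true_response[attr], method="spearman")
            assert rho > 0.999


class TestProductF:
    def test_matches_two_way_anova_oracle(self):
        rng = np.random.default_rng(0)
        y = rng.normal(50, 10, (5, 6)) + rng.normal(0, 5, (5, 1))
        res = sp.product_f_values(_tensor(y[:, :, None]))[0]
        oracle = two_way_anova_f(y)
        assert res.f_value == pytest.approx(oracle, abs=1e-6)
        assert (res.df_num, res.df_den) == (5, 20)

    def test_matches_statsmodels_mixedlm_on_incomplete_data(self):
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(7)
        I, J = 6, 8
        y = rng.normal(50, 10, (I, J)) + rng.normal(0, 6, (I, 1))
        mask = rng.random((I, J)) < 0.85
        rows = [
            {"score": y[i, j], "assessor": f"A{i}", "product": f"P{j}"}
            for i in range(I) for j in range(J) if mask[i, j]
        ]
        df = pd.DataFrame(rows)
        f, q, _ = sp._mixed_f_one_attribute(df)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = smf.mixedlm("score ~ C(product)", df, groups=df["assessor"]).fit(
                reml=True, method="powell", maxiter=5000
            )
        names = res.model.exog_names
        sel = [i for i, nm in enumerate(names) if nm.startswith("C(product)")]
        b = np.asarray(res.fe_params)[sel]
        cov = np.asarray(res.cov_params())[np.ix_(sel, sel)]
        f_sm = float(b @ np.linalg.solve(cov, b)) / len(sel)
        assert f == pytest.approx(f_sm, rel=0.02)

    def test_invariant_to_assessor_affine_transform_after_standardization(self):
        rng = np.random.default_rng(1)
        y = rng.normal(50, 10, (4, 6, 2))
        t = _tensor(y)
        y2 = y * np.array([1.0, 2.0, 0.5, 3.0])[:, None, None] + np.array(
            [0.0, 10.0, -5.0, 20.0]
        )[:, None, None]
        t2 = _tensor(y2)
        bt1, _, _ = sp.standardize_panel(t)
        bt2, _, _ = sp.standardize_panel(t2)
        f1 = [r.f_value for r in sp.product_f_values(bt1)]
        f2 = [r.f_value for r in sp.product_f_values(bt2)]
        np.testing.assert_allclose(f1, f2, rtol=1e-8)

    def test_f_increases_with_simulated_effect_size(self, design):
        medians = []
        for effect in (0.0, 6.0, 14.0):
            fs = []
            for seed in range(4):
                em = sd.EffectMap(
                    baseline={"a": 50.0},
                    effects={"a": [("tomato_dose", "high", effect)]},
                )
                cfg = sd.PanelSimConfig(n_assessors=6, n_sessions=1, noise_sd=6,
                                        assessor_offset_sd=4, assessor_scale_sd=0.1,
                                        seed=100 + seed)
                panel, _ = sd.simulate_panel(design, em, cfg)
                fs.append(sp.product_f_values(panel.to_tensor())[0].f_value)
            medians.append(np.median(fs))
        assert medians[0] < medians[1] < medians[2]

    def test_strong_effect_beats_pure_noise(self, design):
        wins = 0
        n_runs = 10
        for seed in range(n_runs):
            em = sd.EffectMap(
                baseline={"signal": 50.0, "noise": 50.0},
                effects={"signal": [("tomato_dose", "high", 14)]},
            )
            cfg = sd.PanelSimConfig(n_assessors=6, n_sessions=1, noise_sd=6,
                                    seed=500 + seed)
            panel, _ = sd.simulate_panel(design, em, cfg)
            res = {r.attribute: r.f_value for r in sp.product_f_values(panel.to_tensor())}
            wins += res["signal"] > res["noise"]
        assert wins >= int(0.95 * n_runs)

    def test_too_few_products_rejected(self):
        with pytest.raises(ValueError):
            sp.product_f_values(_tensor(np.zeros((3, 1, 1))))
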