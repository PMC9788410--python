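import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flavorlink import models as M


def _reference_nipals(X, Y, A):
    """Independent machine-precision NIPALS (power iteration to 1e-15),
    used purely as a cross-implementation oracle."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    xm, ym = X.mean(0), Y.mean(0)
    Xc, Yc = X - xm, Y - ym
    W, P, Q = [], [], []
    for _ in range(A):
        u = Yc[:, int(np.argmax((Yc**2).sum(0)))].copy()
        w_old = None
        for _ in range(100000):
            w = Xc.T @ u
            w /= np.linalg.norm(w)
            t = Xc @ w
            q = Yc.T @ t / (t @ t)
            u = Yc @ q / (q @ q)
            if w_old is not None and np.linalg.norm(w - w_old) < 1e-15:
                break
            w_old = w
        t = Xc @ w
        p = Xc.T @ t / (t @ t)
        q = Yc.T @ t / (t @ t)
        Xc = Xc - np.outer(t, p)
        Yc = Yc - np.outer(t, q)
        W.append(w), P.append(p), Q.append(q)
    W, P, Q = np.array(W).T, np.array(P).T, np.array(Q).T
    B = W @ np.linalg.solve(P.T @ W, Q.T)
    return lambda Xn: (np.asarray(Xn, float) - xm) @ B + ym


class TestPLS:
    def test_collinear_limit_perfect_training_fit(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=12)
        X = np.column_stack([2 * y, -y])
        m = M.fit_pls(X, y, 1)
        np.testing.assert_allclose(m.predict(X)[:, 0], y, atol=1e-10)

    def test_one_component_closed_form(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 5))
        y = rng.normal(size=10)
        m = M.fit_pls(X, y, 1)
        Xc = X - X.mean(0)
        yc = y - y.mean()
        w = Xc.T @ yc
        w /= np.linalg.norm(w)
        t = Xc @ w
        b = w * (t @ yc) / (t @ t)
        np.testing.assert_allclose(m.coef()[:, 0], b, atol=1e-10)

    @pytest.mark.parametrize("m_resp", [1, 3])
    def test_matches_independent_nipals_reference(self, m_resp):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 5))
        Y = rng.normal(size=(10, m_resp))
        Xn = rng.normal(size=(6, 5))
        model = M.fit_pls(X, Y, 3)
        ref = _reference_nipals(X, Y, 3)
        np.testing.assert_allclose(model.predict(Xn), ref(Xn), atol=1e-8)

    def test_matches_sklearn_within_its_convergence(self):
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 6))
        Y = rng.normal(size=(12, 2))
        Xn = rng.normal(size=(5, 6))
        model = M.fit_pls(X, Y, 3)
        sk = PLSRegression(n_components=3, scale=False, tol=1e-12, max_iter=5000).fit(X, Y)
        np.testing.assert_allclose(model.predict(Xn), sk.predict(Xn), atol=1e-6)

    def test_scores_orthogonal_and_training_fit_reproduced(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(15, 8))
        Y = rng.normal(size=(15, 2))
        m = M.fit_pls(X, Y, 4)
        G = m.T.T @ m.T
        np.testing.assert_allclose(G - np.diag(np.diag(G)), 0, atol=1e-8)
        # X_c B == T Q' (training fit identity)
        np.testing.assert_allclose(
            (X - m.x_mean) @ m.coef(), m.T @ m.Q.T, atol=1e-8
        )

    def test_feature_permutation_invariance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(12, 6))
        y = rng.normal(size=12)
        perm = rng.permutation(6)
        m1 = M.fit_pls(X, y, 3)
        m2 = M.fit_pls(X[:, perm], y, 3)
        Xn = rng.normal(size=(4, 6))
        np.testing.assert_allclose(
            m1.predict(Xn), m2.predict(Xn[:, perm]), atol=1e-10
        )

    def test_json_round_trip_preserves_predictions(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(12, 5))
        Y = rng.normal(size=(12, 2))
        m = M.fit_pls(X, Y, 3)
        m2 = M.PLSModel.from_dict(m.to_dict())
        Xn = rng.normal(size=(4, 5))
        np.testing.assert_allclose(m.predict(Xn), m2.predict(Xn), atol=1e-12)

    def test_excess_components_reduced_with_warning(self, caplog):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(4, 10))
        y = rng.normal(size=4)
        with caplog.at_level("WARNING"):
            m = M.fit_pls(X, y, 9)
        assert m.n_components <= 3


class TestVIP:
    def test_identical_columns_all_unit_vip(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=12)
        X = np.tile(col[:, None], (1, 5))
        y = 2 * col + rng.normal(size=12) * 0.01
        v = M.vip(M.fit_pls(X, y, 1))
        np.testing.assert_allclose(v, 1.0, atol=1e-8)

    def test_normalization_identity_on_random_models(self):
        rng = np.random.default_rng(1)
        for p in (3, 10, 25):
            X = rng.normal(size=(20, p))
            Y = rng.normal(size=(20, 2))
            v = M.vip(M.fit_pls(X, Y, 3))
            assert (v**2).sum() == pytest.approx(p, abs=1e-8)

    def test_planted_feature_ranks_first(self):
        hits = 0
        n_runs = 20
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(30, 21))
            y = 2.0 * X[:, 7] + rng.normal(size=30) * 0.3
            v = M.vip(M.fit_pls(X, y, 2))
            hits += int(np.argmax(v) == 7)
        assert hits >= int(0.95 * n_runs)


class TestPLSDA:
    def test_separable_two_class_training_points(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(-3, 0.3, (10, 4)), rng.normal(3, 0.3, (10, 4))])
        labels = np.array(["low"] * 10 + ["high"] * 10)
        Y, classes = M.one_hot(labels)
        m = M.fit_pls(X, Y, 2)
        pred = M.plsda_predict(m, X, classes)
        assert (pred == labels).all()

    def test_tie_goes_to_first_training_label(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 3))
        labels = np.array(["b", "a"] * 5)
        Y, classes = M.one_hot(labels)
        m = M.fit_pls(X, Y, 1)
        # at the training centroid predictions equal the class means: a tie
        pred = M.plsda_predict(m, m.x_mean[None, :], classes)
        assert pred[0] == "b"  # first label seen in training order

    def test_three_class_blobs_high_bacc(self):
        rng = np.random.default_rng(2)
        centers = np.array([[-4, 0], [4, 0], [0, 6]])
        Xtr = np.vstack([rng.normal(c, 0.5, (15, 2)) for c in centers])
        ytr = np.repeat(["a", "b", "c"], 15)
        Xte = np.vstack([rng.normal(c, 0.5, (10, 2)) for c in centers])
        yte = np.repeat(["a", "b", "c"], 10)
        Y, classes = M.one_hot(ytr)
        m = M.fit_pls(Xtr, Y, 2)
        pred = M.plsda_predict(m, Xte, classes)
        bacc = M.balanced_accuracy(M.confusion_summary(yte, pred, classes))
        assert bacc > 0.9

    def test_feature_mismatch_rejected(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(8, 4))
        Y, classes = M.one_hot(np.array(["a", "b"] * 4))
        m = M.fit_pls(X, Y, 1)
        with pytest.raises(ValueError, match="mismatch"):
            M.plsda_predict(m, rng.normal(size=(2, 5)), classes)


class TestMetrics:
    def test_bacc_hand_value(self):
        c = M.ConfusionSummary(
            classes=["pos", "neg"],
            tpr=np.array([0.8, 0.6]),
            tnr=np.array([0.6, 0.8]),
            counts=np.array([10, 10]),
        )
        assert M.balanced_accuracy(c) == pytest.approx(0.7)

    def test_bacc_perfect_and_random(self):
        y = np.array(["a", "b"] * 200)
        assert M.balanced_accuracy(M.confusion_summary(y, y)) == 1.0
        rng = np.random.default_rng(0)
        pred = rng.choice(["a", "b"], size=400)
        bacc = M.balanced_accuracy(M.confusion_summary(y, pred))
        assert bacc == pytest.approx(0.5, abs=0.06)

    def test_bacc_empty_class_named_in_error(self):
        y = np.array(["a", "a", "b", "b"])
        with pytest.raises(ValueError, match="'c'"):
            M.confusion_summary(y, y, classes=["a", "b", "c"])

    def test_q_squared_hand_values(self):
        assert M.q_squared([1.0, 2.0, 3.0], [2.0, 2.0, 2.0]) == pytest.approx(0.0)
        y = np.array([1.0, 2.0, 4.0])
        assert M.q_squared(y, y) == 1.0
        assert M.q_squared([1.0, 2.0, 3.0], [3.0, 3.0, 3.0]) < 0

    def test_q_squared_constant_y_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            M.q_squared([2.0, 2.0], [1.0, 3.0])

    def test_rmsep_values(self):
        assert M.rmsep([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert M.rmsep([1.0, -1.0], [0.0, 0.0]) == 1.0

    @given(
        c=st.floats(min_value=-100, max_value=100, allow_nan=False),
        seed=st.integers(0, 10_000),
    )
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_rmsep_homogeneous_in_scale(self, c, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=8)
        yh = rng.normal(size=8)
        assert M.rmsep(c * y, c * yh) == pytest.approx(abs(c) * M.rmsep(y, yh), rel=1e-9, abs=1e-9)


class TestRandomForest:
    def test_null_importance_centred_at_zero(self):
        imps = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(25, 6))
            y = rng.normal(size=25)
            f = M.rf_fit(X, y, n_trees=60, seed=seed)
            imps.append(f.importance)
        imps = np.array(imps)  # 20 seeds x 6 features
        mean = imps.mean()
        se = imps.mean(axis=1).std(ddof=1) / np.sqrt(len(imps))
        assert abs(mean) <= 2 * se + 0.05 * np.abs(imps).mean()

    def test_planted_predictor_ranks_first(self):
        hits = 0
        n_runs = 20
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(40, 8))
            y = 3.0 * X[:, 2] + rng.normal(size=40) * 0.3
            _, ranks = M.rf_rank(X, y, n_trees=80, seed=seed)
            hits += int(ranks[2] == 1)
        assert hits >= int(0.95 * n_runs)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        _, r1 = M.rf_rank(X, y, n_trees=50, seed=11)
        _, r2 = M.rf_rank(X, y, n_trees=50, seed=11)
        assert np.array_equal(r1, r2)

    def test_bad_inputs_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError, match="n_trees"):
            M.rf_fit(X, np.zeros(10), n_trees=0)
        with pytest.raises(ValueError, match="5 samples"):
            M.rf_fit(X[:3], np.zeros(3), n_trees=10)
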