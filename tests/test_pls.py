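"""PLS engine: scaling, NIPALS fits, orthogonalization, VIP."""

import numpy as np
import pandas as pd
import pytest

from cytosig import pls
from cytosig.errors import FitError


def random_instance(rng, n=20, p=8, r=1, signal=True):
    X = rng.normal(size=(n, p))
    if r == 1 and signal:
        y = X @ rng.normal(size=p) + 0.3 * rng.normal(size=n)
    else:
        y = rng.normal(size=n)
    Xs, xm, xsd, _ = pls.autoscale(X)
    Ys, coding = pls.encode_response(y)
    return X, y, Xs, Ys, coding


class TestAutoscale:
    def test_hand_example_n_minus_1(self):
        Xs, mean, sd, _ = pls.autoscale(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(Xs[:, 0], [-1, 0, 1])
        assert mean[0] == 2.0 and sd[0] == 1.0  # sample SD convention

    def test_idempotent(self, rng):
        X = rng.normal(size=(30, 4))
        Xs, *_ = pls.autoscale(X)
        Xs2, *_ = pls.autoscale(Xs)
        np.testing.assert_allclose(Xs, Xs2, atol=1e-12)

    def test_constant_column(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        with pytest.raises(FitError, match="constant"):
            pls.autoscale(X)
        Xs, mean, sd, kept = pls.autoscale(X, drop_constant=True)
        assert Xs.shape[1] == 1 and kept.tolist() == [1]


class TestEncodeResponse:
    def test_dummy_coding(self):
        Ys, coding = pls.encode_response(np.array(["AD", "WT", "AD"]))
        assert coding.classes == ["AD", "WT"]
        raw = coding.encode(np.array(["AD", "WT", "AD"]))
        np.testing.assert_allclose(raw, [[1, 0], [0, 1], [1, 0]])

    def test_numeric_single_column(self):
        Ys, coding = pls.encode_response(np.array([30, 60, 120, 180]))
        assert coding.kind == "numeric" and Ys.shape == (4, 1)
        assert abs(Ys.mean()) < 1e-12

    def test_single_class_errors(self):
        with pytest.raises(FitError):
            pls.encode_response(np.array(["AD", "AD"]))


class TestFitPredict:
    def test_pls1_single_predictor_is_ols(self, rng):
        x = rng.normal(size=25)
        y = 2.0 * x + rng.normal(size=25)
        model = pls.fit_model(x[:, None], y, 1)
        yhat = pls.predict(model, x[:, None])
        beta = np.polyfit(x, y, 1)
        np.testing.assert_allclose(yhat, np.polyval(beta, x), atol=1e-8)

    def test_exact_fit_on_first_principal_direction(self, rng):
        # Y exactly linear in the dominant X direction: 1 LV gives R^2 = 1
        n, p = 40, 6
        t = rng.normal(size=n) * 5
        X = np.outer(t, rng.normal(size=p)) + 0.0
        X += rng.normal(size=(n, p)) * 1e-9
        y = 3.0 + 2.0 * t
        model = pls.fit_model(X, y, 1)
        yhat = pls.predict(model, X)
        assert 1 - np.var(y - yhat) / np.var(y) > 1 - 1e-8

    def test_recovers_beta_with_orthonormal_columns(self, rng):
        # with orthonormal X the first weight vector is exactly beta's
        # direction, so a single component recovers the least-squares fit
        n, p = 30, 5
        Q, _ = np.linalg.qr(rng.normal(size=(n, p)))
        beta = rng.normal(size=p)
        model = pls.fit_pls(Q, (Q @ beta)[:, None], 1)
        np.testing.assert_allclose(model.coef[:, 0], beta, atol=1e-8)

    def test_full_rank_pls_equals_least_squares(self, rng):
        n, p = 30, 5
        X = rng.normal(size=(n, p))
        y = X @ rng.normal(size=p) + rng.normal(size=n)
        model = pls.fit_pls(X, y[:, None], p)
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(model.coef[:, 0], beta, atol=1e-8)

    def test_predict_training_equals_fitted(self, rng):
        X, y, *_ = random_instance(rng)
        model = pls.fit_model(X, y, 2)
        np.testing.assert_allclose(
            pls.predict(model, X), pls.fitted_values(model)[:, 0], atol=1e-10
        )

    def test_all_mean_sample_predicts_mean(self, rng):
        X, y, *_ = random_instance(rng)
        model = pls.fit_model(X, y, 2)
        pred = pls.predict(model, X.mean(axis=0)[None, :])
        assert pred[0] == pytest.approx(y.mean(), abs=1e-8)

    def test_da_argmax_and_tie_break(self, rng):
        X = rng.normal(size=(20, 4))
        labels = np.array(["AD"] * 10 + ["WT"] * 10)
        X[:10] += 2.0
        model = pls.fit_model(X, labels, 1)
        _, pred = pls.predict(model, X)
        assert (pred[:10] == "AD").mean() > 0.8
        # a dead-center sample ties the (symmetric) dummy predictions
        _, tied = pls.predict(model, X.mean(axis=0)[None, :])
        assert tied[0] == "AD"  # first class in sorted order
        assert model.tie_log

    def test_a_too_large_errors(self, rng):
        X, y, *_ = random_instance(rng, n=10, p=4)
        with pytest.raises(FitError):
            pls.fit_model(X, y, 10)

    def test_column_mismatch_errors(self, rng):
        X = pd.DataFrame(rng.normal(size=(15, 3)), columns=list("abc"))
        model = pls.fit_model(X, rng.normal(size=15), 1)
        with pytest.raises(FitError, match="missing predictor"):
            pls.predict(model, X.rename(columns={"a": "zzz"}))

    def test_deterministic_fit(self, rng):
        X, y, *_ = random_instance(rng)
        m1 = pls.fit_model(X, y, 3)
        m2 = pls.fit_model(X, y, 3)
        np.testing.assert_array_equal(m1.coef, m2.coef)

    def test_score_orthogonality_and_reconstruction(self, rng):
        for r_labels in (False, True):
            X = rng.normal(size=(25, 7))
            resp = (
                np.array(["a", "b"])[rng.integers(0, 2, 25)]
                if r_labels else rng.normal(size=25)
            )
            model = pls.fit_model(X, resp, 3)
            T = model.scores
            G = T.T @ T
            off = G - np.diag(np.diag(G))
            assert np.abs(off).max() < 1e-8 * np.abs(np.diag(G)).max()
            # predictions from coef match reconstruction from (T, Q)
            Xs = (X - model.x_mean) / model.x_sd
            np.testing.assert_allclose(
                Xs @ model.coef, T @ model.y_loadings.T, atol=1e-8
            )


class TestAgainstReferenceImplementation:
    def test_matches_sklearn_predictions(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        for a in (1, 2, 3):
            for trial in range(5):
                X = rng.normal(size=(20, 8))
                y = X @ rng.normal(size=8) + rng.normal(size=20)
                model = pls.fit_model(X, y, a)
                ref = sklearn.PLSRegression(n_components=a, scale=True)
                ref.fit(X, y)
                np.testing.assert_allclose(
                    pls.predict(model, X), ref.predict(X).ravel(), atol=1e-6
                )

    def test_scale_equivariance(self, rng):
        X = rng.normal(size=(20, 6)) + 5
        y = X @ rng.normal(size=6)
        m1 = pls.fit_model(X, y, 2)
        X2 = X.copy()
        X2[:, 3] *= 1000.0
        m2 = pls.fit_model(X2, y, 2)
        np.testing.assert_allclose(
            pls.predict(m1, X), pls.predict(m2, X2), atol=1e-8
        )
        np.testing.assert_allclose(
            pls.vip_scores(m1), pls.vip_scores(m2), atol=1e-8
        )


class TestOrthogonalize:
    def test_single_lv_unchanged_predictions(self, rng):
        X, y, *_ = random_instance(rng)
        model = pls.fit_model(X, y, 1)
        om = pls.orthogonalize(model)
        np.testing.assert_allclose(
            pls.predict(model, X), pls.predict(om, X), atol=1e-10
        )

    @pytest.mark.parametrize("a", [2, 3])
    def test_prediction_invariance_and_decorrelation(self, rng, a):
        X, y, *_ = random_instance(rng, n=30, p=10)
        model = pls.fit_model(X, y, a)
        om = pls.orthogonalize(model)
        np.testing.assert_allclose(
            pls.predict(model, X), pls.predict(om, X), atol=1e-8
        )
        yhat = pls.fitted_values(om)[:, 0]
        for k in range(1, a):
            c = np.corrcoef(om.scores[:, k], yhat)[0, 1]
            assert abs(c) < 1e-8

    def test_orientation_positive_response_pole(self, rng):
        X = rng.normal(size=(40, 6))
        y = X[:, 0] * 4 + rng.normal(size=40)
        om = pls.orthogonalize(pls.fit_model(X, y, 2))
        # samples with larger response should score positive on LV1
        assert np.corrcoef(om.scores[:, 0], y)[0, 1] > 0

    def test_da_positive_class_orientation(self, rng):
        X = rng.normal(size=(30, 5))
        labels = np.array(["AD"] * 15 + ["WT"] * 15)
        X[:15, 0] += 3
        om = pls.orthogonalize(
            pls.fit_model(X, labels, 2), positive_class="AD"
        )
        assert om.scores[:15, 0].mean() > om.scores[15:, 0].mean()


class TestVip:
    def test_equal_weights_symmetric(self, rng):
        t = rng.normal(size=30)
        X = np.column_stack([t, t]) + rng.normal(size=(30, 2)) * 1e-9
        y = t.copy()
        model = pls.fit_model(X, y, 1)
        np.testing.assert_allclose(pls.vip_scores(model), [1.0, 1.0], atol=1e-4)

    def test_all_weight_on_one_predictor(self, rng):
        x = rng.normal(size=40)
        X = np.column_stack([x, rng.normal(size=40) * 1e-9])
        # second column is pure tiny noise; after autoscaling it is still
        # uncorrelated with y, so the LV1 weight concentrates on column 1
        y = x.copy()
        model = pls.fit_model(X, y, 1)
        vip = pls.vip_scores(model)
        assert vip[0] == pytest.approx(np.sqrt(2), abs=0.05)
        assert vip[1] == pytest.approx(0.0, abs=0.05)

    @pytest.mark.parametrize("a", [1, 2, 3])
    def test_mean_square_is_one(self, rng, a):
        X, y, *_ = random_instance(rng)
        for model in (pls.fit_model(X, y, a),
                      pls.orthogonalize(pls.fit_model(X, y, a))):
            vip = pls.vip_scores(model)
            assert np.mean(vip**2) == pytest.approx(1.0, abs=1e-8)
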