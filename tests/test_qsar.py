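"""NIPALS PLS QSAR: fitting, validation, outlier pruning, prediction."""
import numpy as np
import pytest

from pepscreen import (
    PlsModel,
    QsarDataset,
    encode_peptides,
    exclude_outliers,
    fit_dataset,
    fit_pls,
    loo_q2,
    predict,
    predict_many,
)
from pepscreen.synthetic import gen_qsar_dataset


def toy_instance(rng, n=5, p=2):
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = 0.5 + X @ beta
    return X, y


class TestFitPls:
    def test_noiseless_full_rank_r2_is_one(self, rng):
        X, y = toy_instance(rng, n=8, p=2)
        model = fit_pls(X, y, n_components=2)
        assert model.r2 == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(model.predict_log_ic50(X), y, atol=1e-10)

    def test_pls_equals_ols_at_full_rank(self, rng):
        # with n_components = rank(X), PLS collapses to least squares
        X, _ = toy_instance(rng, n=5, p=2)
        y = rng.normal(size=5)
        model = fit_pls(X, y, n_components=2)
        ols = np.linalg.lstsq(np.column_stack([np.ones(5), X]), y, rcond=None)[0]
        assert model.intercept == pytest.approx(ols[0], rel=1e-8)
        np.testing.assert_allclose(model.coefficients, ols[1:], rtol=1e-8)

    def test_single_component_matches_closed_form(self, rng):
        # hand oracle: first PLS direction on autoscaled data is
        # w = X'y/||X'y||, t = Xw, b = (t'y)/(t't); B = w·b back-transformed
        X, _ = toy_instance(rng, n=5, p=2)
        y = rng.normal(size=5)
        xm, xs = X.mean(0), X.std(0, ddof=1)
        ym, ys = y.mean(), y.std(ddof=1)
        Xs, ysc = (X - xm) / xs, (y - ym) / ys
        w = Xs.T @ ysc
        w /= np.linalg.norm(w)
        t = Xs @ w
        b = (t @ ysc) / (t @ t)
        expected = ys * (w * b) / xs
        model = fit_pls(X, y, n_components=1)
        np.testing.assert_allclose(model.coefficients, expected, rtol=1e-10)
        assert model.intercept == pytest.approx(ym - xm @ expected, rel=1e-10)

    def test_matches_sklearn_oracle(self):
        # independent cross-check of the two-component fit on synthetic data
        from sklearn.cross_decomposition import PLSRegression
        ds, _ = gen_qsar_dataset(7, n=60, length=6, sigma=0.3)
        X, y = ds.descriptors(), ds.log_ic50
        model = fit_pls(X, y, n_components=2)
        sk = PLSRegression(n_components=2, scale=True).fit(X, y)
        np.testing.assert_allclose(model.predict_log_ic50(X),
                                   sk.predict(X).ravel(), atol=1e-9)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(11)
        beta = rng.normal(0, 0.05, size=30)
        ds, truth = gen_qsar_dataset(11, n=100, length=6, beta=beta, sigma=0.05)
        model = fit_pls(ds.descriptors(), ds.log_ic50, n_components=10)
        cos = (model.coefficients @ beta) / (
            np.linalg.norm(model.coefficients) * np.linalg.norm(beta))
        assert cos > 0.9

    def test_r2_nondecreasing_in_components(self):
        ds, _ = gen_qsar_dataset(3, n=50, length=3, sigma=0.3)
        X, y = ds.descriptors(), ds.log_ic50
        r2s = [fit_pls(X, y, a).r2 for a in range(1, 6)]
        assert np.all(np.diff(r2s) >= -1e-12)

    def test_score_orthogonality(self):
        ds, _ = gen_qsar_dataset(5, n=40, length=6, sigma=0.2)
        model = fit_pls(ds.descriptors(), ds.log_ic50, n_components=4)
        T = model.scores_t
        gram = T.T @ T
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(gram)).max()

    def test_affine_descriptor_rescaling_invariance(self, rng):
        ds, _ = gen_qsar_dataset(9, n=40, length=3, sigma=0.2)
        X, y = ds.descriptors(), ds.log_ic50
        scale = rng.uniform(0.1, 10, size=X.shape[1])
        shift = rng.normal(size=X.shape[1])
        m1 = fit_pls(X, y, 2)
        m2 = fit_pls(X * scale + shift, y, 2)
        Xt = X[:10] * scale + shift
        np.testing.assert_allclose(m1.predict_log_ic50(X[:10]),
                                   m2.predict_log_ic50(Xt), atol=1e-8)

    def test_constant_y_rejected(self, rng):
        X = rng.normal(size=(10, 4))
        with pytest.raises(ValueError, match="constant"):
            fit_pls(X, np.ones(10), 2)

    def test_too_few_samples_rejected(self, rng):
        X = rng.normal(size=(3, 4))
        with pytest.raises(ValueError, match="at least"):
            fit_pls(X, rng.normal(size=3), 2)

    def test_zero_variance_columns_flagged(self, rng):
        X = rng.normal(size=(12, 4))
        X[:, 2] = 7.0
        y = X[:, 0] + rng.normal(size=12)
        model = fit_pls(X, y, 2)
        assert model.zero_variance_columns == (2,)


class TestLooQ2:
    def test_noiseless_q2_near_one(self):
        ds, _ = gen_qsar_dataset(2, n=40, length=3, sigma=0.0)
        X, y = ds.descriptors(), ds.log_ic50
        q2 = loo_q2(X, y, n_components=10)
        assert q2 > 0.95

    def test_pure_noise_q2_typically_nonpositive(self):
        vals = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(15, 10))
            y = rng.normal(size=15)
            vals.append(loo_q2(X, y, 2))
        assert np.mean(vals) < 0

    def test_q2_bounded_by_r2(self):
        for seed in range(5):
            ds, _ = gen_qsar_dataset(seed, n=30, length=3, sigma=0.3)
            X, y = ds.descriptors(), ds.log_ic50
            assert loo_q2(X, y, 2) <= fit_pls(X, y, 2).r2

    def test_two_samples_error(self, rng):
        with pytest.raises(ValueError):
            loo_q2(rng.normal(size=(2, 3)), rng.normal(size=2), 1)


class TestOutlierExclusion:
    def test_clean_data_zero_exclusions(self):
        ds, _ = gen_qsar_dataset(4, n=60, length=6, sigma=0.1)
        model = fit_dataset(ds, 2, with_q2=False)
        pruned, refit = exclude_outliers(model, ds)
        # allow chance flags but a clean generator should barely prune
        assert len(refit.excluded_indices) <= 2
        assert len(pruned) >= len(ds) - 2

    def test_planted_gross_outliers_recovered(self):
        ds, _ = gen_qsar_dataset(6, n=100, length=6, sigma=0.2)
        y = ds.log_ic50
        planted = [5, 40, 77]
        ic50 = ds.ic50_um.copy()
        shift = 10 * y.std(ddof=1)
        for i in planted:  # shift downward to stay under the admission bound
            ic50[i] = 10 ** (y[i] - shift)
        corrupted = QsarDataset(ds.sequences, ic50, ds.length_class)
        model = fit_dataset(corrupted, 2, with_q2=False)
        _, refit = exclude_outliers(model, corrupted)
        assert set(planted) <= set(refit.excluded_indices)

    def test_infinite_threshold_is_identity(self):
        ds, _ = gen_qsar_dataset(8, n=30, length=3, sigma=0.3)
        model = fit_dataset(ds, 2, with_q2=False)
        pruned, refit = exclude_outliers(model, ds, threshold_sd=np.inf)
        assert len(pruned) == len(ds)
        assert refit.excluded_indices == ()

    def test_never_prunes_below_minimum(self):
        ds, _ = gen_qsar_dataset(10, n=10, length=3, sigma=1.0)
        model = fit_dataset(ds, 2, with_q2=False)
        pruned, _ = exclude_outliers(model, ds, threshold_sd=0.1, max_rounds=50)
        assert len(pruned) >= model.n_components + 2


class TestPredict:
    def test_training_peptides_recovered_in_exact_fit_limit(self):
        ds, _ = gen_qsar_dataset(2, n=40, length=3, sigma=0.0)
        model = fit_pls(ds.descriptors(), ds.log_ic50, n_components=15,
                        length_class=3)
        for seq, ic in list(zip(ds.sequences, ds.ic50_um))[:5]:
            assert predict(model, seq).predicted_ic50 == pytest.approx(ic, rel=1e-6)

    def test_zero_coefficients_predict_intercept(self):
        ds, _ = gen_qsar_dataset(2, n=20, length=3, sigma=0.1)
        model = fit_dataset(ds, 2, with_q2=False)
        model.coefficients = np.zeros_like(model.coefficients)
        for seq in ["AAA", "WWW", "KYR"]:
            assert predict(model, seq).predicted_ic50 == \
                pytest.approx(10 ** model.intercept)

    def test_heldout_rmse_tracks_noise(self):
        beta = np.random.default_rng(0).normal(0, 0.04, 30)
        sigma = 0.2
        train, _ = gen_qsar_dataset(20, n=400, length=6, beta=beta, sigma=sigma)
        test, truth = gen_qsar_dataset(21, n=200, length=6, beta=beta, sigma=sigma)
        model = fit_pls(train.descriptors(), train.log_ic50, 10, length_class=6)
        preds = np.array([predict(model, s).predicted_log_ic50
                          for s in test.sequences])
        rmse = np.sqrt(np.mean((preds - test.log_ic50) ** 2))
        assert rmse == pytest.approx(sigma, rel=0.25)

    def test_length_mismatch_directs_to_right_model(self):
        ds, _ = gen_qsar_dataset(2, n=20, length=3, sigma=0.1)
        model = fit_dataset(ds, 2, with_q2=False)
        with pytest.raises(ValueError, match="length 6"):
            predict(model, "AAAAAA")

    def test_predict_many_routes_by_length(self):
        models = {}
        for length, seed in [(3, 1), (6, 2)]:
            ds, _ = gen_qsar_dataset(seed, n=30, length=length, sigma=0.2)
            models[length] = fit_dataset(ds, 2, with_q2=False)
        recs = predict_many(models, ["AAA", "AAAAAA", "AAAAA"])
        assert [r.peptide for r in recs] == ["AAA", "AAAAAA"]


class TestSerialization:
    def test_json_round_trip_bit_reproducible(self, tmp_path):
        ds, _ = gen_qsar_dataset(2, n=30, length=3, sigma=0.2)
        model = fit_dataset(ds, 2)
        path = tmp_path / "model.json"
        model.to_json(path)
        again = PlsModel.from_json(path)
        for seq in ds.sequences[:5]:
            assert predict(again, seq).predicted_ic50 == \
                predict(model, seq).predicted_ic50
        assert again.r2 == model.r2 and again.q2 == model.q2


class TestQsarDataset:
    def test_admission_filter(self):
        ds = QsarDataset.admit(["AAA", "WWW", "KKK"], [10.0, 20_000.0, 5.0], 3)
        assert ds.sequences == ("AAA", "KKK")

    def test_nonpositive_ic50_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            QsarDataset(("AAA",), np.array([-1.0]), 3)

    def test_csv_round_trip(self, tmp_path):
        import pandas as pd
        ds, _ = gen_qsar_dataset(2, n=15, length=3, sigma=0.2)
        f = tmp_path / "train.csv"
        pd.DataFrame({"peptide": ds.sequences,
                      "ic50_uM": ds.ic50_um}).to_csv(f, index=False)
        again = QsarDataset.from_csv(f, 3)
        assert again.sequences == ds.sequences
        np.testing.assert_allclose(again.ic50_um, ds.ic50_um)
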