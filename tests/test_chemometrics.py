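"""Linear and PLS modelling of pigment content from colour parameters."""

import numpy as np
import pytest

from carotlab.chemometrics import (
    PLSColourRegressor,
    build_report_tables,
    compare_to_reference,
    cross_validate,
    fit_multiple_linear,
    fit_pls,
    fit_single_linear,
    load_reference_models,
    report_pls,
)
from carotlab.synthetic import default_design, generate_truth


def ols_coefficients(X, y):
    """Independent oracle: normal-equations least squares with intercept."""
    A = np.column_stack([np.ones(len(X)), X])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return beta[0], beta[1:]


class TestSingleLinear:
    def test_exact_line(self):
        x = np.arange(10.0)
        rep = fit_single_linear(x, 2 * x)
        assert rep.r2 == pytest.approx(1.0)
        assert rep.coefficients["x"] == pytest.approx(2.0)

    def test_constant_response(self):
        rep = fit_single_linear(np.arange(5.0), np.full(5, 3.0))
        assert rep.r2 == 0.0

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            fit_single_linear(np.ones(5), np.arange(5.0))

    def test_type_one_error_rate(self):
        # independent x and y: slope p-value should be uniform
        rng = np.random.default_rng(42)
        n, reps, alpha = 1000, 500, 0.05
        rejections = 0
        for _ in range(reps):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            if fit_single_linear(x, y).p_value < alpha:
                rejections += 1
        assert 0.03 <= rejections / reps <= 0.07


class TestMultipleLinear:
    def test_orthonormal_design_recovers_coefficients(self):
        q, _ = np.linalg.qr(np.random.default_rng(0).normal(size=(40, 5)))
        beta = np.array([1.0, -2.0, 0.5, 3.0, -1.5])
        # the model standardises X; build y from the standardised design
        sd = q.std(axis=0, ddof=1)
        qz = (q - q.mean(axis=0)) / sd
        y = qz @ beta
        rep = fit_multiple_linear(q, y)
        got = np.array([rep.coefficients[c] for c in
                        ("L_star", "a_star", "b_star", "C_star", "h_deg")])
        assert np.allclose(got, beta, atol=1e-8)
        assert rep.r2 == pytest.approx(1.0)

    def test_duplicated_column_named_in_error(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 5))
        X[:, 3] = X[:, 1]  # C_star duplicates a_star
        with pytest.raises(np.linalg.LinAlgError, match="a_star.*C_star"):
            fit_multiple_linear(X, rng.normal(size=30))

    def test_recovers_generative_r2_on_synthetic_study(self):
        # average calibration R^2 over seeds should sit near the generative
        # signal fraction var(link) / (var(link) + sigma^2)
        r2_obs, r2_gen = [], []
        for seed in range(15):
            truth = generate_truth(default_design(seed=seed))
            X = truth[["L_true", "a_true", "b_true", "C_true", "h_true"]].to_numpy()
            y = truth["tcc"].to_numpy()
            rep = fit_multiple_linear(X, y)
            r2_obs.append(rep.r2_ss)
            sigma2 = 2.2**2
            link_var = np.var(y) - sigma2
            r2_gen.append(link_var / (link_var + sigma2))
        assert abs(np.mean(r2_obs) - np.mean(r2_gen)) < 0.05


class TestPLS:
    def test_full_rank_pls_equals_ols(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            X = rng.normal(size=(30, 5))
            y = rng.normal(size=30)
            model = fit_pls(X, y, n_components=5)
            icpt, beta = ols_coefficients(X, y)
            assert np.abs(model.coef_ - beta).max() < 1e-8
            assert model.intercept_ == pytest.approx(icpt, abs=1e-8)

    def test_matches_sklearn_pls_at_reduced_rank(self):
        # independent cross-check of the NIPALS sequence itself
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 5))
        y = X @ np.array([1.0, 0.5, -0.2, 0.0, 2.0]) + rng.normal(0, 0.5, 40)
        for k in (1, 2, 3):
            ours = fit_pls(X, y, n_components=k)
            ref = PLSRegression(n_components=k, scale=True).fit(X, y.reshape(-1, 1))
            assert np.abs(ours.coef_ - ref.coef_.ravel()).max() < 1e-8

    def test_single_relevant_predictor_concentrates_first_weight(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(5000, 5))
        y = 3.0 * X[:, 2]
        model = fit_pls(X, y, n_components=1)
        w = model.x_weights_[:, 0]
        assert abs(w[2]) > 0.99
        # oracle: the covariance-maximising direction is X_s' y_s normalised
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        ys = (y - y.mean()) / y.std(ddof=1)
        w_oracle = Xs.T @ ys
        w_oracle /= np.linalg.norm(w_oracle)
        assert np.allclose(np.abs(w), np.abs(w_oracle), atol=1e-12)

    def test_latent_and_coefficient_paths_agree(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            X = rng.normal(size=(30, 5))
            y = rng.normal(size=30)
            model = fit_pls(X, y, n_components=5)
            Xnew = rng.normal(size=(10, 5))
            assert np.abs(model.predict(Xnew) - model.predict_via_scores(Xnew)).max() < 1e-9

    def test_too_many_components_rejected(self):
        X = np.random.default_rng(0).normal(size=(30, 5))
        with pytest.raises(ValueError, match="exceeds"):
            fit_pls(X, X[:, 0], n_components=6)

    def test_constant_column_rejected(self):
        X = np.random.default_rng(0).normal(size=(30, 5))
        X[:, 4] = 1.0
        with pytest.raises(ValueError, match="constant"):
            fit_pls(X, X[:, 0])

    def test_fit_invariant_to_row_permutation(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(50, 5))
        y = rng.normal(size=50)
        perm = rng.permutation(50)
        a = fit_pls(X, y)
        b = fit_pls(X[perm], y[perm])
        assert np.allclose(a.coef_, b.coef_) and a.intercept_ == pytest.approx(b.intercept_)

    def test_serialisation_round_trip(self):
        rng = np.random.default_rng(13)
        X, y = rng.normal(size=(30, 5)), rng.normal(size=30)
        model = fit_pls(X, y)
        clone = PLSColourRegressor.from_dict(model.to_dict())
        assert np.allclose(clone.predict(X), model.predict(X))


class TestCrossValidation:
    def test_segment_sizes_near_equal(self):
        rng = np.random.default_rng(2)
        X, y = rng.normal(size=(96, 5)), rng.normal(size=96)
        cv = cross_validate(X, y, n_segments=10, seed=0)
        sizes = np.bincount(cv.fold_assignments)
        assert sizes.sum() == 96 and set(sizes) <= {9, 10}

    def test_noiseless_linear_response(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 5))
        y = X @ np.array([1.0, -1.0, 0.5, 2.0, 0.3]) + 4.0
        cv = cross_validate(X, y, n_segments=10, seed=1)
        assert cv.rmsep < 1e-8

    def test_rmsep_recovers_generative_noise_sd(self):
        sigma = 2.2  # the study's total-carotenoid noise SD
        ratios = []
        for seed in range(20):
            truth = generate_truth(default_design(seed=100 + seed))
            X = truth[["L_true", "a_true", "b_true", "C_true", "h_true"]].to_numpy()
            y = truth["tcc"].to_numpy()
            cv = cross_validate(X, y, n_segments=10, seed=seed)
            ratios.append(cv.rmsep / sigma)
        assert 0.8 <= np.mean(ratios) <= 1.2

    def test_rmsep_usually_exceeds_calibration_rmse(self):
        above = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            X = rng.normal(size=(50, 5))
            y = X @ rng.normal(size=5) + rng.normal(0, 1.0, 50)
            rep, _ = report_pls(X, y, seed=seed)
            above += rep.rmsep >= rep.rmse_cal
        assert above > 10  # majority direction on noisy data

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="segments"):
            cross_validate(np.zeros((5, 5)), np.zeros(5), n_segments=10)

    def test_range_relative_rmsep_flag(self):
        rng = np.random.default_rng(77)
        X = rng.normal(size=(40, 5))
        y = X @ rng.normal(size=5) + rng.normal(0, 1.0, 40) + 10.0
        by_mean = cross_validate(X, y, seed=0)
        by_range = cross_validate(X, y, seed=0, relative_to="range")
        assert by_mean.rmsep == by_range.rmsep
        assert by_range.rmsep_pct == pytest.approx(
            100.0 * by_range.rmsep / (y.max() - y.min())
        )
        with pytest.raises(ValueError, match="relative_to"):
            cross_validate(X, y, seed=0, relative_to="median")


class TestReferenceComparison:
    def test_reference_against_itself(self):
        ref = load_reference_models()
        coef = ref["models"]["eq8"]["coefficients"]
        out = compare_to_reference(coef, "eq8")
        assert all(abs(d) < 1e-12 for d in out["deltas"].values())
        assert out["cosine_similarity"] == pytest.approx(1.0)
        assert out["sign_agreement"] == 1.0

    def test_two_printed_tcc_versions_differ(self):
        # the WF0 total-carotenoid model is printed twice with different
        # coefficients; the comparison must surface non-zero deltas
        ref = load_reference_models()
        out = compare_to_reference(ref["models"]["eq9"]["coefficients"], "table3:tcc")
        assert any(abs(d) > 0.5 for d in out["deltas"].values())

    def test_sign_agreement_bounded(self):
        rng = np.random.default_rng(21)
        out = compare_to_reference(rng.normal(size=5), "eq8")
        assert 0.0 <= out["sign_agreement"] <= 1.0

    def test_unknown_key_rejected(self):
        with pytest.raises(KeyError, match="unknown reference"):
            compare_to_reference(np.ones(5), "eq99")


class TestReportTables:
    def test_grid_shape_from_pls_reports(self):
        rng = np.random.default_rng(31)
        reports = []
        for pig in ("tcc", "tac"):
            for cond in ("WF-1", "WF0", "WF+1", "PF0", "PF+1", "PF+2"):
                X, y = rng.normal(size=(40, 5)), rng.normal(size=40)
                rep, _ = report_pls(X, y, pigment=pig, light_condition=cond, seed=0)
                reports.append(rep)
        tables = build_report_tables(reports)
        grid = tables["pls_by_condition"]
        assert len(grid) == 12
        assert grid["r2"].between(0, 1).all()

    def test_empty_input_gives_header_only(self):
        tables = build_report_tables([])
        for df in tables.values():
            assert df.empty and len(df.columns) > 0
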