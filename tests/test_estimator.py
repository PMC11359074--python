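"""PCA + score-regression estimator: fitting, prediction, LOOCV."""

import dataclasses

import numpy as np
import pytest
from sklearn.decomposition import PCA as SklearnPCA
from sklearn.linear_model import LinearRegression

from gaitpcr import layout
from gaitpcr.estimator import (
    CohortMatrices,
    assemble_matrices,
    fit_estimation_model,
    fit_pca,
    fit_score_regressions,
    load_model,
    pca_project,
    pca_reconstruct,
    predict_waveforms,
    run_loocv,
    save_model,
)
from gaitpcr.evaluation import evaluate_loocv
from gaitpcr.misalignment import default_conditions
from gaitpcr.synthetic import CohortSpec, SubjectWaveforms, generate_cohort


class TestAssembleMatrices:
    def test_matrix_layout(self, small_cohort):
        m = assemble_matrices(small_cohort.subjects)
        n = len(small_cohort.subjects)
        assert m.X.shape == (n, 303)
        assert m.Y.shape == (n, 2121)
        # column blocks: axis-major input, variable-major output
        subj = small_cohort.subjects[0]
        np.testing.assert_array_equal(
            m.X[0, layout.axis_slice("y")], subj.accel_pelvis_frame[1]
        )
        np.testing.assert_array_equal(
            m.Y[0, layout.variable_slice("hip_sagittal_moment")],
            subj.outputs[layout.OUTPUT_VARIABLES.index("hip_sagittal_moment")],
        )

    def test_angle_and_moment_column_split(self):
        assert layout.N_ANGLE_COLUMNS == 1212
        assert layout.N_MOMENT_COLUMNS == 909
        assert layout.N_ANGLE_COLUMNS + layout.N_MOMENT_COLUMNS == 2121

    def test_single_zero_subject_gives_zero_rows(self):
        subj = SubjectWaveforms("S0", np.zeros((3, 101)), np.zeros((21, 101)))
        m = assemble_matrices([subj])
        assert m.X.shape == (1, 303) and not m.X.any()
        assert m.Y.shape == (1, 2121) and not m.Y.any()

    def test_non_finite_waveforms_named_in_error(self, small_cohort):
        bad = SubjectWaveforms("SBAD", np.full((3, 101), np.nan),
                               np.zeros((21, 101)))
        with pytest.raises(ValueError, match="SBAD"):
            assemble_matrices(small_cohort.subjects[:2] + [bad])


class TestFitPCA:
    def test_rank_one_matrix_selects_single_component(self, rng):
        base = rng.normal(size=10)
        M = np.outer(rng.normal(size=8), base)
        model = fit_pca(M, ccr_threshold=0.90)
        assert model.n_components == 1
        assert model.ccr == pytest.approx(1.0)

    def test_full_ccr_reconstruction_lossless(self, rng):
        M = rng.normal(size=(12, 30))
        model = fit_pca(M, ccr_threshold=1.0)
        recon = pca_reconstruct(model, pca_project(model, M))
        np.testing.assert_allclose(recon, M, atol=1e-8)

    def test_component_count_matches_population_spectrum_oracle(self):
        # oracle: eigenvalues of the generator's noiseless population
        # covariance A diag(v) A^T, computed from the known link model
        spec = CohortSpec(n_subjects=150, accel_noise_sd=0.0,
                          output_noise_sd=0.0, seed=31)
        cohort = generate_cohort(spec)
        lm = cohort.link_model
        A = np.vstack([
            lm.input_basis @ lm.input_loadings[a] for a in range(3)
        ])  # (303, k)
        G = (A * lm.latent_variances) @ A.T
        eig = np.sort(np.linalg.eigvalsh(G))[::-1]
        ccr = np.cumsum(eig) / eig.sum()
        m_oracle = int(np.searchsorted(ccr, 0.90 - 1e-12) + 1)

        M = assemble_matrices(cohort.subjects).X
        model = fit_pca(M, ccr_threshold=0.90)
        assert abs(model.n_components - m_oracle) <= 1
        assert model.ccr >= 0.90

    def test_loadings_orthonormal_and_variances_descending(self, small_cohort):
        M = assemble_matrices(small_cohort.subjects).Y
        model = fit_pca(M, 0.90)
        np.testing.assert_allclose(
            model.loadings @ model.loadings.T,
            np.eye(model.n_components), atol=1e-8,
        )
        assert np.all(np.diff(model.explained_variances) <= 1e-12)
        # deterministic sign: largest-magnitude entry of each row positive
        for row in model.loadings:
            assert row[np.argmax(np.abs(row))] > 0

    def test_ccr_selection_monotone_in_threshold(self, small_cohort):
        M = assemble_matrices(small_cohort.subjects).X
        counts = [fit_pca(M, th).n_components
                  for th in (0.5, 0.7, 0.8, 0.9, 0.95, 0.99, 1.0)]
        assert counts == sorted(counts)

    def test_matches_sklearn_subspace_and_spectrum(self, rng):
        M = rng.normal(size=(25, 40))
        model = fit_pca(M, 0.90)
        sk = SklearnPCA(n_components=model.n_components).fit(M)
        np.testing.assert_allclose(model.explained_variances,
                                   sk.explained_variance_, rtol=1e-10)
        # same subspace: components agree up to sign
        dots = np.abs(np.sum(model.loadings * sk.components_, axis=1))
        np.testing.assert_allclose(dots, 1.0, atol=1e-8)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fit_pca(np.ones((5, 4)))


class TestProjectReconstruct:
    def test_column_means_project_to_zero_scores(self, rng):
        model = fit_pca(rng.normal(size=(10, 6)), 0.9)
        np.testing.assert_allclose(pca_project(model, model.column_means),
                                   0.0, atol=1e-10)

    def test_zero_scores_reconstruct_to_column_means(self, rng):
        model = fit_pca(rng.normal(size=(10, 6)), 0.9)
        np.testing.assert_allclose(
            pca_reconstruct(model, np.zeros(model.n_components)),
            model.column_means, atol=1e-12,
        )

    def test_two_row_toy_matrix_scores(self):
        # rows (0,0,0) and (2,2,2): one component along (1,1,1)/sqrt(3),
        # centered rows are -/+ (1,1,1), so the scores are -/+ sqrt(3)
        M = np.array([[0.0, 0.0, 0.0], [2.0, 2.0, 2.0]])
        model = fit_pca(M, 0.90)
        assert model.n_components == 1
        scores = pca_project(model, M)[:, 0]
        np.testing.assert_allclose(scores, [-np.sqrt(3), np.sqrt(3)],
                                   atol=1e-12)

    def test_reconstruction_is_least_squares_projection(self, rng):
        # reconstruct(project(x)) minimizes ||x - (mean + L^T s)|| over s
        model = fit_pca(rng.normal(size=(15, 8)), 0.8)
        for _ in range(5):
            x = rng.normal(size=8)
            recon = pca_reconstruct(model, pca_project(model, x))
            s_opt, *_ = np.linalg.lstsq(model.loadings.T,
                                        x - model.column_means, rcond=None)
            oracle = model.column_means + model.loadings.T @ s_opt
            np.testing.assert_allclose(recon, oracle, atol=1e-9)

    def test_length_mismatch_rejected(self, rng):
        model = fit_pca(rng.normal(size=(10, 6)), 0.9)
        with pytest.raises(ValueError):
            pca_project(model, np.zeros(5))
        with pytest.raises(ValueError):
            pca_reconstruct(model, np.zeros(model.n_components + 1))


class TestScoreRegressions:
    def test_exact_linear_map_reproduced(self, rng):
        S_in = rng.normal(size=(30, 4))
        B = rng.normal(size=(3, 4))
        S_out = S_in @ B.T + np.array([1.0, -2.0, 0.5])
        reg = fit_score_regressions(S_in, S_out)
        np.testing.assert_allclose(reg.predict(S_in), S_out, atol=1e-8)
        np.testing.assert_allclose(reg.coefficients, B, atol=1e-8)

    def test_single_score_slope_and_intercept(self, rng):
        S_in = rng.normal(size=(50, 1))
        S_out = 2.0 * S_in + 1.0
        reg = fit_score_regressions(S_in, S_out)
        assert reg.coefficients[0, 0] == pytest.approx(2.0)
        assert reg.intercepts[0] == pytest.approx(1.0)

    def test_independent_noise_coefficients_shrink(self, rng):
        # OLS consistency: pure-noise outputs give near-zero coefficients
        S_in = rng.standard_normal((10000, 3))
        S_out = rng.standard_normal((10000, 2))
        reg = fit_score_regressions(S_in, S_out)
        assert np.max(np.abs(reg.coefficients)) < 0.1

    def test_residuals_orthogonal_to_predictors(self, rng):
        S_in = rng.normal(size=(40, 5))
        S_out = rng.normal(size=(40, 3))
        reg = fit_score_regressions(S_in, S_out)
        resid = S_out - reg.predict(S_in)
        np.testing.assert_allclose(S_in.T @ resid, 0.0, atol=1e-6)

    def test_matches_sklearn_ols(self, rng):
        S_in = rng.normal(size=(40, 5))
        S_out = rng.normal(size=(40, 3))
        reg = fit_score_regressions(S_in, S_out)
        sk = LinearRegression().fit(S_in, S_out)
        np.testing.assert_allclose(reg.coefficients, sk.coef_, atol=1e-10)
        np.testing.assert_allclose(reg.intercepts, sk.intercept_, atol=1e-10)

    def test_underdetermined_rejected(self, rng):
        with pytest.raises(ValueError, match="underdetermined"):
            fit_score_regressions(rng.normal(size=(5, 4)),
                                  rng.normal(size=(5, 2)))


class TestPredictWaveforms:
    def test_output_has_full_waveform_length(self, small_cohort):
        m = assemble_matrices(small_cohort.subjects)
        model = fit_estimation_model(m)
        out = predict_waveforms(model, m.X[0])
        assert out.shape == (2121,)

    def test_mean_input_predicts_intercept_reconstruction(self, small_cohort):
        m = assemble_matrices(small_cohort.subjects)
        model = fit_estimation_model(m)
        out = predict_waveforms(model, model.input_pca.column_means)
        expected = pca_reconstruct(model.output_pca,
                                   model.regressions.intercepts)
        np.testing.assert_allclose(out, expected, atol=1e-9)

    def test_noiseless_cohort_training_rows_predicted_exactly(
        self, noiseless_cohort
    ):
        # with full-rank PCA the linear chain is correctly specified and
        # reproduces every training subject's outputs
        m = assemble_matrices(noiseless_cohort.subjects)
        model = fit_estimation_model(m, ccr_threshold=1.0)
        for i in (0, 7, 23):
            pred = predict_waveforms(model, m.X[i])
            np.testing.assert_allclose(pred, m.Y[i],
                                       rtol=1e-6, atol=1e-6)


class TestLOOCV:
    def test_each_fold_trains_on_all_but_one_subject(self, small_cohort):
        res = run_loocv(small_cohort.subjects[:12])
        assert res.n_training_rows == 11
        assert set(res.predictions) == {"M20", "M10", "ZERO", "P10", "P20"}

    def test_matches_manually_fitted_fold(self, small_cohort):
        subjects = small_cohort.subjects[:15]
        res = run_loocv(subjects)
        m = assemble_matrices(subjects[1:])
        model = fit_estimation_model(m, 0.90)
        pred = predict_waveforms(model, subjects[0].accel_pelvis_frame.reshape(-1))
        np.testing.assert_allclose(res.predictions["ZERO"][0], pred,
                                   atol=1e-10)

    def test_held_out_outputs_never_leak_into_own_prediction(self, small_cohort):
        subjects = list(small_cohort.subjects[:15])
        res_a = run_loocv(subjects)
        tampered = SubjectWaveforms(
            subjects[0].subject_id,
            subjects[0].accel_pelvis_frame,
            subjects[0].outputs + 1e6,
        )
        res_b = run_loocv([tampered] + subjects[1:])
        for label in res_a.predictions:
            np.testing.assert_allclose(res_b.predictions[label][0],
                                       res_a.predictions[label][0], atol=1e-8)

    def test_noiseless_zero_condition_recovery(self, noiseless_cohort):
        res = run_loocv(noiseless_cohort.subjects,
                        conditions=default_conditions()[:3])
        records = evaluate_loocv(res)
        zero = records[records.condition == "ZERO"]
        assert zero.nrmse.mean() < 5.0

    def test_frozen_component_mode_uses_constant_counts(self, small_cohort):
        res = run_loocv(small_cohort.subjects[:15], component_mode="frozen")
        assert len(set(res.fold_components_in.tolist())) == 1
        assert len(set(res.fold_components_out.tolist())) == 1

    def test_too_small_cohort_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="too small"):
            run_loocv(small_cohort.subjects[:3])


class TestSerialization:
    def test_round_trip_preserves_predictions(self, tmp_path, small_cohort):
        m = assemble_matrices(small_cohort.subjects)
        model = fit_estimation_model(m)
        save_model(model, tmp_path / "bundle")
        loaded = load_model(tmp_path / "bundle")
        for i in (0, 5):
            np.testing.assert_allclose(
                predict_waveforms(loaded, m.X[i]),
                predict_waveforms(model, m.X[i]), atol=1e-10,
            )
        assert loaded.training_subject_ids == model.training_subject_ids

    def test_foreign_directory_rejected(self, tmp_path):
        (tmp_path / "manifest.json").write_text("{}")
        with pytest.raises(ValueError):
            load_model(tmp_path)
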