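import numpy as np
import pytest

import chemocal as cc
from chemocal.models import NIPALS_TOL


class TestCLS:
    def test_one_component_exact_proportionality(self):
        C = np.array([[1.0], [2.0]])
        A = np.array([[0.1, 0.2], [0.2, 0.4]])
        m = cc.fit_cls(C, A)
        assert np.allclose(m.internals["K"], [[0.1, 0.2]])
        assert cc.predict(m, np.array([[0.3, 0.6]]))[0, 0] == pytest.approx(3.0)

    def test_noiseless_calibration_is_exact(self, calibration_blocks, grid):
        C, A = calibration_blocks
        m = cc.fit_cls(C, A, wavelengths=grid.wavelengths)
        assert np.abs(cc.predict(m, A) - C).max() <= 1e-8

    def test_duplicate_columns_raise_singular_design(self):
        C = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        A = np.random.default_rng(0).normal(size=(3, 5))
        with pytest.raises(cc.SingularDesignError, match="comp"):
            cc.fit_cls(C, A)

    def test_k_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        C = rng.uniform(1, 10, size=(5, 2))
        A = rng.normal(size=(5, 4))
        m = cc.fit_cls(C, A)
        oracle = np.linalg.inv(C.T @ C) @ C.T @ A  # brute-force normal equations
        assert np.allclose(m.internals["K"], oracle, atol=1e-12)

    def test_zero_spectrum_predicts_zero(self, calibration_blocks):
        C, A = calibration_blocks
        m = cc.fit_cls(C, A)
        assert np.allclose(cc.predict(m, np.zeros((1, A.shape[1]))), 0.0)

    def test_intercept_absorbs_constant_background(self, calibration_blocks):
        C, A = calibration_blocks
        m = cc.fit_cls(C, A + 0.05, intercept=True)
        assert np.abs(cc.predict(m, A + 0.05) - C).max() <= 1e-8


class TestPCR:
    def test_rank2_matches_cls_on_noiseless_data(self, calibration_blocks):
        C, A = calibration_blocks
        pred_pcr = cc.predict(cc.fit_pcr(C, A, 2), A)
        pred_cls = cc.predict(cc.fit_cls(C, A), A)
        assert np.abs(pred_pcr - pred_cls).max() <= 1e-8

    def test_full_rank_equals_minimum_norm_least_squares(self, noisy_blocks):
        C, A, _, _ = noisy_blocks
        n = A.shape[0]
        m = cc.fit_pcr(C, A, n - 1)
        Ac = A - A.mean(axis=0)
        Cc = C - C.mean(axis=0)
        B_oracle = np.linalg.pinv(Ac) @ Cc  # brute-force pseudoinverse
        assert np.abs(m.B - B_oracle).max() <= 1e-10

    @pytest.mark.parametrize("k", [0, -1, 13, 200])
    def test_out_of_range_n_latent_rejected(self, noisy_blocks, k):
        C, A, _, _ = noisy_blocks
        with pytest.raises(ValueError):
            cc.fit_pcr(C, A, k)

    def test_matches_sklearn_pca_regression(self, noisy_blocks):
        """Independent cross-check of the PCR coefficients against sklearn."""
        sklearn = pytest.importorskip("sklearn")
        from sklearn.decomposition import PCA
        from sklearn.linear_model import LinearRegression

        C, A, _, Aval = noisy_blocks
        k = 3
        ours = cc.fit_pcr(C, A, k)
        pca = PCA(n_components=k).fit(A)
        reg = LinearRegression().fit(pca.transform(A), C)
        pred_oracle = reg.predict(pca.transform(Aval))
        assert np.abs(cc.predict(ours, Aval) - pred_oracle).max() <= 1e-8


class TestPLS:
    def test_single_component_one_lv_matches_closed_form(self, clean_spectra, design):
        cal = [i for i, r in enumerate(design.role) if r == "calibration"]
        c = design.conc[cal][:, :1]
        A = clean_spectra.absorbance[cal]
        m = cc.fit_pls(c, A, 1)
        # closed form: univariate regression of centered c on the first score
        Ac = A - A.mean(axis=0)
        cc_ = c - c.mean(axis=0)
        w = Ac.T @ cc_[:, 0]
        w /= np.linalg.norm(w)
        t = Ac @ w
        beta = (t @ cc_[:, 0]) / (t @ t)
        pred_oracle = c.mean() + (Ac @ w) * beta
        assert np.abs(cc.predict(m, A)[:, 0] - pred_oracle).max() <= 1e-8

    def test_noiseless_two_lv_recovers_100_percent(self, calibration_blocks):
        C, A = calibration_blocks
        pred = cc.predict(cc.fit_pls(C, A, 2), A)
        assert np.allclose(100 * pred / C, 100.0, atol=1e-6)

    def test_n_latent_above_limit_rejected(self, calibration_blocks):
        C, A = calibration_blocks
        with pytest.raises(ValueError):
            cc.fit_pls(C, A, 13)

    def test_matches_sklearn_pls2(self, noisy_blocks):
        """Independent cross-check against sklearn's NIPALS PLS2."""
        sklearn = pytest.importorskip("sklearn")
        from sklearn.cross_decomposition import PLSRegression

        C, A, _, Aval = noisy_blocks
        k = 3
        ours = cc.fit_pls(C, A, k)
        oracle = PLSRegression(n_components=k, scale=False, tol=NIPALS_TOL,
                               max_iter=500).fit(A, C)
        assert np.abs(cc.predict(ours, Aval) - oracle.predict(Aval)).max() <= 1e-6

    def test_pls_converges_to_pcr_at_full_rank(self, noisy_blocks):
        C, A, _, Aval = noisy_blocks
        k = A.shape[0] - 1
        p1 = cc.predict(cc.fit_pcr(C, A, k), Aval)
        p2 = cc.predict(cc.fit_pls(C, A, k), Aval)
        assert np.abs(p1 - p2).max() <= 1e-6


class TestPredictContract:
    @pytest.mark.parametrize("fit", [
        lambda C, A: cc.fit_pcr(C, A, 2),
        lambda C, A: cc.fit_pls(C, A, 2),
    ])
    def test_mean_spectrum_predicts_mean_concentration(self, noisy_blocks, fit):
        C, A, _, _ = noisy_blocks
        m = fit(C, A)
        pred = cc.predict(m, A.mean(axis=0, keepdims=True))
        assert np.allclose(pred[0], C.mean(axis=0), atol=1e-10)

    def test_batch_equals_per_sample(self, noisy_blocks):
        C, A, _, Aval = noisy_blocks
        m = cc.fit_pls(C, A, 2)
        batch = cc.predict(m, Aval)
        rows = np.vstack([cc.predict(m, Aval[i:i + 1]) for i in range(Aval.shape[0])])
        # BLAS may take different kernels for matrix vs single-row products
        assert np.allclose(batch, rows, rtol=0, atol=1e-12)

    def test_grid_mismatch_reports_wavelengths(self, noisy_blocks, grid):
        C, A, _, _ = noisy_blocks
        m = cc.fit_pls(C, A, 2, wavelengths=grid.wavelengths)
        other = cc.SpectraSet(grid=cc.WavelengthGrid(grid.wavelengths[:-10]),
                              absorbance=A[:, :-10])
        with pytest.raises(cc.GridMismatchError, match="missing"):
            cc.predict(m, other)

    def test_model_json_round_trip(self, tmp_path, noisy_blocks, grid):
        C, A, _, Aval = noisy_blocks
        m = cc.fit_pls(C, A, 2, wavelengths=grid.wavelengths,
                       component_names=["fv", "rv"])
        path = tmp_path / "model.json"
        cc.save_model(m, path)
        back = cc.load_model(path)
        assert back.method == "pls" and back.n_latent == 2
        assert back.component_names == ["fv", "rv"]
        assert np.array_equal(back.B, m.B)
        assert np.array_equal(
            cc.predict(back, Aval), cc.predict(m, Aval))


def test_rmsep_does_not_improve_with_more_noise(design, grid, cal_val_indices):
    """Mean RMSEP over replicates is monotone in the noise SD (stress test)."""
    cal, val = cal_val_indices
    C, Cval = design.conc[cal], design.conc[val]
    means = []
    for sd in (0.001, 0.002, 0.004):
        rmseps = []
        for rep in range(200):
            noise = cc.NoiseModel(seed=1000 + rep, noise_sd=sd)
            s = cc.simulate_mixtures(design, cc.DEFAULT_COMPONENTS, noise, grid)
            m = cc.fit_pls(C, s.absorbance[cal], 2)
            resid = cc.predict(m, s.absorbance[val]) - Cval
            rmseps.append(np.sqrt((resid**2).mean()))
        means.append(np.mean(rmseps))
    assert means[0] < means[1] < means[2]
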