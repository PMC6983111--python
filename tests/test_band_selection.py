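"""Unfolding, PCA against a dense eigendecomposition oracle, waveband
selection, and the from-scratch one-way ANOVA."""

import numpy as np
import pytest
from scipy import stats

from ghsw.band_selection import (
    PCAModel,
    band_anova,
    band_ranking,
    fit_pca,
    refold_scores,
    select_wavebands,
    unfold,
)
from ghsw.hypercube_io import SampleMask

from conftest import make_cube, matrix_from_array


def eig_oracle(x: np.ndarray):
    """Independent dense covariance eigendecomposition (descending)."""
    xc = x - x.mean(axis=0)
    cov = xc.T @ xc / (x.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    return evals[order], evecs[:, order]


def model_from_loading(loading, wavelengths=None):
    """Minimal PCAModel carrying one loading column, for selection tests."""
    loading = np.asarray(loading, float)
    if wavelengths is None:
        wavelengths = np.linspace(900.0, 1700.0, len(loading))
    return PCAModel(
        loadings=loading[:, None],
        scores=np.zeros((2, 1)),
        explained_variance_fraction=np.array([1.0]),
        mean_spectrum=np.zeros(len(loading)),
        wavelengths=np.asarray(wavelengths, float),
    )


class TestUnfold:
    def test_row_major_ordering(self):
        vals = np.arange(12, dtype=float).reshape(2, 2, 3)
        cube = make_cube(vals)
        mask = SampleMask(mask=np.ones((2, 2), dtype=bool))
        m = unfold([(cube, mask)])
        assert m.rows.shape == (4, 3)
        np.testing.assert_array_equal(m.rows[0], vals[0, 0])
        assert m.index[0] == (0, 0, 0)
        assert m.index[1] == (0, 0, 1)

    def test_mask_excludes_pixels(self):
        cube = make_cube(np.zeros((2, 2, 3)))
        mask = np.ones((2, 2), dtype=bool)
        mask[1, 1] = False
        m = unfold([(cube, SampleMask(mask=mask))])
        assert m.rows.shape[0] == 3

    def test_unfold_refold_round_trip(self):
        rng = np.random.default_rng(4)
        vals = rng.random((3, 4, 5))
        cube = make_cube(vals)
        mask = rng.random((3, 4)) > 0.3
        m = unfold([(cube, SampleMask(mask=mask), "s")])
        rebuilt = np.full((3, 4, 5), np.nan)
        for i, (_, r, c) in enumerate(m.index):
            rebuilt[r, c] = m.rows[i]
        np.testing.assert_array_equal(rebuilt[mask], vals[mask])

    def test_wavelength_mismatch_names_sample(self):
        a = make_cube(np.zeros((2, 2, 3)))
        b = make_cube(np.zeros((2, 2, 3)), wavelengths=[1, 2, 3])
        mask = SampleMask(mask=np.ones((2, 2), dtype=bool))
        with pytest.raises(ValueError, match="bad_sample"):
            unfold([(a, mask, "ok"), (b, mask, "bad_sample")])


class TestFitPCA:
    def test_rank_one_matrix_concentrates_variance(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        x = np.outer([1.0, 2.0, 3.0, 0.5, -1.0, 2.5], v)
        model = fit_pca(matrix_from_array(x), 2)
        assert model.explained_variance_fraction[0] == pytest.approx(1.0, abs=1e-10)

    def test_matches_dense_eigendecomposition(self):
        rng = np.random.default_rng(20)
        x = rng.random((6, 4))
        model = fit_pca(matrix_from_array(x), 4)
        evals, evecs = eig_oracle(x)
        total = evals.sum()
        np.testing.assert_allclose(
            model.explained_variance_fraction * total, evals, atol=1e-8
        )
        np.testing.assert_allclose(np.abs(model.loadings), np.abs(evecs), atol=1e-8)

    def test_band_permutation_equivariance(self):
        rng = np.random.default_rng(8)
        x = rng.random((20, 5))
        perm = np.array([3, 0, 4, 1, 2])
        m1 = fit_pca(matrix_from_array(x), 3)
        m2 = fit_pca(matrix_from_array(x[:, perm]), 3)
        np.testing.assert_allclose(
            np.abs(m2.loadings), np.abs(m1.loadings[perm]), atol=1e-8
        )

    def test_loading_columns_orthonormal_and_sign_fixed(self):
        rng = np.random.default_rng(9)
        model = fit_pca(matrix_from_array(rng.random((30, 6))), 4)
        gram = model.loadings.T @ model.loadings
        np.testing.assert_allclose(gram, np.eye(4), atol=1e-8)
        for j in range(4):
            i = np.argmax(np.abs(model.loadings[:, j]))
            assert model.loadings[i, j] > 0

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError, match="n_components"):
            fit_pca(matrix_from_array(np.zeros((3, 2))), 5)


class TestRefoldScores:
    def test_single_pixel_mask(self):
        cube = make_cube(np.arange(8, dtype=float).reshape(2, 2, 2))
        mask = np.zeros((2, 2), dtype=bool)
        mask[1, 0] = True
        big = make_cube(np.random.default_rng(0).random((2, 2, 2)))
        full = SampleMask(mask=np.ones((2, 2), dtype=bool))
        m = unfold([(big, full, "a"), (cube, SampleMask(mask=mask), "b")])
        model = fit_pca(m, 2)
        img = refold_scores(model, m, component=1, sample_id="b")
        assert np.isfinite(img).sum() == 1
        row = [i for i, (sid, _, _) in enumerate(m.index) if sid == "b"][0]
        assert img[1, 0] == model.scores[row, 0]

    def test_unknown_sample_errors(self):
        cube = make_cube(np.random.default_rng(1).random((2, 2, 2)))
        m = unfold([(cube, SampleMask(mask=np.ones((2, 2), bool)), "a")])
        model = fit_pca(m, 1)
        with pytest.raises(ValueError, match="unknown sample"):
            refold_scores(model, m, component=1, sample_id="zzz")

    def test_discriminating_component_contrasts_whitened_region(
        self, ensemble_products
    ):
        """Standardized score difference inside vs outside the planted
        whitened region exceeds 2 on an abnormal phantom."""
        from ghsw import calibrate, generate_cube, normalize, segment_background
        from ghsw.synthetic_data import PhantomSpec

        spec = PhantomSpec(spatial_shape=(80, 125), whitening_fraction=0.45, seed=55)
        raw, refs, truth = generate_cube(spec)
        cal = calibrate(raw, refs)
        mask = segment_background(cal)
        norm = normalize(cal, mask)
        m = unfold([(norm, mask, "x")])
        model = fit_pca(m, 3)
        # project onto the ensemble's discriminating loading direction
        comp = ensemble_products["order"][0]
        load = ensemble_products["model"].loadings[:, comp - 1]
        img = np.full(mask.mask.shape, np.nan)
        proj = (m.rows - m.rows.mean(axis=0)) @ load
        for i, (_, r, c) in enumerate(m.index):
            img[r, c] = proj[i]
        inside = img[truth.whitening_mask & mask.mask]
        outside = img[~truth.whitening_mask & mask.mask]
        pooled = np.sqrt(0.5 * (inside.var() + outside.var()))
        assert abs(inside.mean() - outside.mean()) / pooled > 2


class TestSelectWavebands:
    def test_single_peak(self):
        load = np.zeros(20)
        load[10] = 1.0
        model = model_from_loading(load)
        assert select_wavebands(model, 1, 1) == [model.wavelengths[10]]

    def test_monotone_loading_has_endpoint_extrema_only(self):
        model = model_from_loading(np.linspace(0.1, 1.0, 10))
        with pytest.warns(UserWarning, match="extrema"):
            got = select_wavebands(model, 1, 3)
        assert got == [model.wavelengths[9]]  # only the high endpoint qualifies

    def test_plateau_first_index_wins(self):
        load = np.array([0.1, 0.5, 0.5, 0.5, 0.1, 0.9, 0.1])
        model = model_from_loading(load)
        got = select_wavebands(model, 1, 2)
        assert got == sorted([model.wavelengths[1], model.wavelengths[5]])

    def test_tie_broken_toward_lower_wavelength(self):
        load = np.array([0.1, 0.8, 0.1, 0.8, 0.1])
        model = model_from_loading(load)
        assert select_wavebands(model, 1, 1) == [model.wavelengths[1]]

    def test_negative_extrema_count_by_magnitude(self):
        load = np.array([0.0, -0.9, 0.0, 0.4, 0.0])
        model = model_from_loading(load)
        got = select_wavebands(model, 1, 2)
        assert got == sorted([model.wavelengths[1], model.wavelengths[3]])

    def test_planted_features_recovered_from_ensemble(self, ensemble_products):
        wl = ensemble_products["model"].wavelengths
        expected = sorted(
            [wl[np.argmin(np.abs(wl - 950))], wl[np.argmin(np.abs(wl - 1326))]]
        )
        np.testing.assert_allclose(ensemble_products["selected"], expected, atol=1e-9)


class TestBandAnova:
    def test_identical_groups_give_zero_f(self):
        f, p = band_anova([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert f == 0.0
        assert p == 1.0

    def test_perfect_separation_gives_infinite_f(self):
        f, p = band_anova([0.0, 0.0], [1.0, 1.0])
        assert np.isinf(f)
        assert p == 0.0

    def test_hand_computed_f_on_toy_groups(self):
        # {1,2} vs {3,5}: SSB = 2(1.5-2.75)^2 + 2(4-2.75)^2 = 6.25,
        # SSW = 0.5 + 2 = 2.5, F = (6.25/1)/(2.5/2) = 5.0
        f, p = band_anova([1.0, 2.0], [3.0, 5.0])
        assert f == pytest.approx(5.0, abs=1e-12)
        assert p == pytest.approx(stats.f.sf(5.0, 1, 2), abs=1e-12)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(14)
        a, b = rng.normal(0, 1, 8), rng.normal(0.7, 1, 9)
        f, p = band_anova(a, b)
        ref = stats.f_oneway(a, b)
        assert f == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_f_equals_t_squared_for_two_groups(self):
        rng = np.random.default_rng(15)
        a, b = rng.normal(0, 1, 6), rng.normal(1, 1, 7)
        f, _ = band_anova(a, b)
        t = stats.ttest_ind(a, b).statistic
        assert f == pytest.approx(t**2, rel=1e-12)

    def test_band_column_selection_and_small_group_rejected(self):
        a = np.array([[1.0, 10.0], [2.0, 20.0]])
        b = np.array([[3.0, 30.0], [5.0, 50.0]])
        f0, _ = band_anova(a, b, band=0)
        assert f0 == pytest.approx(5.0, abs=1e-12)
        with pytest.raises(ValueError, match="at least 2"):
            band_anova([1.0], [2.0, 3.0])

    def test_ranking_table_puts_separated_band_first(self):
        rng = np.random.default_rng(16)
        wl = np.array([900.0, 1000.0, 1100.0])
        a = rng.normal(0, 0.1, (5, 3))
        b = rng.normal(0, 0.1, (5, 3))
        b[:, 2] += 3.0  # only the last band separates the groups
        df = band_ranking(a, b, wl)
        assert df.iloc[0]["wavelength_nm"] == 1100.0
        assert (df["F"] >= 0).all()
        assert ((df["p"] > 0) & (df["p"] <= 1)).all()
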