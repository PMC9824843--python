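import numpy as np
import pytest

from lignivis.chemometrics import (
    SpectraTimeSeries,
    calibrate_scores,
    fit_pca,
    mask_disturbances,
    mean_center,
    predict_poh,
    select_monitoring_pc,
    select_region,
)
from lignivis.kinetics import simulate_trajectory
from lignivis.presets import SLS_60
from lignivis.synthetic import (
    Chromophore,
    ChromophoreSet,
    GaussianBand,
    NoiseModel,
    generate_inline_spectra,
)


def _series(n_t=20, wl=None, rng_seed=0):
    if wl is None:
        wl = np.linspace(342.0, 825.0, 50)
    rng = np.random.default_rng(rng_seed)
    A = rng.random((n_t, len(wl)))
    return SpectraTimeSeries(
        times=np.linspace(0, 5, n_t), wavelengths=wl, absorbance=A
    )


class TestSelectRegion:
    def test_default_region_bounds_inclusive(self):
        s = _series()
        sub = select_region(s, 600.0, 800.0)
        assert sub.wavelengths[0] >= 600.0 and sub.wavelengths[-1] <= 800.0
        assert sub.n_wavelengths < s.n_wavelengths

    def test_full_range_is_identity(self):
        s = _series()
        sub = select_region(s, s.wavelengths[0], s.wavelengths[-1])
        np.testing.assert_array_equal(sub.absorbance, s.absorbance)

    def test_bad_bounds(self):
        s = _series()
        with pytest.raises(ValueError):
            select_region(s, 800.0, 600.0)
        with pytest.raises(ValueError):
            select_region(s, 900.0, 1000.0)


class TestMeanCenter:
    def test_column_means_zero_and_idempotent(self):
        s = _series()
        centered, mean = mean_center(s)
        np.testing.assert_allclose(centered.mean(axis=0), 0.0, atol=1e-12)
        again = centered - centered.mean(axis=0)
        np.testing.assert_allclose(again, centered, atol=1e-12)

    def test_constant_matrix_centers_to_zero(self):
        wl = np.linspace(600, 800, 10)
        s = SpectraTimeSeries(
            times=np.arange(5.0), wavelengths=wl, absorbance=np.full((5, 10), 3.3)
        )
        centered, mean = mean_center(s)
        np.testing.assert_allclose(centered, 0.0, atol=1e-12)
        np.testing.assert_allclose(mean, 3.3)

    def test_single_spectrum_rejected(self):
        wl = np.linspace(600, 800, 10)
        s = SpectraTimeSeries(
            times=np.array([0.0]), wavelengths=wl, absorbance=np.ones((1, 10))
        )
        with pytest.raises(ValueError):
            mean_center(s)


class TestFitPCA:
    def test_rank_one_matrix_single_component(self):
        u = np.linspace(-1, 1, 12)[:, None]
        v = np.random.default_rng(3).random((1, 8))
        X = u @ v
        X -= X.mean(axis=0)
        with pytest.warns(UserWarning):
            model = fit_pca(X, n_components=3)
        assert model.explained_variance_fraction[0] == pytest.approx(1.0, abs=1e-12)

    def test_loadings_match_covariance_eigendecomposition(self):
        """SVD route agrees with an explicit covariance eigensolve up to sign."""
        rng = np.random.default_rng(11)
        X = rng.random((5, 3))
        X -= X.mean(axis=0)
        model = fit_pca(X, n_components=3)
        w, V = np.linalg.eigh(X.T @ X)
        order = np.argsort(w)[::-1]
        V = V[:, order]
        for k in range(3):
            dot = abs(float(model.loadings[:, k] @ V[:, k]))
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_sklearn_cross_check(self):
        """Scores and explained variance match scikit-learn's PCA."""
        sklearn = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(5)
        X = rng.random((30, 12))
        Xc = X - X.mean(axis=0)
        model = fit_pca(Xc, n_components=3)
        sk = sklearn.PCA(n_components=3).fit(X)
        np.testing.assert_allclose(
            np.abs(model.scores), np.abs(sk.transform(X)), atol=1e-8
        )
        np.testing.assert_allclose(
            model.explained_variance_fraction,
            sk.explained_variance_ratio_,
            atol=1e-8,
        )

    def test_orthonormality_reconstruction_variance(self):
        rng = np.random.default_rng(7)
        X = rng.random((15, 10))
        Xc = X - X.mean(axis=0)
        model = fit_pca(Xc, n_components=10)
        PtP = model.loadings.T @ model.loadings
        np.testing.assert_allclose(PtP, np.eye(10), atol=1e-8)
        np.testing.assert_allclose(
            model.scores @ model.loadings.T, Xc, atol=1e-8
        )
        assert np.all(np.diff(model.explained_variance_fraction) <= 1e-12)
        assert model.explained_variance_fraction.sum() == pytest.approx(
            1.0, abs=1e-8
        )
        # component variances sum to the total centered variance
        np.testing.assert_allclose(
            np.sum(model.scores**2), np.sum(Xc**2), atol=1e-8
        )

    def test_score_columns_orthogonal(self):
        rng = np.random.default_rng(13)
        Xc = rng.random((20, 8))
        Xc -= Xc.mean(axis=0)
        model = fit_pca(Xc, n_components=3)
        G = model.scores.T @ model.scores
        off = G - np.diag(np.diag(G))
        np.testing.assert_allclose(off, 0.0, atol=1e-8)

    def test_sign_convention(self):
        rng = np.random.default_rng(17)
        Xc = rng.random((20, 8))
        Xc -= Xc.mean(axis=0)
        model = fit_pca(Xc, n_components=3)
        for k in range(3):
            j = np.argmax(np.abs(model.loadings[:, k]))
            assert model.loadings[j, k] > 0

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            fit_pca(np.zeros((4, 3)), n_components=5)


class TestMaskDisturbances:
    def test_no_events_all_retained(self):
        s = _series()
        assert mask_disturbances(s).all()

    def test_single_event_window(self):
        t = np.arange(0.0, 2.0, 1.0 / 120.0)
        wl = np.linspace(600, 800, 5)
        s = SpectraTimeSeries(
            times=t, wavelengths=wl, absorbance=np.zeros((len(t), 5))
        )
        mask = mask_disturbances(s, sampling_events=np.array([1.0]))
        excluded = t[~mask]
        assert excluded.min() >= 1.0 - 1e-12
        assert excluded.max() <= 1.0 + 2.0 / 60.0 + 1e-12

    def test_overlapping_windows_merge(self):
        t = np.linspace(0.0, 1.0, 121)
        wl = np.linspace(600, 800, 5)
        s = SpectraTimeSeries(
            times=t, wavelengths=wl, absorbance=np.zeros((121, 5))
        )
        m = mask_disturbances(
            s, sampling_events=np.array([0.5, 0.51]), post_window_min=2.0
        )
        gap = t[~m]
        assert gap.min() >= 0.5 - 1e-12 and gap.max() <= 0.51 + 2.0 / 60.0 + 1e-12
        # excluded region is one contiguous block
        idx = np.flatnonzero(~m)
        assert np.all(np.diff(idx) == 1)


def _poh_driven_spectra(extra_drift=0.0, seed=0):
    """Noise-free spectra whose only kinetic variation follows [POH]."""
    chroms = [
        Chromophore(
            bands=(GaussianBand(center=700.0, width=60.0, amplitude=2.0),),
            driver="poh",
        )
    ]
    if extra_drift:
        chroms.append(
            Chromophore(
                bands=(GaussianBand(center=630.0, width=30.0, amplitude=extra_drift),),
                driver="drift",
            )
        )
    noise = NoiseModel(seed=seed).quiet()
    spectra = generate_inline_spectra(
        SLS_60.params,
        SLS_60.init,
        chromophores=ChromophoreSet(components=tuple(chroms)),
        noise=noise,
        coarse=True,
    )
    truth = simulate_trajectory(SLS_60.params, SLS_60.init, spectra.times)
    return spectra, truth


class TestMonitoringSelectionAndCalibration:
    def test_single_source_selects_pc1_with_perfect_fit(self):
        spectra, truth = _poh_driven_spectra()
        sub = select_region(spectra)
        centered, mean = mean_center(sub)
        with pytest.warns(UserWarning):  # rank-1 input
            model = fit_pca(centered, n_components=3, mean_spectrum=mean)
        pc = select_monitoring_pc(model, truth, sub.times)
        assert pc == 1
        cal = calibrate_scores(model, pc, truth, sub.times)
        assert cal.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_dominant_drift_pushes_signal_to_pc2(self):
        """A drift component with larger variance claims PC1."""
        spectra, truth = _poh_driven_spectra(extra_drift=30.0)
        sub = select_region(spectra)
        centered, mean = mean_center(sub)
        model = fit_pca(centered, n_components=3, mean_spectrum=mean)
        assert select_monitoring_pc(model, truth, sub.times) == 2

    def test_constant_reference_rejected(self):
        spectra, _ = _poh_driven_spectra()
        sub = select_region(spectra)
        centered, mean = mean_center(sub)
        with pytest.warns(UserWarning):
            model = fit_pca(centered, n_components=3, mean_spectrum=mean)
        frozen = simulate_trajectory(
            SLS_60.params.__class__(k1=0.0), SLS_60.init, sub.times
        )
        with pytest.raises(ValueError):
            select_monitoring_pc(model, frozen, sub.times)

    def test_score_sign_flip_leaves_r2(self):
        spectra, truth = _poh_driven_spectra()
        sub = select_region(spectra)
        centered, mean = mean_center(sub)
        with pytest.warns(UserWarning):
            model = fit_pca(centered, n_components=3, mean_spectrum=mean)
        cal = calibrate_scores(model, 1, truth, sub.times)
        flipped = fit_pca(centered, n_components=3, mean_spectrum=mean)
        object.__setattr__(flipped, "scores", -flipped.scores)
        cal2 = calibrate_scores(flipped, 1, truth, sub.times)
        assert cal2.r_squared == pytest.approx(cal.r_squared, abs=1e-12)
        assert cal2.slope == pytest.approx(-cal.slope, rel=1e-9)

    def test_r2_affine_invariance_of_score_axis(self):
        """R^2 is unchanged by any affine transformation of the score."""
        spectra, truth = _poh_driven_spectra()
        sub = select_region(spectra)
        centered, mean = mean_center(sub)
        with pytest.warns(UserWarning):
            model = fit_pca(centered, n_components=3, mean_spectrum=mean)
        cal = calibrate_scores(model, 1, truth, sub.times)
        scaled = fit_pca(centered, n_components=3, mean_spectrum=mean)
        object.__setattr__(scaled, "scores", 3.7 * scaled.scores - 1.2)
        cal2 = calibrate_scores(scaled, 1, truth, sub.times)
        assert cal2.r_squared == pytest.approx(cal.r_squared, abs=1e-10)

    def test_initial_window_excluded(self):
        spectra, truth = _poh_driven_spectra()
        sub = select_region(spectra)
        centered, mean = mean_center(sub)
        with pytest.warns(UserWarning):
            model = fit_pca(centered, n_components=3, mean_spectrum=mean)
        cal = calibrate_scores(
            model, 1, truth, sub.times, excluded_initial_window=0.25
        )
        n_in_window = int(np.count_nonzero(sub.times < 0.25))
        assert cal.n_points == sub.n_times - n_in_window

    def test_predict_round_trip_residuals(self):
        """Residual variance of predictions equals (1 - R^2) * var(ref)."""
        spectra, truth = _poh_driven_spectra()
        noise = NoiseModel(seed=3)
        noisy = generate_inline_spectra(
            SLS_60.params, SLS_60.init, noise=noise, coarse=True
        )
        sub = select_region(noisy)
        centered, mean = mean_center(sub)
        model = fit_pca(centered, n_components=3, mean_spectrum=mean)
        mask = mask_disturbances(sub)
        pc = select_monitoring_pc(model, truth, sub.times, mask)
        cal = calibrate_scores(model, pc, truth, sub.times, mask=mask)
        keep = mask & (sub.times >= cal.excluded_initial_window)
        score = model.scores[keep, pc - 1]
        ref = truth.poh_at(sub.times[keep])
        pred = predict_poh(cal, score)
        ss_res = np.sum((ref - pred) ** 2)
        ss_tot = np.sum((ref - ref.mean()) ** 2)
        assert 1.0 - ss_res / ss_tot == pytest.approx(cal.r_squared, abs=1e-10)

    def test_end_to_end_default_scenario_correlation(self):
        """Selected score tracks true [POH] with |r| >= 0.97 at default noise."""
        noise = NoiseModel(seed=42)
        spectra = generate_inline_spectra(
            SLS_60.params, SLS_60.init, noise=noise, coarse=True
        )
        truth = simulate_trajectory(SLS_60.params, SLS_60.init, spectra.times)
        sub = select_region(spectra)
        centered, mean = mean_center(sub)
        model = fit_pca(centered, n_components=3, mean_spectrum=mean)
        mask = mask_disturbances(sub)
        pc = select_monitoring_pc(model, truth, sub.times, mask)
        score = model.scores[mask, pc - 1]
        ref = truth.poh_at(sub.times[mask])
        r = abs(np.corrcoef(score, ref)[0, 1])
        assert r >= 0.97
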