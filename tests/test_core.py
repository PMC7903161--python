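import numpy as np
import pytest

from sass.core import (
    SassModel,
    SensorCovariance,
    apply_projection,
    band_covariance,
    build_projection,
    fit_sass,
    harmonic_sass,
    joint_diagonalize,
    select_component_count,
    selection_mse_curve,
    ssp_baseline,
)
from sass.preprocess import FilterSpec, design_fir, filter_data, filter_recording
from sass.recording import MultichannelRecording
from sass.ssvep import trial_table
from sass.synth import SessionConfig, generate_session

from oracles import gevd_eigenvalues_bruteforce, random_spd

BAND = (9.0, 11.0)


def cov_of(matrix, labels=None, band=BAND, condition="stim"):
    matrix = np.asarray(matrix, dtype=float)
    labels = labels or tuple(f"ch{i}" for i in range(matrix.shape[0]))
    return SensorCovariance(matrix=matrix, band=band, condition=condition,
                            n_samples_used=1000, channel_labels=tuple(labels))


def make_rec(data, fs=500.0, events=()):
    data = np.atleast_2d(data)
    return MultichannelRecording(
        data=data, fs=fs,
        channel_labels=[f"ch{i}" for i in range(data.shape[0])],
        events=list(events),
    )


class TestBandCovariance:
    def test_uncorrelated_channels_near_identity(self, rng):
        rec = make_rec(rng.standard_normal((2, 200000)))
        cov = band_covariance(rec, BAND)
        assert abs(cov.matrix[0, 1]) < 0.05
        np.testing.assert_allclose(np.diag(cov.matrix), 1.0, atol=0.05)

    def test_rank_one_data(self, rng):
        x = rng.standard_normal(50000)
        topo = np.array([1.0, -0.5, 0.25])
        rec = make_rec(np.outer(topo, x))
        cov = band_covariance(rec, BAND)
        np.testing.assert_allclose(cov.matrix, np.var(x, ddof=1) * np.outer(topo, topo),
                                   rtol=1e-10, atol=1e-12)
        assert np.linalg.matrix_rank(cov.matrix, tol=1e-8) == 1

    def test_zero_variance_channel_rejected(self, rng):
        data = rng.standard_normal((3, 1000))
        data[1] = 0.0
        with pytest.raises(ValueError, match="zero-variance"):
            band_covariance(make_rec(data), BAND)

    def test_rank_deficient_warns(self, rng):
        data = rng.standard_normal((5, 4))
        with pytest.warns(UserWarning, match="rank-deficient"):
            band_covariance(make_rec(data), BAND)

    def test_stim_eigenvalue_dominance(self, small_session, band_kernel):
        cfg, no_stim, stim, _ = small_session
        A = band_covariance(filter_recording(stim, band_kernel), BAND)
        B = band_covariance(filter_recording(no_stim, band_kernel), BAND)
        ratio = (np.linalg.eigvalsh(A.matrix)[-1]
                 / np.linalg.eigvalsh(B.matrix)[-1])
        assert ratio >= cfg.artifact_gain**2 / 10


class TestJointDiagonalize:
    def test_identical_covariances_all_unit(self, rng):
        m = random_spd(6, rng)
        model = joint_diagonalize(cov_of(m), cov_of(m, condition="no_stim"))
        np.testing.assert_allclose(model.lambdas, 1.0, rtol=1e-8)

    def test_diagonal_case(self):
        A = cov_of(np.diag([100.0, 1.0]))
        B = cov_of(np.eye(2), condition="no_stim")
        model = joint_diagonalize(A, B)
        np.testing.assert_allclose(model.lambdas, [100.0, 1.0], rtol=1e-10)
        w1 = model.W[0] / np.linalg.norm(model.W[0])
        assert abs(abs(w1[0]) - 1.0) < 1e-10

    def test_generalized_eigen_identity_and_normalization(self, rng):
        A, B = random_spd(8, rng), random_spd(8, rng)
        model = joint_diagonalize(cov_of(A), cov_of(B, condition="no_stim"))
        for lam, w in zip(model.lambdas, model.W):
            np.testing.assert_allclose(A @ w, lam * (B @ w), rtol=1e-7,
                                       atol=1e-8 * np.abs(A @ w).max())
            assert np.isclose(w @ B @ w, 1.0, rtol=1e-8)
            assert np.isclose(lam, (w @ A @ w) / (w @ B @ w), rtol=1e-8)

    def test_sorted_descending(self, rng):
        model = joint_diagonalize(
            cov_of(random_spd(7, rng)),
            cov_of(random_spd(7, rng), condition="no_stim"),
        )
        assert np.all(np.diff(model.lambdas) <= 1e-12)

    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_against_characteristic_polynomial_oracle(self, n):
        rng = np.random.default_rng(100 + n)
        for _ in range(10):
            A, B = random_spd(n, rng), random_spd(n, rng)
            model = joint_diagonalize(cov_of(A), cov_of(B, condition="no_stim"))
            roots = gevd_eigenvalues_bruteforce(A, B)[::-1]
            np.testing.assert_allclose(model.lambdas, roots, rtol=1e-6)

    def test_label_mismatch_rejected(self, rng):
        A = cov_of(random_spd(3, rng))
        B = cov_of(random_spd(3, rng), labels=("x", "y", "z"),
                   condition="no_stim")
        with pytest.raises(ValueError, match="channel"):
            joint_diagonalize(A, B)

    def test_singular_b_beyond_regularization(self, rng):
        A = cov_of(random_spd(3, rng))
        B = cov_of(np.zeros((3, 3)), condition="no_stim")
        with pytest.raises(ValueError):
            joint_diagonalize(A, B)


class TestBuildProjection:
    def test_k0_is_identity(self, rng):
        model = joint_diagonalize(
            cov_of(random_spd(6, rng)),
            cov_of(random_spd(6, rng), condition="no_stim"),
        )
        P = build_projection(model, 0).P
        np.testing.assert_allclose(P, np.eye(6), atol=1e-10)

    def test_diagonal_case_k1(self):
        model = joint_diagonalize(
            cov_of(np.diag([100.0, 1.0])),
            cov_of(np.eye(2), condition="no_stim"),
        )
        P = build_projection(model, 1).P
        np.testing.assert_allclose(P, np.diag([0.0, 1.0]), atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_idempotency_and_rank(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 10))
        model = joint_diagonalize(
            cov_of(random_spd(n, rng)),
            cov_of(random_spd(n, rng), condition="no_stim"),
        )
        k = int(rng.integers(0, n + 1))
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # k = n legitimately warns
            P = build_projection(model, k).P
        assert np.abs(P @ P - P).max() < 1e-8
        assert np.linalg.matrix_rank(P, tol=1e-8) == n - k

    def test_k_equals_n_warns_zero_matrix(self, rng):
        model = joint_diagonalize(
            cov_of(random_spd(4, rng)),
            cov_of(random_spd(4, rng), condition="no_stim"),
        )
        with pytest.warns(UserWarning, match="zero matrix"):
            P = build_projection(model, 4).P
        np.testing.assert_allclose(P, 0.0, atol=1e-8)

    def test_retained_component_time_courses_invariant(self, rng):
        # spectral containment: w_i^T (P x) = w_i^T x for retained i
        model = joint_diagonalize(
            cov_of(random_spd(6, rng)),
            cov_of(random_spd(6, rng), condition="no_stim"),
        )
        k = 2
        P = build_projection(model, k).P
        W_ret = model.W[k:]
        np.testing.assert_allclose(W_ret @ P, W_ret, atol=1e-8)

    def test_projection_invariant_to_filter_scaling(self, rng):
        model = joint_diagonalize(
            cov_of(random_spd(5, rng)),
            cov_of(random_spd(5, rng), condition="no_stim"),
        )
        P1 = build_projection(model, 2).P
        scales = rng.uniform(0.5, 3.0, size=5)
        scaled = SassModel(
            W=scales[:, None] * model.W, lambdas=model.lambdas,
            band=model.band, channel_labels=model.channel_labels,
        )
        P2 = build_projection(scaled, 2).P
        np.testing.assert_allclose(P1, P2, atol=1e-8)

    def test_degenerate_eigenvalue_tie(self):
        # projection depends only on the invariant subspace of tied lambdas
        model = joint_diagonalize(
            cov_of(np.diag([5.0, 5.0, 1.0])),
            cov_of(np.eye(3), condition="no_stim"),
        )
        P = build_projection(model, 2).P
        np.testing.assert_allclose(P, np.diag([0.0, 0.0, 1.0]), atol=1e-8)

    def test_k_out_of_range(self, rng):
        model = joint_diagonalize(
            cov_of(random_spd(3, rng)),
            cov_of(random_spd(3, rng), condition="no_stim"),
        )
        with pytest.raises(ValueError):
            build_projection(model, 4)


class TestSelectComponentCount:
    def test_identical_recordings_select_zero(self, rng):
        data = rng.standard_normal((4, 20000))
        rec = make_rec(data)
        A = band_covariance(rec, BAND)
        model = joint_diagonalize(A, cov_of(A.matrix, condition="no_stim"))
        k = select_component_count(model, rec, make_rec(data.copy()))
        assert k == 0

    def test_single_artifact_source_selects_one(self):
        cfg = SessionConfig(n_channels=16, n_trials=200, seed=0,
                            nonlinearity_coeffs=(1.0, 0.1))
        no_stim, stim, _ = generate_session(cfg)
        model = fit_sass(stim, no_stim, BAND)
        assert model.k_rejected == 1

    def test_k_matches_argmin_of_stored_curve(self, recovery_session):
        _, no_stim, stim, _ = recovery_session
        model = fit_sass(stim, no_stim, BAND)
        assert model.k_rejected == int(np.argmin(model.selection_curve))
        assert model.selection_curve.size == model.n_channels + 1

    def test_residual_power_monotone_up_to_true_k(self):
        cfg = SessionConfig(n_channels=16, n_trials=120, seed=1,
                            nonlinearity_coeffs=(1.0, 0.1),
                            n_artifact_sources=3)
        no_stim, stim, _ = generate_session(cfg)
        kernel = design_fir(FilterSpec(*BAND), cfg.fs)
        stim_f = filter_recording(stim, kernel)
        nostim_f = filter_recording(no_stim, kernel)
        A = band_covariance(stim_f, BAND, "stim")
        B = band_covariance(nostim_f, BAND, "no_stim")
        model = joint_diagonalize(A, B)
        residual = []
        for k in range(4):
            P = build_projection(model, k).P
            cleaned = np.einsum("ij,jk,ik->i", P, A.matrix, P)
            residual.append(np.sum(cleaned - np.diag(B.matrix)))
        assert np.all(np.diff(residual) <= 0)


class TestApplyProjection:
    def test_identity_projection_noop(self, rng):
        rec = make_rec(rng.standard_normal((3, 1000)))
        out = apply_projection(np.eye(3), rec)
        np.testing.assert_array_equal(out.data, rec.data)
        assert out.events == rec.events

    def test_label_mismatch_rejected(self, rng, recovery_session):
        _, no_stim, stim, _ = recovery_session
        model = fit_sass(stim, no_stim, BAND)
        other = make_rec(rng.standard_normal((16, 5000)))
        with pytest.raises(ValueError, match="match"):
            apply_projection(model, other)

    def test_cleaned_power_within_factor_two_of_nostim(self, recovery_session,
                                                       band_kernel):
        cfg, no_stim, stim, _ = recovery_session
        model = fit_sass(stim, no_stim, BAND)
        stim_f = filter_recording(stim, band_kernel)
        nostim_f = filter_recording(no_stim, band_kernel)
        occ = [lb for lb in stim.channel_labels if lb in
               ("O1", "Oz", "O2", "POz")]
        idx = stim.index_of(occ)
        raw_ratio = (stim_f.data[idx].var(axis=1)
                     / nostim_f.data[idx].var(axis=1)).max()
        assert raw_ratio > 1e4
        cleaned = apply_projection(model, stim_f)
        ratio = cleaned.data[idx].var(axis=1) / nostim_f.data[idx].var(axis=1)
        assert np.all((ratio > 0.5) & (ratio < 2.0))

    def test_no_overcorrection_of_nostim_recording(self, recovery_session,
                                                   band_kernel):
        cfg, no_stim, stim, _ = recovery_session
        model = fit_sass(stim, no_stim, BAND)
        nostim_f = filter_recording(no_stim, band_kernel)
        from sass.preprocess import virtual_occipital

        onsets = [s for s, _ in no_stim.events]
        before = trial_table(virtual_occipital(nostim_f), onsets, cfg.fs, 10.0)
        after_rec = apply_projection(model, nostim_f)
        after = trial_table(virtual_occipital(after_rec), onsets, cfg.fs, 10.0)
        change = np.abs(after.amplitude - before.amplitude) / before.amplitude
        assert np.median(change) < 0.10


class TestHarmonicSass:
    def test_band_layout(self, recovery_session):
        _, no_stim, stim, _ = recovery_session
        fits = harmonic_sass(stim, no_stim, 10.0, [1, 2, 3])
        assert [band for band, _ in fits] == [(9.0, 11.0), (19.0, 21.0),
                                              (29.0, 31.0)]

    def test_overlapping_bands_rejected(self, recovery_session):
        _, no_stim, stim, _ = recovery_session
        with pytest.raises(ValueError, match="overlap"):
            harmonic_sass(stim, no_stim, 10.0, [1, 2], half_width=6.0)

    def test_band_above_nyquist_rejected(self, recovery_session):
        _, no_stim, stim, _ = recovery_session
        with pytest.raises(ValueError, match="Nyquist"):
            harmonic_sass(stim, no_stim, 10.0, [1, 25])

    def test_harmonic_filters_differ(self, recovery_session):
        _, no_stim, stim, _ = recovery_session
        fits = harmonic_sass(stim, no_stim, 10.0, [1, 2])
        w10 = fits[0][1].W[0] / np.linalg.norm(fits[0][1].W[0])
        w20 = fits[1][1].W[0] / np.linalg.norm(fits[1][1].W[0])
        assert abs(w10 @ w20) < 0.99

    def test_fundamental_cleaning_leaves_harmonic_artifact(
        self, recovery_session
    ):
        cfg, no_stim, stim, _ = recovery_session
        fits = harmonic_sass(stim, no_stim, 10.0, [1, 2])
        model10 = fits[0][1]
        cleaned = apply_projection(model10, stim)  # broadband application
        kernel20 = design_fir(FilterSpec(19.0, 21.0), cfg.fs)
        p_cleaned = filter_data(cleaned.data, kernel20).var(axis=1)
        p_nostim = filter_data(no_stim.data, kernel20).var(axis=1)
        assert (p_cleaned / p_nostim).max() > 10


class TestSspBaseline:
    def test_k0_identity(self, rng):
        P = ssp_baseline(cov_of(random_spd(4, rng)), 0)
        np.testing.assert_allclose(P, np.eye(4), atol=1e-12)

    def test_symmetric_idempotent(self, rng):
        P = ssp_baseline(cov_of(random_spd(6, rng)), 2)
        np.testing.assert_allclose(P, P.T, atol=1e-12)
        np.testing.assert_allclose(P @ P, P, atol=1e-10)

    def test_sass_retains_more_ssvep_than_ssp_under_overlap(self):
        """Overlap fixture: the artifact topography shares 80% of its
        direction with the brain source; SSP blindly removes the overlap,
        SASS avoids the direction that carries brain variance."""
        rng = np.random.default_rng(42)
        n, fs, dur = 6, 500.0, 120.0
        t = np.arange(int(dur * fs)) / fs
        s = np.zeros(n)
        s[0] = 1.0  # brain topography
        a = np.zeros(n)
        a[0], a[1] = 0.8, 0.6  # artifact topography, 80% overlap
        kernel = design_fir(FilterSpec(*BAND), fs)

        def narrowband_noise(scale):
            return scale * filter_data(rng.standard_normal((n, t.size)), kernel)

        brain = 3.0 * np.cos(2 * np.pi * 10 * t)
        artifact = 300.0 * filter_data(rng.standard_normal(t.size), kernel)
        artifact /= artifact.std() / 300.0
        nostim = np.outer(s, brain) + narrowband_noise(20.0)
        stim = np.outer(s, brain) + np.outer(a, artifact) + narrowband_noise(20.0)
        A = cov_of(np.cov(stim))
        B = cov_of(np.cov(nostim), condition="no_stim")
        P_sass = build_projection(joint_diagonalize(A, B), 1).P
        P_ssp = ssp_baseline(A, 1)
        amp_sass = abs(s @ P_sass @ s)
        amp_ssp = abs(s @ P_ssp @ s)
        assert amp_sass >= 1.2 * amp_ssp
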