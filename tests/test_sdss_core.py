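"""Covariance smoothing, MVDR weights, beamforming and post-filters.

The smoothing operations are checked against an independent brute-force
block-average oracle written here with explicit loops.
"""

import numpy as np
import pytest

from conftest import random_hermitian_psd
from sdss import (ArrayGeometry, CovarianceEstimate, SnapshotFrame, SourceSet,
                  backward_smooth, beamform_image, fb_smooth, forward_smooth,
                  mainlobe_width, mvdr_weights, sample_covariance,
                  simulate_snapshots, snr_postfilter, wiener_postfilter)


# --------------------------------------------------------------- oracles ---

def oracle_forward(mat: np.ndarray, q: int) -> np.ndarray:
    """Triple-loop block average, independent of the library path."""
    m = mat.shape[0]
    sub = m - q + 1
    out = np.zeros((sub, sub), dtype=complex)
    for i in range(q):
        for r in range(sub):
            for c in range(sub):
                out[r, c] += mat[i + r, i + c]
    return out / q


def oracle_backward(mat: np.ndarray, q: int) -> np.ndarray:
    m = mat.shape[0]
    j = np.zeros((m, m))
    for i in range(m):
        j[i, m - 1 - i] = 1.0
    return oracle_forward(j @ mat.conj() @ j, q)


# ------------------------------------------------------ sample covariance ---

class TestSampleCovariance:
    def test_zero_frame_gives_zero_matrix(self):
        frame = SnapshotFrame(np.zeros((3, 5), dtype=complex))
        assert np.all(sample_covariance(frame).matrix == 0)

    def test_repeated_basis_vector_gives_rank_one_projector(self):
        e1 = np.zeros((4, 6), dtype=complex)
        e1[0, :] = 1.0
        r = sample_covariance(SnapshotFrame(e1)).matrix
        expected = np.zeros((4, 4))
        expected[0, 0] = 1.0
        assert np.allclose(r, expected)

    def test_orthogonal_snapshots_average_outer_products(self):
        x = np.array([[1.0, 0.0], [0.0, 1.0]], dtype=complex)
        r = sample_covariance(SnapshotFrame(x)).matrix
        assert np.allclose(r, 0.5 * np.eye(2))


# ---------------------------------------------------------------- smoothing ---

class TestSmoothing:
    def test_identity_smooths_to_identity(self):
        r = CovarianceEstimate(np.eye(5))
        for q in (1, 2, 5):
            sub = 5 - q + 1
            assert np.allclose(forward_smooth(r, q).matrix, np.eye(sub))
            assert np.allclose(backward_smooth(r, q).matrix, np.eye(sub))
            assert np.allclose(fb_smooth(r, q).matrix, np.eye(sub))

    def test_q_one_returns_input_unchanged(self, rng):
        mat = random_hermitian_psd(rng, 4)
        r = CovarianceEstimate(mat)
        assert np.allclose(forward_smooth(r, 1).matrix, r.matrix)

    def test_forward_hand_example_m3_q2(self):
        mat = np.array([[2.0, 1.0, 0.0], [1.0, 3.0, 1.0], [0.0, 1.0, 4.0]])
        out = forward_smooth(CovarianceEstimate(mat), 2).matrix
        assert np.allclose(out, [[2.5, 1.0], [1.0, 3.5]])

    def test_backward_equals_forward_on_persymmetric_real_input(self, rng):
        # J R J = R for a centro-symmetric real matrix
        base = random_hermitian_psd(rng, 4).real
        j = np.eye(4)[::-1]
        mat = 0.5 * (base + j @ base @ j)
        r = CovarianceEstimate(mat)
        assert np.allclose(backward_smooth(r, 2).matrix,
                           forward_smooth(r, 2).matrix)

    def test_backward_complex_hand_case_matches_oracle(self):
        mat = np.array([[2.0, 1.0j, 0.0], [-1.0j, 3.0, 0.5], [0.0, 0.5, 4.0]])
        r = CovarianceEstimate(mat)
        assert np.allclose(backward_smooth(r, 2).matrix, oracle_backward(mat, 2),
                           atol=1e-14)

    def test_fb_is_mean_of_forward_and_backward(self, rng):
        mat = random_hermitian_psd(rng, 4)
        r = CovarianceEstimate(mat)
        expected = 0.5 * (forward_smooth(r, 2).matrix + backward_smooth(r, 2).matrix)
        assert np.allclose(fb_smooth(r, 2).matrix, expected, atol=1e-14)

    @pytest.mark.parametrize("m", range(2, 7))
    def test_smoothing_matches_bruteforce_oracle_all_sizes(self, m):
        rng = np.random.default_rng(m)
        for q in range(1, m + 1):
            for _ in range(5):
                mat = random_hermitian_psd(rng, m)
                r = CovarianceEstimate(mat)
                assert np.abs(forward_smooth(r, q).matrix
                              - oracle_forward(mat, q)).max() < 1e-12
                assert np.abs(backward_smooth(r, q).matrix
                              - oracle_backward(mat, q)).max() < 1e-12
                fb = fb_smooth(r, q).matrix
                assert np.abs(fb - 0.5 * (oracle_forward(mat, q)
                                          + oracle_backward(mat, q))).max() < 1e-12

    def test_fb_output_persymmetric_and_psd(self, rng):
        for _ in range(20):
            mat = random_hermitian_psd(rng, 6)
            fb = fb_smooth(CovarianceEstimate(mat), 3).matrix
            j = np.eye(fb.shape[0])[::-1]
            scale = np.linalg.norm(fb)
            assert np.linalg.norm(j @ fb.conj() @ j - fb) <= 1e-10 * scale
            assert np.linalg.eigvalsh(fb)[0] >= -1e-10 * np.real(np.trace(fb))

    def test_q_out_of_range_raises(self, rng):
        r = CovarianceEstimate(random_hermitian_psd(rng, 3))
        with pytest.raises(ValueError):
            forward_smooth(r, 4)

    def test_coherent_pair_rank_restored_by_smoothing(self):
        """Two fully coherent echoes: sample covariance is rank 1, the
        smoothed sub-array covariance recovers a usable second eigenvalue."""
        geom = ArrayGeometry(16, 8)
        src = SourceSet(angles=np.array([-0.25, 0.2]),
                        amplitudes=np.array([1.0, 0.8]))
        frame = simulate_snapshots(geom, src, noise_variance=0.0,
                                   num_snapshots=64, seed=4, coherent=True)
        r = sample_covariance(frame)
        ev_full = np.linalg.eigvalsh(r.matrix)[::-1]
        assert ev_full[1] < 1e-10 * ev_full[0]  # coherent -> rank 1
        ev_sub = np.linalg.eigvalsh(fb_smooth(r, geom.num_subarrays).matrix)[::-1]
        assert ev_sub[1] > 0.1 * ev_sub[0]


# ------------------------------------------------------------ MVDR weights ---

class TestMvdrWeights:
    def test_identity_covariance_reduces_to_das(self):
        r = CovarianceEstimate(np.eye(4))
        a = np.exp(1j * np.linspace(0, 2, 4))
        w = mvdr_weights(r, a, loading=0.0).weights
        assert np.allclose(w, a / np.real(a.conj() @ a))

    def test_diagonal_hand_example(self):
        r = CovarianceEstimate(np.diag([1.0, 4.0]))
        w = mvdr_weights(r, np.array([1.0, 1.0]), loading=0.0).weights
        assert np.allclose(w, [0.8, 0.2])

    def test_distortionless_constraint(self, rng):
        mat = random_hermitian_psd(rng, 5)
        a = np.exp(-1j * np.pi * np.arange(5) * 0.3)
        w = mvdr_weights(CovarianceEstimate(mat), a).weights
        assert abs(w.conj() @ a - 1.0) < 1e-8

    def test_scale_invariance_of_weights(self, rng):
        mat = random_hermitian_psd(rng, 4)
        a = np.exp(-1j * np.arange(4) * 0.7)
        w1 = mvdr_weights(CovarianceEstimate(mat), a, loading=0.0).weights
        w2 = mvdr_weights(CovarianceEstimate(7.5 * mat), a, loading=0.0).weights
        assert np.allclose(w1, w2)

    def test_singular_covariance_reports_loading_advice(self):
        r = CovarianceEstimate(np.zeros((3, 3)))
        with pytest.raises(np.linalg.LinAlgError, match="loading"):
            mvdr_weights(r, np.ones(3), loading=0.0)


# ---------------------------------------------------------- image formation ---

class TestBeamformImage:
    def test_point_source_peaks_at_true_angle_both_methods(self, small_geometry):
        theta0 = 0.18
        src = SourceSet(angles=np.array([theta0]), amplitudes=np.array([1.0]))
        frame = simulate_snapshots(small_geometry, src, noise_variance=1e-4,
                                   num_snapshots=256, seed=21)
        grid = np.linspace(-0.5, 0.5, 201)
        for method in ("das", "mvdr_sdss"):
            img = beamform_image(frame, small_geometry, grid, method=method, q=3)
            assert abs(grid[np.argmax(img.pixels)] - theta0) <= grid[1] - grid[0]

    def test_mvdr_mainlobe_narrower_than_das(self, two_source_frame,
                                             small_geometry):
        grid = np.linspace(-0.6, 0.6, 481)
        das = beamform_image(two_source_frame, small_geometry, grid, "das")
        mv = beamform_image(two_source_frame, small_geometry, grid, "mvdr_sdss", q=3)
        assert (mainlobe_width(grid, mv.pixels)
                <= mainlobe_width(grid, das.pixels))

    def test_zero_frame_gives_zero_image(self, small_geometry):
        frame = SnapshotFrame(np.zeros((8, 4), dtype=complex))
        img = beamform_image(frame, small_geometry, np.linspace(-0.3, 0.3, 11),
                             method="das")
        assert np.all(img.pixels == 0)

    def test_unknown_method_rejected(self, two_source_frame, small_geometry):
        with pytest.raises(ValueError):
            beamform_image(two_source_frame, small_geometry,
                           np.array([0.0]), method="music")

    def test_log_compression_clips_to_dynamic_range(self, two_source_frame,
                                                    small_geometry):
        img = beamform_image(two_source_frame, small_geometry,
                             np.linspace(-0.6, 0.6, 101), "das",
                             dynamic_range_db=40.0)
        db = img.log_compressed()
        assert db.max() == 0.0 and db.min() >= -40.0


# -------------------------------------------------------------- post-filters ---

class TestPostFilters:
    def test_wiener_zero_noise_is_identity(self, rng):
        img = rng.random(16)
        assert np.allclose(wiener_postfilter(img, 0.0).pixels, img)

    def test_wiener_noise_equal_signal_power_halves_constant_image(self):
        img = np.full(10, 2.0)
        out = wiener_postfilter(img, 4.0).pixels  # signal power = 2^2
        assert np.allclose(out, 1.0)

    def test_snr_zero_gives_zero_image(self, rng):
        img = rng.random(12)
        assert np.all(snr_postfilter(img, 0.0).pixels == 0)

    def test_gains_bounded_in_unit_interval(self, rng):
        img = rng.random(50) * 5
        for out in (wiener_postfilter(img, 0.7).pixels,
                    snr_postfilter(img, rng.random(50)).pixels):
            assert np.all(out <= img + 1e-12) and np.all(out >= 0)

    def test_negative_noise_power_rejected(self):
        with pytest.raises(ValueError):
            wiener_postfilter(np.ones(4), -1.0)
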