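"""Central-slice operations: projection fidelity, adjointness, filters."""

import numpy as np
import pytest

from cryolite.fourier import (
    FourierVolume,
    extract_slice,
    good_fft_size,
    insert_slice,
    lowpass_filter,
    oversampled_ft,
    phase_shift,
    slice_to_image,
)
from cryolite.geometry import euler_to_matrix
from cryolite.io import MapVolume
from cryolite.simulate import smooth_phantom


def analytic_gaussian_projection(blobs, A, D):
    """Exact projection of a sum of 3D Gaussians along the view of A."""
    u = np.arange(D) - D // 2
    X, Y = np.meshgrid(u, u, indexing="xy")
    out = np.zeros((D, D))
    for center, sigma, amp in blobs:
        p = A @ np.asarray(center, dtype=float)
        out += (amp * np.sqrt(2 * np.pi) * sigma
                * np.exp(-((X - p[0]) ** 2 + (Y - p[1]) ** 2) / (2 * sigma ** 2)))
    return out


class TestOversampledFt:
    def test_zero_map_transforms_to_zero(self):
        vol = oversampled_ft(MapVolume(np.zeros((8, 8, 8))))
        assert vol.grid.shape == (16, 16, 16)
        np.testing.assert_array_equal(vol.grid, 0)

    def test_dc_term_equals_voxel_sum(self, rng):
        data = rng.normal(size=(8, 8, 8))
        vol = oversampled_ft(MapVolume(data))
        assert vol.grid[8, 8, 8].real == pytest.approx(data.sum(), rel=1e-10)

    def test_parseval(self, rng):
        data = rng.normal(size=(8, 8, 8))
        vol = oversampled_ft(MapVolume(data))
        P3 = 16 ** 3
        assert (np.abs(vol.grid) ** 2).sum() / P3 == pytest.approx(
            (data ** 2).sum(), rel=1e-9)

    def test_non_cubic_rejected(self):
        with pytest.raises(ValueError):
            oversampled_ft(np.zeros((8, 8, 10)))


class TestExtractSlice:
    def test_identity_rotation_gives_z_projection(self, phantom32, phantom32_ft):
        img = slice_to_image(extract_slice(phantom32_ft, np.eye(3)))
        proj = phantom32.data.sum(axis=0)
        assert np.linalg.norm(img - proj) / np.linalg.norm(proj) < 1e-10

    def test_projection_matches_analytic_oracle_under_2_percent(self, rng):
        ph, blobs = smooth_phantom(64)
        vol = oversampled_ft(ph)
        for _ in range(5):
            ang = (rng.uniform(0, 360),
                   np.degrees(np.arccos(rng.uniform(-1, 1))),
                   rng.uniform(0, 360))
            A = euler_to_matrix(*ang)
            img = slice_to_image(extract_slice(vol, A))
            proj = analytic_gaussian_projection(blobs, A, 64)
            assert (np.linalg.norm(img - proj)
                    / np.linalg.norm(proj)) < 0.02

    def test_spherically_symmetric_phantom_is_rotation_invariant(self, rng):
        from cryolite.simulate import GaussianBlob, PhantomSpec, make_phantom

        ph = make_phantom(PhantomSpec(32, 1.0, [GaussianBlob((0, 0, 0), 3.0)]))
        vol = oversampled_ft(ph)
        ref = slice_to_image(extract_slice(vol, np.eye(3)))
        for _ in range(3):
            A = euler_to_matrix(rng.uniform(0, 360), rng.uniform(0, 180),
                                rng.uniform(0, 360))
            img = slice_to_image(extract_slice(vol, A))
            assert np.abs(img - ref).max() < 0.02 * np.abs(ref).max()

    def test_invalid_rotation_rejected(self, phantom32_ft):
        with pytest.raises(ValueError):
            extract_slice(phantom32_ft, 2.0 * np.eye(3))


class TestInsertSlice:
    def test_adjoint_identity(self, rng):
        D, P = 16, 32
        grid = rng.normal(size=(P, P, P)) + 1j * rng.normal(size=(P, P, P))
        V = FourierVolume(grid=grid, pad=2, src_size=D)
        for _ in range(10):
            ang = (rng.uniform(0, 360),
                   np.degrees(np.arccos(rng.uniform(-1, 1))),
                   rng.uniform(0, 360))
            R = euler_to_matrix(*ang)
            s = rng.normal(size=(D, D)) + 1j * rng.normal(size=(D, D))
            lhs = np.vdot(extract_slice(V, R).data, s)
            ad = np.zeros((P, P, P), complex)
            aw = np.zeros((P, P, P))
            insert_slice(ad, aw, s, R, 1.0)
            rhs = np.vdot(grid, ad)
            assert abs(lhs - rhs) / abs(lhs) < 1e-6

    def test_zero_weight_leaves_accumulators_unchanged(self, rng):
        ad = np.zeros((16, 16, 16), complex)
        aw = np.zeros((16, 16, 16))
        s = rng.normal(size=(8, 8)) + 0j
        insert_slice(ad, aw, s, np.eye(3), 0.0)
        assert not ad.any() and not aw.any()

    def test_insertion_is_linear_in_weight(self, rng):
        s = rng.normal(size=(8, 8)) + 1j * rng.normal(size=(8, 8))
        R = euler_to_matrix(30, 60, 10)
        a1 = np.zeros((16, 16, 16), complex)
        w1 = np.zeros((16, 16, 16))
        insert_slice(a1, w1, s, R, 1.0)
        insert_slice(a1, w1, s, R, 1.0)
        a2 = np.zeros((16, 16, 16), complex)
        w2 = np.zeros((16, 16, 16))
        insert_slice(a2, w2, s, R, 2.0)
        np.testing.assert_allclose(a1, a2, atol=1e-12)
        np.testing.assert_allclose(w1, w2, atol=1e-12)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            insert_slice(np.zeros((8, 8), complex), np.zeros((8, 8)),
                         np.zeros((4, 4), complex), 0.0, -1.0)


class TestPhaseShift:
    def test_zero_shift_is_identity(self, rng):
        s = rng.normal(size=(16, 16)) + 1j * rng.normal(size=(16, 16))
        np.testing.assert_array_equal(phase_shift(s, 0, 0), s)

    def test_integer_shift_matches_circular_roll(self, rng):
        from cryolite.fourier import centered_fft, centered_ifft

        img = rng.normal(size=(16, 16))
        shifted = centered_ifft(phase_shift(centered_fft(img), 3, -2)).real
        np.testing.assert_allclose(shifted, np.roll(img, (-2, 3), axis=(0, 1)),
                                   atol=1e-10)

    def test_magnitudes_unchanged(self, rng):
        s = rng.normal(size=(16, 16)) + 1j * rng.normal(size=(16, 16))
        out = phase_shift(s, 0.37, -1.42)
        np.testing.assert_allclose(np.abs(out), np.abs(s), atol=1e-12)


class TestLowpass:
    def test_constant_image_unchanged(self):
        img = np.full((32, 32), 3.5)
        np.testing.assert_allclose(lowpass_filter(img, 8.0, 1.0), img,
                                   atol=1e-10)

    def test_high_frequency_sinusoid_removed(self):
        x = np.arange(32)
        img = 1.0 + np.sin(2 * np.pi * 12 * x / 32)[None, :] * np.ones((32, 1))
        out = lowpass_filter(img, 8.0, 1.0)  # cutoff shell 4, content shell 12
        np.testing.assert_allclose(out, np.full_like(img, img.mean()),
                                   atol=1e-6)

    def test_idempotent_outside_edge_band(self, rng):
        from cryolite.fourier import centered_fft, shell_indices

        img = rng.normal(size=(32, 32))
        once = lowpass_filter(img, 4.0, 1.0)
        twice = lowpass_filter(once, 4.0, 1.0)
        # repeated application only re-attenuates the cosine edge band;
        # spectra away from the edge must agree exactly
        q = np.arange(32) - 16
        r = np.hypot(*np.meshgrid(q, q, indexing="ij"))
        cutoff = 32 / 4.0
        outside_edge = (r <= cutoff) | (r > cutoff + 2)
        d = np.abs(centered_fft(twice) - centered_fft(once))
        assert d[outside_edge].max() < 1e-9 * np.abs(centered_fft(once)).max()

    def test_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError):
            lowpass_filter(np.zeros((16, 16)), 1.5, 1.0)


class TestGoodFftSize:
    def test_powers_of_two_fixed(self):
        assert good_fft_size(4096) == 4096

    def test_4097_rounds_to_4116(self):
        assert good_fft_size(4097) == 4116

    def test_agrees_with_brute_force(self):
        def smooth(m):
            for p in (2, 3, 5, 7):
                while m % p == 0:
                    m //= p
            return m == 1

        for n in range(1, 2000):
            m = good_fft_size(n)
            assert m >= n and smooth(m)
            assert all(not smooth(k) for k in range(n, m))

    def test_idempotent(self):
        for n in (1, 17, 97, 1013):
            m = good_fft_size(n)
            assert good_fft_size(m) == m


def test_hermitian_symmetry_of_real_map_slices(phantom32_ft):
    sl = extract_slice(phantom32_ft, euler_to_matrix(25, 70, 110)).data
    D = 32
    # compare F(q) with conj(F(-q)) away from the asymmetric Nyquist edge
    inner = sl[1:, 1:]
    mirrored = np.conj(inner[::-1, ::-1])
    assert np.abs(inner - mirrored).max() < 1e-8 * np.abs(inner).max()
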