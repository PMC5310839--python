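"""Probability-weight computation and weighted accumulation (E-step)."""

import numpy as np
import pytest

from cryolite.expectation import (
    Accumulator,
    NoiseModel,
    WeightGrid,
    accumulate,
    diffs_to_weights,
    estep_pass,
    select_significant,
    squared_diff,
)
from cryolite.fourier import (
    centered_fft,
    extract_slice,
    insert_slice,
    oversampled_ft,
    shell_indices,
    shift_ramp,
)
from cryolite.geometry import OrientationGrid, euler_to_matrix, make_inplane_grid
from cryolite.simulate import default_phantom, render_particles


def brute_force_diff(img_ft, proj_ft, dx, dy, sigma2_pix):
    """Per-pixel loop oracle for the noise-weighted squared difference."""
    D = img_ft.shape[0]
    total = 0.0
    for r in range(D):
        for c in range(D):
            qx, qy = c - D // 2, r - D // 2
            ph = np.exp(-2j * np.pi * (qx * dx + qy * dy) / D)
            d = img_ft[r, c] * ph - proj_ft[r, c]
            total += (abs(d) ** 2) / (2.0 * sigma2_pix[r, c])
    return total


class TestSquaredDiff:
    def test_zero_when_image_equals_projection(self, rng):
        img = rng.normal(size=(8, 8)) + 1j * rng.normal(size=(8, 8))
        noise = NoiseModel(np.ones(5))
        d = squared_diff(img, img, [(0.0, 0.0)], noise)
        assert d[0] == pytest.approx(0.0, abs=1e-10)

    def test_matches_pixel_loop_oracle(self, rng):
        D = 32
        img = (rng.normal(size=(D, D)) + 1j * rng.normal(size=(D, D)))
        proj = (rng.normal(size=(D, D)) + 1j * rng.normal(size=(D, D)))
        noise = NoiseModel(rng.uniform(0.5, 2.0, D // 2 + 1))
        s2 = noise.sigma2[shell_indices(D, 2)]
        for trans in [(0.0, 0.0), (1.0, -2.0), (0.5, 0.25)]:
            got = squared_diff(img, proj, [trans], noise)[0]
            want = brute_force_diff(img, proj, trans[0], trans[1], s2)
            assert got == pytest.approx(want, rel=1e-5)

    def test_scaling_noise_variance_scales_inversely(self, rng):
        img = rng.normal(size=(8, 8)) + 0j
        proj = rng.normal(size=(8, 8)) + 0j
        d1 = squared_diff(img, proj, [(0, 0)], NoiseModel(np.ones(5)))
        d2 = squared_diff(img, proj, [(0, 0)], NoiseModel(np.full(5, 4.0)))
        assert d2[0] == pytest.approx(d1[0] / 4.0, rel=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            squared_diff(np.zeros((8, 8), complex), np.zeros((6, 6), complex),
                         [(0, 0)], NoiseModel(np.ones(5)))


class TestDiffsToWeights:
    def test_equal_diffs_uniform_priors_give_uniform_weights(self):
        w = diffs_to_weights(np.full((2, 3, 4), 7.0)).weights
        np.testing.assert_allclose(w, 1.0 / 24, atol=1e-12)

    def test_dominant_hypothesis_takes_all_mass(self):
        diffs = np.full((1, 10, 1), 100.0)
        diffs[0, 3, 0] = 50.0
        w = diffs_to_weights(diffs).weights
        others = np.delete(w.ravel(), 3)
        assert w[0, 3, 0] == pytest.approx(1.0, abs=1e-12)
        assert (others < 1e-20).all()

    def test_matches_extended_precision_softmax(self, rng):
        diffs = rng.uniform(0, 60, size=(10, 10, 10))
        w = diffs_to_weights(diffs).weights
        ld = np.asarray(diffs, dtype=np.longdouble)
        expect = np.exp(-(ld - ld.min()))
        expect /= expect.sum()
        np.testing.assert_allclose(w, expect.astype(float), rtol=1e-10)

    def test_priors_must_be_valid(self):
        with pytest.raises(ValueError):
            diffs_to_weights(np.zeros((2, 1, 1)), class_priors=[0.0, 0.0])


class TestSelectSignificant:
    def test_single_dominant_weight(self):
        w = np.full(100, 0.0005 / 99)
        w[42] = 0.9995
        grid = WeightGrid(weights=(w / w.sum()).reshape(1, 100, 1))
        sel = select_significant(grid, 0.999)
        assert list(sel) == [42]

    def test_uniform_with_full_mass_selects_all(self):
        grid = WeightGrid(weights=np.full((1, 5, 2), 0.1))
        assert len(select_significant(grid, 1.0)) == 10

    def test_matches_sort_and_scan_oracle(self, rng):
        w = rng.dirichlet(np.ones(60)).reshape(3, 5, 4)
        sel = select_significant(WeightGrid(weights=w), 0.95)
        flat = w.ravel()
        order = np.argsort(-flat, kind="stable")
        csum = np.cumsum(flat[order])
        n = np.searchsorted(csum, 0.95 - 1e-12) + 1
        assert set(sel) == set(order[:n])


class TestAccumulate:
    def test_unit_weight_equals_single_insert(self, rng):
        D = 16
        img = rng.normal(size=(D, D)) + 1j * rng.normal(size=(D, D))
        noise = NoiseModel(np.ones(D // 2 + 1))
        ang = np.array([20.0, 40.0, 60.0])
        acc = Accumulator(n_classes=1, grid_size=2 * D, ndim=3, src_size=D)
        accumulate(img, [(0, ang, (1.0, -1.0), 1.0)], acc, noise)
        ad = np.zeros((2 * D,) * 3, complex)
        aw = np.zeros((2 * D,) * 3)
        shifted = img * shift_ramp(D, 1.0, -1.0)
        insert_slice(ad, aw, shifted, euler_to_matrix(*ang), 1.0,
                     oversample=True)
        np.testing.assert_allclose(acc.data[0], ad, atol=1e-9)
        np.testing.assert_allclose(acc.weight[0], aw, atol=1e-12)
        assert acc.class_sums[0] == pytest.approx(1.0)

    def test_two_particles_accumulate_additively(self, rng):
        D = 16
        noise = NoiseModel(np.ones(D // 2 + 1))
        ang = np.array([0.0, 30.0, 0.0])
        imgs = [rng.normal(size=(D, D)) + 0j for _ in range(2)]
        both = Accumulator(n_classes=1, grid_size=2 * D, ndim=3, src_size=D)
        for img in imgs:
            accumulate(img, [(0, ang, (0.0, 0.0), 1.0)], both, noise)
        single = [Accumulator(n_classes=1, grid_size=2 * D, ndim=3, src_size=D)
                  for _ in range(2)]
        for img, acc in zip(imgs, single):
            accumulate(img, [(0, ang, (0.0, 0.0), 1.0)], acc, noise)
        np.testing.assert_allclose(both.data[0],
                                   single[0].data[0] + single[1].data[0],
                                   atol=1e-9)
        assert both.n_particles == 2

    def test_mass_conservation_per_particle(self, rng):
        D = 16
        noise = NoiseModel(np.ones(D // 2 + 1))
        entries = [(0, np.array([0.0, 0.0, a]), (0.0, 0.0), w)
                   for a, w in [(0, 0.6), (45, 0.3), (90, 0.1)]]
        acc = Accumulator(n_classes=1, grid_size=2 * D, ndim=2, src_size=D)
        accumulate(rng.normal(size=(D, D)) + 0j, entries, acc, noise)
        assert acc.class_sums.sum() == pytest.approx(1.0, abs=1e-12)


class TestEstepPass:
    def _stack(self, n, D=24, noise_sigma=0.0, mode="inplane", seed=5):
        ph = default_phantom(D)
        stack, truth = render_particles(ph, n, noise_sigma=noise_sigma,
                                        orientation_mode=mode, seed=seed)
        imgs_ft = np.stack([centered_fft(i.astype(float))
                            for i in stack.data]).astype(np.complex64)
        return ph, imgs_ft, truth

    def test_single_hypothesis_gets_unit_weight(self, rng):
        D = 16
        img = rng.normal(size=(D, D)).astype(float)
        ref = oversampled_ft(img)
        grid = OrientationGrid(np.array([[0.0, 0.0, 0.0]]), angular_step=15.0)
        noise = NoiseModel(np.ones(D // 2 + 1))
        acc, assign, ll = estep_pass(
            centered_fft(img)[None].astype(np.complex64), [ref], grid, noise,
            fine_factor=1)
        assert assign["max_weight"][0] == pytest.approx(1.0)

    def test_noise_free_particles_recover_grid_orientation(self):
        D = 24
        ph = default_phantom(D)
        psis = make_inplane_grid(30.0)
        orientations = np.column_stack(
            [np.zeros(6), np.zeros(6), psis[[0, 2, 4, 6, 8, 10]]])
        stack, truth = render_particles(ph, 6, orientations=orientations,
                                        seed=7)
        imgs_ft = np.stack([centered_fft(i.astype(float))
                            for i in stack.data]).astype(np.complex64)
        ref2d = oversampled_ft(ph.data.sum(axis=0))
        grid = OrientationGrid(
            np.column_stack([np.zeros_like(psis), np.zeros_like(psis), psis]),
            angular_step=30.0)
        noise = NoiseModel.from_stack(imgs_ft)
        acc, assign, ll = estep_pass(imgs_ft, [ref2d], grid, noise,
                                     fine_factor=1)
        np.testing.assert_allclose(assign["psi"], orientations[:, 2],
                                   atol=1e-6)
        assert (assign["max_weight"] > 0.999).all()

    def test_fine_pass_never_worse_than_coarse(self):
        ph, imgs_ft, _ = self._stack(8, noise_sigma=1.0)
        ref2d = oversampled_ft(ph.data.sum(axis=0))
        psis = make_inplane_grid(30.0)
        grid = OrientationGrid(
            np.column_stack([np.zeros_like(psis), np.zeros_like(psis), psis]),
            angular_step=30.0)
        noise = NoiseModel.from_stack(imgs_ft)
        _, coarse, _ = estep_pass(imgs_ft, [ref2d], grid, noise, fine_factor=1)
        _, fine, _ = estep_pass(imgs_ft, [ref2d], grid, noise, fine_factor=2)
        assert (fine["best_diff"] <= coarse["best_diff"] + 1e-3).all()

    def test_weight_normalisation_enforced(self):
        with pytest.raises(ValueError):
            WeightGrid(weights=np.full((1, 2, 1), 0.7))
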