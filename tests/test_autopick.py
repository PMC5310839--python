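"""Template matching, peak search, and pick evaluation."""

import numpy as np
import pytest
from scipy import ndimage

from cryolite.autopick import (
    PickSet,
    RValueMap,
    TemplatePicker,
    evaluate_picks,
    filtered_vs_unfiltered_overlap,
    pick_peaks,
    rvalue_map,
)
from cryolite.simulate import default_phantom, render_micrograph, render_particles


def _template(D=24, seed=0):
    ph = default_phantom(D)
    stack, _ = render_particles(ph, 1, orientations=np.array([[0., 0., 0.]]),
                                seed=seed)
    return stack.data[0]


def direct_masked_ncc(mic, tmpl, cx, cy):
    """Spatial-domain locally normalised correlation at one position."""
    h = tmpl.shape[0]
    c = (h - 1) / 2.0
    yy, xx = np.mgrid[:h, :h]
    mask = ((xx - c) ** 2 + (yy - c) ** 2) <= (h / 2.0 - 1) ** 2
    # the FFT path scores the patch whose start is (cy, cx) - (h-1)//2
    patch = np.zeros((h, h))
    ys, xs = cy - (h - 1) // 2, cx - (h - 1) // 2
    for r in range(h):
        for col in range(h):
            rr, cc = ys + r, xs + col
            if 0 <= rr < mic.shape[0] and 0 <= cc < mic.shape[1]:
                patch[r, col] = mic[rr, cc]
    t = tmpl * mask
    t = t - mask * t.sum() / mask.sum()
    tn = t / np.sqrt((t ** 2).sum())
    pm = patch[mask]
    var = pm.var()
    if var <= 0:
        return 0.0
    return float((tn * patch).sum() / np.sqrt(var * mask.sum()))


class TestRValueMap:
    def test_fft_equals_direct_spatial_correlation(self, rng):
        mic = rng.normal(size=(64, 64))
        tmpl = _template(16)
        rmap = rvalue_map(mic, tmpl, angular_step=360.0)
        for cy, cx in [(20, 20), (32, 40), (10, 50)]:
            want = direct_masked_ncc(mic, tmpl, cx, cy)
            assert rmap.scores[cy, cx] == pytest.approx(want, abs=1e-4)

    def test_embedded_template_found_at_its_location(self):
        tmpl = _template(24)
        mic = np.zeros((128, 128))
        x0, y0 = 40, 70  # template center
        mic[y0 - 12:y0 + 12, x0 - 12:x0 + 12] = tmpl
        rmap = rvalue_map(mic, tmpl, angular_step=360.0)
        yy, xx = np.unravel_index(np.argmax(rmap.scores), rmap.scores.shape)
        assert abs(xx - x0) <= 1 and abs(yy - y0) <= 1

    def test_rotated_copy_found_when_rotation_sampled(self):
        tmpl = _template(24)
        rot = ndimage.rotate(tmpl, 90, reshape=False, order=1)
        mic = np.zeros((160, 160))
        mic[28:52, 28:52] = tmpl
        mic[98:122, 98:122] = rot
        rmap = rvalue_map(mic, tmpl, angular_step=90.0)
        picks = pick_peaks(rmap, threshold=0.5, min_dist_px=20)
        got = {(round(x), round(y)) for x, y in zip(picks.x[:2], picks.y[:2])}
        want_centers = {(39, 39), (109, 109)}
        assert all(min(abs(gx - wx) + abs(gy - wy)
                       for wx, wy in want_centers) <= 2 for gx, gy in got)

    def test_max_over_rotations_dominates_single_rotation(self, rng):
        mic = rng.normal(size=(48, 48))
        tmpl = _template(16)
        multi = rvalue_map(mic, tmpl, angular_step=90.0)
        single = rvalue_map(mic, tmpl, angular_step=360.0)
        assert (multi.scores >= single.scores - 1e-6).all()

    def test_invariant_to_constant_offset(self, rng):
        mic = rng.normal(size=(48, 48))
        tmpl = _template(16)
        a = rvalue_map(mic, tmpl, angular_step=360.0).scores
        b = rvalue_map(mic + 100.0, tmpl, angular_step=360.0).scores
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_template_larger_than_micrograph_rejected(self):
        with pytest.raises(ValueError):
            rvalue_map(np.zeros((16, 16)), np.zeros((32, 32)))


class TestPickPeaks:
    def test_single_peak_above_threshold(self):
        s = np.zeros((32, 32))
        s[10, 20] = 0.9
        picks = pick_peaks(RValueMap(scores=s), threshold=0.5, min_dist_px=5)
        assert len(picks) == 1
        assert (picks.x[0], picks.y[0]) == (20.0, 10.0)

    def test_equal_maxima_within_min_dist_keep_lower_index(self):
        s = np.zeros((32, 32))
        s[10, 10] = 0.8
        s[10, 13] = 0.8
        picks = pick_peaks(RValueMap(scores=s), threshold=0.5, min_dist_px=5)
        assert len(picks) == 1
        assert picks.x[0] == 10.0  # flat-index tie-break

    def test_matches_greedy_suppression_oracle(self, rng):
        s = rng.uniform(0, 1, size=(64, 64))
        rmap = RValueMap(scores=s)
        picks = pick_peaks(rmap, threshold=0.6, min_dist_px=6)
        # oracle: exhaustive greedy over local maxima
        lm = (s >= ndimage.maximum_filter(s, size=3, mode="nearest"))
        cand = [(-(s[y, x]), y * 64 + x, x, y)
                for y, x in zip(*np.nonzero(lm & (s >= 0.6)))]
        cand.sort()
        kept = []
        for _, _, x, y in cand:
            if all((x - kx) ** 2 + (y - ky) ** 2 >= 36 for kx, ky in kept):
                kept.append((x, y))
        assert list(zip(picks.x, picks.y)) == [(float(x), float(y))
                                               for x, y in kept]

    def test_no_two_picks_within_min_dist(self, rng):
        s = rng.uniform(0, 1, size=(48, 48))
        picks = pick_peaks(RValueMap(scores=s), threshold=0.3, min_dist_px=7)
        pts = picks.coords()
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                assert np.hypot(*(pts[i] - pts[j])) >= 7

    def test_empty_result_allowed(self):
        picks = pick_peaks(RValueMap(scores=np.zeros((8, 8))), 0.5, 3)
        assert len(picks) == 0


class TestEvaluatePicks:
    def test_perfect_picks(self):
        ref = PickSet(x=np.array([5.0, 50.0]), y=np.array([5.0, 50.0]),
                      score=np.zeros(2))
        res = evaluate_picks(ref, ref, cutoff_px=35)
        assert res["recall"] == 1.0 and res["fdr"] == 0.0

    def test_forced_half_recall_half_fdr(self):
        ref = PickSet(x=np.array([0.0, 100.0]), y=np.array([0.0, 100.0]),
                      score=np.zeros(2))
        picked = PickSet(x=np.array([10.0, 300.0]), y=np.array([0.0, 300.0]),
                         score=np.zeros(2))
        res = evaluate_picks(picked, ref, cutoff_px=35)
        assert res["recall"] == 0.5 and res["fdr"] == 0.5

    def test_greedy_matches_optimal_assignment_for_separated_points(self, rng):
        from scipy.optimize import linear_sum_assignment

        for _ in range(5):
            ref = rng.uniform(0, 500, size=(8, 2))
            jitter = rng.uniform(-5, 5, size=(8, 2))
            picked = ref + jitter
            res = evaluate_picks(
                PickSet(x=picked[:, 0], y=picked[:, 1], score=np.zeros(8)),
                PickSet(x=ref[:, 0], y=ref[:, 1], score=np.zeros(8)),
                cutoff_px=35)
            d = np.sqrt(((picked[:, None] - ref[None]) ** 2).sum(-1))
            rows, cols = linear_sum_assignment(d)
            optimal = {(int(r), int(c)) for r, c in zip(rows, cols)
                       if d[r, c] <= 35}
            got = {(i, j) for i, j, _ in res["matches"]}
            assert got == optimal

    def test_empty_picked_gives_nan_fdr(self):
        ref = PickSet(x=np.array([1.0]), y=np.array([1.0]), score=np.zeros(1))
        res = evaluate_picks(PickSet(), ref)
        assert res["recall"] == 0.0 and np.isnan(res["fdr"])

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            evaluate_picks(PickSet(), PickSet())


class TestEndToEnd:
    def test_noise_free_overlap_is_perfect(self):
        tmpl = _template(24)
        mic, truth = render_micrograph(tmpl[None], size=(200, 200),
                                       n_particles=4, noise_sigma=0.0, seed=2)
        ov = filtered_vs_unfiltered_overlap(mic, tmpl[None], lowpass_A=8.0,
                                            angular_step=360.0, threshold=0.4,
                                            min_dist_px=20)
        assert ov == 1.0

    def test_picker_estimator_recovers_embedded_particles(self):
        tmpl = _template(24)
        mic, truth = render_micrograph(tmpl[None], size=(256, 256),
                                       n_particles=6, noise_sigma=0.0, seed=5)
        picker = TemplatePicker(templates=tmpl[None], threshold=0.5,
                                min_dist_px=20, angular_step=360.0)
        picks = picker.pick(mic)
        from cryolite.io import star_to_index

        ref = PickSet(x=star_to_index(truth.df["rlnCoordinateX"].to_numpy()),
                      y=star_to_index(truth.df["rlnCoordinateY"].to_numpy()),
                      score=np.zeros(len(truth)))
        res = evaluate_picks(picks, ref, cutoff_px=5)
        assert res["recall"] == 1.0 and res["fdr"] == 0.0
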