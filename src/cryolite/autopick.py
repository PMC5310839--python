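"""Template-based semi-automated particle picking.

A micrograph is optionally low-pass filtered and downscaled to the
resolution limit of the templates (discarding high frequencies shrinks the
FFTs that dominate the cost), then cross-correlated against every template
at every in-plane rotation.  The per-pixel score is a locally normalised
cross-correlation: templates are made zero-mean and unit-norm under a
circular mask, and the micrograph's local mean and variance under the same
mask are obtained with FFT box filters.  The maximum over templates and
rotations forms the score map (the pick probability map); a greedy
non-maximum-suppression peak search turns it into particle coordinates.

FFT working sizes are padded to 7-smooth integers (:func:`good_fft_size`)
to avoid the large-prime-factor penalty of FFT implementations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator

from .fourier import good_fft_size, lowpass_filter
from .geometry import make_inplane_grid
from .io import ImageStack

__all__ = [
    "RValueMap",
    "PickSet",
    "rvalue_map",
    "pick_peaks",
    "evaluate_picks",
    "filtered_vs_unfiltered_overlap",
    "TemplatePicker",
]


@dataclass
class RValueMap:
    """Per-pixel best template-match score for one micrograph."""

    scores: np.ndarray
    scale: int = 1                      # downscale factor to original pixels
    best_template: np.ndarray | None = None
    best_rotation: np.ndarray | None = None
    border_px: int = 0                  # exclusion zone (map pixels)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("score map contains non-finite values")


@dataclass
class PickSet:
    """Picked coordinates in original-micrograph pixels, scores descending."""

    x: np.ndarray = field(default_factory=lambda: np.empty(0))
    y: np.ndarray = field(default_factory=lambda: np.empty(0))
    score: np.ndarray = field(default_factory=lambda: np.empty(0))
    template: np.ndarray | None = None
    rotation: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.x)

    def coords(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


def _fourier_downscale(img: np.ndarray, factor: int) -> np.ndarray:
    """Downscale by cropping the centered Fourier transform (band-limited).

    The image is first trimmed to a multiple of ``factor`` so downsampled
    pixel ``j`` corresponds exactly to original pixel ``j * factor``.
    """
    if factor <= 1:
        return img
    from .fourier import centered_fft, centered_ifft

    h, w = img.shape
    nh, nw = h // factor, w // factor
    img = img[: nh * factor, : nw * factor]
    F = centered_fft(img)
    lo_h = nh * factor // 2 - nh // 2
    lo_w = nw * factor // 2 - nw // 2
    Fc = F[lo_h:lo_h + nh, lo_w:lo_w + nw]
    return centered_ifft(Fc).real * (nh * nw) / (img.shape[0] * img.shape[1])


def _circular_mask(size: int) -> np.ndarray:
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[:size, :size]
    return ((xx - c) ** 2 + (yy - c) ** 2) <= (size / 2.0 - 1) ** 2


def _correlate_full(mic_F, kernel, fshape):
    """FFT cross-correlation; returns the 'full' linear correlation map."""
    K = np.fft.rfft2(kernel[::-1, ::-1], fshape)
    return np.fft.irfft2(mic_F * K, fshape)


def rvalue_map(
    micrograph: np.ndarray,
    templates,
    pixel_size: float = 1.0,
    angular_step: float = 5.0,
    lowpass_A: float | None = None,
) -> RValueMap:
    """Locally normalised template-match score map of a micrograph.

    The map's maximum over all templates and in-plane rotations is stored
    per pixel, together with which template/rotation produced it.
    """
    mic = np.asarray(micrograph, dtype=float)
    tmpl = templates.data if isinstance(templates, ImageStack) else np.asarray(templates)
    if tmpl.ndim == 2:
        tmpl = tmpl[None]
    if tmpl.shape[1] != tmpl.shape[2]:
        raise ValueError("templates must be square")
    if tmpl.shape[1] > min(mic.shape):
        raise ValueError("template larger than micrograph")
    if angular_step <= 0:
        raise ValueError("angular_step must be positive")

    scale = 1
    if lowpass_A is not None:
        mic = lowpass_filter(mic, lowpass_A, pixel_size)
        scale = max(1, int(lowpass_A / (2.0 * pixel_size)))
        scale = min(scale, tmpl.shape[1] // 8) if tmpl.shape[1] >= 16 else 1
        scale = max(1, scale)
        if scale > 1:
            mic = _fourier_downscale(mic, scale)
            tmpl = np.stack([
                _fourier_downscale(
                    lowpass_filter(t, lowpass_A, pixel_size), scale)
                for t in tmpl
            ])

    mic = mic - mic.mean()  # makes zero-padding neutral at the borders
    H, W = mic.shape
    h = tmpl.shape[1]
    mask = _circular_mask(h).astype(float)
    n_mask = mask.sum()
    fshape = (good_fft_size(H + h - 1), good_fft_size(W + h - 1))
    mic_F = np.fft.rfft2(mic, fshape)
    mic2_F = np.fft.rfft2(mic * mic, fshape)

    # local first and second moments of the micrograph under the mask
    local_sum = _correlate_full(mic_F, mask, fshape)
    local_sum2 = _correlate_full(mic2_F, mask, fshape)
    local_var = local_sum2 / n_mask - (local_sum / n_mask) ** 2
    local_norm = np.sqrt(np.maximum(local_var, 1e-12) * n_mask)

    rotations = make_inplane_grid(angular_step)
    best = np.full(fshape, -np.inf)
    best_t = np.zeros(fshape, dtype=np.int16)
    best_r = np.zeros(fshape, dtype=np.int16)
    for ti, t in enumerate(tmpl):
        for ri, ang in enumerate(rotations):
            rt = ndimage.rotate(t, ang, reshape=False, order=1, mode="constant")
            rt = rt * mask
            rt -= mask * rt.sum() / n_mask
            norm = np.sqrt((rt ** 2).sum())
            if norm < 1e-12:
                continue
            cc = _correlate_full(mic_F, rt / norm, fshape) / local_norm
            better = cc > best
            best[better] = cc[better]
            best_t[better] = ti
            best_r[better] = ri
    # center-aligned crop: score at (y, x) corresponds to the template
    # centered on micrograph pixel (y, x)
    off = h - 1 - (h - 1) // 2
    sl = (slice(off, off + H), slice(off, off + W))
    return RValueMap(scores=best[sl], scale=scale,
                     best_template=best_t[sl], best_rotation=best_r[sl],
                     border_px=h // 2)


def pick_peaks(rmap: RValueMap, threshold: float, min_dist_px: float) -> PickSet:
    """Greedy peak search with non-maximum suppression.

    Local maxima scoring at least ``threshold`` are accepted in descending
    score order (ties resolved toward the lower flat index); any later peak
    within ``min_dist_px`` (original pixels) of an accepted one is
    suppressed.  Coordinates are returned in the original pixel frame.
    """
    if min_dist_px < 1:
        raise ValueError("min_dist_px must be >= 1")
    s = rmap.scores
    local_max = s >= ndimage.maximum_filter(s, size=3, mode="nearest")
    ok = local_max & (s >= threshold)
    b = rmap.border_px
    if b > 0:  # particle centers need full template support
        ok[:b, :] = ok[-b:, :] = False
        ok[:, :b] = ok[:, -b:] = False
    cand = np.nonzero(ok)
    scores = s[cand]
    order = np.argsort(-scores, kind="stable")
    ys, xs = cand[0][order], cand[1][order]
    scores = scores[order]

    min_d_ds = min_dist_px / rmap.scale
    keep_x, keep_y, keep_s, keep_t, keep_r = [], [], [], [], []
    for x, y, sc in zip(xs, ys, scores):
        ok = True
        for px_, py_ in zip(keep_x, keep_y):
            if (x - px_) ** 2 + (y - py_) ** 2 < min_d_ds ** 2:
                ok = False
                break
        if ok:
            keep_x.append(x)
            keep_y.append(y)
            keep_s.append(sc)
            if rmap.best_template is not None:
                keep_t.append(rmap.best_template[y, x])
                keep_r.append(rmap.best_rotation[y, x])
    f = float(rmap.scale)
    return PickSet(
        x=np.asarray(keep_x, float) * f,
        y=np.asarray(keep_y, float) * f,
        score=np.asarray(keep_s, float),
        template=np.asarray(keep_t) if keep_t else None,
        rotation=np.asarray(keep_r) if keep_r else None,
    )


def evaluate_picks(picked: PickSet, reference: PickSet,
                   cutoff_px: float = 35.0) -> dict:
    """Recall and false-discovery rate of picks against reference coordinates.

    Matching is one-to-one and greedy by ascending distance within
    ``cutoff_px``; recall is matched/|reference| and FDR is
    (|picked| - matched)/|picked| (NaN when nothing was picked).
    """
    if cutoff_px <= 0:
        raise ValueError("cutoff must be positive")
    if len(reference) == 0:
        raise ValueError("reference pick set is empty")
    if len(picked) == 0:
        return {"recall": 0.0, "fdr": float("nan"), "matches": [],
                "n_matched": 0}
    pc, rc = picked.coords(), reference.coords()
    d = np.sqrt(((pc[:, None, :] - rc[None, :, :]) ** 2).sum(axis=2))
    pairs = [(d[i, j], i, j) for i in range(len(pc)) for j in range(len(rc))
             if d[i, j] <= cutoff_px]
    pairs.sort()
    used_p, used_r, matches = set(), set(), []
    for dist, i, j in pairs:
        if i in used_p or j in used_r:
            continue
        used_p.add(i)
        used_r.add(j)
        matches.append((i, j, dist))
    n = len(matches)
    return {
        "recall": n / len(rc),
        "fdr": (len(pc) - n) / len(pc),
        "matches": matches,
        "n_matched": n,
    }


def filtered_vs_unfiltered_overlap(
    micrograph,
    templates,
    pixel_size: float = 1.0,
    lowpass_A: float = 20.0,
    angular_step: float = 5.0,
    threshold: float = 0.3,
    min_dist_px: float = 20.0,
    cutoff_px: float | None = None,
    top_n: int | None = None,
) -> float:
    """Fraction of picks shared by filtered and unfiltered picking.

    Runs the full pick pipeline twice (with and without low-pass filtering
    plus downscaling) and reports matched picks within ``cutoff_px``
    (default: ``min_dist_px``) divided by the larger pick count.
    """
    cutoff = cutoff_px if cutoff_px is not None else min_dist_px
    picks = []
    for lp in (lowpass_A, None):
        rm = rvalue_map(micrograph, templates, pixel_size=pixel_size,
                        angular_step=angular_step, lowpass_A=lp)
        ps = pick_peaks(rm, threshold, min_dist_px)
        if top_n is not None and len(ps) > top_n:
            ps = PickSet(x=ps.x[:top_n], y=ps.y[:top_n], score=ps.score[:top_n])
        picks.append(ps)
    a, b = picks
    if len(a) == 0 and len(b) == 0:
        warnings.warn("no picks in either run; overlap undefined, returning 0")
        return 0.0
    if len(a) == 0 or len(b) == 0:
        return 0.0
    res = evaluate_picks(a, b if len(b) else a, cutoff_px=cutoff)
    return res["n_matched"] / max(len(a), len(b))


class TemplatePicker(BaseEstimator):
    """Estimator-style front end for template picking.

    Parameters mirror :func:`rvalue_map` and :func:`pick_peaks`; call
    :meth:`pick` per micrograph.
    """

    def __init__(self, templates=None, pixel_size=1.0, angular_step=5.0,
                 lowpass_A=None, threshold=0.3, min_dist_px=20.0):
        self.templates = templates
        self.pixel_size = pixel_size
        self.angular_step = angular_step
        self.lowpass_A = lowpass_A
        self.threshold = threshold
        self.min_dist_px = min_dist_px

    def fit(self, X=None, y=None):
        if self.templates is None:
            raise ValueError("TemplatePicker needs templates")
        return self

    def pick(self, micrograph) -> PickSet:
        self.fit()
        rmap = rvalue_map(micrograph, self.templates,
                          pixel_size=self.pixel_size,
                          angular_step=self.angular_step,
                          lowpass_A=self.lowpass_A)
        self.rvalue_map_ = rmap
        return pick_peaks(rmap, self.threshold, self.min_dist_px)
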