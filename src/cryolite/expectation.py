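"""The expectation step of regularised-likelihood refinement.

For every particle, squared differences between its Fourier transform and
reference projections are evaluated over all classes, orientations and
translations, under a Gaussian noise model with per-resolution-shell
variance ``sigma2``:

    diff(k, i, t) = sum_pixels |shift(X, t) - P_{k,i}|^2 / (2 sigma2_shell)

Differences become posterior probability weights through a max-subtracted
softmax with class priors; the smallest set of hypotheses carrying a fixed
probability mass (default 0.999) is kept "significant"; the search then
re-examines a locally refined grid around those hypotheses before the
weighted particle images are back-projected into per-class accumulators.

The heavy arithmetic runs in single precision (complex64 inner products via
BLAS); all accumulators are double precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fourier import (
    FourierVolume,
    extract_slices_batch,
    insert_slice,
    radial_shell_average,
    shell_indices,
    shift_ramp,
)
from .geometry import OrientationGrid, euler_to_matrix, refine_grid

__all__ = [
    "NoiseModel",
    "WeightGrid",
    "Accumulator",
    "squared_diff",
    "diffs_to_weights",
    "select_significant",
    "accumulate",
    "estep_pass",
]


# ---------------------------------------------------------------------------
# noise model
# ---------------------------------------------------------------------------


@dataclass
class NoiseModel:
    """Per-shell Gaussian noise variance in Fourier intensity units.

    ``sigma2[s]`` is the variance of each of the two (real/imaginary)
    components of a Fourier pixel in resolution shell ``s``; there are
    ``D // 2 + 1`` shells for images of size ``D``.
    """

    sigma2: np.ndarray

    def __post_init__(self) -> None:
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        if np.any(self.sigma2 <= 0) or not np.all(np.isfinite(self.sigma2)):
            raise ValueError("sigma2 must be positive and finite in every shell")

    @property
    def n_shells(self) -> int:
        return len(self.sigma2)

    def pixel_sigma2(self, D: int) -> np.ndarray:
        """sigma2 mapped onto the centered D x D Fourier plane (flattened)."""
        return self.sigma2[shell_indices(D, 2).ravel()]

    @classmethod
    def from_stack(cls, imgs_ft: np.ndarray, floor: float = 1e-10,
                   rel_floor: float = 1e-5) -> "NoiseModel":
        """Initialise from the power spectrum of (particle - mean particle).

        Shells are floored at ``rel_floor`` times the strongest shell so that
        (near-)noise-free data cannot produce quasi-infinite weights.
        """
        imgs_ft = np.asarray(imgs_ft)
        res = imgs_ft - imgs_ft.mean(axis=0, keepdims=True)
        power = (np.abs(res) ** 2).mean(axis=0) / 2.0
        shells = radial_shell_average(power)
        return cls(sigma2=np.maximum(shells,
                                     max(floor, rel_floor * shells.max())))


@dataclass
class WeightGrid:
    """Normalised posterior weights over (class, orientation, translation)."""

    weights: np.ndarray  # shape (K, M, T)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        total = self.weights.sum()
        if not np.isfinite(total) or abs(total - 1.0) > 1e-6:
            raise ValueError(f"weights must sum to 1, got {total}")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")


# ---------------------------------------------------------------------------
# difference and weight computations
# ---------------------------------------------------------------------------


def squared_diff(img_ft: np.ndarray, proj_ft, translations,
                 noise: NoiseModel) -> np.ndarray:
    """Noise-weighted squared difference per translation.

    ``diff[t] = sum |shift(img, t) - proj|^2 / (2 sigma2_shell)`` over the
    centered Fourier plane.
    """
    proj = proj_ft.data if hasattr(proj_ft, "data") else np.asarray(proj_ft)
    img_ft = np.asarray(img_ft)
    if img_ft.shape != proj.shape:
        raise ValueError(f"shape mismatch {img_ft.shape} vs {proj.shape}")
    translations = np.atleast_2d(translations)
    if len(translations) == 0:
        raise ValueError("need at least one translation")
    D = img_ft.shape[0]
    w = 1.0 / (2.0 * noise.pixel_sigma2(D))
    out = np.empty(len(translations))
    for t, (dx, dy) in enumerate(translations):
        res = img_ft * shift_ramp(D, dx, dy) - proj
        out[t] = float(((res.real ** 2 + res.imag ** 2).ravel() * w).sum())
    return out


def diffs_to_weights(diffs: np.ndarray, class_priors=None,
                     orientation_prior=None) -> WeightGrid:
    """Convert (K, M, T) squared differences to normalised posterior weights.

    Weights are proportional to ``prior * exp(-(diff - min diff))``; the
    minimum subtraction makes the exponentials overflow-safe.
    """
    diffs = np.asarray(diffs, dtype=float)
    if diffs.ndim != 3:
        diffs = diffs.reshape((1,) * (3 - diffs.ndim) + diffs.shape)
    if not np.all(np.isfinite(diffs)):
        raise ValueError("differences must be finite")
    K = diffs.shape[0]
    if class_priors is None:
        class_priors = np.full(K, 1.0 / K)
    class_priors = np.asarray(class_priors, dtype=float)
    if np.any(class_priors < 0) or class_priors.sum() <= 0:
        raise ValueError("class priors must be non-negative with positive sum")
    logw = -(diffs - diffs.min())
    with np.errstate(divide="ignore"):
        logw += np.log(class_priors)[:, None, None]
    if orientation_prior is not None:
        logw += np.log(np.asarray(orientation_prior))[None, :, None]
    logw -= logw.max()
    w = np.exp(logw)
    return WeightGrid(weights=w / w.sum())


def select_significant(weights, mass: float = 0.999) -> np.ndarray:
    """Flat indices of the smallest weight set with cumulative mass >= mass.

    Ordered by descending weight; ties break deterministically toward the
    lower flat index.
    """
    w = weights.weights if isinstance(weights, WeightGrid) else np.asarray(weights)
    flat = w.ravel()
    order = np.argsort(-flat, kind="stable")
    csum = np.cumsum(flat[order])
    n_keep = int(np.searchsorted(csum, mass * flat.sum() - 1e-12) + 1)
    return order[: min(n_keep, flat.size)]


# ---------------------------------------------------------------------------
# accumulation
# ---------------------------------------------------------------------------


@dataclass
class Accumulator:
    """Double-precision running sums for the maximisation step."""

    n_classes: int
    grid_size: int          # pad * D
    ndim: int               # 2 for class averages, 3 for maps
    src_size: int
    pad: int = 2
    data: np.ndarray = field(init=False)
    weight: np.ndarray = field(init=False)
    sigma2_num: np.ndarray = field(init=False)
    sigma2_den: np.ndarray = field(init=False)
    class_sums: np.ndarray = field(init=False)
    n_particles: int = 0

    def __post_init__(self) -> None:
        shape = (self.n_classes,) + (self.grid_size,) * self.ndim
        self.data = np.zeros(shape, dtype=np.complex128)
        self.weight = np.zeros(shape, dtype=np.float64)
        n_shells = self.src_size // 2 + 1
        self.sigma2_num = np.zeros(n_shells)
        self.sigma2_den = np.zeros(n_shells)
        self.class_sums = np.zeros(self.n_classes)

    def merge(self, other: "Accumulator") -> None:
        self.data += other.data
        self.weight += other.weight
        self.sigma2_num += other.sigma2_num
        self.sigma2_den += other.sigma2_den
        self.class_sums += other.class_sums
        self.n_particles += other.n_particles


def accumulate(img_ft: np.ndarray, entries, acc: Accumulator,
               noise: NoiseModel, projections=None) -> None:
    """Back-project one particle's significant hypotheses into ``acc``.

    ``entries`` is an iterable of ``(k, angles, (dx, dy), weight)`` with
    normalised weights; ``projections`` optionally supplies the matching
    reference slices so that per-shell residuals can feed the noise update.
    """
    D = img_ft.shape[0]
    shells = shell_indices(D, 2).ravel()
    n_shells = acc.src_size // 2 + 1
    npix_shell = np.bincount(shells, minlength=n_shells)
    # group by orientation so each distinct view costs one insertion
    groups: dict = {}
    for j, (k, angles, trans, w) in enumerate(entries):
        if w <= 0:
            continue
        key = (int(k), round(float(angles[0]), 6), round(float(angles[1]), 6),
               round(float(angles[2]), 6))
        groups.setdefault(key, []).append((j, trans, float(w)))
    for (k, rot, tilt, psi), members in groups.items():
        combined = np.zeros((D, D), dtype=np.complex128)
        wsum = 0.0
        for j, trans, w in members:
            shifted = (img_ft * shift_ramp(D, trans[0], trans[1])
                       ).astype(np.complex128)
            combined += w * shifted
            wsum += w
            if projections is not None:
                res = shifted - projections[j]
                p2 = (res.real ** 2 + res.imag ** 2).ravel()
                acc.sigma2_num += w * np.bincount(shells, weights=p2,
                                                  minlength=n_shells)
                acc.sigma2_den += w * 2.0 * npix_shell
        R = euler_to_matrix(rot, tilt, psi) if acc.ndim == 3 else psi
        insert_slice(acc.data[k], acc.weight[k], combined / wsum, R,
                     weight=wsum, pad=acc.pad, oversample=True)
        acc.class_sums[k] += wsum
    acc.n_particles += 1


# ---------------------------------------------------------------------------
# full E-step pass
# ---------------------------------------------------------------------------


def _projection_bank(refs, grid: OrientationGrid, dtype=np.complex64):
    """Slices for every (class, orientation) of a shared grid: (K, M, D*D)."""
    is3d = refs[0].ndim == 3
    if is3d:
        Rs = [euler_to_matrix(*a) for a in grid.angles]
    else:
        Rs = list(grid.angles[:, 2])
    D = refs[0].src_size
    bank = np.empty((len(refs), len(grid), D * D), dtype=dtype)
    for k, ref in enumerate(refs):
        bank[k] = extract_slices_batch(ref, Rs, dtype=dtype).reshape(len(grid), -1)
    return bank


def _grid_diffs(imgs_ft: np.ndarray, bank: np.ndarray, translations,
                noise: NoiseModel, dtype=np.complex64, chunk: int = 64):
    """Squared differences for all particles against a shared projection bank.

    Returns an array of shape (N, K, M, T).
    """
    N, D, _ = imgs_ft.shape
    K, M, _ = bank.shape
    translations = np.atleast_2d(translations)
    T = len(translations)
    real_t = np.float32 if dtype == np.complex64 else np.float64
    s2 = noise.pixel_sigma2(D).astype(real_t)
    w1 = (1.0 / s2)
    w2 = (0.5 * w1)

    B = (bank.conj() * w1[None, None, :]).reshape(K * M, -1)
    c_proj = ((bank.real ** 2 + bank.imag ** 2) * w2[None, None, :]).sum(axis=-1)
    ramps = np.stack(
        [shift_ramp(D, dx, dy).ravel() for dx, dy in translations]
    ).astype(dtype)

    diffs = np.empty((N, K, M, T), dtype=real_t)
    flat_imgs = imgs_ft.reshape(N, -1).astype(dtype)
    c_img = ((flat_imgs.real ** 2 + flat_imgs.imag ** 2) * w2[None, :]).sum(axis=-1)
    for lo in range(0, N, chunk):
        sel = flat_imgs[lo:lo + chunk]
        n = len(sel)
        shifted = (sel[:, None, :] * ramps[None, :, :]).reshape(n * T, -1)
        cross = (shifted @ B.T).real  # (n*T, K*M)
        cross = cross.reshape(n, T, K, M).transpose(0, 2, 3, 1)
        diffs[lo:lo + n] = (
            c_img[lo:lo + n, None, None, None] + c_proj[None, :, :, None] - cross)
    return diffs


def _loglik_proxy(diffs: np.ndarray, class_priors, noise: NoiseModel,
                  D: int) -> float:
    """Sum over particles of log sum_kit prior * exp(-diff), including the
    Gaussian normalisation term, as a monotonicity diagnostic."""
    K = diffs.shape[1]
    logp = np.log(np.maximum(np.asarray(class_priors, float), 1e-300))
    a = -diffs.astype(np.float64) + logp[None, :, None, None]
    amax = a.max(axis=(1, 2, 3), keepdims=True)
    lse = amax[:, 0, 0, 0] + np.log(np.exp(a - amax).sum(axis=(1, 2, 3)))
    const = float(np.log(2.0 * np.pi * noise.pixel_sigma2(D)).sum())
    return float(lse.sum() - diffs.shape[0] * const)


def estep_pass(
    imgs_ft: np.ndarray,
    refs: list[FourierVolume],
    grid: OrientationGrid,
    noise: NoiseModel,
    class_priors=None,
    fine_factor: int = 2,
    significance_mass: float = 0.999,
    dtype=np.complex64,
    local_grids: list[OrientationGrid] | None = None,
    max_refine_orientations: int = 16,
    max_accumulate_entries: int = 64,
) -> tuple[Accumulator, pd.DataFrame, float]:
    """One expectation pass: coarse search, local refinement, accumulation.

    Parameters
    ----------
    imgs_ft : (N, D, D) complex
        Centered Fourier transforms of the particle images.
    refs : list of FourierVolume
        One oversampled reference per class (all 2D or all 3D).
    grid : OrientationGrid
        Shared coarse search grid.  If ``local_grids`` is given (one grid
        per particle) the shared grid is skipped and each particle is
        evaluated on its own neighbourhood (local searches).
    fine_factor : int
        Sampling refinement between the coarse and fine pass; 1 disables
        the second pass.

    Returns
    -------
    (Accumulator, assignments, loglik) where ``assignments`` holds the
    maximum-weight class/orientation/translation per particle and ``loglik``
    the coarse-grid log-likelihood diagnostic.
    """
    if len(refs) == 0:
        raise ValueError("need at least one reference")
    N, D, _ = imgs_ft.shape
    K = len(refs)
    if class_priors is None:
        class_priors = np.full(K, 1.0 / K)
    is3d = refs[0].ndim == 3
    acc = Accumulator(n_classes=K, grid_size=refs[0].grid.shape[0],
                      ndim=refs[0].ndim, src_size=D, pad=refs[0].pad)

    rows = []
    loglik = 0.0

    if local_grids is None:
        bank = _projection_bank(refs, grid, dtype=dtype)
        diffs = _grid_diffs(imgs_ft, bank, grid.translations, noise, dtype=dtype)
        loglik = _loglik_proxy(diffs, class_priors, noise, D)
    else:
        bank = None

    for p in range(N):
        if local_grids is None:
            pgrid = grid
            pdiffs = diffs[p]
        else:
            pgrid = local_grids[p]
            pbank = _projection_bank(refs, pgrid, dtype=dtype)
            pdiffs = _grid_diffs(imgs_ft[p:p + 1], pbank, pgrid.translations,
                                 noise, dtype=dtype)[0]
            loglik += _loglik_proxy(pdiffs[None], class_priors, noise, D)
        wg = diffs_to_weights(pdiffs, class_priors)
        sel = select_significant(wg, significance_mass)

        # refine only once the posterior has localised; a flat posterior
        # (early iterations) gains nothing from denser sampling
        uniq_orients = np.unique(np.unravel_index(sel, wg.weights.shape)[1])
        if fine_factor >= 2 and len(uniq_orients) <= max_refine_orientations:
            Ksel, Msel, Tsel = np.unravel_index(sel, wg.weights.shape)
            fine = refine_grid(pgrid, np.unique(Msel), factor=fine_factor)
            fbank_refs = [refs[k] for k in sorted(set(Ksel))]
            kmap = sorted(set(Ksel))
            fbank = _projection_bank(fbank_refs, fine, dtype=dtype)
            fdiffs_sub = _grid_diffs(imgs_ft[p:p + 1], fbank, fine.translations,
                                     noise, dtype=dtype)[0]
            # embed the refined classes in a full (K, Mf, Tf) grid of +inf
            fdiffs = np.full((K,) + fdiffs_sub.shape[1:], np.inf,
                             dtype=np.float64)
            for j, k in enumerate(kmap):
                fdiffs[k] = fdiffs_sub[j]
            fdiffs[~np.isfinite(fdiffs)] = fdiffs_sub.max() + 50.0
            wg = diffs_to_weights(fdiffs, class_priors)
            sel = select_significant(wg, significance_mass)
            use_grid, use_diffs = fine, fdiffs
            use_bank, use_kmap = fbank, {k: j for j, k in enumerate(kmap)}
        else:
            use_grid, use_diffs = pgrid, pdiffs
            use_bank = bank if bank is not None else pbank
            use_kmap = {k: k for k in range(K)}

        if len(sel) > max_accumulate_entries:
            sel = sel[:max_accumulate_entries]  # already sorted by weight
        Ks, Ms, Ts = np.unravel_index(sel, wg.weights.shape)
        wsel = wg.weights.ravel()[sel]
        wsel = wsel / wsel.sum()
        entries = []
        proj_list = []
        for k, m, t, w in zip(Ks, Ms, Ts, wsel):
            if int(k) not in use_kmap:
                continue  # class dropped before refinement; weight is negligible
            ang = use_grid.angles[m]
            entries.append((int(k), ang, use_grid.translations[t], float(w)))
            proj_list.append(
                use_bank[use_kmap[int(k)], m].reshape(D, D).astype(np.complex128))
        accumulate(imgs_ft[p], entries, acc, noise, projections=proj_list)

        best = int(np.argmax(wsel))
        kb, mb, tb = int(Ks[best]), int(Ms[best]), int(Ts[best])
        ang = use_grid.angles[mb]
        rows.append({
            "class": kb,
            "rot": float(ang[0]), "tilt": float(ang[1]), "psi": float(ang[2]),
            "dx": float(use_grid.translations[tb][0]),
            "dy": float(use_grid.translations[tb][1]),
            "max_weight": float(wsel[best]),
            "best_diff": float(use_diffs[kb, mb, tb]),
        })

    assignments = pd.DataFrame(rows)
    return acc, assignments, loglik
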