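"""The maximisation step: gridding reconstruction and model updates.

Accumulated Fourier-space sums (weighted back-projected slices and their
interpolation weights) are turned into an updated real-space reference by
an iterative weighted-average solve with Wiener-style damping where the
sampling weight vanishes, followed by inverse transform, cropping of the
two-fold padding and division by the interpolation kernel's real-space
window.  Everything here runs in double precision; single-precision
reconstruction is known to drift, which is why the expectation step alone
is allowed to run in float32.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .expectation import Accumulator, NoiseModel
from .fourier import centered_ifft, shell_indices
from .io import MapVolume

__all__ = ["gridding_reconstruct", "update_references", "Reconstruction"]


def _kernel_window(D: int, P: int, ndim: int) -> np.ndarray:
    """Real-space window of the multilinear gridding kernel (sinc^2 per axis),
    evaluated on the cropped D-sized box."""
    x = (np.arange(D) - D // 2) / P
    w1 = np.sinc(x) ** 2
    grids = np.meshgrid(*([w1] * ndim), indexing="ij")
    out = np.ones_like(grids[0])
    for g in grids:
        out = out * g
    return np.maximum(out, 1e-3)


def gridding_reconstruct(
    acc_data: np.ndarray,
    acc_weight: np.ndarray,
    tau2: np.ndarray | None = None,
    n_iter: int = 10,
    pad: int = 2,
    voxel_size: float = 1.0,
    fill_passes: int = 6,
):
    """Solve for the reference transform and return the real-space map.

    The sampled voxels are estimated by Wiener-damped division of the
    accumulated data by the accumulated interpolation weights; voxels the
    slices never reached (angular sampling gaps) are filled by an onion-shell
    neighbourhood average and then relaxed toward the harmonic interpolant of
    their sampled surroundings (``n_iter`` Jacobi sweeps).  The inverse
    transform is cropped from ``pad*D`` to ``D`` and divided by the real-space
    window of the trilinear gridding kernel.  All arithmetic is double
    precision.

    Parameters
    ----------
    acc_data, acc_weight : ndarray
        Accumulated complex data and real sampling weights on the
        ``(pad * D)``-sized grid (2D or 3D).
    tau2 : ndarray, optional
        Per-shell signal power regulariser; where given, poorly sampled
        frequencies are damped by ``1 / tau2`` instead of the default
        small-constant damping.
    n_iter : int
        Relaxation sweeps for the gap interpolant (no-op when the grid has
        no gaps).
    """
    acc_data = np.asarray(acc_data, dtype=np.complex128)
    acc_weight = np.asarray(acc_weight, dtype=np.float64)
    if np.any(acc_weight < 0):
        raise ValueError("sampling weights must be non-negative")
    P = acc_data.shape[0]
    D = P // pad
    ndim = acc_data.ndim

    wmax = acc_weight.max()
    if wmax == 0.0:
        warnings.warn("empty accumulator: returning an all-zero map")
        zero = np.zeros((D,) * ndim)
        return MapVolume(zero, voxel_size) if ndim == 3 else zero

    if tau2 is not None:
        sh = np.minimum(shell_indices(P, ndim) // pad, len(tau2) - 1)
        lam = 1.0 / np.maximum(np.asarray(tau2, float)[sh], 1e-30)
        lam = np.minimum(lam, wmax)  # keep the damping numerically tame
    else:
        lam = wmax * 1e-8

    known = acc_weight > 0
    Fhat = np.where(known, acc_data / (acc_weight + lam), 0.0)

    F = Fhat.copy()
    if not known.all():
        grown = known.copy()
        for _ in range(max(0, fill_passes)):
            if grown.all():
                break
            sm = (ndimage.uniform_filter(F.real, 3)
                  + 1j * ndimage.uniform_filter(F.imag, 3))
            cnt = ndimage.uniform_filter(grown.astype(float), 3)
            fill = sm / np.maximum(cnt, 1e-9)
            F = np.where(known, Fhat, np.where(cnt > 1e-9, fill, F))
            grown |= cnt > 1e-9
        nb = 3 ** ndim - 1
        for _ in range(max(0, n_iter)):
            sm = (ndimage.uniform_filter(F.real, 3)
                  + 1j * ndimage.uniform_filter(F.imag, 3))
            F = np.where(known, Fhat, sm * (3 ** ndim / nb) - F / nb)

    real = centered_ifft(F).real
    lo = P // 2 - D // 2
    sl = tuple(slice(lo, lo + D) for _ in range(ndim))
    cropped = real[sl] / _kernel_window(D, P, ndim)
    if ndim == 3:
        return MapVolume(cropped, voxel_size=voxel_size)
    return cropped


class Reconstruction:
    """An updated reference with optional FSC curve and signal-power spectrum."""

    def __init__(self, map, fsc_halves=None, tau2=None):
        self.map = map
        self.fsc_halves = fsc_halves
        self.tau2 = tau2


def update_references(
    acc: Accumulator,
    tau2: np.ndarray | None = None,
    n_iter: int = 10,
    voxel_size: float = 1.0,
    sigma2_floor: float = 1e-10,
):
    """Reconstruct every class and refresh priors and the noise model.

    Returns ``(references, class_priors, noise)`` where references are
    real-space maps/images, priors are the class occupancies and the noise
    variance is the accumulated per-shell weighted residual mean (floored).
    """
    refs = []
    for k in range(acc.n_classes):
        refs.append(
            gridding_reconstruct(acc.data[k], acc.weight[k], tau2=tau2,
                                 n_iter=n_iter, pad=acc.pad,
                                 voxel_size=voxel_size))
    total = acc.class_sums.sum()
    priors = (acc.class_sums / total if total > 0
              else np.full(acc.n_classes, 1.0 / acc.n_classes))
    den = np.maximum(acc.sigma2_den, 1e-30)
    sigma2 = acc.sigma2_num / den
    rel = 1e-5 * sigma2.max() if sigma2.max() > 0 else 0.0
    sigma2 = np.maximum(sigma2, max(sigma2_floor, rel))
    sigma2[acc.sigma2_den <= 0] = np.maximum(sigma2[acc.sigma2_den > 0].mean()
                                             if np.any(acc.sigma2_den > 0)
                                             else 1.0, sigma2_floor)
    return refs, priors, NoiseModel(sigma2=sigma2)
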