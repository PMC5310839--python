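"""Oversampled Fourier representations and central-slice operations.

A reference map of linear size ``D`` is zero-padded to ``pad * D`` (default
two-fold) before transforming, so that slices through the 3D transform can
be interpolated accurately.  By the central-slice theorem the 2D transform
of a projection along the view axis of rotation ``A`` equals the central
plane of the 3D transform spanned by the first two rows of ``A``; a particle
image of size ``D`` samples that plane at integer multiples of ``pad`` grid
units of the oversampled transform, where trilinear interpolation is cheap
and accurate.

All transforms here are kept in "centered" layout (DC at index ``n // 2``)
via fftshift sandwiches; interpolation indices are relative to that center.
Insertion (:func:`insert_slice`) uses exactly the same interpolation weights
as extraction in scatter form and is therefore the adjoint of
:func:`extract_slice` by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FourierVolume",
    "FourierSlice",
    "centered_fft",
    "centered_ifft",
    "oversampled_ft",
    "extract_slice",
    "insert_slice",
    "slice_to_image",
    "image_to_slice",
    "phase_shift",
    "shift_ramp",
    "lowpass_filter",
    "good_fft_size",
    "shell_indices",
    "radial_shell_average",
]


def centered_fft(a: np.ndarray) -> np.ndarray:
    """FFT with the origin at the array center both in real and Fourier space."""
    return np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(a)))


def centered_ifft(A: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(A)))


@dataclass
class FourierVolume:
    """Oversampled, centered Fourier transform of a real reference.

    ``grid`` is complex with linear size ``pad * src_size`` in 2 (class
    average) or 3 (map) dimensions.
    """

    grid: np.ndarray
    pad: int
    src_size: int
    voxel_size: float = 1.0

    def __post_init__(self) -> None:
        if self.pad < 2:
            raise ValueError("oversampling factor must be >= 2")
        expect = self.pad * self.src_size
        if any(s != expect for s in self.grid.shape):
            raise ValueError(
                f"grid shape {self.grid.shape} inconsistent with pad*D={expect}")

    @property
    def ndim(self) -> int:
        return self.grid.ndim


@dataclass
class FourierSlice:
    """Centered 2D Fourier transform of one projection/reference image."""

    data: np.ndarray
    voxel_size: float = 1.0

    @property
    def size(self) -> int:
        return self.data.shape[-1]


def _pad_centered(a: np.ndarray, P: int) -> np.ndarray:
    out = np.zeros((P,) * a.ndim, dtype=a.dtype)
    sl = tuple(slice(P // 2 - s // 2, P // 2 - s // 2 + s) for s in a.shape)
    out[sl] = a
    return out


def oversampled_ft(map_or_image, pad: int = 2, voxel_size: float | None = None
                   ) -> FourierVolume:
    """Zero-pad a cubic map (or square image) ``pad``-fold and transform it."""
    from .io import MapVolume  # local import to avoid cycle

    if isinstance(map_or_image, MapVolume):
        map_or_image.require_cubic()
        data = map_or_image.data
        voxel_size = map_or_image.voxel_size if voxel_size is None else voxel_size
    else:
        data = np.asarray(map_or_image)
        voxel_size = 1.0 if voxel_size is None else voxel_size
    if data.ndim not in (2, 3):
        raise ValueError("expected a 2D image or 3D map")
    sizes = set(data.shape)
    if len(sizes) != 1:
        raise ValueError(f"reference must be square/cubic, got {data.shape}")
    D = data.shape[0]
    grid = centered_fft(_pad_centered(data.astype(np.float64), pad * D))
    return FourierVolume(grid=grid, pad=pad, src_size=D, voxel_size=voxel_size)


# ---------------------------------------------------------------------------
# slice extraction / insertion
# ---------------------------------------------------------------------------


def _slice_sample_coords(vol: FourierVolume, R: np.ndarray) -> np.ndarray:
    """Oversampled-grid coordinates (last-axis order z,y,x / y,x) of the
    central-plane sample points for a D x D output slice."""
    D, pad = vol.src_size, vol.pad
    q = np.arange(D) - D // 2
    qx, qy = np.meshgrid(q, q, indexing="xy")  # qy varies along rows
    if vol.ndim == 3:
        k = np.stack([qx, qy, np.zeros_like(qx)], axis=-1).reshape(-1, 3)
        pts = k @ np.asarray(R, dtype=float)  # == (R^T k^T)^T: object-frame coords
        return pts[:, ::-1] * pad  # (z, y, x) order
    if np.isscalar(R):
        a = np.radians(R)
        c, s = np.cos(a), np.sin(a)
        M = np.array([[c, -s], [s, c]])
    else:
        M = np.asarray(R, dtype=float)
    k = np.stack([qx, qy], axis=-1).reshape(-1, 2)
    pts = k @ M
    return pts[:, ::-1] * pad  # (y, x)


def _interp_corners(coords: np.ndarray, P: int):
    """Multilinear corners and weights for centered-grid coordinates.

    Returns flat indices into the P^nd grid and weights; out-of-grid corners
    get zero weight (frequencies beyond the stored radius read as zero).
    """
    nd = coords.shape[1]
    g = coords + P // 2
    g0 = np.floor(g).astype(np.int64)
    frac = g - g0
    npts = coords.shape[0]
    idx = np.zeros((2 ** nd, npts), dtype=np.int64)
    wts = np.ones((2 ** nd, npts))
    valid = np.ones((2 ** nd, npts), dtype=bool)
    for corner in range(2 ** nd):
        flat = np.zeros(npts, dtype=np.int64)
        ok = np.ones(npts, dtype=bool)
        w = np.ones(npts)
        for ax in range(nd):
            bit = (corner >> ax) & 1
            gi = g0[:, ax] + bit
            ok &= (gi >= 0) & (gi < P)
            w *= frac[:, ax] if bit else (1.0 - frac[:, ax])
            flat = flat * P + np.clip(gi, 0, P - 1)
        idx[corner] = flat
        wts[corner] = w
        valid[corner] = ok
    wts[~valid] = 0.0
    return idx, wts


def extract_slice(vol: FourierVolume, R, dtype=np.complex128) -> FourierSlice:
    """Interpolate the central slice of ``vol`` oriented by rotation ``R``.

    ``R`` is a 3x3 rotation matrix for volumes, or an in-plane angle in
    degrees (or 2x2 matrix) for 2D references.  Values outside the stored
    grid are zero.
    """
    if vol.ndim == 3:
        R = np.asarray(R, dtype=float)
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValueError("rotation matrix must have determinant +1")
    coords = _slice_sample_coords(vol, R)
    P = vol.grid.shape[0]
    idx, wts = _interp_corners(coords, P)
    flat = vol.grid.ravel()
    vals = (flat[idx] * wts).sum(axis=0)
    D = vol.src_size
    return FourierSlice(data=vals.reshape(D, D).astype(dtype),
                        voxel_size=vol.voxel_size)


def extract_slices_batch(vol: FourierVolume, Rs, dtype=np.complex64,
                         chunk: int = 256) -> np.ndarray:
    """Extract many slices at once; ``Rs`` is a list of rotation matrices
    (3D volumes) or in-plane angles in degrees (2D references)."""
    D = vol.src_size
    P = vol.grid.shape[0]
    flat = vol.grid.ravel()
    out = np.empty((len(Rs), D, D), dtype=dtype)
    for lo in range(0, len(Rs), chunk):
        batch = Rs[lo:lo + chunk]
        coords = np.concatenate(
            [_slice_sample_coords(vol, R) for R in batch], axis=0)
        idx, wts = _interp_corners(coords, P)
        vals = (flat[idx] * wts).sum(axis=0)
        out[lo:lo + len(batch)] = vals.reshape(len(batch), D, D).astype(dtype)
    return out


def _oversampled_slice_samples(data: np.ndarray, R, P: int, ndim: int):
    """Sample coordinates and values of a slice upsampled to the padded
    in-plane rate (grid-unit spacing 1 instead of ``pad``).

    The slice image is zero-padded two-fold in real space, which evaluates
    the slice transform exactly at the intermediate frequencies; the padded
    plane is then oriented by ``R``.
    """
    D = data.shape[0]
    img = centered_ifft(data)
    padded = np.zeros((P, P), dtype=complex)
    lo = P // 2 - D // 2
    padded[lo:lo + D, lo:lo + D] = img
    vals = centered_fft(padded).ravel()
    q = np.arange(P) - P // 2
    qx, qy = np.meshgrid(q, q, indexing="xy")
    if ndim == 3:
        k = np.stack([qx, qy, np.zeros_like(qx)], axis=-1).reshape(-1, 3)
        M = np.asarray(R, dtype=float)
    else:
        a = np.radians(R) if np.isscalar(R) else None
        M = (np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
             if a is not None else np.asarray(R, dtype=float))
        k = np.stack([qx, qy], axis=-1).reshape(-1, 2)
    return (k @ M)[:, ::-1], vals


def insert_slice(acc_data: np.ndarray, acc_weight: np.ndarray,
                 slice_data, R, weight: float = 1.0,
                 pad: int = 2, oversample: bool = False) -> None:
    """Scatter a 2D Fourier slice back into 3D (or 2D) accumulators.

    Each slice pixel is distributed over the neighbouring grid voxels with
    the same multilinear weights used by :func:`extract_slice`, making the
    pair an exact adjoint.  ``acc_weight`` accrues the interpolation weights
    times ``weight``.

    With ``oversample=True`` the slice is first upsampled two-fold in-plane
    (exact trigonometric interpolation via real-space zero-padding) so the
    inserted samples sit one grid unit apart on the padded grid instead of
    ``pad``; this removes in-plane coverage holes and is what reconstruction
    paths use.  The plain variant is the exact adjoint of
    :func:`extract_slice`.
    """
    if weight < 0:
        raise ValueError("insertion weight must be >= 0")
    if weight == 0.0:
        return
    data = slice_data.data if isinstance(slice_data, FourierSlice) else slice_data
    P = acc_data.shape[0]
    D = data.shape[0]
    if oversample:
        coords, vals = _oversampled_slice_samples(data, R, P, acc_data.ndim)
    else:
        fake = _FakeVol(P=P, pad=pad, src_size=D, ndim=acc_data.ndim)
        coords = _slice_sample_coords(fake, R)
        vals = data.ravel()
    idx, wts = _interp_corners(coords, P)
    w = wts * weight
    flat_idx = idx.ravel()
    np.add.at(acc_data.reshape(-1), flat_idx, (w * vals[None, :]).ravel())
    np.add.at(acc_weight.reshape(-1), flat_idx, w.ravel())


class _FakeVol:
    """Light stand-in carrying just the fields _slice_sample_coords needs."""

    def __init__(self, P, pad, src_size, ndim):
        self.grid = np.empty((0,) * ndim)
        self.pad = pad
        self.src_size = src_size
        self.ndim = ndim


# ---------------------------------------------------------------------------
# image <-> slice, shifts, filters
# ---------------------------------------------------------------------------


def slice_to_image(sl: FourierSlice | np.ndarray) -> np.ndarray:
    """Inverse transform of a centered Fourier slice to a real image."""
    data = sl.data if isinstance(sl, FourierSlice) else sl
    return centered_ifft(data).real


def image_to_slice(img: np.ndarray, voxel_size: float = 1.0) -> FourierSlice:
    return FourierSlice(data=centered_fft(np.asarray(img, dtype=float)),
                        voxel_size=voxel_size)


def shift_ramp(D: int, dx: float, dy: float) -> np.ndarray:
    """Phase ramp exp(-2*pi*i*(qx*dx + qy*dy)/D) on the centered D x D plane."""
    q = np.arange(D) - D // 2
    qx, qy = np.meshgrid(q, q, indexing="xy")
    return np.exp(-2j * np.pi * (qx * dx + qy * dy) / D)


def phase_shift(sl: FourierSlice | np.ndarray, dx: float, dy: float):
    """Translate by (dx, dy) pixels via a Fourier phase ramp."""
    if not (np.isfinite(dx) and np.isfinite(dy)):
        raise ValueError("shifts must be finite")
    data = sl.data if isinstance(sl, FourierSlice) else np.asarray(sl)
    out = data * shift_ramp(data.shape[-1], dx, dy)
    if isinstance(sl, FourierSlice):
        return FourierSlice(data=out, voxel_size=sl.voxel_size)
    return out


def shell_indices(D: int, ndim: int = 2) -> np.ndarray:
    """Integer resolution-shell index per centered Fourier pixel (max D//2)."""
    q = np.arange(D) - D // 2
    grids = np.meshgrid(*([q] * ndim), indexing="ij")
    r = np.sqrt(sum(g.astype(float) ** 2 for g in grids))
    return np.minimum(np.round(r).astype(int), D // 2)


def radial_shell_average(power: np.ndarray) -> np.ndarray:
    """Average a (real) Fourier-plane quantity over integer shells."""
    D = power.shape[-1]
    sh = shell_indices(D, power.ndim)
    counts = np.bincount(sh.ravel(), minlength=D // 2 + 1)
    sums = np.bincount(sh.ravel(), weights=power.ravel(), minlength=D // 2 + 1)
    return sums / np.maximum(counts, 1)


def lowpass_filter(image: np.ndarray, resolution_A: float, pixel_size_A: float,
                   edge_shells: float = 2.0) -> np.ndarray:
    """Cosine-edged low-pass filter at ``resolution_A`` (applies to 2D or 3D).

    The pass band keeps frequencies below ``1/resolution``; a raised-cosine
    edge of ``edge_shells`` Fourier pixels avoids ringing.  The mean (DC
    term) is always preserved.
    """
    image = np.asarray(image, dtype=float)
    if resolution_A < 2.0 * pixel_size_A:
        raise ValueError(
            f"resolution {resolution_A} A is beyond Nyquist ({2 * pixel_size_A} A)")
    D = image.shape[0]
    cutoff = D * pixel_size_A / resolution_A  # shell index of 1/resolution
    q = np.arange(D) - D // 2
    grids = np.meshgrid(*([q] * image.ndim), indexing="ij")
    r = np.sqrt(sum(g.astype(float) ** 2 for g in grids))
    mask = np.ones_like(r)
    edge = (r > cutoff) & (r <= cutoff + edge_shells)
    mask[r > cutoff + edge_shells] = 0.0
    mask[edge] = 0.5 * (1.0 + np.cos(np.pi * (r[edge] - cutoff) / edge_shells))
    return centered_ifft(centered_fft(image) * mask).real


def good_fft_size(n: int) -> int:
    """Smallest m >= n whose prime factors are all <= 7."""
    if n < 1:
        raise ValueError("n must be >= 1")
    m = int(n)
    while True:
        k = m
        for p in (2, 3, 5, 7):
            while k % p == 0:
                k //= p
        if k == 1:
            return m
        m += 1
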