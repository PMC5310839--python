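"""Drivers for 2D/3D classification and gold-standard 3D auto-refinement.

The drivers are scikit-learn style estimators: parameters are constructor
arguments, ``fit`` consumes a particle stack, and results are exposed as
trailing-underscore attributes.  All randomness flows from ``random_state``
so that a rerun with the same seed reproduces the same assignments.

Gold-standard refinement splits the particles into two random halves that
are refined strictly independently; the Fourier shell correlation (FSC)
between the two half-maps measures reproducible signal, and solvent-mask
induced FSC inflation is corrected by phase randomisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator
from sklearn.utils import check_random_state

from .expectation import NoiseModel, estep_pass
from .fourier import (
    centered_fft,
    lowpass_filter,
    oversampled_ft,
    shell_indices,
)
from .geometry import (
    OrientationGrid,
    euler_to_matrix,
    fibonacci_directions,
    make_inplane_grid,
    make_sphere_grid,
    make_translation_grid,
    rotation_distance_deg,
)
from .io import ImageStack, MapVolume
from .maximization import gridding_reconstruct, update_references

__all__ = [
    "FscCurve",
    "fsc",
    "solvent_mask",
    "postprocess",
    "Classify2D",
    "Classify3D",
    "AutoRefine3D",
    "classify",
    "autorefine",
    "angular_agreement",
]


# ---------------------------------------------------------------------------
# FSC / masking / postprocessing
# ---------------------------------------------------------------------------


@dataclass
class FscCurve:
    values: np.ndarray          # per shell, in [-1, 1]
    frequencies: np.ndarray     # 1/Angstrom

    def resolution(self, threshold: float = 0.143,
                   pixel_size: float | None = None) -> float:
        """1/frequency of the first shell dropping below ``threshold``."""
        below = np.nonzero(self.values[1:] < threshold)[0]
        if below.size == 0:
            return 1.0 / self.frequencies[-1]
        s = below[0] + 1
        return 1.0 / self.frequencies[s]


def _as_array(m) -> np.ndarray:
    return m.data if isinstance(m, MapVolume) else np.asarray(m)


def fsc(map1, map2, pixel_size: float = 1.0) -> FscCurve:
    """Fourier shell correlation between two equally-sized maps/images."""
    a, b = _as_array(map1), _as_array(map2)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    if isinstance(map1, MapVolume):
        pixel_size = map1.voxel_size
    A, B = centered_fft(a), centered_fft(b)
    sh = shell_indices(a.shape[0], a.ndim).ravel()
    n_shells = a.shape[0] // 2 + 1
    num = np.bincount(sh, weights=(A * B.conj()).real.ravel(), minlength=n_shells)
    da = np.bincount(sh, weights=(np.abs(A) ** 2).ravel(), minlength=n_shells)
    db = np.bincount(sh, weights=(np.abs(B) ** 2).ravel(), minlength=n_shells)
    den = np.sqrt(da * db)
    values = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    freqs = np.arange(n_shells) / (a.shape[0] * pixel_size)
    freqs[0] = 1e-12  # avoid division by zero for the DC shell
    return FscCurve(values=values, frequencies=freqs)


def solvent_mask(map, threshold: float, lowpass_A: float = 15.0,
                 edge_px: float = 5.0, pixel_size: float | None = None):
    """Soft solvent mask: binarised low-pass map with a cosine edge.

    The map is low-pass filtered (default 15 A), binarised at ``threshold``
    and extended outwards by a ``edge_px``-pixel wide cosine-shaped soft
    edge falling from 1 to 0.
    """
    data = _as_array(map)
    px = map.voxel_size if isinstance(map, MapVolume) else (pixel_size or 1.0)
    res = max(lowpass_A, 2.0 * px)
    smooth = lowpass_filter(data, res, px)
    binary = smooth >= threshold
    if not binary.any():
        raise ValueError("threshold leaves an empty mask")
    dist = ndimage.distance_transform_edt(~binary)
    mask = np.zeros_like(smooth)
    mask[binary] = 1.0
    edge = (~binary) & (dist <= edge_px)
    mask[edge] = 0.5 * (1.0 + np.cos(np.pi * dist[edge] / edge_px))
    if isinstance(map, MapVolume):
        return MapVolume(mask, voxel_size=px)
    return mask


def _randomize_phases(a: np.ndarray, start_shell: int, rng) -> np.ndarray:
    """Replace Fourier phases beyond ``start_shell`` with random ones while
    preserving amplitudes and Hermitian symmetry (the output stays real)."""
    F = np.fft.fftn(a)
    D = a.shape[0]
    # frequency radius in the unshifted layout
    q = np.fft.fftfreq(D) * D
    grids = np.meshgrid(*([q] * a.ndim), indexing="ij")
    r = np.sqrt(sum(g ** 2 for g in grids))
    u = rng.uniform(0.0, 2.0 * np.pi, size=F.shape)
    mirror = tuple(
        np.mod(-np.arange(D), D) for _ in range(a.ndim))
    u_mirror = u[np.ix_(*mirror)]
    phi = u - u_mirror  # antisymmetric: keeps the map real
    sel = r >= start_shell
    F = np.where(sel, np.abs(F) * np.exp(1j * (np.angle(F) + phi)), F)
    return np.fft.ifftn(F).real


def postprocess(half1, half2, mask, pixel_size: float | None = None,
                fsc_threshold: float = 0.143, rand_at_fsc: float = 0.8,
                random_state=0):
    """Masked, phase-randomisation-corrected FSC and resolution estimate.

    The masked FSC is recomputed after randomising the phases of both half
    maps beyond the shell where the masked FSC first falls below
    ``rand_at_fsc``; the corrected curve is
    ``(FSC_masked - FSC_rand) / (1 - FSC_rand)`` beyond that shell, which
    removes the correlation the mask itself introduces.

    Returns ``(FscCurve, resolution_in_A)``.
    """
    a, b = _as_array(half1), _as_array(half2)
    m = _as_array(mask)
    if not (a.shape == b.shape == m.shape):
        raise ValueError("half maps and mask must share dimensions")
    if not m.any():
        raise ValueError("mask is all zero")
    px = half1.voxel_size if isinstance(half1, MapVolume) else (pixel_size or 1.0)
    rng = check_random_state(random_state)

    masked = fsc(a * m, b * m, pixel_size=px)
    below = np.nonzero(masked.values[1:] < rand_at_fsc)[0]
    corrected = masked.values.copy()
    if below.size:
        start = int(below[0] + 1) + 2  # a couple of shells of safety margin
        if start < len(masked.values) - 1:
            ra = _randomize_phases(a, start, rng)
            rb = _randomize_phases(b, start, rng)
            randomized = fsc(ra * m, rb * m, pixel_size=px)
            beyond = np.arange(len(corrected)) > start
            denom = 1.0 - randomized.values
            safe = beyond & (np.abs(denom) > 1e-6)
            corrected[safe] = ((masked.values[safe] - randomized.values[safe])
                               / denom[safe])
    curve = FscCurve(values=corrected, frequencies=masked.frequencies)
    return curve, curve.resolution(fsc_threshold)


def angular_agreement(table1: pd.DataFrame, table2: pd.DataFrame,
                      tol_deg: float = 1.0, align_frames: bool = True
                      ) -> float:
    """Fraction of particles whose assigned orientations agree within
    ``tol_deg`` degrees (geodesic rotation distance).

    Refinement determines orientations only up to a global rotation of
    the reference frame; with ``align_frames`` the best single rotation
    between the two solutions (chordal mean, projected onto SO(3)) is
    removed before comparing.
    """
    if len(table1) != len(table2):
        raise ValueError("tables must describe the same particles")
    As = [euler_to_matrix(r["rot"], r["tilt"], r["psi"])
          for _, r in table1.iterrows()]
    Bs = [euler_to_matrix(r["rot"], r["tilt"], r["psi"])
          for _, r in table2.iterrows()]
    if align_frames and len(As) > 1:
        M = sum(A.T @ B for A, B in zip(As, Bs))
        U, _, Vt = np.linalg.svd(M)
        G = U @ np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))]) @ Vt
        Bs = [B @ G.T for B in Bs]
    close = sum(rotation_distance_deg(A, B) <= tol_deg
                for A, B in zip(As, Bs))
    return close / max(len(As), 1)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


def _stack_data(X) -> tuple[np.ndarray, float]:
    if isinstance(X, ImageStack):
        return np.asarray(X.data, dtype=float), X.pixel_size
    X = np.asarray(X, dtype=float)
    if X.ndim != 3 or X.shape[1] != X.shape[2]:
        raise ValueError("expected a stack of square images (N, D, D)")
    return X, 1.0


def _validate_stack(data: np.ndarray) -> None:
    norms = np.abs(data).sum(axis=(1, 2))
    if np.any(norms == 0):
        raise ValueError("stack contains all-zero particle images")
    if not np.all(np.isfinite(data)):
        raise ValueError("stack contains non-finite values")


class _BaseRefineEM(BaseEstimator):
    """Shared parameters and E-M plumbing for the refinement drivers."""

    def __init__(self, n_iter=10, angular_step=15.0, trans_radius=1.0,
                 fine_factor=2, significance_mass=0.999, pixel_size=None,
                 init_lowpass_A=None, dtype="float32", random_state=0):
        self.n_iter = n_iter
        self.angular_step = angular_step
        self.trans_radius = trans_radius
        self.fine_factor = fine_factor
        self.significance_mass = significance_mass
        self.pixel_size = pixel_size
        self.init_lowpass_A = init_lowpass_A
        self.dtype = dtype
        self.random_state = random_state

    # -- helpers ----------------------------------------------------------

    def _complex_dtype(self):
        return np.complex64 if str(self.dtype) == "float32" else np.complex128

    def _prep(self, X):
        data, px = _stack_data(X)
        if self.pixel_size is not None:
            px = self.pixel_size
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        _validate_stack(data)
        imgs_ft = np.stack([centered_fft(img) for img in data])
        return data, imgs_ft.astype(self._complex_dtype()), px

    def _init_lowpass(self, img, px):
        res = self.init_lowpass_A
        if res is None:
            res = 8.0 * px
        res = max(res, 2.0 * px)
        D = img.shape[0]
        if D * px / res < 1.0:  # cutoff below the first shell: keep DC + shell 1
            res = D * px / 1.5
        return lowpass_filter(img, max(res, 2.0 * px), px)


class Classify2D(_BaseRefineEM):
    """Reference-free 2D classification by regularised-likelihood E-M.

    Particles are aligned against ``n_classes`` class averages over
    in-plane rotations and translations; averages, priors and the noise
    spectrum are re-estimated each iteration.

    Attributes (after ``fit``)
    --------------------------
    class_averages_ : list of 2D arrays
    labels_ : (N,) int class assignment (maximum posterior weight)
    orientations_ : DataFrame with psi/dx/dy/max_weight per particle
    class_priors_, noise_, loglik_per_iter_
    """

    def __init__(self, n_classes=2, n_iter=10, angular_step=15.0,
                 trans_radius=1.0, fine_factor=2, significance_mass=0.999,
                 pixel_size=None, init_lowpass_A=None, dtype="float32",
                 random_state=0):
        super().__init__(n_iter=n_iter, angular_step=angular_step,
                         trans_radius=trans_radius, fine_factor=fine_factor,
                         significance_mass=significance_mass,
                         pixel_size=pixel_size, init_lowpass_A=init_lowpass_A,
                         dtype=dtype, random_state=random_state)
        self.n_classes = n_classes

    def _init_references(self, data, px, rng):
        N = len(data)
        perm = rng.permutation(N)
        refs = []
        for k in range(self.n_classes):
            # a random half-subset keeps single-class alignment runs
            # seed-dependent as well (stochastic initialisation)
            subset = (perm[: max(2, N // 2)] if self.n_classes == 1
                      else perm[k::self.n_classes])
            refs.append(self._init_lowpass(data[subset].mean(axis=0), px))
        return refs

    def fit(self, X, y=None):
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        data, imgs_ft, px = self._prep(X)
        rng = check_random_state(self.random_state)
        refs = self._init_references(data, px, rng)
        noise = NoiseModel.from_stack(imgs_ft)
        priors = np.full(self.n_classes, 1.0 / self.n_classes)
        psis = make_inplane_grid(self.angular_step)
        grid = OrientationGrid(
            angles=np.column_stack([np.zeros_like(psis), np.zeros_like(psis), psis]),
            angular_step=self.angular_step,
            translations=make_translation_grid(self.trans_radius),
        )
        logliks = []
        assignments = None
        for _ in range(self.n_iter):
            fvols = [oversampled_ft(r, voxel_size=px) for r in refs]
            acc, assignments, ll = estep_pass(
                imgs_ft, fvols, grid, noise, class_priors=priors,
                fine_factor=self.fine_factor,
                significance_mass=self.significance_mass,
                dtype=self._complex_dtype())
            refs, priors, noise = update_references(acc, voxel_size=px)
            logliks.append(ll)
        self.class_averages_ = refs
        self.references_ = refs
        self.labels_ = assignments["class"].to_numpy()
        self.orientations_ = assignments
        self.class_priors_ = priors
        self.noise_ = noise
        self.loglik_per_iter_ = logliks
        self.n_iter_ = self.n_iter
        self.pixel_size_ = px
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


class Classify3D(_BaseRefineEM):
    """3D classification: multiple maps refined simultaneously.

    Orientations are sampled over the full sphere plus in-plane angles and
    translations.  Initial references may be supplied; otherwise each class
    starts from a low-passed reconstruction of the particles back-projected
    at random orientations.
    """

    def __init__(self, n_classes=2, n_iter=10, angular_step=15.0,
                 trans_radius=1.0, fine_factor=2, significance_mass=0.999,
                 pixel_size=None, init_lowpass_A=None, dtype="float32",
                 random_state=0, initial_references=None):
        super().__init__(n_iter=n_iter, angular_step=angular_step,
                         trans_radius=trans_radius, fine_factor=fine_factor,
                         significance_mass=significance_mass,
                         pixel_size=pixel_size, init_lowpass_A=init_lowpass_A,
                         dtype=dtype, random_state=random_state)
        self.n_classes = n_classes
        self.initial_references = initial_references

    def _random_backprojection(self, imgs_ft, subset, px, rng, D):
        from .expectation import Accumulator, accumulate

        acc = Accumulator(n_classes=1, grid_size=2 * D, ndim=3, src_size=D)
        for p in subset:
            ang = np.array([rng.uniform(0, 360),
                            np.degrees(np.arccos(rng.uniform(-1, 1))),
                            rng.uniform(0, 360)])
            noise = NoiseModel(np.ones(D // 2 + 1))
            accumulate(imgs_ft[p].astype(np.complex128),
                       [(0, ang, (0.0, 0.0), 1.0)], acc, noise)
        vol = gridding_reconstruct(acc.data[0], acc.weight[0], voxel_size=px)
        return self._init_lowpass(vol.data, px)

    def fit(self, X, y=None):
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        data, imgs_ft, px = self._prep(X)
        D = data.shape[1]
        rng = check_random_state(self.random_state)
        if self.initial_references is not None:
            refs = [self._init_lowpass(_as_array(r).astype(float), px)
                    for r in self.initial_references]
            if len(refs) != self.n_classes:
                raise ValueError("need one initial reference per class")
        else:
            perm = rng.permutation(len(data))
            refs = [
                self._random_backprojection(imgs_ft, perm[k::self.n_classes],
                                            px, rng, D)
                for k in range(self.n_classes)
            ]
        noise = NoiseModel.from_stack(imgs_ft)
        priors = np.full(self.n_classes, 1.0 / self.n_classes)
        grid = make_sphere_grid(self.angular_step,
                                translations=make_translation_grid(self.trans_radius))
        logliks = []
        assignments = None
        for _ in range(self.n_iter):
            fvols = [oversampled_ft(r, voxel_size=px) for r in refs]
            acc, assignments, ll = estep_pass(
                imgs_ft, fvols, grid, noise, class_priors=priors,
                fine_factor=self.fine_factor,
                significance_mass=self.significance_mass,
                dtype=self._complex_dtype())
            maps, priors, noise = update_references(acc, voxel_size=px)
            refs = [m.data for m in maps]
            logliks.append(ll)
        self.references_ = [MapVolume(r, voxel_size=px) for r in refs]
        self.labels_ = assignments["class"].to_numpy()
        self.orientations_ = assignments
        self.class_priors_ = priors
        self.noise_ = noise
        self.loglik_per_iter_ = logliks
        self.pixel_size_ = px
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


class AutoRefine3D(_BaseRefineEM):
    """Gold-standard single-class 3D refinement.

    The particle set is split into two random halves refined strictly
    independently against their own references.  The angular step is halved
    whenever the half-map FSC resolution stalls, switching from the global
    search grid to local searches around each particle's previous
    orientation; refinement stops once the step falls below
    ``stop_step_deg`` (default: an eighth of the initial step) and the
    resolution is stable.
    """

    def __init__(self, n_iter=10, angular_step=15.0, trans_radius=0.0,
                 fine_factor=2, significance_mass=0.999, pixel_size=None,
                 init_lowpass_A=None, dtype="float32", random_state=0,
                 stop_step_deg=None, fsc_threshold=0.143):
        super().__init__(n_iter=n_iter, angular_step=angular_step,
                         trans_radius=trans_radius, fine_factor=fine_factor,
                         significance_mass=significance_mass,
                         pixel_size=pixel_size, init_lowpass_A=init_lowpass_A,
                         dtype=dtype, random_state=random_state)
        self.stop_step_deg = stop_step_deg
        self.fsc_threshold = fsc_threshold

    def _local_grids(self, prev: pd.DataFrame, step: float, trans):
        """Per-particle neighbourhood grids around previous orientations."""
        from .geometry import _direction_lattice, _n_directions
        dirs, tree = _direction_lattice(_n_directions(step))
        chord = 2.0 * np.sin(np.radians(2.5 * step) / 2.0)
        grids = []
        for _, row in prev.iterrows():
            g = OrientationGrid(np.array([[row["rot"], row["tilt"], row["psi"]]]),
                                angular_step=step)
            center = g.directions()[0]
            idx = tree.query_ball_point(center, chord)
            cand = dirs[idx] if idx else center[None]
            tilt = np.degrees(np.arccos(np.clip(cand[:, 2], -1, 1)))
            rot = np.degrees(np.arctan2(cand[:, 1], cand[:, 0])) % 360.0
            psis = (row["psi"] + step * np.arange(-2, 3)) % 360.0
            angles = np.column_stack([
                np.repeat(rot, len(psis)),
                np.repeat(tilt, len(psis)),
                np.tile(psis, len(rot)),
            ])
            angles = np.vstack([[row["rot"], row["tilt"], row["psi"]], angles])
            grids.append(OrientationGrid(angles, angular_step=step,
                                         translations=trans))
        return grids

    def fit(self, X, initial_map=None, y=None):
        if initial_map is None:
            raise ValueError("autorefine needs an initial 3D reference map")
        data, imgs_ft, px = self._prep(X)
        if isinstance(initial_map, MapVolume) and self.pixel_size is None:
            px = initial_map.voxel_size
        N, D = data.shape[0], data.shape[1]
        if N < 4:
            raise ValueError("need at least 2 particles per half-set")
        rng = check_random_state(self.random_state)
        perm = rng.permutation(N)
        halves = [np.sort(perm[: N // 2]), np.sort(perm[N // 2:])]

        init = self._init_lowpass(_as_array(initial_map).astype(float), px)
        refs = [init.copy(), init.copy()]
        noises = [NoiseModel.from_stack(imgs_ft[h]) for h in halves]
        trans = make_translation_grid(self.trans_radius)
        step = float(self.angular_step)
        # annealing below a quarter of the initial step is reference-limited
        # at desk scale: alignment accuracy saturates near the interpolation
        # fidelity of the reconstructed references
        stop_step = (self.stop_step_deg if self.stop_step_deg is not None
                     else self.angular_step / 4.0)

        prev_assign = [None, None]
        prev_res_shell = -1
        schedule = []
        fsc_curve = None
        finest_iters = 0
        for it in range(self.n_iter):
            schedule.append(step)
            new_refs = []
            for h in (0, 1):
                fvol = oversampled_ft(refs[h], voxel_size=px)
                if it == 0 or prev_assign[h] is None or step == self.angular_step:
                    grid = make_sphere_grid(step, translations=trans)
                    local = None
                else:
                    grid = make_sphere_grid(step, translations=trans)
                    local = self._local_grids(prev_assign[h], step, trans)
                acc, assign, _ = estep_pass(
                    imgs_ft[halves[h]], [fvol], grid, noises[h],
                    fine_factor=self.fine_factor,
                    significance_mass=self.significance_mass,
                    dtype=self._complex_dtype(), local_grids=local)
                maps, _, noises[h] = update_references(acc, voxel_size=px)
                new_refs.append(maps[0].data)
                prev_assign[h] = assign
            fsc_curve = fsc(new_refs[0], new_refs[1], pixel_size=px)
            below = np.nonzero(fsc_curve.values[1:] < self.fsc_threshold)[0]
            res_shell = int(below[0] + 1) if below.size else D // 2
            # regularise: keep each half map only to its supported resolution
            keep_res = max((D * px) / max(res_shell + 2, 1), 2.0 * px)
            refs = [lowpass_filter(r, keep_res, px) for r in new_refs]
            if step <= stop_step:
                finest_iters += 1
                if finest_iters >= 3 and res_shell <= prev_res_shell:
                    break
            elif res_shell <= prev_res_shell:
                step = step / 2.0
            prev_res_shell = max(prev_res_shell, res_shell)

        table = pd.concat(
            [prev_assign[0].assign(particle=halves[0], half=1),
             prev_assign[1].assign(particle=halves[1], half=2)]
        ).sort_values("particle").reset_index(drop=True)
        self.half_maps_ = [MapVolume(r, voxel_size=px) for r in new_refs]
        self.map_ = MapVolume(0.5 * (new_refs[0] + new_refs[1]), voxel_size=px)
        self.orientations_ = table
        self.fsc_ = fsc_curve
        self.resolution_A_ = fsc_curve.resolution(self.fsc_threshold)
        self.angular_step_schedule_ = schedule
        self.final_step_deg_ = step
        self.halves_ = halves
        self.pixel_size_ = px
        return self


# ---------------------------------------------------------------------------
# thin functional wrappers
# ---------------------------------------------------------------------------


def classify(stack, n_classes=2, mode="2d", **kwargs):
    """Classify a particle stack; returns the fitted estimator."""
    cls = Classify2D if mode == "2d" else Classify3D
    return cls(n_classes=n_classes, **kwargs).fit(stack)


def autorefine(stack, initial_map, **kwargs):
    """Gold-standard auto-refinement; returns the fitted estimator."""
    return AutoRefine3D(**kwargs).fit(stack, initial_map=initial_map)
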