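"""Orientation sampling and Euler-angle conventions.

Orientations use intrinsic ZYZ Euler angles ``(rot, tilt, psi)`` in degrees,
the convention used by STAR particle tables, with the rotation matrix
``A = Rz(psi) @ Ry(tilt) @ Rz(rot)``.  An image formed by projecting a map
along the view axis of ``A`` has Fourier coefficients on the central plane
spanned by the first two rows of ``A``.

Directions on the sphere are sampled on a pole-inclusive Fibonacci lattice,
a deterministic quasi-uniform construction whose point count scales as
``1/step^2``; each direction is paired with a ring of in-plane angles at the
same step.  Adaptive refinement replaces a coarse grid by fine neighbourhoods
around selected orientations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Orientation",
    "OrientationGrid",
    "euler_to_matrix",
    "matrix_to_euler",
    "rotation_distance_deg",
    "make_inplane_grid",
    "make_sphere_grid",
    "make_translation_grid",
    "refine_grid",
]


@dataclass
class Orientation:
    rot: float = 0.0
    tilt: float = 0.0
    psi: float = 0.0
    dx: float = 0.0
    dy: float = 0.0

    def matrix(self) -> np.ndarray:
        return euler_to_matrix(self.rot, self.tilt, self.psi)


@dataclass
class OrientationGrid:
    """An ordered set of orientations plus a translation search grid.

    ``angles`` has one ``(rot, tilt, psi)`` row per orientation (degrees);
    ``translations`` one ``(dx, dy)`` row per in-plane offset (pixels).
    """

    angles: np.ndarray
    angular_step: float
    translations: np.ndarray = field(default_factory=lambda: np.zeros((1, 2)))
    is_fine_pass: bool = False

    def __post_init__(self) -> None:
        self.angles = np.atleast_2d(np.asarray(self.angles, dtype=float))
        self.translations = np.atleast_2d(np.asarray(self.translations, dtype=float))
        if self.angular_step <= 0:
            raise ValueError("angular_step must be positive")

    def __len__(self) -> int:
        return len(self.angles)

    @property
    def n_translations(self) -> int:
        return len(self.translations)

    def matrices(self) -> np.ndarray:
        return np.stack([euler_to_matrix(*a) for a in self.angles])

    def directions(self) -> np.ndarray:
        """Unit view vectors (third row of each rotation matrix)."""
        rot = np.radians(self.angles[:, 0])
        tilt = np.radians(self.angles[:, 1])
        return np.column_stack(
            [np.sin(tilt) * np.cos(rot), np.sin(tilt) * np.sin(rot), np.cos(tilt)]
        )


def _rz(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _ry(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def euler_to_matrix(rot: float, tilt: float, psi: float) -> np.ndarray:
    """ZYZ Euler angles (degrees) -> 3x3 rotation matrix."""
    if not np.all(np.isfinite([rot, tilt, psi])):
        raise ValueError("Euler angles must be finite")
    r, t, p = np.radians([rot, tilt, psi])
    return _rz(p) @ _ry(t) @ _rz(r)


def matrix_to_euler(A: np.ndarray) -> tuple[float, float, float]:
    """Inverse of :func:`euler_to_matrix`; degenerate tilts put all spin in psi."""
    A = np.asarray(A, dtype=float)
    tilt = float(np.degrees(np.arccos(np.clip(A[2, 2], -1.0, 1.0))))
    if abs(A[2, 2]) > 1.0 - 1e-12:
        rot = 0.0
        psi = float(np.degrees(np.arctan2(A[1, 0], A[0, 0])))
        if A[2, 2] < 0:
            psi = -psi
    else:
        rot = float(np.degrees(np.arctan2(A[2, 1], -A[2, 0])))
        psi = float(np.degrees(np.arctan2(A[1, 2], A[0, 2])))
    return rot % 360.0, tilt, psi % 360.0


def rotation_distance_deg(A: np.ndarray, B: np.ndarray) -> float:
    """Geodesic angle (degrees) between two rotation matrices."""
    tr = np.trace(np.asarray(A) @ np.asarray(B).T)
    return float(np.degrees(np.arccos(np.clip((tr - 1.0) / 2.0, -1.0, 1.0))))


def make_inplane_grid(step_deg: float) -> np.ndarray:
    """Equally spaced in-plane angles {0, step, ...} < 360 degrees."""
    if not 0 < step_deg <= 360:
        raise ValueError("in-plane step must satisfy 0 < step <= 360")
    return np.arange(0.0, 360.0 - 1e-9, step_deg)


def fibonacci_directions(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors including both poles (n >= 2)."""
    i = np.arange(n)
    z = 1.0 - 2.0 * i / (n - 1) if n > 1 else np.array([1.0])
    phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


from functools import lru_cache


@lru_cache(maxsize=64)
def _direction_lattice(n: int):
    """Cached Fibonacci lattice plus KD-tree for neighbourhood queries."""
    dirs = fibonacci_directions(n)
    return dirs, cKDTree(dirs)


def _n_directions(step_deg: float) -> int:
    # hexagonal-packing area argument: one point per (sqrt(3)/2) d^2 steradian
    d = np.radians(step_deg)
    return max(2, int(np.ceil(8.0 * np.pi / (np.sqrt(3.0) * d * d))))


def make_sphere_grid(
    step_deg: float,
    psi_step_deg: float | None = None,
    translations: np.ndarray | None = None,
) -> OrientationGrid:
    """Quasi-uniform orientations at roughly ``step_deg`` spacing.

    Each sphere direction ``(rot, tilt)`` is combined with in-plane angles
    sampled at ``psi_step_deg`` (defaults to ``step_deg``).
    """
    if step_deg <= 0:
        raise ValueError("angular step must be positive")
    psi_step = psi_step_deg if psi_step_deg is not None else step_deg
    dirs = fibonacci_directions(_n_directions(step_deg))
    tilt = np.degrees(np.arccos(np.clip(dirs[:, 2], -1.0, 1.0)))
    rot = np.degrees(np.arctan2(dirs[:, 1], dirs[:, 0])) % 360.0
    psis = make_inplane_grid(min(psi_step, 360.0))
    angles = np.column_stack(
        [
            np.repeat(rot, len(psis)),
            np.repeat(tilt, len(psis)),
            np.tile(psis, len(rot)),
        ]
    )
    if translations is None:
        translations = np.zeros((1, 2))
    return OrientationGrid(angles=angles, angular_step=step_deg,
                           translations=translations)


def make_translation_grid(radius_px: float, step_px: float = 1.0) -> np.ndarray:
    """Square grid of (dx, dy) offsets with |dx|,|dy| <= radius, centred on 0."""
    if radius_px < 0:
        raise ValueError("translation radius must be >= 0")
    axis = np.arange(-radius_px, radius_px + 1e-9, step_px)
    if len(axis) == 0 or 0.0 not in np.round(axis, 9):
        axis = np.unique(np.concatenate([axis, [0.0]]))
    dx, dy = np.meshgrid(axis, axis, indexing="xy")
    return np.column_stack([dx.ravel(), dy.ravel()])


def _dedupe_angles(angles: np.ndarray) -> np.ndarray:
    key = np.round(angles, 6) % 360.0
    _, idx = np.unique(key, axis=0, return_index=True)
    return angles[np.sort(idx)]


def refine_grid(
    coarse: OrientationGrid,
    selected: np.ndarray,
    factor: int = 2,
) -> OrientationGrid:
    """Local grid at ``coarse.angular_step / factor`` around selected orientations.

    For each selected orientation at most ``factor**3`` fine candidates are
    kept (nearest by rotation distance), so the fine grid never exceeds
    ``len(selected) * factor**3`` orientations; the selected orientations
    themselves are always included.  Translations are refined to half the
    coarse spacing around the full coarse range.
    """
    selected = np.asarray(selected, dtype=int)
    if selected.size == 0:
        raise ValueError("refine_grid needs a non-empty selection")
    if factor < 2 or int(factor) != factor:
        raise ValueError("refinement factor must be an integer >= 2")
    fine_step = coarse.angular_step / factor
    sel_angles = coarse.angles[selected]

    if np.allclose(coarse.angles[:, :2], 0.0):  # pure in-plane grid (2D mode)
        offs = fine_step * np.arange(-(factor - 1), factor)
        psis = (sel_angles[:, 2][:, None] + offs[None, :]).ravel() % 360.0
        angles = _dedupe_angles(
            np.column_stack([np.zeros_like(psis), np.zeros_like(psis), psis]))
        return OrientationGrid(angles=angles, angular_step=fine_step,
                               translations=_refined_translations(coarse),
                               is_fine_pass=True)

    # candidate fine directions from a full fine sphere lattice (cached)
    fine_dirs, tree = _direction_lattice(_n_directions(fine_step))
    sel_dirs = OrientationGrid(sel_angles, coarse.angular_step).directions()
    chord = 2.0 * np.sin(np.radians(coarse.angular_step) / 2.0)

    out = []
    for (srot, stilt, spsi), sdir in zip(sel_angles, sel_dirs):
        idx = tree.query_ball_point(sdir, chord * 0.75)
        cand_dirs = fine_dirs[idx] if idx else sdir[None]
        tilt = np.degrees(np.arccos(np.clip(cand_dirs[:, 2], -1.0, 1.0)))
        rot = np.degrees(np.arctan2(cand_dirs[:, 1], cand_dirs[:, 0])) % 360.0
        psis = (spsi + fine_step * np.arange(-(factor - 1), factor)) % 360.0
        cand = np.column_stack(
            [
                np.repeat(rot, len(psis)),
                np.repeat(tilt, len(psis)),
                np.tile(psis, len(rot)),
            ]
        )
        cand = np.vstack([[srot, stilt, spsi], cand])
        # rank candidates by geodesic distance to the parent, keep factor^3
        Aref = euler_to_matrix(srot, stilt, spsi)
        dist = np.array([rotation_distance_deg(euler_to_matrix(*c), Aref) for c in cand])
        order = np.argsort(dist, kind="stable")[: factor ** 3]
        out.append(cand[order])
    angles = _dedupe_angles(np.vstack(out))
    return OrientationGrid(angles=angles, angular_step=fine_step,
                           translations=_refined_translations(coarse),
                           is_fine_pass=True)


def _refined_translations(coarse: OrientationGrid) -> np.ndarray:
    if coarse.n_translations <= 1:
        return coarse.translations
    spac = np.diff(np.unique(coarse.translations[:, 0]))
    step = float(spac.min()) if spac.size else 1.0
    radius = float(np.abs(coarse.translations).max())
    return make_translation_grid(radius, step / 2.0)
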