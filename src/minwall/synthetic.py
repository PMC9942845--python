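"""Synthetic voxel cells with known ground truth.

Stand-ins for segmented microscopy cells: convex-ish solids voxelized on a
(possibly anisotropic) grid, planar cuts producing daughter-pair label
grids at a requested volume fraction, and a brute-force planar-cut scan
that serves as an independent minimal-area oracle for the phase-field
relaxation.

The "wedge" kind approximates a young leaf segment cell: a lightly tapered
triangular-prism-like solid elongated along the adaxial--abaxial axis
(axis 0 here), so its minimal-area planar cut is periclinal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import CellMask, LabelGrid, STRUCT_6

__all__ = [
    "ShapeSpec",
    "make_shape",
    "make_label_grid",
    "slice_with_plane",
    "brute_force_min_plane",
    "fibonacci_hemisphere",
]

ShapeKind = Literal["cuboid", "ellipsoid", "wedge", "rounded_brick"]


@dataclass
class ShapeSpec:
    """Recipe for a voxelized solid.

    Parameters
    ----------
    kind
        One of ``cuboid``, ``ellipsoid``, ``wedge``, ``rounded_brick``.
    dimensions
        Full per-axis extents in µm (for the ellipsoid the semi-axes are
        half of these).
    rotation_axis, rotation_deg
        Rigid rotation applied to the solid before voxelization.
    spacing
        Per-axis voxel size in µm; a scalar means isotropic.
    surface_noise_amplitude
        Std of a smooth, seeded radial perturbation of the surface (µm);
        must stay below 10% of the smallest extent.
    seed
        Seed for the noise field; generation is bit-reproducible
        given (spec, seed).
    """

    kind: ShapeKind = "cuboid"
    dimensions: tuple[float, float, float] = (10.0, 8.0, 6.0)
    rotation_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    rotation_deg: float = 0.0
    spacing: float | tuple[float, float, float] = 0.2
    surface_noise_amplitude: float = 0.0
    wedge_taper: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        self.dimensions = tuple(float(d) for d in self.dimensions)
        if any(d <= 0 for d in self.dimensions):
            raise ValueError("extents must be positive")
        if self.surface_noise_amplitude >= 0.1 * min(self.dimensions):
            raise ValueError("noise amplitude must be < 10% of the smallest extent")

    @property
    def spacing_tuple(self) -> tuple[float, float, float]:
        return tuple(float(s) for s in np.broadcast_to(self.spacing, (3,)))


def _rotation_matrix(axis, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0 or angle_deg == 0:
        return np.eye(3)
    axis = axis / n
    th = np.deg2rad(angle_deg)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(th) * k + (1 - np.cos(th)) * (k @ k)


def _implicit(kind: str, p: np.ndarray, dims, taper: float) -> np.ndarray:
    """Signed implicit function in µm-like units; negative inside.

    ``p`` has shape (..., 3) in body coordinates centered on the solid.
    """
    h = np.asarray(dims) / 2.0
    if kind == "cuboid":
        return np.max(np.abs(p) - h, axis=-1)
    if kind == "ellipsoid":
        q = np.linalg.norm(p / h, axis=-1)
        return (q - 1.0) * h.min()
    if kind == "rounded_brick":
        q = np.sum((np.abs(p) / h) ** 4, axis=-1) ** 0.25
        return (q - 1.0) * h.min()
    if kind == "wedge":
        # tapered brick: extent along axis 2 shrinks linearly along axis 1
        t = np.clip(p[..., 1] / (2 * h[1]) + 0.5, 0.0, 1.0)
        w = h[2] * (1.0 - taper * t)
        f_box = np.maximum(np.abs(p[..., 0]) - h[0], np.abs(p[..., 1]) - h[1])
        return np.maximum(f_box, np.abs(p[..., 2]) - w)
    raise ValueError(f"unknown shape kind: {kind}")


def _smooth_noise(shape, rng: np.random.Generator, coarse: int = 5) -> np.ndarray:
    """Smooth unit-std random field: coarse white noise, cubic-upsampled."""
    base = rng.standard_normal((coarse,) * 3)
    factors = [s / coarse for s in shape]
    f = ndimage.zoom(base, factors, order=3, grid_mode=True, mode="nearest")
    f = f[: shape[0], : shape[1], : shape[2]]
    sd = f.std()
    return f / sd if sd > 0 else f


def _voxelize(spec: ShapeSpec) -> tuple[np.ndarray, tuple[float, float, float]]:
    spacing = spec.spacing_tuple
    rot = _rotation_matrix(spec.rotation_axis, spec.rotation_deg)
    half = np.asarray(spec.dimensions) / 2.0
    # bounding box of the rotated solid from the 8 canonical corners
    corners = np.array(
        [[sx * half[0], sy * half[1], sz * half[2]] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
    )
    ext = np.abs(corners @ rot.T).max(axis=0) + spec.surface_noise_amplitude
    margin = 2
    shape = tuple(int(np.ceil(2 * e / s)) + 2 * margin for e, s in zip(ext, spacing))
    center = np.array([(n / 2.0) * s for n, s in zip(shape, spacing)])

    idx = np.indices(shape).astype(float)
    coords = np.stack(
        [(idx[a] + 0.5) * spacing[a] - center[a] for a in range(3)], axis=-1
    )
    body = coords @ rot  # world -> body coordinates (rot maps body -> world)
    f = _implicit(spec.kind, body, spec.dimensions, spec.wedge_taper)
    if spec.surface_noise_amplitude > 0:
        rng = np.random.default_rng(spec.seed)
        f = f + spec.surface_noise_amplitude * _smooth_noise(shape, rng)
    occ = f <= 0.0
    if not occ.any():
        raise ValueError("shape empty at the given spacing")
    lab, n = ndimage.label(occ, structure=STRUCT_6)
    if n > 1:
        counts = np.bincount(lab.ravel())[1:]
        occ = lab == (int(np.argmax(counts)) + 1)
    return occ, spacing


def make_shape(spec: ShapeSpec) -> CellMask:
    """Voxelize a solid on an isotropic grid and return it as a cell mask."""
    spacing = spec.spacing_tuple
    if not (spacing[0] == spacing[1] == spacing[2]):
        raise ValueError("make_shape requires isotropic spacing; use make_label_grid")
    occ, spacing = _voxelize(spec)
    return CellMask(occupancy=occ, spacing=spacing[0], source_label=1)


def make_label_grid(spec: ShapeSpec, label: int = 1) -> LabelGrid:
    """Voxelize a solid on a (possibly anisotropic) grid as a label image."""
    occ, spacing = _voxelize(spec)
    return LabelGrid(labels=occ.astype(np.int32) * int(label), spacing=spacing)


# ---------------------------------------------------------------------------
# Planar cuts


def slice_with_plane(
    mask: CellMask, normal, fraction: float, tol: float = 0.01
) -> LabelGrid:
    """Cut a cell mask with a plane into daughters labeled 1 and 2.

    The plane offset along ``normal`` is found by bisection so that label 1
    (the lower side along the normal) holds ``fraction`` of the physical
    volume to within ``tol``.  Labels partition the mask exactly.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must be strictly inside (0, 1), got {fraction}")
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    coords = np.argwhere(mask.occupancy)
    s = (coords + 0.5) @ n * mask.spacing
    total = len(s)
    # deterministic sub-layer tie-break: axis-aligned planes quantize the
    # offset to whole lattice layers, which cannot hit arbitrary fractions;
    # an infinitesimal lexicographic ramp splits within a layer instead
    s = s + np.arange(total) * (mask.spacing * 1e-12)

    lo, hi = s.min() - mask.spacing, s.max() + mask.spacing
    for _ in range(64):
        c = 0.5 * (lo + hi)
        frac = np.count_nonzero(s < c) / total
        if frac < fraction:
            lo = c
        else:
            hi = c
    c = 0.5 * (lo + hi)
    achieved = np.count_nonzero(s < c) / total
    if abs(achieved - fraction) > tol:
        raise ValueError(
            f"unreachable fraction {fraction} at this resolution (closest {achieved:.4f})"
        )
    labels = np.zeros(mask.occupancy.shape, dtype=np.int32)
    below = s < c
    labels[tuple(coords[below].T)] = 1
    labels[tuple(coords[~below].T)] = 2
    return LabelGrid(labels=labels, spacing=(mask.spacing,) * 3)


# ---------------------------------------------------------------------------
# Brute-force planar minimal-area oracle


def fibonacci_hemisphere(n: int) -> np.ndarray:
    """Deterministic near-uniform direction set on the upper half-sphere."""
    i = np.arange(n)
    z = (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def _cut_area(mask: np.ndarray, below: np.ndarray, normal: np.ndarray, spacing: float) -> float:
    """Cross-section area of a planar cut by corrected voxel-face counting.

    Raw face counting overestimates oblique planes (Manhattan effect); each
    face is therefore weighted by the projection of the plane normal onto
    the face normal, which sums to the geometric area for an ideal plane.
    """
    area = 0.0
    for a in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[a] = slice(None, -1)
        sl_hi[a] = slice(1, None)
        sl_lo, sl_hi = tuple(sl_lo), tuple(sl_hi)
        cut = (below[sl_lo] != below[sl_hi]) & mask[sl_lo] & mask[sl_hi]
        area += np.count_nonzero(cut) * spacing**2 * abs(normal[a])
    return float(area)


def brute_force_min_plane(
    mask: CellMask,
    fraction: float = 0.5,
    n_orientations: int = 400,
    tie_rtol: float = 0.03,
) -> tuple[np.ndarray, float, pd.DataFrame]:
    """Scan planar cuts over orientations; return the minimal-area one.

    Directions are the three lattice axes, the three inertial eigen-axes,
    then ``n_orientations`` points of a deterministic Fibonacci spiral on
    the half-sphere.  For each direction the plane is offset to the
    requested volume fraction and the cut cross-section measured by
    projection-corrected face counting.  Ties within ``tie_rtol`` of the
    minimum keep the earliest scan entry and are flagged in the table.

    Returns ``(best_normal, best_area_um2, table)``; the table has one row
    per orientation with the achieved area.
    """
    from .grids import inertial_axes

    coords = np.argwhere(mask.occupancy)
    occ = mask.occupancy
    dirs = [np.eye(3)[a] for a in range(3)]
    dirs.extend(inertial_axes(mask).axes)
    dirs.extend(fibonacci_hemisphere(n_orientations))
    dirs = np.asarray(dirs)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)

    centers = (coords + 0.5) * mask.spacing
    areas = np.empty(len(dirs))
    below3 = np.zeros(occ.shape, dtype=bool)
    for k, nhat in enumerate(dirs):
        s = centers @ nhat
        c = np.quantile(s, fraction)
        below = s < c
        below3[tuple(coords.T)] = below
        areas[k] = _cut_area(occ, below3, nhat, mask.spacing)
        below3[tuple(coords.T)] = False

    best = int(np.argmin(areas))
    tie = areas <= areas[best] * (1.0 + tie_rtol)
    # earliest scan entry among ties wins (deterministic tie-break)
    best = int(np.flatnonzero(tie)[0])
    table = pd.DataFrame(
        {
            "nx": dirs[:, 0],
            "ny": dirs[:, 1],
            "nz": dirs[:, 2],
            "area_um2": areas,
            "is_tie_minimum": tie,
        }
    )
    return dirs[best].copy(), float(areas[best]), table
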