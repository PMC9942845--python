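"""Observed division-plane orientation from segmented daughter pairs.

The normal of the newly formed wall is estimated directly from the label
image: every pair of 6-neighbor voxels where one daughter touches the
other contributes the unit vector pointing from daughter 1 to daughter 2,
and the average of these contributions (renormalized) is the plane normal.
The result is sign-ambiguous: the normal and its negation describe the
same plane.

Because the 6-neighbor unit vectors live on the lattice axes, evaluating
the sum on an anisotropic grid would bias the direction toward the finely
sampled axes; grids are therefore resampled to isotropic spacing first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import LabelGrid, resample_isotropic

__all__ = ["ObservedNormal", "observed_division_normal", "daughter_volume_ratio"]


@dataclass
class ObservedNormal:
    """Unit normal of the observed division plane (sign-ambiguous).

    ``pair_count`` is the number of contributing 6-neighbor voxel pairs and
    ``raw_magnitude`` the length of the averaged vector before
    renormalization: 1 for a perfectly flat axis-aligned wall, smaller for
    oblique or curved walls.
    """

    direction: np.ndarray
    pair_count: int
    raw_magnitude: float


def _require_label(grid: LabelGrid, label: int) -> None:
    if label <= 0:
        raise ValueError("daughter labels must be > 0")
    if not (grid.labels == label).any():
        raise ValueError(f"label not found: {label}")


def observed_division_normal(
    grid: LabelGrid, label1: int, label2: int, magnitude_floor: float = 0.2
) -> ObservedNormal:
    """Average 6-neighbor contact vector between two daughter labels.

    For every 6-neighbor pair (r, r') with ``m(r) = label1`` and
    ``m(r') = label2``, the unit vector (r' - r)/|r' - r| is accumulated;
    the sum is divided by the pair count and renormalized to unit length.

    Raises if the daughters share no 6-neighbor pair, or if the averaged
    vector's length falls below ``magnitude_floor`` (an interface too
    convoluted to carry one orientation).
    """
    _require_label(grid, label1)
    _require_label(grid, label2)
    grid = resample_isotropic(grid)
    a = grid.labels == label1
    b = grid.labels == label2

    vec = np.zeros(3)
    pairs = 0
    for axis in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        sl_lo, sl_hi = tuple(sl_lo), tuple(sl_hi)
        n_plus = int(np.count_nonzero(a[sl_lo] & b[sl_hi]))  # r' = r + e_axis
        n_minus = int(np.count_nonzero(a[sl_hi] & b[sl_lo]))  # r' = r - e_axis
        vec[axis] += n_plus - n_minus
        pairs += n_plus + n_minus

    if pairs == 0:
        raise ValueError("daughters not in contact (no 6-neighbor pair)")
    mean_vec = vec / pairs
    raw_magnitude = float(np.linalg.norm(mean_vec))
    if raw_magnitude < magnitude_floor:
        raise ValueError(
            f"interface orientation undefined: averaged vector length "
            f"{raw_magnitude:.3f} < floor {magnitude_floor}"
        )
    return ObservedNormal(
        direction=mean_vec / raw_magnitude,
        pair_count=pairs,
        raw_magnitude=raw_magnitude,
    )


def daughter_volume_ratio(grid: LabelGrid, label1: int, label2: int) -> float:
    """V1 / (V1 + V2) from physical voxel volumes."""
    _require_label(grid, label1)
    _require_label(grid, label2)
    v1 = grid.label_volume(label1)
    v2 = grid.label_volume(label2)
    return v1 / (v1 + v2)
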