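"""Observed-vs-simulated plane comparison and tissue-frame classification.

Division-plane normals are sign-ambiguous (a plane and its flipped normal
are the same plane), so all angles here are folded into [0°, 90°] using the
absolute dot product.  Orientation classes follow the leaf-tissue
vocabulary: a wall whose normal lies along the adaxial–abaxial axis is
periclinal (it creates inner/outer layers); along the proximal–distal axis,
transverse; along the medio-lateral axis, longitudinal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "OrientationFrame",
    "AngleComparison",
    "angle_between",
    "classify_orientation",
    "polar_table",
]


@dataclass
class OrientationFrame:
    """Orthonormal tissue axes: adaxial–abaxial, proximal–distal, medio-lateral."""

    adaxial_abaxial: np.ndarray
    proximal_distal: np.ndarray
    medio_lateral: np.ndarray

    def __post_init__(self) -> None:
        axes = []
        for name in ("adaxial_abaxial", "proximal_distal", "medio_lateral"):
            v = np.asarray(getattr(self, name), dtype=float)
            if abs(np.linalg.norm(v) - 1.0) > 1e-6:
                raise ValueError(f"{name} must be unit length")
            axes.append(v)
            setattr(self, name, v)
        for i in range(3):
            for j in range(i + 1, 3):
                if abs(axes[i] @ axes[j]) > 1e-6:
                    raise ValueError("frame axes must be pairwise orthogonal")

    @property
    def axes(self) -> np.ndarray:
        return np.stack([self.adaxial_abaxial, self.proximal_distal, self.medio_lateral])


@dataclass
class AngleComparison:
    """Folded angle between observed and simulated normals for one cell."""

    cell_id: str
    delta_theta: float  # degrees, [0, 90]
    global_min: bool | str = True  # True | False | "tie"
    orientation_class: str = "ambiguous"


def _as_unit(v, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError(f"{name} is the zero vector")
    if abs(n - 1.0) > 0.01:
        raise ValueError(f"{name} is not unit length (|v| = {n:.4f})")
    if abs(n - 1.0) > 1e-12:
        if abs(n - 1.0) > 1e-9:
            warnings.warn(f"{name} renormalized (|v| = {n:.6f})", stacklevel=3)
        v = v / n
    return v


def angle_between(n_obs, n_sim) -> float:
    """Folded angle (degrees, [0, 90]) between two plane normals.

    Uses arccos of the absolute dot product, so n and -n are equivalent;
    symmetric in its arguments.
    """
    a = _as_unit(n_obs, "n_obs")
    b = _as_unit(n_sim, "n_sim")
    return float(np.degrees(np.arccos(np.clip(abs(a @ b), 0.0, 1.0))))


_CLASS_BY_AXIS = ("periclinal", "transverse", "longitudinal")


def classify_orientation(
    normal, frame: OrientationFrame, tolerance_deg: float = 10.0
) -> str:
    """Nearest tissue axis of a plane normal, with an ambiguity band.

    Returns ``ambiguous`` when the two best axes are closer than
    ``tolerance_deg`` apart in folded angle.
    """
    angles = np.array([angle_between(normal, ax) for ax in frame.axes])
    order = np.argsort(angles)
    if angles[order[1]] - angles[order[0]] < tolerance_deg:
        return "ambiguous"
    return _CLASS_BY_AXIS[int(order[0])]


def polar_table(comparisons: list[AngleComparison]) -> pd.DataFrame:
    """One row per cell, sorted by cell_id; polar-scatter ready.

    Plot ``delta_theta`` as the polar angle: rows on the horizontal axis
    (0°) are cells whose observed wall coincides with the area-minimal
    prediction; rows near 90° deviate maximally.
    """
    rows = [
        {
            "cell_id": c.cell_id,
            "delta_theta_deg": c.delta_theta,
            "global_min": c.global_min,
            "orientation_class": c.orientation_class,
        }
        for c in comparisons
    ]
    table = pd.DataFrame(
        rows, columns=["cell_id", "delta_theta_deg", "global_min", "orientation_class"]
    )
    return table.sort_values("cell_id", kind="stable").reset_index(drop=True)
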