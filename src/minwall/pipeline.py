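"""End-to-end per-cell experiment: observe, simulate, compare.

For each cell in a manifest the pipeline extracts the mother shape,
quantifies the observed division plane and daughter volume ratio from the
daughter labels, relaxes the phase-field model seeded from the three
inertial eigen-axes with that measured ratio, and reports the folded angle
between the observed wall normal and the area-minimal (global-minimum)
prediction, plus the tissue-frame orientation class.  Cells may come from
label stacks on disk or from synthetic fixture specs sliced at a known
plane.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .compare import AngleComparison, OrientationFrame, angle_between, classify_orientation, polar_table
from .grids import CellMask, LabelGrid, extract_cell, load_label_stack
from .observed import daughter_volume_ratio, observed_division_normal
from .phasefield import DivisionPlaneResult, SimulationConfig, find_min_planes
from .synthetic import ShapeSpec, make_shape, slice_with_plane

__all__ = ["CellEntry", "RunManifest", "run_pipeline"]

log = logging.getLogger("minwall.pipeline")


@dataclass
class CellEntry:
    """One cell of a run manifest.

    Either ``grid_path`` (a label stack with the two daughter labels) or
    ``shape`` plus ``slice_normal``/``slice_fraction`` (a synthetic mother
    sliced into daughters on the fly) must be given.  ``mother_label``
    is optional: when absent the mother region is the union of the two
    daughters, as in post-division segmentations.
    """

    cell_id: str
    grid_path: str | Path | None = None
    spacing: tuple[float, float, float] | None = None
    shape: ShapeSpec | None = None
    slice_normal: tuple[float, float, float] | None = None
    slice_fraction: float = 0.5
    daughter_labels: tuple[int, int] = (1, 2)
    mother_label: int | None = None
    frame: OrientationFrame | None = None


@dataclass
class RunManifest:
    """Cells to process plus the shared simulation configuration."""

    cells: list[CellEntry]
    config: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        ids = [c.cell_id for c in self.cells]
        if len(set(ids)) != len(ids):
            raise ValueError("cell_ids must be unique")


def _load_cell(entry: CellEntry) -> LabelGrid:
    if entry.grid_path is not None:
        return load_label_stack(entry.grid_path, spacing=entry.spacing)
    if entry.shape is not None:
        if entry.slice_normal is None:
            raise ValueError(f"{entry.cell_id}: synthetic entry needs slice_normal")
        mask = make_shape(entry.shape)
        return slice_with_plane(mask, entry.slice_normal, entry.slice_fraction)
    raise ValueError(f"{entry.cell_id}: entry has neither grid_path nor shape")


def _mother_mask(grid: LabelGrid, entry: CellEntry) -> CellMask:
    if entry.mother_label is not None:
        return extract_cell(grid, entry.mother_label)
    l1, l2 = entry.daughter_labels
    union = np.isin(grid.labels, [l1, l2]).astype(np.int32)
    merged = LabelGrid(labels=union, spacing=grid.spacing, origin=grid.origin)
    return extract_cell(merged, 1)


def run_pipeline(
    manifest: RunManifest,
) -> tuple[pd.DataFrame, list[dict]]:
    """Process every manifest cell; tolerate per-cell failures.

    Returns ``(polar table, per-cell records)``.  Each record carries the
    observed normal, volume ratio, all three relaxation results and the
    comparison; failed cells get a record with an ``error`` key and are
    skipped in the table.  Deterministic given manifest + config.
    """
    comparisons: list[AngleComparison] = []
    records: list[dict] = []
    if not manifest.cells:
        log.warning("empty manifest: nothing to do")
        return polar_table([]), []

    for entry in manifest.cells:
        try:
            grid = _load_cell(entry)
            l1, l2 = entry.daughter_labels
            obs = observed_division_normal(grid, l1, l2)
            ratio = daughter_volume_ratio(grid, l1, l2)
            mother = _mother_mask(grid, entry)
            cfg = replace(manifest.config, volume_ratio=ratio)
            results: list[DivisionPlaneResult] = find_min_planes(mother, cfg)
            best = results[0]
            dtheta = angle_between(obs.direction, best.normal)
            # the observed wall coincides with the global minimum when the
            # folded angle is small; the flag mirrors per-cell coincidence calls
            global_min: bool | str = "tie" if best.tie else bool(dtheta <= 10.0)
            klass = (
                classify_orientation(obs.direction, entry.frame)
                if entry.frame is not None
                else "ambiguous"
            )
            comparisons.append(
                AngleComparison(
                    cell_id=entry.cell_id,
                    delta_theta=dtheta,
                    global_min=global_min,
                    orientation_class=klass,
                )
            )
            records.append(
                {
                    "cell_id": entry.cell_id,
                    "observed_normal": obs.direction,
                    "observed_pair_count": obs.pair_count,
                    "observed_raw_magnitude": obs.raw_magnitude,
                    "volume_ratio": ratio,
                    "results": results,
                    "delta_theta_deg": dtheta,
                    "orientation_class": klass,
                }
            )
            log.info(
                "%s: dtheta=%.2f deg, S=%.4f (sim), converged=%s, steps=%d",
                entry.cell_id, dtheta, best.area_sim, best.converged, best.steps,
            )
        except Exception as exc:  # per-cell isolation: record and continue
            log.error("%s failed: %s", entry.cell_id, exc)
            records.append({"cell_id": entry.cell_id, "error": str(exc)})

    return polar_table(comparisons), records
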