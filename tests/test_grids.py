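"""Label-grid I/O, cell extraction and voxel morphometrics."""

import numpy as np
import pytest

from minwall import (
    CellMask,
    LabelGrid,
    SimulationConfig,
    centroid_and_volume,
    extract_cell,
    inertial_axes,
    load_label_stack,
    save_label_stack,
    to_sim_grid,
)
from minwall.grids import resample_isotropic


def _ball_labels(radius_vox: float, spacing, margin=2) -> LabelGrid:
    """Digitized ball of given radius (in units of the finest spacing)."""
    h = min(spacing)
    r_um = radius_vox * h
    shape = tuple(int(np.ceil(2 * r_um / s)) + 2 * margin for s in spacing)
    idx = np.indices(shape)
    c = [(n / 2) * s for n, s in zip(shape, spacing)]
    d2 = sum(((idx[a] + 0.5) * spacing[a] - c[a]) ** 2 for a in range(3))
    return LabelGrid((d2 <= r_um**2).astype(np.int32), spacing)


# ---------------------------------------------------------------------------
# I/O


@pytest.mark.parametrize("suffix", [".tif", ".npz"])
def test_label_stack_round_trip(tmp_path, suffix):
    """Writer followed by reader is the identity on labels and spacing."""
    rng = np.random.default_rng(0)
    labels = rng.integers(0, 3, size=(6, 5, 4)).astype(np.int32)
    grid = LabelGrid(labels, spacing=(0.1, 0.1, 0.25))
    path = tmp_path / f"stack{suffix}"
    save_label_stack(grid, path)
    back = load_label_stack(path)
    np.testing.assert_array_equal(back.labels, labels)
    assert back.spacing == pytest.approx(grid.spacing)
    assert back.label_set == {0, 1, 2}


def test_uniform_stack_single_cell(tmp_path):
    grid = LabelGrid(np.ones((4, 4, 4), dtype=np.int32), spacing=(0.1, 0.1, 0.25))
    path = tmp_path / "ones.npz"
    save_label_stack(grid, path)
    back = load_label_stack(path)
    assert back.label_set == {1}
    assert np.count_nonzero(back.labels == 1) == 64


def test_non_integer_labels_rejected(tmp_path):
    path = tmp_path / "float.npz"
    np.savez(path, labels=np.ones((3, 3, 3), dtype=np.float32),
             spacing=np.array([0.1, 0.1, 0.1]))
    with pytest.raises(ValueError, match="non-integer"):
        load_label_stack(path)
    with pytest.raises(ValueError, match="non-integer"):
        LabelGrid(np.ones((3, 3, 3), dtype=float), spacing=(0.1, 0.1, 0.1))


def test_spacing_required_and_positive(tmp_path):
    path = tmp_path / "bare.npz"
    np.savez(path, labels=np.ones((3, 3, 3), dtype=np.int32))
    with pytest.raises(ValueError, match="spacing"):
        load_label_stack(path)
    with pytest.raises(ValueError, match="positive"):
        LabelGrid(np.ones((3, 3, 3), dtype=np.int32), spacing=(0.1, 0.0, 0.1))


# ---------------------------------------------------------------------------
# extract_cell


def test_extract_isotropic_is_threshold_identity():
    labels = np.zeros((8, 8, 8), dtype=np.int32)
    labels[2:6, 2:6, 2:6] = 5
    grid = LabelGrid(labels, spacing=(0.2, 0.2, 0.2))
    mask = extract_cell(grid, 5)
    assert mask.voxel_count == 64
    assert mask.volume == pytest.approx(64 * 0.2**3)
    assert mask.spacing == 0.2
    assert mask.source_label == 5


def test_extract_resampling_preserves_volume():
    """Anisotropic ball resampled to isotropic keeps physical volume to 2%."""
    grid = _ball_labels(radius_vox=20, spacing=(0.1, 0.1, 0.25))
    before = grid.label_volume(1)
    mask = extract_cell(grid, 1)
    assert mask.spacing == 0.1
    assert mask.volume == pytest.approx(before, rel=0.02)


def test_extract_errors():
    grid = LabelGrid(np.ones((4, 4, 4), dtype=np.int32), spacing=(0.1,) * 3)
    with pytest.raises(ValueError, match="label not found"):
        extract_cell(grid, 7)
    with pytest.raises(ValueError, match="extracellular"):
        extract_cell(grid, 0)


# ---------------------------------------------------------------------------
# centroid / volume / inertia


def test_centroid_and_volume_closed_form():
    occ = np.zeros((6, 6, 6), bool)
    occ[0:4, 0:4, 0:4] = True
    mask = CellMask(occ, spacing=1.0)
    centroid, volume = centroid_and_volume(mask)
    np.testing.assert_allclose(centroid, (2.0, 2.0, 2.0))
    assert volume == 64.0


def test_centroid_translation_equivariance():
    occ = np.zeros((10, 10, 10), bool)
    occ[1:4, 2:6, 3:5] = True
    c0, v0 = centroid_and_volume(CellMask(occ, spacing=0.5))
    shifted = np.roll(occ, (2, 1, 3), axis=(0, 1, 2))
    c1, v1 = centroid_and_volume(CellMask(shifted, spacing=0.5))
    np.testing.assert_allclose(c1 - c0, np.array([2, 1, 3]) * 0.5, atol=1e-12)
    assert v1 == v0


def test_ball_volume_analytic():
    grid = _ball_labels(radius_vox=10, spacing=(1.0, 1.0, 1.0))
    mask = extract_cell(grid, 1)
    _, volume = centroid_and_volume(mask)
    assert volume == pytest.approx(4 / 3 * np.pi * 10**3, rel=0.02)


def test_inertial_axes_cuboid_ordering():
    occ = np.zeros((44, 24, 14), bool)
    occ[2:42, 2:22, 2:12] = True  # 40 x 20 x 10
    axes = inertial_axes(CellMask(occ, spacing=1.0))
    assert not axes.degenerate_flag
    assert np.all(np.diff(axes.moments) <= 0)
    # leading axis along the 40-voxel direction, then 20, then 10
    for i in range(3):
        assert abs(axes.axes[i][i]) > 0.999
    # orthonormality
    np.testing.assert_allclose(axes.axes @ axes.axes.T, np.eye(3), atol=1e-10)


def test_inertial_axes_ball_degenerate():
    grid = _ball_labels(radius_vox=12, spacing=(1.0, 1.0, 1.0))
    axes = inertial_axes(extract_cell(grid, 1))
    assert axes.degenerate_flag
    assert np.ptp(axes.moments) / axes.moments[0] < 0.03


def test_inertial_axes_rotated_cuboid():
    """Leading eigen-axis tracks a 30° in-plane rotation of the long axis."""
    from minwall import ShapeSpec, make_shape

    mask = make_shape(
        ShapeSpec(kind="cuboid", dimensions=(12.0, 6.0, 4.0), spacing=0.15,
                  rotation_axis=(0, 0, 1), rotation_deg=30.0)
    )
    axes = inertial_axes(mask)
    expected = np.array([np.cos(np.deg2rad(30)), np.sin(np.deg2rad(30)), 0.0])
    angle = np.degrees(np.arccos(np.clip(abs(axes.axes[0] @ expected), 0, 1)))
    assert angle < 2.0


# ---------------------------------------------------------------------------
# simulation grid


def test_to_sim_grid_longest_axis_site_count():
    occ = np.zeros((40, 30, 24), bool)
    occ[2:38, 2:28, 2:22] = True
    mask = CellMask(occ, spacing=0.2)
    cfg = SimulationConfig(domain_length=1.5)
    domain, scale = to_sim_grid(mask, cfg)
    # margin of 1 on each side around round(domain_length / dx) = 30 sites
    assert domain.shape[0] == 30 + 2
    assert not domain[0].any() and not domain[-1].any()
    assert scale == pytest.approx(36 * 0.2 / 1.5)


def test_to_sim_grid_area_round_trip():
    """(simulation cross-section) x scale^2 recovers the physical area."""
    occ = np.zeros((84, 54, 44), bool)
    occ[2:82, 2:52, 2:42] = True  # 16 x 10 x 8 µm at 0.2 µm
    mask = CellMask(occ, spacing=0.2)
    cfg = SimulationConfig(domain_length=1.6)
    domain, scale = to_sim_grid(mask, cfg)
    mid = domain.shape[0] // 2
    area_sim = np.count_nonzero(domain[mid]) * cfg.dx**2
    assert area_sim * scale**2 == pytest.approx(10.0 * 8.0, rel=0.02)


def test_to_sim_grid_under_resolved():
    occ = np.zeros((6, 6, 6), bool)
    occ[2:4, 2, 2] = True  # 2-voxel mask
    mask = CellMask(occ, spacing=0.2)
    with pytest.raises(ValueError, match="under-resolved"):
        to_sim_grid(mask, SimulationConfig())


def test_resample_isotropic_whole_grid():
    grid = _ball_labels(radius_vox=15, spacing=(0.1, 0.1, 0.25))
    iso = resample_isotropic(grid)
    assert iso.spacing == (0.1, 0.1, 0.1)
    assert iso.label_volume(1) == pytest.approx(grid.label_volume(1), rel=0.02)
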