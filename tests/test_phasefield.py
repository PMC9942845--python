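"""Phase-field relaxation: initialization, dynamics, measures."""

import numpy as np
import pytest

from minwall import (
    PhaseField,
    SimulationConfig,
    division_surface_area,
    euler_step,
    field_surface_area,
    field_volume,
    free_energy,
    init_plane_split,
    relax,
    relax_mother,
    simulated_normal,
)
from minwall.phasefield import AREA_CALIBRATION
from minwall.compare import angle_between

EPS = 0.045
DX = 0.05


def _box_domain(shape):
    dom = np.zeros(shape, bool)
    dom[1:-1, 1:-1, 1:-1] = True
    return dom


def _tanh_profile(x, center, eps=EPS):
    return (1 + np.tanh((x - center) / (2 * np.sqrt(2) * eps))) / 2


def test_config_default_time_step():
    cfg = SimulationConfig()
    assert cfg.dt == pytest.approx((cfg.dx / cfg.eps) ** 2 / 30)
    with pytest.raises(ValueError):
        SimulationConfig(volume_ratio=1.0)
    with pytest.raises(ValueError):
        SimulationConfig(eps=-1)


# ---------------------------------------------------------------------------
# initialization


def test_init_symmetric_split_offset_zero():
    dom = _box_domain((34, 20, 20))
    cfg = SimulationConfig()
    f1, f2 = init_plane_split(dom, (1, 0, 0), cfg)
    assert abs(f1.meta["init_offset_sites"]) < 1.0  # through the centroid
    v1, v2 = field_volume(f1), field_volume(f2)
    assert v1 == pytest.approx(v2, rel=0.05)


@pytest.mark.parametrize("ratio", [0.3, 0.42])
def test_init_asymmetric_ratio_within_one_layer(ratio):
    dom = _box_domain((40, 22, 20))
    cfg = SimulationConfig(volume_ratio=ratio)
    f1, f2 = init_plane_split(dom, (1, 0, 0), cfg)
    achieved = field_volume(f1) / (field_volume(f1) + field_volume(f2))
    layer = 1.0 / 38  # one lattice layer of the 38-site axis
    assert abs(achieved - ratio) <= layer


def test_init_fields_disjoint_and_scaled():
    dom = _box_domain((34, 20, 20))
    cfg = SimulationConfig()
    f1, f2 = init_plane_split(dom, (0.6, 0.8, 0.0), cfg)
    assert np.all(f1.values + f2.values <= cfg.volume_fill + 1e-12)
    assert np.all((f1.values > 0) <= dom)  # clamped outside
    total = field_volume(f1) + field_volume(f2)
    assert total == pytest.approx(cfg.volume_fill * dom.sum() * cfg.dx**3, rel=1e-9)


def test_init_degenerate_domain_errors():
    dom = _box_domain((10, 20, 20))
    with pytest.raises(ValueError, match="degenerate"):
        init_plane_split(dom, (1, 0, 0), SimulationConfig())


# ---------------------------------------------------------------------------
# dynamics


def test_zero_fields_are_stationary_with_zero_targets():
    dom = _box_domain((20, 20, 20))
    cfg = SimulationConfig()
    f1 = PhaseField(np.zeros(dom.shape), dom, cfg.dx)
    f2 = PhaseField(np.zeros(dom.shape), dom, cfg.dx)
    euler_step((f1, f2), cfg, targets=(0.0, 0.0))
    assert np.all(f1.values == 0) and np.all(f2.values == 0)


def test_1d_tanh_profile_is_steady():
    """The equilibrium tanh interface with matched volume barely moves."""
    shape = (66, 10, 10)
    dom = _box_domain(shape)
    x = (np.arange(shape[0]) + 0.5) * DX
    prof = _tanh_profile(x, x[shape[0] // 2])
    vals = np.zeros(shape)
    vals[..., :, :] = prof[:, None, None]
    f1 = PhaseField(vals, dom, DX)
    f2 = PhaseField(np.zeros(shape), dom, DX)
    v0 = field_volume(f1)
    cfg = SimulationConfig(max_steps=3000)
    (f1, f2), steps, converged = relax((f1, f2), cfg, targets=(v0, 0.0))
    assert converged and steps < 3000  # per-step change < 1e-7 after transient
    # the profile stays a tanh interface at the same position
    mid = np.interp(0.5, f1.values[1:-1, 5, 5], np.arange(1, shape[0] - 1))
    assert abs(mid - (shape[0] // 2 - 0.5)) < 1.0


def test_free_energy_descends_without_volume_forcing():
    """dF/dt <= 0 for the pure gradient flow (volume force ~ 0)."""
    shape = (30, 22, 22)
    dom = _box_domain(shape)
    rng = np.random.default_rng(7)
    base = rng.random((5, 5, 5))
    from scipy.ndimage import zoom

    smooth = np.clip(zoom(base, np.array(shape) / 5, order=3)[: shape[0], : shape[1], : shape[2]], 0, 1)
    f1 = PhaseField(smooth * 0.6, dom, DX)
    f2 = PhaseField((1 - smooth) * 0.6, dom, DX)
    cfg = SimulationConfig(alpha=1e-9)
    energies = [free_energy(f1, f2, cfg)]
    for _ in range(60):
        euler_step((f1, f2), cfg, targets=(0.0, 0.0))
        # targets 0 with alpha ~ 0: pure free-energy descent
        energies.append(free_energy(f1, f2, cfg))
    diffs = np.diff(energies)
    assert np.all(diffs <= 1e-12)


def test_exclusion_term_reduces_overlap():
    """Where both daughters coexist, the beta term pushes them apart."""
    shape = (24, 24, 24)
    dom = _box_domain(shape)
    f1 = PhaseField(dom * 0.5, dom, DX)
    f2 = PhaseField(dom * 0.5, dom, DX)
    cfg = SimulationConfig(alpha=1e-9, beta=1.0)
    overlap0 = float((f1.values**2 * f2.values**2).sum())
    euler_step((f1, f2), cfg, targets=(0.0, 0.0))
    overlap1 = float((f1.values**2 * f2.values**2).sum())
    assert overlap1 < overlap0


def test_instability_guard_halves_dt():
    """A wildly unstable dt is retried with halved steps instead of blowing up."""
    shape = (26, 12, 12)
    dom = _box_domain(shape)
    cfg = SimulationConfig(dt=1.2, max_steps=400, steady_tol=1e-5)
    f1, f2 = init_plane_split(dom, (1, 0, 0), cfg)
    (f1, f2), steps, _ = relax((f1, f2), cfg)
    assert np.all(np.isfinite(f1.values))
    assert f1.meta["dt_used"] < 1.2


# ---------------------------------------------------------------------------
# measures


def test_field_volume_closed_form_and_linearity():
    shape = (22, 22, 22)
    dom = _box_domain(shape)
    vals = np.zeros(shape)
    vals[1:11, 1:21, 1:21] = 1.0  # half of the 20^3 interior
    f = PhaseField(vals, dom, 0.05)
    assert field_volume(f) == pytest.approx(0.5 * 20**3 * 0.05**3)
    f2 = PhaseField(vals * 0.5, dom, 0.05)
    assert field_volume(f2) == pytest.approx(0.5 * field_volume(f))


def test_surface_area_zero_for_uniform_fields():
    shape = (20, 20, 20)
    dom = np.ones(shape, bool)
    assert field_surface_area(PhaseField(np.zeros(shape), dom, DX), EPS) == 0.0
    assert field_surface_area(PhaseField(np.ones(shape), dom, DX), EPS) == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("eps", [0.03, 0.045, 0.06])
def test_planar_interface_calibration(eps):
    """Raw double-well quadrature = A/(6√2); calibrated = A, within 3%."""
    dx = 0.05 * (eps / 0.045)
    n = 64
    x = (np.arange(n) + 0.5) * dx
    prof = _tanh_profile(x, x[n // 2], eps)
    vals = np.broadcast_to(prof[:, None, None], (n, 20, 20)).copy()
    f = PhaseField(vals, np.ones((n, 20, 20), bool), dx)
    area_geo = (20 * dx) ** 2
    raw = field_surface_area(f, eps, calibration=1.0)
    assert raw == pytest.approx(area_geo / AREA_CALIBRATION, rel=0.03)
    assert field_surface_area(f, eps) == pytest.approx(area_geo, rel=0.03)


def _tanh_ball(n, r):
    c = n * DX / 2
    x = (np.arange(n) + 0.5) * DX
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    dist = np.sqrt((X - c) ** 2 + (Y - c) ** 2 + (Z - c) ** 2)
    return PhaseField(_tanh_profile(r - dist, 0.0), np.ones((n, n, n), bool), DX)


def test_tanh_sphere_area():
    f = _tanh_ball(40, 0.4)
    assert field_surface_area(f, EPS) == pytest.approx(4 * np.pi * 0.4**2, rel=0.05)


def test_tanh_ball_volume():
    # radius well above the interface width 2*sqrt(2)*eps ~ 0.13, where the
    # curvature correction to the diffuse-profile volume is negligible
    f = _tanh_ball(72, 1.2)
    assert field_volume(f) == pytest.approx(4 / 3 * np.pi * 1.2**3, rel=0.03)


def test_simulated_normal_planar_and_antisymmetric():
    shape = (20, 20, 44)
    dom = _box_domain(shape)
    z = (np.arange(shape[2]) + 0.5) * DX
    prof = _tanh_profile(z, z[shape[2] // 2])
    f1 = PhaseField(np.broadcast_to(1 - prof, shape).copy(), dom, DX)
    f2 = PhaseField(np.broadcast_to(prof, shape).copy(), dom, DX)
    n = simulated_normal(f1, f2)
    assert abs(n[2]) > 0.999
    n_swapped = simulated_normal(f2, f1)
    np.testing.assert_allclose(n_swapped, -n, atol=1e-9)


def test_simulated_normal_no_contact_errors():
    shape = (20, 20, 20)
    dom = _box_domain(shape)
    f1 = PhaseField(np.zeros(shape), dom, DX)
    f2 = PhaseField(np.zeros(shape), dom, DX)
    with pytest.raises(ValueError, match="contact"):
        simulated_normal(f1, f2)


# ---------------------------------------------------------------------------
# drivers


def test_relax_mother_volume_and_flatness():
    dom = _box_domain((34, 22, 18))
    cfg = SimulationConfig()
    rho0, s0 = relax_mother(dom, cfg)
    target = dom.sum() * cfg.dx**3
    assert field_volume(rho0) == pytest.approx(target, rel=0.02)
    assert np.all(rho0.values[~rho0.domain] == 0)
    # under zero-flux walls the mother field is featureless: S0 << any wall
    assert s0 < 0.05


def test_division_area_formula_identity():
    dom = _box_domain((30, 20, 20))
    cfg = SimulationConfig()
    rho0, _ = relax_mother(dom, cfg)
    zero = PhaseField(np.zeros(dom.shape), dom, cfg.dx)
    s = division_surface_area(rho0, zero, rho0, cfg)
    assert s == pytest.approx(0.0, abs=1e-9)


def test_relaxed_volumes_and_minimal_plane(cuboid_results):
    """The minimal-area steady state honors its volume targets (2%) and
    stays perpendicular to the long axis (5°)."""
    best = cuboid_results[0]
    assert best.converged
    for v, t in zip(best.volumes, best.target_volumes):
        assert abs(v - t) / t <= 0.02
    assert angle_between(best.normal, (1, 0, 0)) <= 5.0


def test_energy_descent_along_relaxation():
    """F decreases monotonically after the initial transient."""
    dom = _box_domain((34, 22, 18))
    cfg = SimulationConfig(max_steps=4000)
    f1, f2 = init_plane_split(dom, (1, 0, 0), cfg)
    (f1, f2), steps, _ = relax((f1, f2), cfg)
    hist = f1.meta["history"]
    f_vals = [h["free_energy"] for h in hist]
    skip = max(1, int(0.05 * len(f_vals)))
    diffs = np.diff(f_vals[skip:])
    assert np.all(diffs <= 1e-9)


def test_mirror_symmetry_of_normals(wedge_mask, wedge_results):
    """Reflecting the mask through a lattice plane reflects the normals."""
    from minwall import CellMask, find_min_planes

    reflected = CellMask(wedge_mask.occupancy[:, ::-1, :].copy(), wedge_mask.spacing)
    res_r = find_min_planes(reflected, SimulationConfig())
    for a, b in zip(wedge_results, res_r):
        mirrored = a.normal * np.array([1, -1, 1])
        assert angle_between(mirrored, b.normal) <= 1.0
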