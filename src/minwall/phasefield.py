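"""Volume-constrained two-phase relaxation to area-minimal division surfaces.

Two phase fields rho_1, rho_2 in [0, 1] represent the daughter cells inside
the mother-cell domain.  Their dynamics descend the interfacial free energy

    F[rho_1, rho_2] = int_Omega sum_i [ eps^2/2 |grad rho_i|^2
                      + 1/4 rho_i^2 (1 - rho_i)^2
                      + beta/2 rho_i^2 rho_j^2 ] dr

augmented by a soft volume-constraint force
g_i = alpha rho_i (1 - rho_i) (V_i0 - V(rho_i)), so each daughter keeps its
target volume while its interface shrinks.  The mother boundary is a
zero-flux (mirror) wall, so fields sit flush against it and the division
interface meets it at 90 degrees, the natural contact condition of an
area-minimizing surface.  At steady state the daughters tile the mother up
to the thin band excluded by the division interface (the reason the
targets sum to only 90% of the mother volume), and the area of the wall
between them is

    S = (S_1 + S_2 - S_0) / 2

with each surface area S_i read off the diffuse interface by the
double-well quadrature (S_0, the mother's own reference field, is
featureless under mirror walls and contributes ~0).  Relaxations seeded
perpendicular to the three inertial eigen-axes of the mother land in the
global and local minima; the smallest S among converged runs is the
geometric-rule prediction of the division plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._kernels import run_block
from .grids import CellMask, inertial_axes, to_sim_grid

__all__ = [
    "SimulationConfig",
    "PhaseField",
    "DivisionPlaneResult",
    "init_plane_split",
    "euler_step",
    "relax",
    "field_volume",
    "field_surface_area",
    "free_energy",
    "relax_mother",
    "division_surface_area",
    "simulated_normal",
    "find_min_planes",
]

#: Eq-area calibration: a flat equilibrium interface contributes
#: 1/(6*sqrt(2)) of its geometric area to the double-well quadrature.
AREA_CALIBRATION = 6.0 * math.sqrt(2.0)


@dataclass
class SimulationConfig:
    """Numerical parameters of the relaxation.

    Defaults: lattice step ``dx = 0.05``, interface parameter
    ``eps = 0.045``, explicit-Euler time step ``dt = (dx/eps)^2 / 30``,
    volume-constraint strength ``alpha = 2``, mutual-exclusion strength
    ``beta = 1``, and daughter target volumes summing to 90% of the
    observed mother volume (the slight deflation keeps the thin
    interfaces from stalling the relaxation).
    """

    dx: float = 0.05
    eps: float = 0.045
    dt: float | None = None
    alpha: float = 2.0
    beta: float = 1.0
    volume_fill: float = 0.90
    volume_ratio: float = 0.5
    domain_length: float = 1.5
    max_steps: int = 200_000
    steady_tol: float = 1e-7
    steady_patience: int = 100
    diag_interval: int = 500
    area_calibration: float = AREA_CALIBRATION
    tie_rtol: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt is None:
            self.dt = (self.dx / self.eps) ** 2 / 30.0
        for name in ("dx", "eps", "dt", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.beta < 0:  # 0 allowed: single-field (mother) relaxation
            raise ValueError("beta must be >= 0")
        if not (0.0 < self.volume_fill <= 1.0):
            raise ValueError("volume_fill must be in (0, 1]")
        if not (0.0 < self.volume_ratio < 1.0):
            raise ValueError("volume_ratio must be in (0, 1)")


@dataclass
class PhaseField:
    """Scalar field rho on a masked simulation lattice.

    ``values`` is clamped to 0 outside ``domain``; ``meta`` carries
    diagnostic extras (initial plane offset, relaxation history).
    """

    values: np.ndarray
    domain: np.ndarray
    dx: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.ascontiguousarray(self.values, dtype=np.float64)
        self.domain = np.ascontiguousarray(self.domain, dtype=bool)
        if self.values.shape != self.domain.shape:
            raise ValueError("values and domain shapes differ")
        self.values[~self.domain] = 0.0

    def copy(self) -> "PhaseField":
        return PhaseField(self.values.copy(), self.domain, self.dx, dict(self.meta))


@dataclass(eq=False)
class DivisionPlaneResult:
    """One converged relaxation: predicted wall normal, area, diagnostics."""

    normal: np.ndarray
    area_sim: float
    area_phys: float
    free_energy: float
    volumes: tuple[float, float]
    target_volumes: tuple[float, float]
    init_axis: int
    steps: int
    converged: bool
    is_global_min: bool = False
    tie: bool = False


def _domain_index(domain: np.ndarray) -> np.ndarray:
    idx = np.argwhere(domain).astype(np.int64)
    if idx.size == 0:
        raise ValueError("empty domain")
    if (
        idx[:, 0].min() == 0
        or idx[:, 1].min() == 0
        or idx[:, 2].min() == 0
        or idx[:, 0].max() == domain.shape[0] - 1
        or idx[:, 1].max() == domain.shape[1] - 1
        or idx[:, 2].max() == domain.shape[2] - 1
    ):
        raise ValueError("domain touches the array edge; an empty margin is required")
    return np.ascontiguousarray(idx)


def _targets(domain: np.ndarray, config: SimulationConfig) -> tuple[float, float]:
    v_mother = float(np.count_nonzero(domain)) * config.dx**3
    v_total = config.volume_fill * v_mother
    return (config.volume_ratio * v_total, (1.0 - config.volume_ratio) * v_total)


# ---------------------------------------------------------------------------
# Initialization


def init_plane_split(
    domain: np.ndarray, axis, config: SimulationConfig
) -> tuple[PhaseField, PhaseField]:
    """Seed the two daughters as half-spaces perpendicular to ``axis``.

    The plane passes near the domain centroid; for asymmetric volume
    ratios its offset is adjusted by bisection so the initial voxel split
    matches ``config.volume_ratio`` to within one lattice layer.  Both
    fields are then multiplied by ``volume_fill`` so the initial volumes
    equal the targets.
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    coords = np.argwhere(domain)
    if coords.size == 0:
        raise ValueError("empty domain")
    s = (coords - coords.mean(axis=0)) @ axis
    span = s.max() - s.min()
    if span < 15:
        raise ValueError(
            f"degenerate domain: {span + 1:.0f} sites along the split axis (< 16)"
        )
    total = len(s)
    # limit of bisection on the (monotone, piecewise-constant) voxel count:
    # snap the offset midway between the lattice layers bracketing the target
    k = int(np.clip(round(config.volume_ratio * total), 1, total - 1))
    ss = np.sort(s)
    c = 0.5 * (ss[k - 1] + ss[k])
    below = s < c

    shape = domain.shape
    rho1 = np.zeros(shape)
    rho2 = np.zeros(shape)
    rho1[tuple(coords[below].T)] = config.volume_fill
    rho2[tuple(coords[~below].T)] = config.volume_fill
    meta = {"init_axis_vector": axis, "init_offset_sites": float(c)}
    return (
        PhaseField(rho1, domain, config.dx, dict(meta)),
        PhaseField(rho2, domain, config.dx, dict(meta)),
    )


# ---------------------------------------------------------------------------
# Dynamics


def euler_step(
    fields: tuple[PhaseField, PhaseField],
    config: SimulationConfig,
    targets: tuple[float, float] | None = None,
) -> tuple[PhaseField, PhaseField]:
    """One explicit Euler update of both fields (in place).

    ``targets`` defaults to the volume targets implied by the domain,
    ``volume_fill`` and ``volume_ratio``.
    """
    f1, f2 = fields
    if f1.domain is not f2.domain and not np.array_equal(f1.domain, f2.domain):
        raise ValueError("fields must share one domain")
    if f1.dx != f2.dx:
        raise ValueError("fields must share dx")
    if targets is None:
        targets = _targets(f1.domain, config)
    idx = _domain_index(f1.domain)
    dom = f1.domain.astype(np.float64)
    b1 = np.zeros_like(f1.values)
    b2 = np.zeros_like(f2.values)
    _, _, maxdiff, finite = run_block(
        f1.values, f2.values, b1, b2, dom, idx, 1,
        config.eps, config.dt, config.dx, config.alpha, config.beta,
        targets[0], targets[1], config.steady_tol, config.steady_patience, 0,
    )
    if not finite or not np.isfinite(f1.values).all() or not np.isfinite(f2.values).all():
        raise FloatingPointError(
            f"non-finite field values after Euler step (dt={config.dt:g}); "
            "reduce dt or increase eps"
        )
    return f1, f2


def relax(
    fields: tuple[PhaseField, PhaseField],
    config: SimulationConfig,
    targets: tuple[float, float] | None = None,
    record_history: bool = True,
) -> tuple[tuple[PhaseField, PhaseField], int, bool]:
    """Iterate the Euler update until steady state.

    Steady state means the max per-site |drho| stays below
    ``config.steady_tol`` for ``config.steady_patience`` consecutive
    steps; the run stops at ``config.max_steps`` otherwise.  On numerical
    blow-up the run restarts from the initial fields with dt halved, up to
    three times.  The relaxation history (step, free energy, volumes, max
    |drho| at each diagnostic interval) is stored in
    ``fields[0].meta["history"]``.
    """
    f1, f2 = fields
    if targets is None:
        targets = _targets(f1.domain, config)
    idx = _domain_index(f1.domain)
    dom = f1.domain.astype(np.float64)
    init1, init2 = f1.values.copy(), f2.values.copy()
    dt = config.dt

    for attempt in range(4):
        steps = 0
        streak = 0
        converged = False
        history: list[dict] = []
        b1 = np.zeros_like(f1.values)
        b2 = np.zeros_like(f2.values)
        blown_up = False
        while steps < config.max_steps:
            block = min(config.diag_interval, config.max_steps - steps)
            done, streak, maxdiff, finite = run_block(
                f1.values, f2.values, b1, b2, dom, idx, block,
                config.eps, dt, config.dx, config.alpha, config.beta,
                targets[0], targets[1], config.steady_tol,
                config.steady_patience, streak,
            )
            steps += done
            # the fused kernel is compiled with fast-math (no-NaN assumptions),
            # so blow-up detection must happen out here
            if not finite or not np.isfinite(f1.values).all() or not np.isfinite(f2.values).all():
                blown_up = True
                break
            if record_history:
                history.append(
                    {
                        "step": steps,
                        "free_energy": free_energy(f1, f2, config),
                        "volume_1": field_volume(f1),
                        "volume_2": field_volume(f2),
                        "max_dpho": maxdiff,
                    }
                )
            if streak >= config.steady_patience:
                converged = True
                break
        if not blown_up:
            break
        # restart with a smaller time step (explicit-scheme stability guard)
        dt *= 0.5
        f1.values[:] = init1
        f2.values[:] = init2
    else:
        raise FloatingPointError("relaxation unstable even after halving dt 3 times")

    np.clip(f1.values, 0.0, 1.0, out=f1.values)
    np.clip(f2.values, 0.0, 1.0, out=f2.values)
    f1.meta["history"] = history
    f1.meta["dt_used"] = dt
    f2.meta["dt_used"] = dt
    return (f1, f2), steps, converged


# ---------------------------------------------------------------------------
# Measurements


def field_volume(fld: PhaseField) -> float:
    """V(rho) = sum(rho) dx^3."""
    return float(fld.values.sum()) * fld.dx**3


def _masked_gradient(values: np.ndarray, domain: np.ndarray, dx: float) -> list[np.ndarray]:
    """Central-difference gradient with mirror values outside the domain.

    A neighbor outside the mother domain (or outside the array) mirrors the
    center value, matching the zero-flux walls of the dynamics; the wall
    itself therefore contributes no spurious gradient to the quadratures.
    """
    v = np.pad(values, 1, mode="edge")
    d = np.pad(domain, 1, mode="edge")
    center = (slice(1, -1),) * 3
    grads = []
    for a in range(3):
        sl_p = list(center)
        sl_m = list(center)
        sl_p[a] = slice(2, None)
        sl_m[a] = slice(None, -2)
        vp = np.where(d[tuple(sl_p)], v[tuple(sl_p)], values)
        vm = np.where(d[tuple(sl_m)], v[tuple(sl_m)], values)
        grads.append((vp - vm) / (2.0 * dx))
    return grads


def _gradient_sq(values: np.ndarray, domain: np.ndarray, dx: float) -> np.ndarray:
    gx, gy, gz = _masked_gradient(values, domain, dx)
    return gx * gx + gy * gy + gz * gz


def field_surface_area(
    fld: PhaseField, eps: float, calibration: float = AREA_CALIBRATION
) -> float:
    """Diffuse-interface surface area by double-well quadrature.

    Integrates ``eps/2 |grad rho|^2 + rho^2 (1 - rho)^2 / (4 eps)`` by the
    midpoint rule.  Along the equilibrium tanh profile both terms
    contribute equally and the integral per unit geometric interface area
    is 1/(6 sqrt 2); the calibration factor (default 6 sqrt 2) converts the
    raw integral into a geometric area.  Pass ``calibration=1`` for the
    raw integral.
    """
    rho = fld.values
    e = 0.5 * eps * _gradient_sq(rho, fld.domain, fld.dx) + rho**2 * (1.0 - rho) ** 2 / (4.0 * eps)
    return float(e[fld.domain].sum()) * fld.dx**3 * calibration


def free_energy(f1: PhaseField, f2: PhaseField, config: SimulationConfig) -> float:
    """Total free energy F[rho1, rho2] by midpoint quadrature."""
    e = 0.0
    for a, b in ((f1, f2), (f2, f1)):
        rho, other = a.values, b.values
        e += (
            0.5 * config.eps**2 * _gradient_sq(rho, a.domain, a.dx)
            + 0.25 * rho**2 * (1.0 - rho) ** 2
            + 0.5 * config.beta * rho**2 * other**2
        )[a.domain].sum()
    return float(e) * f1.dx**3


def division_surface_area(
    f1: PhaseField, f2: PhaseField, f0: PhaseField, config: SimulationConfig
) -> float:
    """S = (S1 + S2 - S0) / 2 from calibrated surface areas, floored at 0.

    The daughters' outer boundary layers conform to the mother's, so their
    contributions cancel against S0 and only the wall between the
    daughters remains.
    """
    s1 = field_surface_area(f1, config.eps, config.area_calibration)
    s2 = field_surface_area(f2, config.eps, config.area_calibration)
    s0 = field_surface_area(f0, config.eps, config.area_calibration)
    return max(0.0, 0.5 * (s1 + s2 - s0))


def simulated_normal(
    f1: PhaseField, f2: PhaseField, weight_floor: float = 1e-8
) -> np.ndarray:
    """Mean normal of the daughter-daughter wall (sign-ambiguous).

    n = -int grad(rho1) rho1 (1-rho1) rho2 (1-rho2) dr, renormalized.  The
    weight concentrates on the region where both interfaces overlap, i.e.
    the division wall.
    """
    w = f1.values * (1.0 - f1.values) * f2.values * (1.0 - f2.values)
    weight = float(w.sum()) * f1.dx**3
    if weight < weight_floor:
        raise ValueError(
            f"no contact surface: interface weight {weight:.3e} < floor {weight_floor:.0e}"
        )
    grads = _masked_gradient(f1.values, f1.domain, f1.dx)
    v = -np.array([float((g * w).sum()) for g in grads]) * f1.dx**3
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("degenerate division-wall normal (zero integral)")
    return v / n


# ---------------------------------------------------------------------------
# Drivers


def relax_mother(
    domain: np.ndarray, config: SimulationConfig
) -> tuple[PhaseField, float]:
    """Relax the single mother reference field and return (rho0, S0).

    Starts from the binary domain mask with target volume ``V(domain)``
    and no exclusion term.  Under the zero-flux walls the mother field has
    no boundary layer to form and relaxes to ~1 throughout, so S0 is the
    (small) residual the same quadrature would report for any daughter's
    wall-hugging bulk; it is subtracted in the division-area formula.
    """
    rho0 = PhaseField(domain.astype(float), domain, config.dx)
    zero = PhaseField(np.zeros(domain.shape), domain, config.dx)
    cfg = replace(config, beta=0.0)
    v_target = float(np.count_nonzero(domain)) * config.dx**3
    (rho0, _), steps, converged = relax(
        (rho0, zero), cfg, targets=(v_target, 0.0), record_history=False
    )
    if not converged:
        raise RuntimeError(f"mother field did not converge in {steps} steps")
    s0 = field_surface_area(rho0, config.eps, config.area_calibration)
    rho0.meta["steps"] = steps
    return rho0, s0


def find_min_planes(
    mask: CellMask, config: SimulationConfig, mother: tuple[PhaseField, float] | None = None
) -> list[DivisionPlaneResult]:
    """Relax from all three inertial eigen-axis seeds; rank division areas.

    Runs one volume-constrained relaxation per eigen-axis of the mother's
    inertia tensor, measures each converged division-wall area S, and
    flags the smallest as the global-minimum candidate.  When the two
    smallest S agree within ``config.tie_rtol`` the minimum is reported as
    a tie (degenerate geometry); the tied result with the lowest eigen-axis
    index is listed first.  Deterministic given (mask, config).
    """
    domain, scale = to_sim_grid(mask, config)
    axes = inertial_axes(mask).axes
    if mother is None:
        rho0, s0 = relax_mother(domain, config)
    else:
        rho0, s0 = mother

    results: list[DivisionPlaneResult] = []
    for i in range(3):
        f1, f2 = init_plane_split(domain, axes[i], config)
        targets = _targets(domain, config)
        (f1, f2), steps, converged = relax((f1, f2), config, targets=targets)
        s = division_surface_area(f1, f2, rho0, config)
        normal = simulated_normal(f1, f2)
        results.append(
            DivisionPlaneResult(
                normal=normal,
                area_sim=s,
                area_phys=s * scale**2,
                free_energy=free_energy(f1, f2, config),
                volumes=(field_volume(f1), field_volume(f2)),
                target_volumes=targets,
                init_axis=i,
                steps=steps,
                converged=converged,
            )
        )

    if not any(r.converged for r in results):
        raise RuntimeError("all three relaxations failed to converge")

    results.sort(key=lambda r: (r.area_sim, r.init_axis))
    s_min = results[0].area_sim
    tied = [r for r in results if r.area_sim <= s_min * (1.0 + config.tie_rtol)]
    is_tie = len(tied) > 1
    winner = min(tied, key=lambda r: r.init_axis)
    for r in results:
        r.tie = is_tie and r in tied
        r.is_global_min = r is winner
    # global-minimum candidate first, the rest by ascending area
    results.sort(key=lambda r: (not r.is_global_min, r.area_sim, r.init_axis))
    return results
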