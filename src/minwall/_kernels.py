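"""Numba kernels for the explicit-Euler phase-field relaxation.

The update implemented here is

    drho_i/dt = eps^2 lap(rho_i)
                + rho_i (1 - rho_i) (rho_i - 1/2 + alpha (V_i0 - V(rho_i)))
                - beta rho_i rho_j^2

with a 7-point Laplacian, V(rho) = sum(rho) dx^3, on the masked mother-cell
domain.  Sites outside the domain are never updated and the Laplacian
mirrors missing neighbors (zero-flux walls), so the division interface
meets the mother boundary at 90 degrees -- the natural contact condition of
an area-minimizing surface.  The volume entering the constraint force is
the volume at the start of each step.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_block"]


@njit(cache=True, fastmath=True)
def run_block(
    r1,
    r2,
    b1,
    b2,
    dom,
    idx,
    nsteps,
    eps,
    dt,
    dx,
    alpha,
    beta,
    v1_target,
    v2_target,
    tol,
    patience,
    streak,
):
    """Advance both fields up to ``nsteps`` explicit-Euler steps.

    ``dom`` is the domain mask as float64 (1 inside, 0 outside); ``idx``
    lists the domain sites (N, 3); ``b1``/``b2`` are scratch buffers (zero
    outside the domain).  Returns ``(steps_done, streak, maxdiff, finite)``
    where ``streak`` counts consecutive steps with max per-site |drho| <
    tol; the loop exits early once ``streak >= patience``.  On exit
    ``r1``/``r2`` hold the current fields.
    """
    n = idx.shape[0]
    dxcube = dx * dx * dx
    lap_c = eps * eps / (dx * dx)

    # current volumes
    v1 = 0.0
    v2 = 0.0
    for m in range(n):
        i, j, k = idx[m, 0], idx[m, 1], idx[m, 2]
        v1 += r1[i, j, k]
        v2 += r2[i, j, k]
    v1 *= dxcube
    v2 *= dxcube

    cur1, cur2 = r1, r2
    new1, new2 = b1, b2
    steps_done = 0
    maxdiff = 0.0
    finite = True

    for _ in range(nsteps):
        g1 = alpha * (v1_target - v1)
        g2 = alpha * (v2_target - v2)
        nv1 = 0.0
        nv2 = 0.0
        maxdiff = 0.0
        for m in range(n):
            i, j, k = idx[m, 0], idx[m, 1], idx[m, 2]
            a = cur1[i, j, k]
            b = cur2[i, j, k]
            # mirror walls: a neighbor outside the domain contributes 0
            d0 = dom[i - 1, j, k]
            d1 = dom[i + 1, j, k]
            d2 = dom[i, j - 1, k]
            d3 = dom[i, j + 1, k]
            d4 = dom[i, j, k - 1]
            d5 = dom[i, j, k + 1]
            lap1 = (
                d0 * (cur1[i - 1, j, k] - a)
                + d1 * (cur1[i + 1, j, k] - a)
                + d2 * (cur1[i, j - 1, k] - a)
                + d3 * (cur1[i, j + 1, k] - a)
                + d4 * (cur1[i, j, k - 1] - a)
                + d5 * (cur1[i, j, k + 1] - a)
            )
            lap2 = (
                d0 * (cur2[i - 1, j, k] - b)
                + d1 * (cur2[i + 1, j, k] - b)
                + d2 * (cur2[i, j - 1, k] - b)
                + d3 * (cur2[i, j + 1, k] - b)
                + d4 * (cur2[i, j, k - 1] - b)
                + d5 * (cur2[i, j, k + 1] - b)
            )
            da = lap_c * lap1 + a * (1.0 - a) * (a - 0.5 + g1) - beta * a * b * b
            db = lap_c * lap2 + b * (1.0 - b) * (b - 0.5 + g2) - beta * b * a * a
            an = a + dt * da
            bn = b + dt * db
            new1[i, j, k] = an
            new2[i, j, k] = bn
            nv1 += an
            nv2 += bn
            d = abs(an - a)
            if abs(bn - b) > d:
                d = abs(bn - b)
            if d > maxdiff:
                maxdiff = d
        v1 = nv1 * dxcube
        v2 = nv2 * dxcube
        cur1, cur2, new1, new2 = new1, new2, cur1, cur2
        steps_done += 1
        # NaN-safe blow-up check: comparisons against NaN are always False,
        # so test the accumulated volumes rather than maxdiff
        if not (np.isfinite(v1) and np.isfinite(v2) and np.isfinite(maxdiff)):
            finite = False
            break
        if maxdiff < tol:
            streak += 1
            if streak >= patience:
                break
        else:
            streak = 0

    if cur1 is not r1:
        for m in range(n):
            i, j, k = idx[m, 0], idx[m, 1], idx[m, 2]
            r1[i, j, k] = cur1[i, j, k]
            r2[i, j, k] = cur2[i, j, k]
    return steps_done, streak, maxdiff, finite
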