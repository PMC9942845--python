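# Methods

## The question the package answers

Plant cells cannot migrate, so the orientation of each division wall
decides tissue architecture. A long-standing default rule — often called
the geometric or minimal-area rule — says the new wall is the
smallest-area surface passing through the mother cell's centroid. Testing
that rule on segmented 3D microscopy data needs three computations:

1. **Observe** — measure the orientation of the actual division wall from
   the labeled daughter pair.
2. **Predict** — find the area-minimal division surface(s) of the mother
   shape at the measured daughter volume ratio.
3. **Compare** — fold the angle between observed and predicted wall
   normals into [0°, 90°] and ask whether the observed wall coincides with
   the *global* minimum or only a local one.

The package implements all three on integer label stacks plus a synthetic
voxel-cell generator, so the whole analysis runs and is validated without
access to the original microscopy segmentations.

## Observed wall orientation

For every pair of 6-neighbor voxels (r, r′) with daughter 1 at r and
daughter 2 at r′, the unit vector (r′ − r)/|r′ − r| is accumulated; the
average over all contributing pairs, renormalized to unit length, is the
wall normal n̂. The normal is sign-ambiguous (n̂ and −n̂ are the same
plane), so all downstream angles use |n̂ · m̂|.

Two numerical choices:

* **Isotropic resampling first.** The six neighbor vectors lie on the
  lattice axes, so on an anisotropic grid (confocal z-spacing 0.18–0.25 µm
  vs finer xy) the average would be biased toward the finely sampled axes.
  Grids are nearest-neighbor resampled to the smallest axis spacing before
  evaluation. Nearest-neighbor (not linear) keeps labels integral.
* **Magnitude floor.** The pre-normalization length of the averaged vector
  is 1 for a flat axis-aligned wall and decreases as the wall becomes
  oblique (≈ mean |cos| between the wall normal and the lattice axes, ~0.57
  at worst) or convoluted. Below a floor of 0.2 the interface carries no
  single orientation and the estimator raises instead of returning noise.

On digitized fixtures ≥ 48 voxels across, cut at random planes with volume
fractions 0.3–0.7, the estimator recovers the generating normal to within
~1° (tested against a 5° bound).

## Phase-field prediction of the minimal wall

Two fields ρ₁, ρ₂ ∈ [0, 1] mark the daughters inside the mother domain Ω.
They evolve by explicit Euler on

∂ρᵢ/∂t = ε²∇²ρᵢ + ρᵢ(1−ρᵢ)(ρᵢ − ½ + α(V᙮ᵢ₀ − V(ρᵢ))) − β ρᵢ ρⱼ²,

the gradient flow of a Ginzburg–Landau energy (gradient penalty + double
well + pairwise exclusion) plus a soft volume constraint
gᵢ = αρᵢ(1−ρᵢ)(Vᵢ₀ − V(ρᵢ)). Default parameters: lattice step dx = 0.05,
interface parameter ε = 0.045, dt = (dx/ε)²/30 ≈ 0.041, α = 2, β = 1. The daughter targets are Vᵢ₀ = rᵢ · 0.9 · V(mother), where
rᵢ is the measured daughter volume ratio; the 10% deflation leaves room
for the volume excluded by the diffuse wall between the daughters, which
otherwise squeezes ("thins") the interface and stalls the relaxation.
V(ρ) = Σρ·dx³ — the linear functional makes the constraint force's fixed
point exact and is the cheapest consistent choice.

Each relaxation is seeded with a binary half-space split of the domain
perpendicular to one of the three eigenvectors of the mother's
centroid-centered second-moment tensor (the inertia axes; centering makes
them origin-independent). For asymmetric ratios the seed plane is offset
from the centroid so the initial voxel split already matches the target
ratio to within one lattice layer — the constraint force then starts at
its fixed point. Three runs (one per axis) land in the global and local
minima; areas are ranked and the smallest flagged as the global-minimum
candidate. When the two smallest areas agree within 3% the minimum is
reported as a tie (degenerate geometry, e.g. a sphere or cube), with the
lowest eigen-axis index listed first for determinism.

**Steady state** means max per-site |Δρ| < 10⁻⁷ sustained over 100
consecutive steps, capped at 200 000 steps. An automatic guard halves dt
and restarts (up to 3 times) if the explicit scheme blows up; blow-up is
detected on the NumPy side because the fused compute kernel is compiled
with fast-math (no-NaN) assumptions.

### Boundary condition at the mother wall

The calculation region Ω is the mother mask on a rescaled lattice (longest
bounding-box side = `domain_length`, default 1.5 ≈ 30 sites, margin of one
empty site). Sites outside Ω are never updated, and the 7-point Laplacian
**mirrors** missing neighbors — zero-flux walls. The fields therefore sit
flush against the wall with no boundary layer, and the division interface
meets the wall at 90°, which is the natural contact condition of an
area-minimizing surface. The alternative — clamping ρ = 0 outside Ω
(Dirichlet) — forces a boundary layer of width ~2√2ε ≈ 0.13 along the
whole mother surface; at the ~30–50 site domains used here that layer
would consume 30–50% of the cell volume, making the volume constraint
unsatisfiable and collapsing the measured wall areas. (At several hundred
sites per axis both conditions agree; zero-flux is the one that works at
this resolution and is also the physically standard wall condition.)

Consequently the mother reference field ρ₀ relaxes from the binary mask
with target V(Ω) and stays ≈ 1 everywhere, so its area reading S₀ ≈ 0.

### Measuring the wall

Surface areas are read off a relaxed field by midpoint quadrature of
∫ [ (ε/2)|∇ρ|² + ρ²(1−ρ)²/(4ε) ] dr over Ω, with wall-mirrored central
differences for ∇ρ. Along the 1D equilibrium profile
ρ(x) = (1 + tanh(x/(2√2ε)))/2 the two integrand terms contribute equally
and the integral per unit geometric area is exactly 1/(6√2); the reported
areas are therefore multiplied by 6√2 (exposed as
`SimulationConfig.area_calibration`) so a flat equilibrium interface of
geometric area A reads ≈ A. Relative comparisons between candidate planes
are unaffected by this constant. The division-wall area is
S = (S₁ + S₂ − S₀)/2, floored at zero, and converted to µm² through the
squared lattice scale factor. The simulated wall normal is
n̂ = −∫∇ρ₁ · ρ₁(1−ρ₁)ρ₂(1−ρ₂) dr, normalized — the weight is nonzero only
where the two daughter interfaces overlap, i.e. on the wall.

### Accuracy at desk scale

On a 1.6 × 1.0 × 0.8 cuboid (equal split, defaults, ~32×20×16 active
sites) the three seeds converge to S = 0.78 / 1.26 / 1.57 against the
analytic cross-sections 0.8 / 1.28 / 1.6, with the minimal-wall normal
< 1° from the long axis; a digitized ball gives all three areas within 5%
of the equatorial disk and is flagged as a tie.

One known resolution limit: β-exclusion keeps the two daughter fields
slightly apart, excluding a band of volume proportional to the wall area.
The residual constraint force compresses that band but cannot remove it,
so converged daughter volumes sit *below* target by an amount that grows
with wall area over cell volume: ~1–2% for the minimal-area (global
minimum) runs of clearly elongated fixtures, and up to ~3–6% for
large-wall seeds, spheres and near-cubic cells at the default ~30-site
domains. This deficit is a
fixed point of the stated dynamics (identical under dt and dt/4), shrinks
roughly linearly with lattice size, and does not disturb the area ranking
or normals. Analyses that need tighter volume control should raise
`domain_length` (cost grows with its cube).

## Brute-force planar oracle

An independent check scans ≥ 400 near-uniform directions (deterministic
Fibonacci spiral on the half-sphere, prepended with the lattice and
inertia axes) for the minimal *planar* cut at the requested volume
fraction. Cut areas are counted from voxel faces between the two sides,
each face weighted by |n̂ · face normal| — the projection correction that
removes the Manhattan overestimate of oblique planes. On convex fixtures
with aspect ratios 1.2–2.5 the phase-field global minimum agrees with the
scan within a few degrees and <10% in area; on non-convex shapes the
smooth surface may legitimately beat every plane, so the oracle is a
lower-bound witness, not an equality.

## Synthetic cells

The generator voxelizes cuboids, ellipsoids, superellipsoidal
"rounded bricks" and a tapered-prism "wedge" (a leaf-segment-like cell,
elongated along the adaxial–abaxial axis so its minimal wall is
periclinal), with optional smooth seeded surface noise (amplitude < 10% of
the smallest extent), on isotropic or anisotropic grids emulating confocal
z-spacing. Daughter pairs are produced by planar cuts whose offset is
chosen so the requested volume fraction is met within 1% (an infinitesimal
lexicographic ramp breaks within-layer ties so axis-aligned cuts can hit
arbitrary fractions). Everything is bit-reproducible given (spec, seed).

What the generator does *not* emulate: segmentation errors, membrane
curvature from turgor, wall thickness, non-convex cell shapes, imaging
noise. Passing tests therefore validate the estimators and the relaxation
on clean geometry; they do not certify behavior on poorly segmented data.

## Orientation classes and the comparison

A tissue frame (adaxial–abaxial, proximal–distal, medio-lateral; required
user input, since organ-surface estimation is out of scope) assigns each
normal the class of its nearest axis — periclinal, transverse,
longitudinal — with an "ambiguous" band when the two best axes differ by
< 10°. Δθ = arccos|n̂_obs · n̂_sim| is reported per cell in a polar-ready
table: rows at 0° mean the observed wall coincides with the area-minimal
prediction.

## Problem sizes and determinism

Default analyses use 0.2 µm voxels (cells ~60–80 voxels long), ~30–40
lattice sites per axis in simulation, 400-direction scans, and converge in
10³–2·10⁵ Euler steps per seed — seconds to ~1 minute per cell on one
core. All randomness (shape noise, scan jitter in tests) flows from
explicit seeds; reruns byte-reproduce all tables, and outputs carry no
timestamps.
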