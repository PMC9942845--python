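"""Shared fixtures: canonical voxel cells and their (costly) relaxations.

The phase-field relaxations are session-scoped so that the unit tests and
the end-to-end checks share one computation per fixture shape.
"""

from __future__ import annotations

import numpy as np
import pytest

from minwall import (
    ShapeSpec,
    SimulationConfig,
    brute_force_min_plane,
    find_min_planes,
    make_shape,
)

# canonical mother: 16 x 10 x 8 µm cuboid, i.e. 1.6 x 1.0 x 0.8 in
# simulation units when the long axis spans domain_length = 1.6
CUBOID_DIMS_UM = (16.0, 10.0, 8.0)
CUBOID_SIM = (1.6, 1.0, 0.8)


@pytest.fixture(scope="session")
def cuboid_mask():
    return make_shape(ShapeSpec(kind="cuboid", dimensions=CUBOID_DIMS_UM, spacing=0.2))


@pytest.fixture(scope="session")
def cuboid_config():
    return SimulationConfig(domain_length=1.6)


@pytest.fixture(scope="session")
def cuboid_results(cuboid_mask, cuboid_config):
    return find_min_planes(cuboid_mask, cuboid_config)


@pytest.fixture(scope="session")
def ball_mask():
    # digitized ball, 12 µm diameter at 0.2 µm spacing (60 voxels across)
    return make_shape(ShapeSpec(kind="ellipsoid", dimensions=(12.0, 12.0, 12.0), spacing=0.2))


@pytest.fixture(scope="session")
def ball_results(ball_mask):
    return find_min_planes(ball_mask, SimulationConfig())


@pytest.fixture(scope="session")
def wedge_mask():
    # leaf-segment-like wedge elongated along axis 0 (adaxial-abaxial)
    return make_shape(ShapeSpec(kind="wedge", dimensions=(16.0, 10.0, 9.0), spacing=0.2))


@pytest.fixture(scope="session")
def wedge_results(wedge_mask):
    return find_min_planes(wedge_mask, SimulationConfig())


#: convex fixtures with aspect ratios in [1.2, 2.5] for the dual-route
#: (phase field vs planar-scan) agreement checks
SUITE_SPECS = [
    ShapeSpec(kind="cuboid", dimensions=(12.0, 10.0, 8.5), spacing=0.2),
    ShapeSpec(kind="cuboid", dimensions=(16.0, 9.0, 8.0), spacing=0.2),
    ShapeSpec(kind="ellipsoid", dimensions=(15.0, 11.0, 9.0), spacing=0.2),
    ShapeSpec(kind="ellipsoid", dimensions=(17.5, 8.0, 7.0), spacing=0.2),
    ShapeSpec(kind="rounded_brick", dimensions=(14.0, 10.0, 8.0), spacing=0.2),
]


def _domain_length_for(spec: ShapeSpec) -> float:
    # keep >= 16 lattice sites along the shortest axis at dx = 0.05
    aspect = max(spec.dimensions) / min(spec.dimensions)
    return max(1.5, 0.85 * aspect)


@pytest.fixture(scope="session")
def convex_suite():
    out = []
    for spec in SUITE_SPECS:
        mask = make_shape(spec)
        cfg = SimulationConfig(domain_length=_domain_length_for(spec))
        results = find_min_planes(mask, cfg)
        normal, area, _ = brute_force_min_plane(mask, 0.5)
        out.append({"spec": spec, "mask": mask, "results": results,
                    "oracle_normal": normal, "oracle_area_um2": area})
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
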