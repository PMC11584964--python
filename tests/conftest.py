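"""Shared fixtures: fast phantom specs and small geometric meshes.

Phantom generation and ICP dominate test time, so expensive pairs are cached
at session scope and the module tests use a coarse ("fast") phantom wherever
the property under test does not depend on fine sampling.
"""

import numpy as np
import pytest
import trimesh

from periomesh import LabeledMesh, PhantomSpec, RigidTransform, generate_phantom_pair
from periomesh.mesh_model import OTHER


def fast_spec(**overrides) -> PhantomSpec:
    """Coarse, quick-to-generate phantom (~3k vertices)."""
    kwargs = dict(
        delta_h=0.3,
        delta_w=0.5,
        noise_sd=0.0,
        mesh_resolution=0.15,
        azimuth_step=0.5,
        seed=0,
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


@pytest.fixture(scope="session")
def fast_pair():
    """Noiseless unposed coarse phantom pair with its truth."""
    return generate_phantom_pair(fast_spec())


@pytest.fixture(scope="session")
def posed_pair():
    """Noiseless coarse pair under a known rigid pose."""
    pose = RigidTransform.from_axis_angle([0.3, -0.5, 0.8], 8.0, (1.0, -0.5, 2.0))
    spec = fast_spec(pose=pose)
    stl0, stl1, truth = generate_phantom_pair(spec)
    return stl0, stl1, truth, pose


@pytest.fixture
def unit_cube() -> LabeledMesh:
    box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    return LabeledMesh(
        np.asarray(box.vertices), np.asarray(box.faces),
        np.full(len(box.vertices), OTHER), frame_id="cube",
    )


def random_convex_mesh(rng: np.random.Generator) -> LabeledMesh:
    """Random convex polyhedron (hull of 8-30 gaussian points)."""
    pts = rng.normal(size=(int(rng.integers(8, 30)), 3)) * rng.uniform(0.5, 3.0)
    hull = trimesh.convex.convex_hull(pts)
    return LabeledMesh(
        np.asarray(hull.vertices), np.asarray(hull.faces),
        np.full(len(hull.vertices), OTHER),
    )
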