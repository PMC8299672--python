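import numpy as np
import pytest

from orthoplan import (
    MountedScene,
    SyntheticCaseConfig,
    TriangleMesh,
    generate_synthetic_case,
    mount_to_aop,
    place_hinge_pivot,
)


@pytest.fixture
def default_config():
    return SyntheticCaseConfig(seed=0)


@pytest.fixture
def default_case(default_config):
    return generate_synthetic_case(default_config)


def build_scene(case, mounted=True):
    """MountedScene from a synthetic case (canonical, cant-free pose)."""
    scene = MountedScene(maxilla=case.maxilla.copy(), mandible=case.mandible.copy())
    scene.hinge_pivot = place_hinge_pivot(scene.maxilla.pivot("Ie"), case.truth)
    if mounted:
        scene = mount_to_aop(scene, case.truth.lambda_deg)
    return scene


@pytest.fixture
def mounted_scene(default_case):
    return build_scene(default_case)


def unit_cube(center=(0.0, 0.0, 0.0), half=0.5):
    """Axis-aligned cube as a consistently outward-oriented 12-triangle
    mesh; used as a geometry oracle target."""
    c = np.asarray(center, dtype=float)
    h = float(half)
    corners = np.array(
        [[x, y, z] for x in (-h, h) for y in (-h, h) for z in (-h, h)]
    ) + c
    # index: bit2 = x, bit1 = y, bit0 = z
    quads = [
        (0, 1, 3, 2),  # -x
        (6, 7, 5, 4),  # +x  (note: winding fixed below via volume sign)
        (0, 4, 5, 1),  # -y
        (2, 3, 7, 6),  # +y
        (0, 2, 6, 4),  # -z
        (1, 5, 7, 3),  # +z
    ]
    faces = []
    for a, b, cc, d in quads:
        faces.append([a, b, cc])
        faces.append([a, cc, d])
    mesh = TriangleMesh(corners, np.asarray(faces))
    if mesh.volume() < 0:
        mesh = TriangleMesh(corners, mesh.faces[:, ::-1])
    assert mesh.is_watertight()
    return mesh


def box_signed_distance(points, center, half):
    """Closed-form signed distance to an axis-aligned cube surface
    (negative inside) — fully independent oracle."""
    p = np.asarray(points, dtype=float) - np.asarray(center, dtype=float)
    q = np.abs(p) - half
    outside = np.linalg.norm(np.maximum(q, 0.0), axis=-1)
    inside = np.minimum(q.max(axis=-1), 0.0)
    return outside + inside


def random_rigid(rng):
    """Random proper rigid transform from an rng."""
    from scipy.spatial.transform import Rotation

    from orthoplan import RigidTransform

    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    t = rng.uniform(-50, 50, 3)
    return RigidTransform(R, t)
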