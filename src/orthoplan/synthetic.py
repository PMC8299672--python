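"""Synthetic ground-truth cases.

Builds toy jaw meshes with exactly known landmark/pivot coordinates and
— crucially — the *lateral projection*: a known 3D mounting
configuration (mounting angle, hinge-axis height and in-plane distance)
is turned into 2D "cephalometric" landmarks in the image convention, so
that the trigonometric recovery in :mod:`orthoplan.cephalometrics` can
be tested against exact truth.  No clinical records are involved;
everything is parametric and seeded.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cephalometrics import (
    CephLandmarkSet2D,
    FacebowGeometry,
    MountingParameters,
    Point2D,
)
from .geometry import RigidTransform
from .mesh import TriangleMesh
from .mounting import JawModel, Pivot
from .photometry import FrontalLandmarks

__all__ = [
    "SyntheticCaseConfig",
    "SyntheticCase",
    "generate_arch_mesh",
    "lateral_project",
    "frontal_project",
    "truth_mounting_parameters",
    "generate_synthetic_case",
]


@dataclass(frozen=True)
class SyntheticCaseConfig:
    """Ground-truth configuration of one synthetic patient.

    Defaults reproduce a typical clinical magnitude for every quantity.
    """

    lambda_true: float = 7.8  # deg, occlusal plane vs axis-orbital plane
    d_up_true: float = 35.8  # mm, hinge axis height above occlusal plane
    d_post_true: float = 89.9  # mm, incisor edge to foot of perpendicular
    pi_ns_dist: float = 110.0  # mm, ear rod to nasal rest
    cant_true: float = 0.0  # deg, transverse occlusal cant
    midline_offset_true: float = 0.0  # mm, dental midline to patient-left
    arch_width: float = 60.0  # mm
    arch_depth: float = 45.0  # mm
    arch_height: float = 12.0  # mm
    tooth_count: int = 14
    interocclusal_gap: float = 2.0  # mm
    ns_offset: float = 30.0  # mm, face-bow hardware constant
    axis_offset: float = 10.0  # mm, hinge axis anterior of ear rods
    jitter_sigma: float = 0.0  # mm, optional 2D landmark noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pi_ns_dist <= self.ns_offset:
            raise ValueError("pi_ns_dist must exceed ns_offset")
        if self.d_up_true <= 0 or self.d_post_true <= 0:
            raise ValueError("hinge-axis distances must be positive")
        for name in ("arch_width", "arch_depth", "arch_height", "interocclusal_gap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tooth_count < 2:
            raise ValueError("tooth_count must be >= 2")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")


@dataclass
class SyntheticCase:
    maxilla: JawModel
    mandible: JawModel
    ceph_landmarks: CephLandmarkSet2D
    frontal_landmarks: FrontalLandmarks
    truth: MountingParameters
    hinge_axis_point: np.ndarray  # world frame, pre-AOP-rotation pose
    config: SyntheticCaseConfig = field(repr=False, default=None)


# ---------------------------------------------------------------------
# nuisance parameters (deterministic per seed)
# ---------------------------------------------------------------------

def _nuisance(config: SyntheticCaseConfig) -> dict:
    rng = np.random.default_rng(config.seed)
    return {
        "eta_deg": float(rng.uniform(-8.0, 8.0)),  # face-bow inclination on film
        "pi_origin": rng.uniform([50.0, 60.0], [90.0, 100.0]),
        "dc_dist": float(rng.uniform(35.0, 50.0)),  # Ie to molar cusp
        "photo_roll_deg": float(rng.uniform(-5.0, 5.0)),
        "jitter_rng": rng,
    }


# ---------------------------------------------------------------------
# arch mesh
# ---------------------------------------------------------------------

def _arch_grid(config: SyntheticCaseConfig) -> tuple[np.ndarray, np.ndarray, int, int]:
    nx = 2 * config.tooth_count + 1  # odd: a column sits exactly on the midline
    nv = 7
    us = np.linspace(-1.0, 1.0, nx)
    vs = np.linspace(0.0, 1.0, nv)
    x = us * config.arch_width / 2.0
    z_front = -config.arch_depth * us**2  # parabolic outer boundary
    z_back = -config.arch_depth - config.arch_width / 8.0  # posterior margin
    X = np.repeat(x[:, None], nv, axis=1)
    Z = z_back + vs[None, :] * (z_front[:, None] - z_back)
    return X, Z, nx, nv


def generate_arch_mesh(config: SyntheticCaseConfig, jaw: str) -> JawModel:
    """Watertight extruded parabolic arch slab with pivots at exact
    known coordinates.  Maxilla: occlusal surface on y = 0, body above;
    mandible: occlusal surface on y = -gap, body below."""
    if jaw not in ("maxilla", "mandible"):
        raise ValueError(f"unknown jaw label {jaw!r}")
    X, Z, nx, nv = _arch_grid(config)
    if jaw == "maxilla":
        y_occ, y_body = 0.0, config.arch_height
    else:
        y_occ = -config.interocclusal_gap
        y_body = y_occ - config.arch_height
    ylo, yhi = min(y_occ, y_body), max(y_occ, y_body)

    grid_xz = np.stack([X.ravel(), Z.ravel()], axis=1)
    lower = np.column_stack([grid_xz[:, 0], np.full(len(grid_xz), ylo), grid_xz[:, 1]])
    upper = np.column_stack([grid_xz[:, 0], np.full(len(grid_xz), yhi), grid_xz[:, 1]])
    vertices = np.vstack([lower, upper])

    def L(i, j):
        return i * nv + j

    def U(i, j):
        return nx * nv + i * nv + j

    faces = []
    for i in range(nx - 1):
        for j in range(nv - 1):
            # lower surface, outward normal -y
            faces.append([L(i, j), L(i + 1, j), L(i + 1, j + 1)])
            faces.append([L(i, j), L(i + 1, j + 1), L(i, j + 1)])
            # upper surface, outward normal +y
            faces.append([U(i, j), U(i + 1, j + 1), U(i + 1, j)])
            faces.append([U(i, j), U(i, j + 1), U(i + 1, j + 1)])

    # perimeter of the (i, j) rectangle; side wall between the two grids
    loop = (
        [(i, 0) for i in range(nx)]
        + [(nx - 1, j) for j in range(1, nv)]
        + [(i, nv - 1) for i in range(nx - 2, -1, -1)]
        + [(0, j) for j in range(nv - 2, 0, -1)]
    )
    for k in range(len(loop)):
        i0, j0 = loop[k]
        i1, j1 = loop[(k + 1) % len(loop)]
        a, b = L(i0, j0), L(i1, j1)
        c, d = U(i1, j1), U(i0, j0)
        faces.append([c, b, a])
        faces.append([d, c, a])

    mesh = TriangleMesh(vertices, np.asarray(faces))
    if mesh.volume() < 0:  # loop direction depends on grid handedness
        mesh = TriangleMesh(vertices, mesh.faces[:, ::-1])

    w2 = config.arch_width / 2.0
    depth = config.arch_depth
    mid = nx // 2
    z_raphe_ant = float(Z[mid, nv - 2])
    z_raphe_post = float(Z[mid, 0])
    model = JawModel(label=jaw, mesh=mesh)
    model.add_pivot(Pivot("Ie", [0.0, y_occ, 0.0]))
    model.add_pivot(Pivot("occ_left", [w2, y_occ, -depth]))
    model.add_pivot(Pivot("occ_right", [-w2, y_occ, -depth]))
    model.add_pivot(Pivot("raphe_ant", [0.0, y_occ, z_raphe_ant]))
    model.add_pivot(Pivot("raphe_post", [0.0, y_occ, z_raphe_post]))
    return model


# ---------------------------------------------------------------------
# projections
# ---------------------------------------------------------------------

def _ceph_points(config: SyntheticCaseConfig, nuisance: dict) -> dict[str, np.ndarray]:
    """Exact 2D landmark positions in the image frame (y down, patient
    facing image-right), before any jitter."""
    eta = math.radians(nuisance["eta_deg"])
    alpha = math.asin(config.ns_offset / config.pi_ns_dist)
    theta = math.radians(config.lambda_true - nuisance["eta_deg"])

    pi = np.asarray(nuisance["pi_origin"], dtype=float)
    u_fb = np.array([math.cos(eta), math.sin(eta)])  # along the face-bow plane
    ns = pi + config.pi_ns_dist * np.array(
        [math.cos(eta + alpha), math.sin(eta + alpha)]
    )
    ax = pi + config.axis_offset * u_fb

    u_occ = np.array([math.cos(theta), math.sin(theta)])  # along occlusal plane
    n_down = np.array([-math.sin(theta), math.cos(theta)])  # +y side of the plane
    foot = ax + config.d_up_true * n_down  # Dc' — foot of the perpendicular
    ie = foot + config.d_post_true * u_occ
    dc = ie - nuisance["dc_dist"] * u_occ
    return {"Pi": pi, "Ns": ns, "Ie": ie, "Dc": dc}


def lateral_project(config: SyntheticCaseConfig) -> CephLandmarkSet2D:
    """Orthographic projection of the ground-truth 3D configuration onto
    the sagittal plane, in image convention; optional Gaussian jitter."""
    nuisance = _nuisance(config)
    points = _ceph_points(config, nuisance)
    if config.jitter_sigma > 0:
        rng = nuisance["jitter_rng"]
        for name in points:
            points[name] = points[name] + rng.normal(0.0, config.jitter_sigma, 2)
    return CephLandmarkSet2D(
        **{k: Point2D(float(v[0]), float(v[1])) for k, v in points.items()}
    )


def truth_mounting_parameters(config: SyntheticCaseConfig) -> MountingParameters:
    """The mounting parameters the cephalometric recovery must
    reproduce (computed from the construction, not from landmarks)."""
    nuisance = _nuisance(config)
    eta = nuisance["eta_deg"]
    alpha = math.degrees(math.asin(config.ns_offset / config.pi_ns_dist))
    theta = config.lambda_true - eta
    omega = math.degrees(math.atan2(config.d_up_true, config.d_post_true))
    facebow = FacebowGeometry(
        dist_pi_ns=config.pi_ns_dist,
        dist_pi_b=math.cos(math.radians(alpha)) * config.pi_ns_dist,
        alpha_deg=alpha,
        epsilon_deg=eta + alpha,
        eta_deg=eta,
    )
    return MountingParameters(
        theta_deg=theta,
        lambda_deg=config.lambda_true,
        phi_deg=theta + omega,
        omega_deg=omega,
        dist_ax_ie=math.hypot(config.d_up_true, config.d_post_true),
        d_up=config.d_up_true,
        d_post=config.d_post_true,
        facebow=facebow,
    )


def frontal_project(config: SyntheticCaseConfig) -> FrontalLandmarks:
    """Frontal-photo landmarks with the configured cant and midline
    offset, under a random whole-photo roll (image frame, patient-left
    at larger x)."""
    nuisance = _nuisance(config)
    roll = math.radians(nuisance["photo_roll_deg"])
    u = np.array([math.cos(roll), math.sin(roll)])  # patient right -> left
    v = np.array([-math.sin(roll), math.cos(roll)])  # anatomically down
    pupil_mid = np.array([90.0, 60.0])
    occ_mid = pupil_mid + 60.0 * v
    cant = math.radians(config.cant_true)
    u_occ = np.array([math.cos(roll + cant), math.sin(roll + cant)])

    def pt(a) -> Point2D:
        return Point2D(float(a[0]), float(a[1]))

    return FrontalLandmarks(
        pupil_left=pt(pupil_mid + 30.0 * u),
        pupil_right=pt(pupil_mid - 30.0 * u),
        occ_left=pt(occ_mid + 25.0 * u_occ),
        occ_right=pt(occ_mid - 25.0 * u_occ),
        dental_midline=pt(occ_mid + config.midline_offset_true * u),
        facial_midline_ref=pt(pupil_mid),
        mm_per_px=1.0,
    )


def generate_synthetic_case(config: SyntheticCaseConfig) -> SyntheticCase:
    """Bundle meshes, 2D landmark sets and ground truth.

    The jaws are delivered in the cant-tilted pose (rotated by
    +cant_true about the antero-posterior axis through the incisor
    edge), so that the standard cant correction restores the canonical
    occlusal-plane-level pose.  The mandible sits in constructed
    occlusion at the configured interocclusal gap.
    """
    maxilla = generate_arch_mesh(config, "maxilla")
    mandible = generate_arch_mesh(config, "mandible")
    if config.cant_true != 0.0:
        tilt = RigidTransform.from_axis_angle(
            [0.0, 0.0, 1.0], config.cant_true, center=[0.0, 0.0, 0.0]
        )
        maxilla = maxilla.transformed(tilt)
        mandible = mandible.transformed(tilt)
    return SyntheticCase(
        maxilla=maxilla,
        mandible=mandible,
        ceph_landmarks=lateral_project(config),
        frontal_landmarks=frontal_project(config),
        truth=truth_mounting_parameters(config),
        hinge_axis_point=np.array([0.0, config.d_up_true, -config.d_post_true]),
        config=config,
    )
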