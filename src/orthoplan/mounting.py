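"""Virtual mounting of jaw meshes in the articulator-equivalent world
frame.

World frame: y up, +z anterior, +x patient-left ("distally" = -z,
"up" = +y).  The mounting sequence is

1. :func:`align_maxilla` — maxillary occlusal plane onto y = 0, palatal
   raphe into the midsagittal x = 0 plane, incisor edge to the origin;
   the mandible follows passively with the same transform.
2. :func:`apply_cant_correction` — tilt about the antero-posterior axis.
3. :func:`place_hinge_pivot` — clone the incisor pivot distally and up
   by the cephalometrically derived distances.
4. :func:`mount_to_aop` — rotate the whole scene about the transverse
   axis through the incisor pivot by lambda so the ground plane becomes
   a parallel of the axis-orbital plane.

Every operation moves a jaw's mesh and its pivots by one and the same
rigid motion.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .cephalometrics import MountingParameters
from .errors import DegenerateGeometry, MissingLandmark, UnknownPivot
from .geometry import RigidTransform, solve_rigid
from .mesh import TriangleMesh

WORLD_FRAME = {"y_up": True, "x": "patient-left", "z": "anterior", "units": "mm"}

ALIGN_LANDMARK_NAMES = ("Ie", "occ_right", "occ_left", "raphe_ant", "raphe_post")

SNAP_TOLERANCE_MM = 1.0


@dataclass(frozen=True)
class Pivot:
    """A named 3D point bound to a jaw; moves rigidly with its mesh."""

    name: str
    position: np.ndarray
    bound_to: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.position, dtype=float).reshape(3)
        if not np.all(np.isfinite(p)):
            raise ValueError(f"pivot {self.name!r}: non-finite position")
        object.__setattr__(self, "position", p)

    def transformed(self, transform: RigidTransform) -> "Pivot":
        return Pivot(self.name, transform.apply(self.position), self.bound_to)


@dataclass
class JawModel:
    """A jaw mesh plus its bound measurement pivots."""

    label: str  # "maxilla" | "mandible"
    mesh: TriangleMesh
    pivots: dict[str, Pivot] = field(default_factory=dict)
    stage: str = "preop"  # "preop" | "postop"

    def __post_init__(self) -> None:
        if self.label not in ("maxilla", "mandible"):
            raise ValueError(f"unknown jaw label {self.label!r}")
        for name, piv in self.pivots.items():
            if piv.name != name:
                raise ValueError(f"pivot key {name!r} != pivot name {piv.name!r}")

    def pivot(self, name: str) -> Pivot:
        try:
            return self.pivots[name]
        except KeyError:
            raise UnknownPivot(f"jaw {self.label!r} has no pivot {name!r}") from None

    def add_pivot(self, pivot: Pivot) -> None:
        if pivot.name in self.pivots:
            raise ValueError(f"duplicate pivot name {pivot.name!r}")
        self.pivots[pivot.name] = replace(pivot, bound_to=self.label)

    def copy(self) -> "JawModel":
        return JawModel(
            label=self.label,
            mesh=self.mesh.copy(),
            pivots={n: Pivot(p.name, p.position.copy(), p.bound_to) for n, p in self.pivots.items()},
            stage=self.stage,
        )

    def transformed(self, transform: RigidTransform) -> "JawModel":
        return JawModel(
            label=self.label,
            mesh=self.mesh.transformed(transform),
            pivots={n: p.transformed(transform) for n, p in self.pivots.items()},
            stage=self.stage,
        )


@dataclass
class MountedScene:
    """Preop jaws in the world frame, plus planning clones.

    ``lambda_applied`` is None until :func:`mount_to_aop` has run.
    """

    maxilla: JawModel
    mandible: JawModel
    hinge_pivot: Optional[Pivot] = None
    lambda_applied: Optional[float] = None
    postop_maxilla: Optional[JawModel] = None
    postop_mandible: Optional[JawModel] = None
    frame: dict = field(default_factory=lambda: dict(WORLD_FRAME))
    transform_log: list = field(default_factory=list)

    def jaws(self) -> list[JawModel]:
        out = [self.maxilla, self.mandible]
        if self.postop_maxilla is not None:
            out.append(self.postop_maxilla)
        if self.postop_mandible is not None:
            out.append(self.postop_mandible)
        return out

    def copy(self) -> "MountedScene":
        return MountedScene(
            maxilla=self.maxilla.copy(),
            mandible=self.mandible.copy(),
            hinge_pivot=None
            if self.hinge_pivot is None
            else Pivot(self.hinge_pivot.name, self.hinge_pivot.position.copy(), self.hinge_pivot.bound_to),
            lambda_applied=self.lambda_applied,
            postop_maxilla=None if self.postop_maxilla is None else self.postop_maxilla.copy(),
            postop_mandible=None if self.postop_mandible is None else self.postop_mandible.copy(),
            frame=dict(self.frame),
            transform_log=list(self.transform_log),
        )

    def _apply_to_all(self, transform: RigidTransform, what: str) -> "MountedScene":
        out = self.copy()
        out.maxilla = out.maxilla.transformed(transform)
        out.mandible = out.mandible.transformed(transform)
        if out.postop_maxilla is not None:
            out.postop_maxilla = out.postop_maxilla.transformed(transform)
        if out.postop_mandible is not None:
            out.postop_mandible = out.postop_mandible.transformed(transform)
        if out.hinge_pivot is not None:
            out.hinge_pivot = out.hinge_pivot.transformed(transform)
        out.transform_log.append({"op": what, "transform": transform.to_dict()})
        return out


# ---------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------

def resolve_mesh_landmarks(mesh: TriangleMesh, landmarks: dict) -> dict[str, np.ndarray]:
    """Turn a name -> coordinate/vertex-index mapping into coordinates.

    Coordinates are snapped to the nearest mesh vertex when that vertex
    is within 1 mm; farther points are rejected as implausible.
    """
    out = {}
    for name, value in landmarks.items():
        if isinstance(value, (int, np.integer)):
            out[name] = mesh.vertices[int(value)].copy()
            continue
        p = np.asarray(value, dtype=float).reshape(3)
        d = np.linalg.norm(mesh.vertices - p, axis=1)
        i = int(np.argmin(d))
        if d[i] > SNAP_TOLERANCE_MM:
            raise ValueError(
                f"landmark {name!r} is {d[i]:.2f} mm from the mesh surface "
                f"(> {SNAP_TOLERANCE_MM:g} mm); not snapped"
            )
        out[name] = mesh.vertices[i].copy()
    return out


def align_maxilla(mesh: TriangleMesh, mesh_landmarks: dict) -> RigidTransform:
    """Closed-form replacement of the interactive grid alignment.

    Returns the rigid motion that carries the best-fit occlusal plane
    (through Ie, occ_right, occ_left) onto y = 0 with the jaw body on
    +y, the raphe line into the x = 0 plane pointing +z anterior, and
    Ie to the origin.
    """
    missing = [n for n in ALIGN_LANDMARK_NAMES if n not in mesh_landmarks]
    if missing:
        raise MissingLandmark(f"alignment landmarks missing: {missing}")
    lm = resolve_mesh_landmarks(mesh, {n: mesh_landmarks[n] for n in ALIGN_LANDMARK_NAMES})

    ie, occ_r, occ_l = lm["Ie"], lm["occ_right"], lm["occ_left"]
    normal = np.cross(occ_r - ie, occ_l - ie)
    span = max(np.linalg.norm(occ_r - ie), np.linalg.norm(occ_l - ie), 1.0)
    if np.linalg.norm(normal) <= 1e-9 * span * span:
        raise DegenerateGeometry("occlusal landmarks are collinear")
    normal = normal / np.linalg.norm(normal)
    # jaw body (and palate) lie above the maxillary occlusal plane
    centroid = mesh.vertices.mean(axis=0)
    if np.dot(normal, centroid - ie) < 0:
        normal = -normal

    raphe_dir = lm["raphe_ant"] - lm["raphe_post"]  # posterior -> anterior
    raphe_in_plane = raphe_dir - np.dot(raphe_dir, normal) * normal
    nrm = np.linalg.norm(raphe_in_plane)
    if nrm <= 1e-9 * np.linalg.norm(raphe_dir):
        raise DegenerateGeometry("raphe line is perpendicular to the occlusal plane")
    z_axis = raphe_in_plane / nrm
    x_axis = np.cross(normal, z_axis)

    R = np.vstack([x_axis, normal, z_axis])  # rows: world x, y, z images
    return RigidTransform(R, -(R @ ie))


def apply_cant_correction(scene: MountedScene, cant_deg: float) -> MountedScene:
    """Rotate both jaws about the antero-posterior (z) axis through the
    upper-incisor pivot by -cant_deg, levelling the occlusal plane."""
    if scene.lambda_applied is not None:
        raise ValueError("cant correction must precede the AOP rotation")
    center = scene.maxilla.pivot("Ie").position
    t = RigidTransform.from_axis_angle([0.0, 0.0, 1.0], -cant_deg, center=center)
    return scene._apply_to_all(t, f"cant_correction({cant_deg:g} deg)")


def place_hinge_pivot(ie_pivot: Pivot, params: MountingParameters) -> Pivot:
    """Clone the incisor pivot distally along the ground plane by
    ``d_post`` and up by ``d_up``: the articulator hinge axis in
    relation to the maxilla (pre-AOP-rotation pose)."""
    offset = np.array([0.0, params.d_up, -params.d_post])
    return Pivot("hinge_axis", ie_pivot.position + offset, bound_to="maxilla")


def mount_to_aop(scene: MountedScene, lambda_deg: float) -> MountedScene:
    """Rotate all jaws and pivots together about the x-axis through the
    incisor pivot by lambda, making the ground plane a parallel of the
    axis-orbital plane.

    The sense (positive about +x = patient-left) drops the anterior end
    of the occlusal plane and leaves the hinge pivot posterosuperior to
    the incisor edge, matching the anatomical outcome rather than any
    screen direction.
    """
    if scene.hinge_pivot is None:
        raise ValueError("hinge pivot must be placed before mounting")
    center = scene.maxilla.pivot("Ie").position
    t = RigidTransform.from_axis_angle([1.0, 0.0, 0.0], lambda_deg, center=center)
    out = scene._apply_to_all(t, f"mount_to_aop({lambda_deg:g} deg)")
    out.lambda_applied = lambda_deg
    return out


def register_bite(source_points, target_points) -> tuple[RigidTransform, float]:
    """Rigid registration of corresponding bite-scan points (stand-in
    for the scanner software's maxilla/mandible registration).

    Returns (transform, RMS residual in mm)."""
    return solve_rigid(source_points, target_points)
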