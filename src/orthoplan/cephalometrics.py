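"""Face-bow geometry and hinge-axis location from four lateral-cephalogram
landmarks.

All computation happens in the radiograph's image frame: the origin sits
in the upper-left corner, x grows to the right, y grows *downward*, and
the patient faces image-right (anterior at larger x).  Coordinates are in
millimetres once :func:`scale_landmarks` has been applied.

Landmarks
---------
Pi
    Porion inferior — deepest point on the lower border of the external
    acoustic meatus (the face-bow ear rod).
Ns
    Nasal rest of the face-bow.  The face-bow hardware holds it at a
    fixed perpendicular offset (default 30 mm) from the face-bow plane.
Ie
    Upper incisor edge.
Dc
    Distobuccal cusp of the first upper molar.  ``Ie-Dc`` defines the
    maxillary occlusal plane.

From these the module derives the inclination of the face-bow plane
(eta), the inclination of the occlusal plane (theta), the mounting angle
``lambda = theta + eta`` between the two, and the position of the
articulator's arbitrary hinge axis ``Ax`` (a fixed distance anterior of
Pi on the face-bow plane) expressed as the perpendicular height ``d_up``
above the occlusal plane and the in-plane distance ``d_post`` from the
upper incisor edge to the foot of that perpendicular.  ``d_up``,
``d_post`` and ``lambda`` are exactly the three numbers needed to mount
the jaw meshes (:mod:`orthoplan.mounting`).
"""
from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path

from .errors import DegenerateGeometry, FormatError, MissingLandmark

__all__ = [
    "Point2D",
    "FacebowConstants",
    "CephLandmarkSet2D",
    "FacebowGeometry",
    "MountingParameters",
    "average_bilateral",
    "facebow_geometry",
    "occlusal_plane_angle",
    "mounting_angle",
    "hinge_axis_parameters",
    "scale_landmarks",
    "read_ceph_landmarks",
]


@dataclass(frozen=True)
class Point2D:
    """A point in the image frame (x right, y down), finite coordinates."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("non-finite coordinate")

    def __sub__(self, other: "Point2D") -> tuple[float, float]:
        return (self.x - other.x, self.y - other.y)

    def distance_to(self, other: "Point2D") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)


@dataclass(frozen=True)
class FacebowConstants:
    """Hardware constants of the articulator/face-bow system.

    ns_offset
        Perpendicular distance of the nasal rest from the face-bow
        plane (mm).
    axis_anterior_offset
        Distance of the articulator hinge axis anterior of the ear rods
        along the face-bow plane (mm).
    """

    ns_offset: float = 30.0
    axis_anterior_offset: float = 10.0

    def __post_init__(self) -> None:
        if self.ns_offset <= 0 or self.axis_anterior_offset <= 0:
            raise ValueError("face-bow constants must be strictly positive")


@dataclass(frozen=True)
class CephLandmarkSet2D:
    """The four landmarks, bilateral doubles already averaged."""

    Pi: Point2D
    Ns: Point2D
    Ie: Point2D
    Dc: Point2D
    scale_mm_per_px: float = 1.0

    def __post_init__(self) -> None:
        if self.scale_mm_per_px <= 0:
            raise ValueError("scale must be positive")
        if self.Pi == self.Ns:
            raise ValueError("Pi and Ns coincide")
        if self.Ie == self.Dc:
            raise ValueError("Ie and Dc coincide")


@dataclass(frozen=True)
class FacebowGeometry:
    """Right triangle Pi-Ns-b, where b is the foot of the perpendicular
    from the nasal rest onto the face-bow plane."""

    dist_pi_ns: float  # ||Pi - Ns||, mm
    dist_pi_b: float  # ||Pi - b||, mm
    alpha_deg: float  # angle between Pi-Ns and the face-bow plane
    epsilon_deg: float  # inclination of Pi-Ns against the horizontal
    eta_deg: float  # inclination of the face-bow plane (eta = eps - alpha)


@dataclass(frozen=True)
class MountingParameters:
    """Everything needed to mount the maxilla against the hinge axis."""

    theta_deg: float  # occlusal-plane inclination
    lambda_deg: float  # angle between face-bow plane and occlusal plane
    phi_deg: float  # inclination of Ax-Ie
    omega_deg: float  # angle between Ax-Ie and the occlusal plane
    dist_ax_ie: float  # ||Ax - Ie||, mm
    d_up: float  # perpendicular height of Ax above the occlusal plane
    d_post: float  # ||Ie - foot of perpendicular|| along the occlusal plane
    facebow: FacebowGeometry

    def to_dict(self) -> dict:
        d = {
            "theta_deg": self.theta_deg,
            "lambda_deg": self.lambda_deg,
            "phi_deg": self.phi_deg,
            "omega_deg": self.omega_deg,
            "dist_ax_ie": self.dist_ax_ie,
            "d_up": self.d_up,
            "d_post": self.d_post,
        }
        d["facebow"] = vars(self.facebow).copy()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MountingParameters":
        fb = FacebowGeometry(**d["facebow"])
        rest = {k: v for k, v in d.items() if k != "facebow"}
        return cls(facebow=fb, **rest)


# ---------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------

def average_bilateral(left: Point2D, right: Point2D) -> Point2D:
    """Componentwise mean of a left/right double contour."""
    return Point2D((left.x + right.x) / 2.0, (left.y + right.y) / 2.0)


def facebow_geometry(
    Pi: Point2D, Ns: Point2D, constants: FacebowConstants = FacebowConstants()
) -> FacebowGeometry:
    """Solve the right triangle between Pi, Ns and the face-bow plane.

    The nasal rest sits at a fixed perpendicular offset from the
    face-bow plane, so the angle ``alpha`` that Pi-Ns makes with the
    plane follows from ``arcsin(ns_offset / ||Pi-Ns||)``; subtracting it
    from the measured inclination ``epsilon`` of Pi-Ns yields the
    inclination ``eta`` of the face-bow plane itself.
    """
    dist_pi_ns = Pi.distance_to(Ns)
    ratio = constants.ns_offset / dist_pi_ns
    if ratio >= 1.0:
        raise DegenerateGeometry(
            f"||Pi-Ns|| = {dist_pi_ns:.3f} mm must exceed the nasal-rest "
            f"offset of {constants.ns_offset:g} mm; check landmarks/scale"
        )
    alpha = math.asin(ratio)
    dist_pi_b = math.cos(alpha) * dist_pi_ns
    epsilon = math.atan2(Ns.y - Pi.y, Ns.x - Pi.x)
    eta = epsilon - alpha
    return FacebowGeometry(
        dist_pi_ns=dist_pi_ns,
        dist_pi_b=dist_pi_b,
        alpha_deg=math.degrees(alpha),
        epsilon_deg=math.degrees(epsilon),
        eta_deg=math.degrees(eta),
    )


def occlusal_plane_angle(Ie: Point2D, Dc: Point2D) -> float:
    """Inclination theta of the occlusal plane Ie-Dc against the
    horizontal, degrees; positive when the plane descends anteriorly
    (image frame, y down)."""
    dx = Ie.x - Dc.x
    if dx == 0.0:
        raise DegenerateGeometry("vertical occlusal plane (x_Ie == x_Dc)")
    return math.degrees(math.atan((Ie.y - Dc.y) / dx))


def mounting_angle(theta_deg: float, eta_deg: float) -> float:
    """Angle lambda between face-bow plane and occlusal plane."""
    return theta_deg + eta_deg


def hinge_axis_parameters(
    landmarks: CephLandmarkSet2D,
    constants: FacebowConstants = FacebowConstants(),
    *,
    axis_mode: str = "eta",
    permissive: bool = False,
) -> MountingParameters:
    """Locate the arbitrary hinge axis relative to the upper incisor edge.

    ``Ax`` is placed ``axis_anterior_offset`` anterior of Pi along the
    face-bow plane.  ``axis_mode`` selects the direction used for that
    step: ``"eta"`` (default) walks along the face-bow plane's actual
    inclination; ``"alpha"`` reproduces the published coordinate
    formulas verbatim (which use the triangle angle alpha instead).  The
    two differ by well under a millimetre for clinical inclinations.

    Returns the mounting parameters; ``d_up`` is the perpendicular
    distance from ``Ax`` down to the occlusal plane and ``d_post`` the
    in-plane distance from the incisor edge back to the foot of that
    perpendicular.

    Raises
    ------
    DegenerateGeometry
        When the hinge axis does not lie strictly above the occlusal
        plane (omega <= 0).  With ``permissive=True`` the exact
        omega == 0 limit returns ``d_up = 0`` and
        ``d_post = ||Ax-Ie||``.
    """
    if axis_mode not in ("eta", "alpha"):
        raise ValueError(f"axis_mode must be 'eta' or 'alpha', got {axis_mode!r}")
    fb = facebow_geometry(landmarks.Pi, landmarks.Ns, constants)
    theta = occlusal_plane_angle(landmarks.Ie, landmarks.Dc)
    lam = mounting_angle(theta, fb.eta_deg)

    direction = math.radians(fb.eta_deg if axis_mode == "eta" else fb.alpha_deg)
    off = constants.axis_anterior_offset
    ax = Point2D(
        landmarks.Pi.x + math.cos(direction) * off,
        landmarks.Pi.y + math.sin(direction) * off,
    )

    dy = landmarks.Ie.y - ax.y
    dx = landmarks.Ie.x - ax.x
    phi = math.atan2(dy, dx)
    omega = phi - math.radians(theta)
    dist_ax_ie = math.hypot(dx, dy)

    if abs(omega) < 1e-12:
        if not permissive:
            raise DegenerateGeometry(
                "hinge axis lies on the occlusal plane (omega == 0)"
            )
        d_up, d_post = 0.0, dist_ax_ie
    elif omega < 0.0:
        raise DegenerateGeometry(
            f"hinge axis below the occlusal plane (omega = "
            f"{math.degrees(omega):.3f} deg); check landmarks"
        )
    else:
        d_up = math.sin(omega) * dist_ax_ie
        d_post = d_up / math.tan(omega)

    return MountingParameters(
        theta_deg=theta,
        lambda_deg=lam,
        phi_deg=math.degrees(phi),
        omega_deg=math.degrees(omega),
        dist_ax_ie=dist_ax_ie,
        d_up=d_up,
        d_post=d_post,
        facebow=fb,
    )


def scale_landmarks(raw: CephLandmarkSet2D, mm_per_px: float) -> CephLandmarkSet2D:
    """Convert a pixel-space landmark set to millimetres."""
    if mm_per_px <= 0:
        raise ValueError("mm_per_px must be positive")

    def s(p: Point2D) -> Point2D:
        return Point2D(p.x * mm_per_px, p.y * mm_per_px)

    return CephLandmarkSet2D(
        Pi=s(raw.Pi), Ns=s(raw.Ns), Ie=s(raw.Ie), Dc=s(raw.Dc), scale_mm_per_px=1.0
    )


# ---------------------------------------------------------------------
# file dialects
# ---------------------------------------------------------------------

_NAMES = ("Pi", "Ns", "Ie", "Dc")


def _point_from_entry(entry) -> Point2D:
    if isinstance(entry, dict):
        left = entry.get("left")
        right = entry.get("right")
        if left is None or right is None:
            raise FormatError("bilateral entry needs both 'left' and 'right'")
        return average_bilateral(
            Point2D(float(left[0]), float(left[1])),
            Point2D(float(right[0]), float(right[1])),
        )
    return Point2D(float(entry[0]), float(entry[1]))


def read_ceph_landmarks(path) -> CephLandmarkSet2D:
    """Read the landmark file (JSON, or CSV with name,x,y[,side] rows).

    Bilateral doubles are averaged; a ``mm_per_px`` entry other than 1
    is applied so the returned set is always in millimetres.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        data = _read_ceph_csv(path)
    else:
        data = json.loads(path.read_text())
    points = {}
    for name in _NAMES:
        if name not in data:
            raise MissingLandmark(f"landmark {name!r} missing from {path}")
        points[name] = _point_from_entry(data[name])
    scale = float(data.get("mm_per_px", 1.0))
    landmarks = CephLandmarkSet2D(**points, scale_mm_per_px=scale)
    if scale != 1.0:
        landmarks = scale_landmarks(landmarks, scale)
    return landmarks


def _read_ceph_csv(path: Path) -> dict:
    sides: dict[str, dict[str, list]] = {}
    scale = 1.0
    with path.open(newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].strip().lower() in ("name", ""):
                continue
            name = row[0].strip()
            if name == "mm_per_px":
                scale = float(row[1])
                continue
            if len(row) < 3:
                raise FormatError(f"{path}: malformed row {row!r}")
            side = row[3].strip().lower() if len(row) > 3 and row[3].strip() else "both"
            sides.setdefault(name, {})[side] = [float(row[1]), float(row[2])]
    data: dict = {"mm_per_px": scale}
    for name, entry in sides.items():
        if "both" in entry:
            data[name] = entry["both"]
        else:
            data[name] = entry
    return data
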