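"""Virtual model surgery on a mounted scene: cloning, planned moves,
displacement measurement, occlusal contact detection, final-splint open
rotation and splint export sets.
"""
from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import MissingStage, PivotMismatch, UnknownPivot
from .geometry import RigidTransform
from .jsonutil import dump_json
from .mounting import JawModel, MountedScene, Pivot
from .mesh import signed_distances
from .stl import write_stl

DEFAULT_CONTACT_TOLERANCE = 0.1  # mm
DEFAULT_OPEN_ROTATION_DEG = 2.0


@dataclass(frozen=True)
class PlannedMove:
    """One rigid move of a jaw: rotation about a center, then a
    translation.  ``center`` is a pivot name on the jaw or an explicit
    3D point."""

    jaw: str
    translation: Sequence[float] = (0.0, 0.0, 0.0)
    rotation_axis: Optional[Sequence[float]] = None
    rotation_angle_deg: float = 0.0
    center: object = "Ie"

    def __post_init__(self) -> None:
        if self.rotation_angle_deg != 0.0:
            if self.rotation_axis is None:
                raise ValueError("rotation requires an axis")
            axis = np.asarray(self.rotation_axis, dtype=float)
            if abs(np.linalg.norm(axis) - 1.0) > 1e-9:
                raise ValueError("rotation axis must be unit-norm")

    @classmethod
    def from_dict(cls, d: dict) -> "PlannedMove":
        rot = d.get("rotation") or {}
        return cls(
            jaw=d["jaw"],
            translation=tuple(d.get("translation", (0.0, 0.0, 0.0))),
            rotation_axis=rot.get("axis"),
            rotation_angle_deg=float(rot.get("angle_deg", 0.0)),
            center=rot.get("center", d.get("center", "Ie")),
        )


@dataclass(frozen=True)
class DisplacementRow:
    name: str
    pre_xyz: tuple
    post_xyz: tuple
    delta_xyz: tuple
    euclidean: float


@dataclass(frozen=True)
class DisplacementReport:
    jaw: str
    rows: tuple[DisplacementRow, ...]

    def row(self, name: str) -> DisplacementRow:
        for r in self.rows:
            if r.name == name:
                return r
        raise UnknownPivot(f"no displacement row for pivot {name!r}")

    def to_dict(self) -> dict:
        return {
            "jaw": self.jaw,
            "rows": [
                {
                    "name": r.name,
                    "pre_xyz": list(r.pre_xyz),
                    "post_xyz": list(r.post_xyz),
                    "delta_xyz": list(r.delta_xyz),
                    "euclidean": r.euclidean,
                }
                for r in self.rows
            ],
        }


@dataclass(frozen=True)
class ContactReport:
    tolerance: float
    upper_indices: tuple[int, ...]
    upper_distances: tuple[float, ...]
    lower_indices: tuple[int, ...]
    lower_distances: tuple[float, ...]

    @property
    def empty(self) -> bool:
        return not (self.upper_indices or self.lower_indices)

    def to_dict(self) -> dict:
        return {
            "tolerance": self.tolerance,
            "upper": {"indices": list(self.upper_indices), "signed_distance_mm": list(self.upper_distances)},
            "lower": {"indices": list(self.lower_indices), "signed_distance_mm": list(self.lower_distances)},
        }


@dataclass(frozen=True)
class SplintExportSet:
    scenario: str  # upper_only | lower_only | bimaxillary
    members: tuple[dict, ...]  # {jaw, stage, open_rotated, file}

    def to_dict(self) -> dict:
        return {"scenario": self.scenario, "members": [dict(m) for m in self.members]}


# ---------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------

def clone_jaw(jaw: JawModel) -> JawModel:
    """Deep postop copy; the original stays in its unoperated position."""
    out = jaw.copy()
    out.stage = "postop"
    return out


def move_jaw(jaw: JawModel, move: PlannedMove) -> JawModel:
    """Apply a planned move: rotation about its center, then the
    translation.  Mesh and pivots move together."""
    if move.jaw != jaw.label:
        raise ValueError(f"move targets {move.jaw!r} but jaw is {jaw.label!r}")
    transform = RigidTransform.from_translation(move.translation)
    if move.rotation_angle_deg != 0.0:
        if isinstance(move.center, str):
            center = jaw.pivot(move.center).position
        else:
            center = np.asarray(move.center, dtype=float).reshape(3)
        rot = RigidTransform.from_axis_angle(
            move.rotation_axis, move.rotation_angle_deg, center=center
        )
        transform = transform.compose(rot)
    return jaw.transformed(transform)


def measure_displacements(pre: JawModel, post: JawModel) -> DisplacementReport:
    """Per-pivot post - pre deltas in the scene frame, ordered by name."""
    if set(pre.pivots) != set(post.pivots):
        raise PivotMismatch(
            f"pivot sets differ: {sorted(pre.pivots)} vs {sorted(post.pivots)}"
        )
    rows = []
    for name in sorted(pre.pivots):
        a = pre.pivots[name].position
        b = post.pivots[name].position
        d = b - a
        rows.append(
            DisplacementRow(
                name=name,
                pre_xyz=tuple(a.tolist()),
                post_xyz=tuple(b.tolist()),
                delta_xyz=tuple(d.tolist()),
                euclidean=float(np.linalg.norm(d)),
            )
        )
    return DisplacementReport(jaw=pre.label, rows=tuple(rows))


def detect_contacts(
    upper: JawModel, lower: JawModel, tolerance: float = DEFAULT_CONTACT_TOLERANCE
) -> ContactReport:
    """Vertices of each mesh within ``tolerance`` of the other mesh
    (signed: negative = penetrating).  Evaluated symmetrically."""
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    d_upper = signed_distances(upper.mesh.vertices, lower.mesh)
    d_lower = signed_distances(lower.mesh.vertices, upper.mesh)
    iu = np.flatnonzero(d_upper <= tolerance)
    il = np.flatnonzero(d_lower <= tolerance)
    return ContactReport(
        tolerance=float(tolerance),
        upper_indices=tuple(int(i) for i in iu),
        upper_distances=tuple(float(d_upper[i]) for i in iu),
        lower_indices=tuple(int(i) for i in il),
        lower_distances=tuple(float(d_lower[i]) for i in il),
    )


def open_rotation(
    mandible: JawModel, hinge: Pivot, angle_deg: float = DEFAULT_OPEN_ROTATION_DEG
) -> JawModel:
    """Rotate the mandible about the hinge pivot's transverse (x) axis
    in the mouth-opening sense (incisor moves inferiorly and
    posteriorly); used to create the final-splint thickness."""
    if angle_deg < 0:
        raise ValueError("open rotation angle must be >= 0")
    t = RigidTransform.from_axis_angle([1.0, 0.0, 0.0], angle_deg, center=hinge.position)
    return mandible.transformed(t)


_SCENARIOS = ("upper_only", "lower_only", "bimaxillary")


def export_splint_set(
    scene: MountedScene,
    scenario: str,
    out_dir,
    *,
    open_rotation_deg: float = DEFAULT_OPEN_ROTATION_DEG,
    ascii: bool = False,
) -> SplintExportSet:
    """Write the splint-fabrication STL set in the common scene frame
    (no re-centering, so downstream CAD sees true relative poses).

    upper_only   -> postop maxilla + open-rotated (unoperated) mandible
    lower_only   -> preop maxilla + open-rotated postop mandible
    bimaxillary  -> postop maxilla, preop mandible (intermediate splint),
                    open-rotated postop mandible (final splint)
    """
    if scenario not in _SCENARIOS:
        raise ValueError(f"scenario must be one of {_SCENARIOS}, got {scenario!r}")
    if scene.hinge_pivot is None:
        raise MissingStage("scene has no hinge pivot; mount before exporting")

    def _need(jaw: Optional[JawModel], what: str) -> JawModel:
        if jaw is None:
            raise MissingStage(f"scenario {scenario!r} requires the {what}")
        return jaw

    members: list[tuple[JawModel, bool]] = []
    if scenario == "upper_only":
        members = [
            (_need(scene.postop_maxilla, "postop maxilla"), False),
            (open_rotation(scene.mandible, scene.hinge_pivot, open_rotation_deg), True),
        ]
    elif scenario == "lower_only":
        members = [
            (scene.maxilla, False),
            (open_rotation(_need(scene.postop_mandible, "postop mandible"), scene.hinge_pivot, open_rotation_deg), True),
        ]
    else:  # bimaxillary
        members = [
            (_need(scene.postop_maxilla, "postop maxilla"), False),
            (scene.mandible, False),
            (open_rotation(_need(scene.postop_mandible, "postop mandible"), scene.hinge_pivot, open_rotation_deg), True),
        ]

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for jaw, rotated in members:
        fname = f"{jaw.label}_{jaw.stage}" + ("_openrot" if rotated else "") + ".stl"
        write_stl(jaw.mesh, out_dir / fname, ascii=ascii)
        manifest.append(
            {"jaw": jaw.label, "stage": jaw.stage, "open_rotated": rotated, "file": fname}
        )
    export = SplintExportSet(scenario=scenario, members=tuple(manifest))
    dump_json(export.to_dict(), out_dir / "splint_manifest.json")
    return export


def write_planning_sheet(
    out_dir,
    *,
    mounting_params=None,
    transverse=None,
    displacement_reports: Sequence[DisplacementReport] = (),
    contact_report: Optional[ContactReport] = None,
    splint_set: Optional[SplintExportSet] = None,
    lambda_applied: Optional[float] = None,
) -> dict:
    """Assemble the machine-readable planning sheet: one JSON document
    plus a flat CSV displacement table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    sheet: dict = {"frame": {"x": "patient-left", "y": "up", "z": "anterior"}}
    if mounting_params is not None:
        sheet["mounting_parameters"] = mounting_params.to_dict()
    if lambda_applied is not None:
        sheet["lambda_applied_deg"] = lambda_applied
    if transverse is not None:
        sheet["transverse_assessment"] = transverse.to_dict()
    if displacement_reports:
        sheet["displacements"] = [r.to_dict() for r in displacement_reports]
    if contact_report is not None:
        sheet["contacts"] = {
            "tolerance": contact_report.tolerance,
            "n_upper": len(contact_report.upper_indices),
            "n_lower": len(contact_report.lower_indices),
            "max_penetration_mm": -min(
                (*contact_report.upper_distances, *contact_report.lower_distances),
                default=0.0,
            ),
        }
    if splint_set is not None:
        sheet["splint_manifest"] = splint_set.to_dict()

    dump_json(sheet, out_dir / "planning_sheet.json")

    with (out_dir / "displacements.csv").open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["jaw", "pivot", "pre_x", "pre_y", "pre_z", "post_x", "post_y", "post_z",
             "dx", "dy", "dz", "euclidean"]
        )
        for report in displacement_reports:
            for r in report.rows:
                writer.writerow(
                    [report.jaw, r.name, *[f"{v:.9g}" for v in (*r.pre_xyz, *r.post_xyz, *r.delta_xyz, r.euclidean)]]
                )
    return sheet


def read_moves(path) -> list[PlannedMove]:
    """Load a planned-move list from JSON."""
    data = json.loads(Path(path).read_text())
    if isinstance(data, dict):
        data = data.get("moves", [])
    return [PlannedMove.from_dict(d) for d in data]
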