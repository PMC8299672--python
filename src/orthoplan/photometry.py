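"""Transverse occlusal cant and dental midline offset from a frontal
photograph.

Image frame: x to the image right, y downward.  A frontal photograph
shows the patient's left side on the image right, so patient-left means
larger x.  Angle measurements need no scale; the midline offset in mm is
only reported when a scale is supplied.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from .cephalometrics import Point2D
from .errors import MissingLandmark

__all__ = ["FrontalLandmarks", "TransverseAssessment", "occlusal_cant", "read_frontal_landmarks"]

_MANDATORY = ("pupil_left", "pupil_right", "occ_left", "occ_right")


@dataclass(frozen=True)
class FrontalLandmarks:
    pupil_left: Optional[Point2D] = None
    pupil_right: Optional[Point2D] = None
    occ_left: Optional[Point2D] = None
    occ_right: Optional[Point2D] = None
    dental_midline: Optional[Point2D] = None
    facial_midline_ref: Optional[Point2D] = None
    mm_per_px: Optional[float] = None


@dataclass(frozen=True)
class TransverseAssessment:
    """cant_deg: signed angle of the occlusal line against the
    interpupillary line; positive = patient-left side inferior.
    midline_offset_mm: signed, positive = dental midline toward the
    patient's left; None when no scale was given."""

    cant_deg: float
    midline_offset_mm: Optional[float] = None

    def to_dict(self) -> dict:
        return {"cant_deg": self.cant_deg, "midline_offset_mm": self.midline_offset_mm}


def occlusal_cant(landmarks: FrontalLandmarks) -> TransverseAssessment:
    """Signed cant of the occlusal line relative to the interpupillary
    line, plus the dental-midline offset when measurable.

    Sign conventions are anchored in the image frame: an unmirrored
    frontal photograph shows the patient's left at larger x, so the
    reference axis along the interpupillary line is oriented toward
    image-right regardless of how the pupils are labelled, and a left/
    right label swap flips the sign of both outputs.
    """
    for name in _MANDATORY:
        if getattr(landmarks, name) is None:
            raise MissingLandmark(f"frontal landmark {name!r} is required")

    # interpupillary axis, oriented toward image-right (= patient-left)
    ux = landmarks.pupil_left.x - landmarks.pupil_right.x
    uy = landmarks.pupil_left.y - landmarks.pupil_right.y
    norm = math.hypot(ux, uy)
    if ux < 0 or (ux == 0 and uy < 0):
        ux, uy = -ux, -uy
    ux, uy = ux / norm, uy / norm
    vx, vy = -uy, ux  # rotated +90 deg: the inferior direction

    wx = landmarks.occ_left.x - landmarks.occ_right.x
    wy = landmarks.occ_left.y - landmarks.occ_right.y
    # inferior component signed by the occ labels, in-line component
    # unsigned so the cant stays within (-90, 90)
    cant = math.degrees(math.atan2(wx * vx + wy * vy, abs(wx * ux + wy * uy)))

    offset = None
    if landmarks.dental_midline is not None and landmarks.mm_per_px is not None:
        anchor = landmarks.facial_midline_ref
        if anchor is None:
            anchor = Point2D(
                (landmarks.pupil_left.x + landmarks.pupil_right.x) / 2.0,
                (landmarks.pupil_left.y + landmarks.pupil_right.y) / 2.0,
            )
        offset = (
            (landmarks.dental_midline.x - anchor.x) * ux
            + (landmarks.dental_midline.y - anchor.y) * uy
        ) * landmarks.mm_per_px

    return TransverseAssessment(cant_deg=cant, midline_offset_mm=offset)


def read_frontal_landmarks(path) -> FrontalLandmarks:
    """Read the frontal-photo landmark JSON (same dialect as the
    cephalometric file: each landmark an [x, y] pair)."""
    data = json.loads(Path(path).read_text())
    kwargs = {}
    for key in (*_MANDATORY, "dental_midline", "facial_midline_ref"):
        if key in data and data[key] is not None:
            kwargs[key] = Point2D(float(data[key][0]), float(data[key][1]))
    if data.get("mm_per_px") is not None:
        kwargs["mm_per_px"] = float(data["mm_per_px"])
    return FrontalLandmarks(**kwargs)
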