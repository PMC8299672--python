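"""Scene archives: a directory of STL files plus ``scene.json``
recording pivots, transforms and mounting state (units: mm)."""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import __version__
from .errors import FormatError
from .jsonutil import dump_json
from .mounting import JawModel, MountedScene, Pivot
from .stl import read_stl, write_stl

_ROLES = ("maxilla", "mandible", "postop_maxilla", "postop_mandible")


def _jaw_entry(role: str, jaw: JawModel, filename: str) -> dict:
    return {
        "role": role,
        "label": jaw.label,
        "stage": jaw.stage,
        "file": filename,
        "pivots": {n: p.position.tolist() for n, p in jaw.pivots.items()},
    }


def save_scene(scene: MountedScene, directory, *, ascii: bool = False) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    jaws = []
    for role in _ROLES:
        jaw = getattr(scene, role if role.startswith("postop") else role)
        if jaw is None:
            continue
        filename = f"{role}.stl"
        write_stl(jaw.mesh, directory / filename, ascii=ascii)
        jaws.append(_jaw_entry(role, jaw, filename))
    doc = {
        "format": "orthoplan-scene",
        "version": __version__,
        "units": "mm",
        "frame": scene.frame,
        "lambda_applied": scene.lambda_applied,
        "hinge_pivot": None
        if scene.hinge_pivot is None
        else {"name": scene.hinge_pivot.name, "position": scene.hinge_pivot.position.tolist()},
        "jaws": jaws,
        "transform_log": scene.transform_log,
    }
    dump_json(doc, directory / "scene.json")
    return directory


def load_scene(directory) -> MountedScene:
    directory = Path(directory)
    doc = json.loads((directory / "scene.json").read_text())
    if doc.get("format") != "orthoplan-scene":
        raise FormatError(f"{directory}: not an orthoplan scene archive")
    loaded: dict[str, JawModel] = {}
    for entry in doc["jaws"]:
        path = directory / entry["file"]
        if not path.exists():
            raise FormatError(f"scene.json references missing file {entry['file']!r}")
        jaw = JawModel(
            label=entry["label"], mesh=read_stl(path), stage=entry["stage"]
        )
        for name, pos in entry["pivots"].items():
            jaw.add_pivot(Pivot(name, np.asarray(pos, dtype=float)))
        loaded[entry["role"]] = jaw
    if "maxilla" not in loaded or "mandible" not in loaded:
        raise FormatError(f"{directory}: scene must contain preop maxilla and mandible")
    hinge = doc.get("hinge_pivot")
    return MountedScene(
        maxilla=loaded["maxilla"],
        mandible=loaded["mandible"],
        postop_maxilla=loaded.get("postop_maxilla"),
        postop_mandible=loaded.get("postop_mandible"),
        hinge_pivot=None
        if hinge is None
        else Pivot(hinge["name"], np.asarray(hinge["position"], dtype=float), "maxilla"),
        lambda_applied=doc.get("lambda_applied"),
        frame=doc.get("frame", {}),
        transform_log=doc.get("transform_log", []),
    )
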