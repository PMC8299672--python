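"""STL reading/writing (binary little-endian and ASCII), units mm."""
from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .errors import FormatError
from .mesh import TriangleMesh

_BINARY_DTYPE = np.dtype(
    [
        ("normal", "<f4", (3,)),
        ("vertices", "<f4", (3, 3)),
        ("attr", "<u2"),
    ]
)


def _dedup(tri_pts: np.ndarray) -> TriangleMesh:
    flat = tri_pts.reshape(-1, 3)
    verts, inverse = np.unique(flat, axis=0, return_inverse=True)
    return TriangleMesh(verts, inverse.reshape(-1, 3))


def read_stl(path) -> TriangleMesh:
    """Read an ASCII or binary STL file; triangles sharing identical
    coordinates are welded back into shared vertices."""
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 15:
        raise FormatError(f"{path}: too short to be an STL file")
    if raw.lstrip()[:5].lower() == b"solid" and b"facet" in raw[:2048].lower():
        return _read_ascii(raw, path)
    return _read_binary(raw, path)


def _read_ascii(raw: bytes, path: Path) -> TriangleMesh:
    try:
        text = raw.decode("ascii", errors="strict")
    except UnicodeDecodeError as exc:
        raise FormatError(f"{path}: invalid ASCII STL") from exc
    coords: list[float] = []
    for line in text.splitlines():
        parts = line.split()
        if parts[:1] == ["vertex"]:
            if len(parts) != 4:
                raise FormatError(f"{path}: malformed vertex line {line!r}")
            try:
                coords.extend(float(p) for p in parts[1:])
            except ValueError as exc:
                raise FormatError(f"{path}: bad vertex number in {line!r}") from exc
    if not coords or len(coords) % 9 != 0:
        raise FormatError(f"{path}: vertex count not a multiple of 3")
    return _dedup(np.asarray(coords).reshape(-1, 3, 3))


def _read_binary(raw: bytes, path: Path) -> TriangleMesh:
    if len(raw) < 84:
        raise FormatError(f"{path}: binary STL truncated header")
    (count,) = struct.unpack_from("<I", raw, 80)
    expected = 84 + count * _BINARY_DTYPE.itemsize
    if len(raw) < expected:
        raise FormatError(f"{path}: binary STL truncated body")
    body = np.frombuffer(raw, dtype=_BINARY_DTYPE, count=count, offset=84)
    return _dedup(body["vertices"].astype(float))


def write_stl(mesh: TriangleMesh, path, ascii: bool = False, name: str = "orthoplan") -> None:
    path = Path(path)
    tri = mesh.triangles
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norms = np.linalg.norm(n, axis=1, keepdims=True)
    n = n / np.where(norms == 0.0, 1.0, norms)
    if ascii:
        lines = [f"solid {name}"]
        for nv, t in zip(n, tri):
            lines.append(f"  facet normal {nv[0]:.9g} {nv[1]:.9g} {nv[2]:.9g}")
            lines.append("    outer loop")
            for v in t:
                lines.append(f"      vertex {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}")
            lines.append("    endloop")
            lines.append("  endfacet")
        lines.append(f"endsolid {name}")
        path.write_text("\n".join(lines) + "\n")
        return
    body = np.zeros(len(tri), dtype=_BINARY_DTYPE)
    body["normal"] = n
    body["vertices"] = tri
    header = name.encode("ascii")[:80].ljust(80, b"\0")
    with path.open("wb") as fh:
        fh.write(header)
        fh.write(struct.pack("<I", len(tri)))
        fh.write(body.tobytes())
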