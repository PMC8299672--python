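"""Minimal triangle-mesh container plus the proximity queries the
planner needs (point-to-surface distance, inside/outside test, volume).

Kept deliberately small: the planner only moves meshes rigidly and
queries distances; no remeshing, booleans or repair.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import RigidTransform


@dataclass
class TriangleMesh:
    vertices: np.ndarray  # (n, 3) float64, mm
    faces: np.ndarray  # (m, 3) int64

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face index out of range")

    # -- basics -------------------------------------------------------
    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy())

    def transformed(self, transform: RigidTransform) -> "TriangleMesh":
        return TriangleMesh(transform.apply(self.vertices), self.faces.copy())

    @property
    def triangles(self) -> np.ndarray:
        """(m, 3, 3) array of triangle corner coordinates."""
        return self.vertices[self.faces]

    def volume(self) -> float:
        """Signed volume via the divergence theorem (positive when
        faces are oriented outward)."""
        t = self.triangles
        return float(np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])).sum() / 6.0)

    def is_watertight(self) -> bool:
        """Every undirected edge used by exactly two faces, once in each
        direction (closed, consistently oriented 2-manifold)."""
        f = self.faces
        directed = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        # no repeated directed edge
        d_view = directed[np.lexsort(directed.T[::-1])]
        if np.any(np.all(d_view[1:] == d_view[:-1], axis=1)):
            return False
        undirected = np.sort(directed, axis=1)
        u_view = undirected[np.lexsort(undirected.T[::-1])]
        if len(u_view) % 2 != 0:
            return False
        return bool(np.all(u_view[1::2] == u_view[0::2]))


# ---------------------------------------------------------------------
# proximity queries
# ---------------------------------------------------------------------

def _point_segment_dist_sq(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    # p: (n, 1, 3) against segments a, b: (1, m, 3) -> (n, m)
    ab = b - a
    denom = np.einsum("...i,...i", ab, ab)
    t = np.einsum("...i,...i", p - a, ab) / np.where(denom == 0.0, 1.0, denom)
    t = np.clip(t, 0.0, 1.0)
    closest = a + t[..., None] * ab
    d = p - closest
    return np.einsum("...i,...i", d, d)


def point_triangle_distances(points, mesh: TriangleMesh, chunk: int = 256) -> np.ndarray:
    """Unsigned distance from each query point to the mesh surface.

    The closest point on a triangle is either the orthogonal projection
    (when it falls inside) or lies on one of the edges, so the edge
    distances plus the interior projection cover all cases exactly.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    tri = mesh.triangles
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    n = np.cross(v1 - v0, v2 - v0)
    nn = np.einsum("ij,ij->i", n, n)
    nn_safe = np.where(nn == 0.0, 1.0, nn)

    out = np.empty(len(pts))
    for lo in range(0, len(pts), chunk):
        p = pts[lo : lo + chunk][:, None, :]  # (c, 1, 3)
        # interior projection, validity via barycentric signs
        w = p - v0[None]
        dist_plane = np.einsum("...i,i...->...", w, n.T) / np.sqrt(nn_safe)[None]
        proj = p - dist_plane[..., None] * (n / np.sqrt(nn_safe)[:, None])[None]
        # barycentric coordinates of proj
        a = proj - v0[None]
        d00 = np.einsum("ij,ij->i", v1 - v0, v1 - v0)[None]
        d01 = np.einsum("ij,ij->i", v1 - v0, v2 - v0)[None]
        d11 = np.einsum("ij,ij->i", v2 - v0, v2 - v0)[None]
        d20 = np.einsum("...i,i...->...", a, (v1 - v0).T)
        d21 = np.einsum("...i,i...->...", a, (v2 - v0).T)
        denom = d00 * d11 - d01 * d01
        denom = np.where(denom == 0.0, 1.0, denom)
        s = (d11 * d20 - d01 * d21) / denom
        t = (d00 * d21 - d01 * d20) / denom
        inside = (s >= 0.0) & (t >= 0.0) & (s + t <= 1.0) & (nn[None] > 0.0)

        d_sq = np.minimum(
            _point_segment_dist_sq(p, v0[None], v1[None]),
            np.minimum(
                _point_segment_dist_sq(p, v1[None], v2[None]),
                _point_segment_dist_sq(p, v2[None], v0[None]),
            ),
        )
        d_sq = np.where(inside, dist_plane**2, d_sq)
        out[lo : lo + chunk] = np.sqrt(d_sq.min(axis=1))
    return out


def winding_numbers(points, mesh: TriangleMesh, chunk: int = 256) -> np.ndarray:
    """Generalised winding number of each point w.r.t. the mesh
    (van Oosterom & Strackee solid-angle sum; ~1 inside a closed,
    outward-oriented mesh, ~0 outside)."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    tri = mesh.triangles
    out = np.empty(len(pts))
    for lo in range(0, len(pts), chunk):
        p = pts[lo : lo + chunk][:, None, :]
        a = tri[None, :, 0] - p
        b = tri[None, :, 1] - p
        c = tri[None, :, 2] - p
        la = np.linalg.norm(a, axis=-1)
        lb = np.linalg.norm(b, axis=-1)
        lc = np.linalg.norm(c, axis=-1)
        num = np.einsum("...i,...i", a, np.cross(b, c))
        den = (
            la * lb * lc
            + np.einsum("...i,...i", a, b) * lc
            + np.einsum("...i,...i", b, c) * la
            + np.einsum("...i,...i", c, a) * lb
        )
        omega = 2.0 * np.arctan2(num, den)
        out[lo : lo + chunk] = omega.sum(axis=1) / (4.0 * np.pi)
    return out


def signed_distances(points, mesh: TriangleMesh) -> np.ndarray:
    """Distance to the mesh surface, negative for points inside the
    (closed) mesh."""
    d = point_triangle_distances(points, mesh)
    inside = np.abs(winding_numbers(points, mesh)) > 0.5
    return np.where(inside, -d, d)
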