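"""Anatomical frames and tibial-plateau reference-plane construction.

The tibial plateau plane is the reference surface for every tunnel
measurement: tunnel height (TTH) is measured perpendicular to it and the
tunnel angle (TTA) is the dihedral angle of the oblique section plane
against it.  Clinically the plane is located with a best-fit circle drawn
tangent to the cortical edge of the medial tibial plateau; the three tangent
points (most anterior, most medial, most posterior points of the medial
plateau rim) define the plane.  Computationally we recover the same three
extremal rim points along the anatomical antero-posterior / medio-lateral
axes, with one refinement pass in the provisional plane, and keep the
circumscribed circle of the three points as a QC diagnostic.

Internal chirality convention: right-handed frame, +Z proximal (superior),
+Y anterior, +X lateral for a right knee.  Left knees are mirrored into this
convention upstream, so "medial" is always the -X side here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

__all__ = [
    "AnatomicalFrame",
    "Contour",
    "PlateauPlane",
    "LandmarkError",
    "extract_medial_plateau_rim",
    "tangent_circle_landmarks",
    "plateau_plane_from_points",
]


class LandmarkError(ValueError):
    """Raised when an anatomical landmark cannot be recovered from a mesh."""


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector")
    return v / n


@dataclass(frozen=True)
class AnatomicalFrame:
    """Right-handed orthonormal anatomical coordinate system (units mm).

    ``ml_axis`` points lateral (for the internal right-knee convention),
    ``ap_axis`` anterior, ``si_axis`` proximal.
    """

    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    ml_axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    ap_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    si_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        for name in ("ml_axis", "ap_axis", "si_axis"):
            object.__setattr__(self, name, _unit(getattr(self, name)))
        g = np.stack([self.ml_axis, self.ap_axis, self.si_axis])
        if not np.allclose(g @ g.T, np.eye(3), atol=1e-8):
            raise ValueError("frame axes must be orthonormal")
        if np.dot(np.cross(self.ml_axis, self.ap_axis), self.si_axis) < 0:
            raise ValueError("frame must be right-handed")

    @property
    def medial_dir(self) -> np.ndarray:
        return -self.ml_axis

    def transformed(self, matrix: np.ndarray) -> "AnatomicalFrame":
        """Frame after a 4x4 homogeneous rigid transform."""
        m = np.asarray(matrix, dtype=float)
        rot = m[:3, :3]
        return AnatomicalFrame(
            origin=rot @ self.origin + m[:3, 3],
            ml_axis=rot @ self.ml_axis,
            ap_axis=rot @ self.ap_axis,
            si_axis=rot @ self.si_axis,
        )


@dataclass
class Contour:
    """Ordered 3D polyline (mm); closed contours store the first point once."""

    points: np.ndarray
    closed: bool = True
    source: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(pts) >= 2:
            keep = np.ones(len(pts), dtype=bool)
            keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-12
            pts = pts[keep]
            if self.closed and len(pts) > 1 and np.linalg.norm(pts[0] - pts[-1]) <= 1e-12:
                pts = pts[:-1]
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)

    @property
    def segments(self) -> np.ndarray:
        """(n, 2, 3) array of polyline segments, wrapping if closed."""
        p = self.points
        q = np.roll(p, -1, axis=0) if self.closed else p[1:]
        start = p if self.closed else p[:-1]
        return np.stack([start, q], axis=1)

    def arc_lengths(self) -> np.ndarray:
        seg = self.segments
        return np.linalg.norm(seg[:, 1] - seg[:, 0], axis=1)

    @property
    def length(self) -> float:
        return float(self.arc_lengths().sum())


@dataclass
class PlateauPlane:
    """Tibial plateau reference plane with its tangent landmarks.

    ``unit_normal`` is oriented proximally (``normal . si_axis > 0``).  The
    fit circle through the three tangent points is diagnostic only.
    """

    point_on_plane: np.ndarray
    unit_normal: np.ndarray
    p_anterior: np.ndarray
    p_medial: np.ndarray
    p_posterior: np.ndarray
    circle_center: np.ndarray | None = None
    circle_radius: float | None = None

    def __post_init__(self) -> None:
        self.point_on_plane = np.asarray(self.point_on_plane, dtype=float)
        self.unit_normal = _unit(self.unit_normal)
        for name in ("p_anterior", "p_medial", "p_posterior"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed distance (mm), positive proximal to the plane."""
        pts = np.asarray(points, dtype=float)
        return (pts - self.point_on_plane) @ self.unit_normal

    def transformed(self, matrix: np.ndarray) -> "PlateauPlane":
        m = np.asarray(matrix, dtype=float)
        rot, t = m[:3, :3], m[:3, 3]
        return PlateauPlane(
            point_on_plane=rot @ self.point_on_plane + t,
            unit_normal=rot @ self.unit_normal,
            p_anterior=rot @ self.p_anterior + t,
            p_medial=rot @ self.p_medial + t,
            p_posterior=rot @ self.p_posterior + t,
            circle_center=None if self.circle_center is None else rot @ self.circle_center + t,
            circle_radius=self.circle_radius,
        )


# ---------------------------------------------------------------------------
# rim extraction


def _proximal_patch_faces(
    mesh: trimesh.Trimesh, frame: AnatomicalFrame, normal_tol_deg: float
) -> np.ndarray:
    cos_tol = np.cos(np.radians(normal_tol_deg))
    mask = mesh.face_normals @ frame.si_axis >= cos_tol
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise LandmarkError(
            "no proximal near-horizontal articular patch found "
            f"(no face normal within {normal_tol_deg} deg of the superior axis)"
        )
    # largest connected component of the candidate faces
    adj = mesh.face_adjacency
    keep = mask[adj].all(axis=1)
    comps = trimesh.graph.connected_components(adj[keep], nodes=idx, min_len=1)
    return max(comps, key=len)


def _boundary_loop(mesh: trimesh.Trimesh, face_idx: np.ndarray) -> np.ndarray:
    """Ordered vertex indices of the outer boundary of a face patch."""
    edges = mesh.edges_sorted.reshape(-1, 2)
    face_of_edge = np.repeat(np.arange(len(mesh.faces)), 3)
    in_patch = np.zeros(len(mesh.faces), dtype=bool)
    in_patch[face_idx] = True
    patch_edges = edges[in_patch[face_of_edge]]
    # boundary edges appear exactly once within the patch
    uniq, counts = np.unique(patch_edges, axis=0, return_counts=True)
    boundary = uniq[counts == 1]
    if len(boundary) < 3:
        raise LandmarkError("degenerate articular patch boundary")
    # chain the boundary edges into loops; keep the longest
    nxt: dict[int, list[int]] = {}
    for a, b in boundary:
        nxt.setdefault(int(a), []).append(int(b))
        nxt.setdefault(int(b), []).append(int(a))
    unused = {tuple(sorted(e)) for e in boundary.tolist()}
    loops = []
    while unused:
        a, b = next(iter(unused))
        loop = [a, b]
        unused.discard((a, b))
        while True:
            cur, prev = loop[-1], loop[-2]
            cand = [v for v in nxt[cur] if tuple(sorted((cur, v))) in unused]
            if not cand:
                break
            v = cand[0]
            unused.discard(tuple(sorted((cur, v))))
            if v == loop[0]:
                break
            loop.append(v)
        loops.append(loop)
    return np.array(max(loops, key=len))


def extract_medial_plateau_rim(
    mesh: trimesh.Trimesh,
    frame: AnatomicalFrame,
    normal_tol_deg: float = 25.0,
) -> Contour:
    """Closed contour bounding the medial half of the proximal articular patch.

    The proximal articular patch is the largest connected component of faces
    whose normals lie within ``normal_tol_deg`` of the superior axis.  The
    medial/lateral split runs through the sagittal plane at the centroid of
    that patch (a stand-in for the tibial-spine midline).  The returned rim
    is ordered counter-clockwise viewed from proximal.
    """
    patch = _proximal_patch_faces(mesh, frame, normal_tol_deg)
    centroids = mesh.triangles_center[patch]
    split = float(np.mean(centroids @ frame.ml_axis))
    medial = patch[(centroids @ frame.ml_axis) <= split]
    if medial.size == 0:
        raise LandmarkError("no medial articular faces found")
    # largest connected component of the medial half
    adj = mesh.face_adjacency
    sel = np.zeros(len(mesh.faces), dtype=bool)
    sel[medial] = True
    comps = trimesh.graph.connected_components(
        adj[sel[adj].all(axis=1)], nodes=medial, min_len=1
    )
    medial = max(comps, key=len)
    loop = _boundary_loop(mesh, medial)
    pts = mesh.vertices[loop]
    # orient CCW viewed from proximal
    uv = np.column_stack([pts @ frame.ml_axis, pts @ frame.ap_axis])
    area2 = np.sum(uv[:, 0] * np.roll(uv[:, 1], -1) - np.roll(uv[:, 0], -1) * uv[:, 1])
    if area2 < 0:
        pts = pts[::-1]
    return Contour(points=pts, closed=True, source="medial_plateau_rim")


# ---------------------------------------------------------------------------
# tangent landmarks and plane fit


def _extremal_point(pts: np.ndarray, direction: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    """Extremal contour vertex along ``direction`` with a deterministic tie-break.

    Ties within ``tol`` are resolved by taking the centroid of the tied
    vertices and snapping it to the nearest tied vertex.
    """
    proj = pts @ direction
    tied = np.flatnonzero(proj >= proj.max() - tol)
    if tied.size == 1:
        return pts[tied[0]]
    centroid = pts[tied].mean(axis=0)
    best = tied[np.argmin(np.linalg.norm(pts[tied] - centroid, axis=1))]
    return pts[best]


def _circle_through(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray):
    """Circumscribed circle of three 3D points -> (center, radius) or (None, None)."""
    a, b = p2 - p1, p3 - p1
    n = np.cross(a, b)
    nn = np.linalg.norm(n)
    if nn < 1e-9:
        return None, None
    n = n / nn
    # solve in the plane spanned by (a, b)
    u = a / np.linalg.norm(a)
    v = np.cross(n, u)
    b2 = np.array([b @ u, b @ v])
    a2 = np.array([np.linalg.norm(a), 0.0])
    d = 2 * (a2[0] * b2[1])
    ux = ((a2 @ a2) * b2[1] - (b2 @ b2) * a2[1]) / d
    uy = ((b2 @ b2) * a2[0] - (a2 @ a2) * b2[0]) / d
    center = p1 + ux * u + uy * v
    return center, float(np.linalg.norm(center - p1))


def tangent_circle_landmarks(rim: Contour, frame: AnatomicalFrame):
    """Three tangent landmarks of the medial plateau rim.

    Returns ``(p_anterior, p_medial, p_posterior, (circle_center, radius))``:
    the rim vertices extremal along +AP, the medial direction and -AP,
    found in the transverse projection and refined once in the provisional
    plane they define.  The circumscribed circle of the three points is the
    computational stand-in for the manually drawn best-fit circle and is
    returned purely as a diagnostic.
    """
    if not rim.closed or len(rim) < 8:
        raise LandmarkError("rim contour must be closed with at least 8 points")
    pts = rim.points

    def pick(ap_dir, med_dir):
        return (
            _extremal_point(pts, ap_dir),
            _extremal_point(pts, med_dir),
            _extremal_point(pts, -ap_dir),
        )

    p_a, p_m, p_p = pick(frame.ap_axis, frame.medial_dir)
    n = np.cross(p_m - p_a, p_p - p_a)
    if np.linalg.norm(n) < 1e-9:
        raise LandmarkError("degenerate rim: tangent points are collinear")
    n = _unit(n)
    if n @ frame.si_axis < 0:
        n = -n
    # one refinement pass: re-find the extremes with the in-provisional-plane
    # components of the anatomical axes
    ap_in = frame.ap_axis - (frame.ap_axis @ n) * n
    med_in = frame.medial_dir - (frame.medial_dir @ n) * n
    if np.linalg.norm(ap_in) > 1e-9 and np.linalg.norm(med_in) > 1e-9:
        p_a, p_m, p_p = pick(_unit(ap_in), _unit(med_in))
    center, radius = _circle_through(p_a, p_m, p_p)
    return p_a, p_m, p_p, (center, radius)


def plateau_plane_from_points(
    p_anterior: np.ndarray,
    p_medial: np.ndarray,
    p_posterior: np.ndarray,
    frame: AnatomicalFrame,
) -> PlateauPlane:
    """Plane through the three tangent points, normal oriented proximally."""
    p_a = np.asarray(p_anterior, dtype=float)
    p_m = np.asarray(p_medial, dtype=float)
    p_p = np.asarray(p_posterior, dtype=float)
    n = np.cross(p_m - p_a, p_p - p_a)
    if np.linalg.norm(n) < 1e-9 * max(np.linalg.norm(p_m - p_a), 1.0):
        raise LandmarkError("tangent points are collinear; cannot fit a plane")
    n = _unit(n)
    if n @ frame.si_axis < 0:
        n = -n
    center, radius = _circle_through(p_a, p_m, p_p)
    return PlateauPlane(
        point_on_plane=p_a,
        unit_normal=n,
        p_anterior=p_a,
        p_medial=p_m,
        p_posterior=p_p,
        circle_center=center,
        circle_radius=radius,
    )


def plateau_plane_from_mesh(
    mesh: trimesh.Trimesh, frame: AnatomicalFrame, normal_tol_deg: float = 25.0
) -> PlateauPlane:
    """Convenience: rim extraction + tangent landmarks + plane fit."""
    rim = extract_medial_plateau_rim(mesh, frame, normal_tol_deg)
    p_a, p_m, p_p, _ = tangent_circle_landmarks(rim, frame)
    return plateau_plane_from_points(p_a, p_m, p_p, frame)
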