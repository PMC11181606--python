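"""Transtibial tunnel simulation: oblique sectioning, entry placement, TTL/TTH.

For a given tibial tunnel angle (TTA), a section plane is passed through the
PCL tibial attachment centre (the tunnel exit), hinged parallel to the
medio-lateral axis and inclined TTA degrees to the tibial plateau plane so
that it descends anteriorly — the computational equivalent of drawing the
inclined line in the lateral view and cutting the bone along it.  On the
resulting oblique cortical cross-section the crest ("TTA") point is the most
anterior contour point; the anteromedial (AM) and anterolateral (AL) tunnel
entries are placed 2 cm medial and lateral of it, measured as arc length
along the cortical outline so the entries stay on bone.

Tunnel length TTL is the Euclidean entry-exit distance; tunnel height TTH
is the perpendicular distance from the entry to the plateau plane.  The
nominal TTA is a property of the section plane, not of the entry-exit
chord: with off-midline entries the true 3D inclination of the tunnel axis
differs slightly and is reported as a diagnostic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import trimesh

from .geometry import AnatomicalFrame, Contour, PlateauPlane

__all__ = [
    "TunnelPlan",
    "ObliqueSection",
    "TunnelMeasurement",
    "SectionError",
    "section_plane",
    "cut_section",
    "crest_point",
    "entry_points",
    "measure_tunnel",
    "simulate_knee",
]

DEFAULT_ANGLES = (40.0, 45.0, 50.0, 55.0, 60.0)


class SectionError(ValueError):
    """Raised when an oblique section cannot be constructed."""


@dataclass(frozen=True)
class TunnelPlan:
    """One simulated drilling configuration."""

    tta: float = 50.0
    approach: Literal["AM", "AL"] = "AM"
    offset_mm: float = 20.0
    angle_set: tuple[float, ...] = DEFAULT_ANGLES

    def __post_init__(self) -> None:
        if not 0.0 < self.tta < 90.0:
            raise ValueError("tta must lie in (0, 90) degrees")
        if self.offset_mm <= 0:
            raise ValueError("offset_mm must be > 0")


@dataclass
class ObliqueSection:
    """Oblique cut of the tibia at one TTA."""

    plane_point: np.ndarray
    plane_normal: np.ndarray
    contour: Contour
    tta: float
    crest: np.ndarray | None = None


@dataclass(frozen=True)
class TunnelMeasurement:
    """Entry/exit pair with its TTL/TTH outcome for one (approach, TTA)."""

    entry: np.ndarray
    exit: np.ndarray
    ttl: float
    tth: float
    tta: float
    approach: Literal["AM", "AL"]
    true_inclination_deg: float | None = None  # diagnostic: 3D axis vs plateau


def section_plane(
    plateau: PlateauPlane,
    exit_point: np.ndarray,
    tta: float,
    frame: AnatomicalFrame,
) -> tuple[np.ndarray, np.ndarray]:
    """Oblique section plane through the tunnel exit at angle ``tta``.

    Returns ``(point, unit_normal)``.  The plane's intersection with the
    plateau plane is parallel to the ML axis (the inclination is realised in
    the lateral/sagittal view) and the plane descends anteriorly, so its
    normal is ``sin(tta) * a + cos(tta) * n`` for anterior axis ``a`` and
    proximal plateau normal ``n`` (both projected consistently).
    """
    if not 0.0 < tta < 90.0:
        raise SectionError("tta must lie in (0, 90) degrees")
    n_plateau = plateau.unit_normal
    ml = frame.ml_axis - (frame.ml_axis @ n_plateau) * n_plateau
    ml = ml / np.linalg.norm(ml)
    anterior = np.cross(n_plateau, ml)
    if anterior @ frame.ap_axis < 0:
        anterior = -anterior
    rad = math.radians(tta)
    normal = math.sin(rad) * anterior + math.cos(rad) * n_plateau
    return np.asarray(exit_point, dtype=float), normal / np.linalg.norm(normal)


def cut_section(
    mesh: trimesh.Trimesh,
    plane_point: np.ndarray,
    plane_normal: np.ndarray,
    tta: float = float("nan"),
) -> ObliqueSection:
    """Outer cortical contour of the mesh-plane intersection.

    Inner loops (e.g. through medullary voids) are discarded; the outer
    loop is the one of greatest perimeter, re-ordered counter-clockwise
    viewed from the plane normal.
    """
    path = mesh.section(plane_origin=plane_point, plane_normal=plane_normal)
    if path is None or len(path.entities) == 0:
        raise SectionError("plane does not intersect the mesh")
    loops = [np.asarray(d, dtype=float) for d in path.discrete]
    closed = [lp for lp in loops if np.linalg.norm(lp[0] - lp[-1]) < 1e-8 and len(lp) > 3]
    if not closed:
        raise SectionError("mesh-plane intersection has no closed loop")

    def perimeter(lp):
        return float(np.linalg.norm(np.diff(lp, axis=0), axis=1).sum())

    outer = max(closed, key=perimeter)[:-1]  # drop duplicated last point
    n = np.asarray(plane_normal, dtype=float)
    n = n / np.linalg.norm(n)
    # in-plane orientation: CCW about the normal
    u = np.cross(n, [0.0, 0.0, 1.0])
    if np.linalg.norm(u) < 1e-8:
        u = np.cross(n, [0.0, 1.0, 0.0])
    u = u / np.linalg.norm(u)
    v = np.cross(n, u)
    uv = np.column_stack([(outer - plane_point) @ u, (outer - plane_point) @ v])
    area2 = np.sum(uv[:, 0] * np.roll(uv[:, 1], -1) - np.roll(uv[:, 0], -1) * uv[:, 1])
    if area2 < 0:
        outer = outer[::-1]
    contour = Contour(points=outer, closed=True, source="oblique_section")
    return ObliqueSection(
        plane_point=np.asarray(plane_point, dtype=float),
        plane_normal=n,
        contour=contour,
        tta=tta,
    )


def crest_point(section: ObliqueSection, frame: AnatomicalFrame, tol: float = 1e-6) -> np.ndarray:
    """Most anterior contour point of the oblique section (the "TTA point").

    If several contour vertices tie within ``tol`` along the anterior axis
    the midpoint of the tied span is taken and snapped to the nearest
    contour vertex, which keeps the choice deterministic on symmetric bones.
    """
    pts = section.contour.points
    if len(pts) == 0:
        raise SectionError("empty section contour")
    proj = pts @ frame.ap_axis
    tied = np.flatnonzero(proj >= proj.max() - tol)
    if tied.size == 1:
        crest = pts[tied[0]]
    else:
        span = pts[tied]
        mid = 0.5 * (span.min(axis=0) + span.max(axis=0))
        crest = span[int(np.argmin(np.linalg.norm(span - mid, axis=1)))]
    section.crest = crest
    return crest


def _walk(points: np.ndarray, start_idx: int, step: int, arc: float) -> np.ndarray:
    """Point at arc length ``arc`` from vertex ``start_idx`` along a closed
    polyline, walking in direction ``step`` (+1/-1), with linear
    interpolation inside the final segment."""
    n = len(points)
    remaining = arc
    i = start_idx
    for _ in range(2 * n):
        j = (i + step) % n
        seg = float(np.linalg.norm(points[j] - points[i]))
        if seg >= remaining:
            t = remaining / seg if seg > 0 else 0.0
            return points[i] + t * (points[j] - points[i])
        remaining -= seg
        i = j
    raise SectionError("contour shorter than the requested entry offset")


def _walk_chord(points: np.ndarray, start_idx: int, step: int, chord: float) -> np.ndarray:
    """First contour point at straight-line distance ``chord`` from the start
    vertex, walking in direction ``step`` (sensitivity-analysis alternative
    to the arc-length rule)."""
    n = len(points)
    origin = points[start_idx]
    i = start_idx
    for _ in range(2 * n):
        j = (i + step) % n
        d_i = float(np.linalg.norm(points[i] - origin))
        d_j = float(np.linalg.norm(points[j] - origin))
        if d_j >= chord > d_i:
            # linear interpolation on the segment for the crossing point
            lo, hi = 0.0, 1.0
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                p = points[i] + mid * (points[j] - points[i])
                if np.linalg.norm(p - origin) < chord:
                    lo = mid
                else:
                    hi = mid
            return points[i] + 0.5 * (lo + hi) * (points[j] - points[i])
        i = j
    raise SectionError("contour never reaches the requested chord distance")


def entry_points(
    section: ObliqueSection,
    frame: AnatomicalFrame,
    offset_mm: float = 20.0,
    mode: Literal["arc", "chord"] = "arc",
) -> tuple[np.ndarray, np.ndarray]:
    """AM and AL tunnel entries, ``offset_mm`` along the contour from the crest.

    The offset (clinically 2 cm) is laid off as arc length along the oblique
    cortical outline in both directions from the crest point, keeping the
    entries on bone; ``mode="chord"`` instead takes the first contour point
    at straight-line distance ``offset_mm`` (the two rules coincide on flat
    faces).  The walk whose endpoint lies further medial is the AM entry,
    the other the AL entry.  Returns ``(am_entry, al_entry)``.
    """
    if offset_mm < 0:
        raise ValueError("offset_mm must be >= 0")
    crest = section.crest if section.crest is not None else crest_point(section, frame)
    pts = section.contour.points
    if section.contour.length < 2 * offset_mm:
        raise SectionError("section contour too short for the entry offset")
    start = int(np.argmin(np.linalg.norm(pts - crest, axis=1)))
    if offset_mm == 0:
        return crest.copy(), crest.copy()
    walker = _walk if mode == "arc" else _walk_chord
    p_fwd = walker(pts, start, +1, offset_mm)
    p_bwd = walker(pts, start, -1, offset_mm)
    med = frame.medial_dir
    if (p_fwd - crest) @ med >= (p_bwd - crest) @ med:
        return p_fwd, p_bwd
    return p_bwd, p_fwd


def measure_tunnel(
    entry: np.ndarray,
    exit_point: np.ndarray,
    plateau: PlateauPlane,
    tta: float = float("nan"),
    approach: Literal["AM", "AL"] = "AM",
) -> TunnelMeasurement:
    """TTL (entry-exit distance) and TTH (entry depth below the plateau)."""
    entry = np.asarray(entry, dtype=float)
    exit_point = np.asarray(exit_point, dtype=float)
    axis = exit_point - entry
    ttl = float(np.linalg.norm(axis))
    if ttl == 0:
        raise ValueError("entry and exit coincide")
    signed = float(plateau.signed_distance(entry))
    if signed > 1e-6:
        warnings.warn(
            "tunnel entry lies proximal to the plateau plane; check landmarks",
            stacklevel=2,
        )
    tth = abs(signed)
    sin_inc = abs(axis @ plateau.unit_normal) / ttl
    return TunnelMeasurement(
        entry=entry,
        exit=exit_point,
        ttl=ttl,
        tth=tth,
        tta=tta,
        approach=approach,
        true_inclination_deg=math.degrees(math.asin(min(sin_inc, 1.0))),
    )


def simulate_knee(
    mesh: trimesh.Trimesh,
    plateau: PlateauPlane,
    pcl_attachment: np.ndarray,
    frame: AnatomicalFrame,
    angle_set: tuple[float, ...] = DEFAULT_ANGLES,
    approaches: tuple[str, ...] = ("AM", "AL"),
    offset_mm: float = 20.0,
    entry_mode: Literal["arc", "chord"] = "arc",
) -> list[TunnelMeasurement]:
    """Measure every (approach, TTA) tunnel for one knee.

    One oblique section per angle serves both approaches.  Deterministic
    for fixed inputs; returns ``len(angle_set) * len(approaches)`` rows.
    """
    rows: list[TunnelMeasurement] = []
    exit_pt = np.asarray(pcl_attachment, dtype=float)
    for tta in angle_set:
        point, normal = section_plane(plateau, exit_pt, tta, frame)
        try:
            section = cut_section(mesh, point, normal, tta=tta)
            crest_point(section, frame)
            am, al = entry_points(section, frame, offset_mm=offset_mm, mode=entry_mode)
        except SectionError as err:
            raise SectionError(f"TTA {tta} deg: {err}") from err
        for approach in approaches:
            entry = am if approach == "AM" else al
            rows.append(measure_tunnel(entry, exit_pt, plateau, tta=tta, approach=approach))
    return rows
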