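"""Tubular geometry processing for 4D outflow-tract surface sequences.

The outflow tract (OFT) of the early embryonic heart is a curved, tapered,
beating tube.  Segmented lumen and myocardium surfaces are represented here as
*structured* tubes: ``n_rings`` planar cross-sectional contours ("rings"),
each discretized by ``n_theta`` vertices, with identical connectivity across
all frames of a cardiac cycle so that rings correspond materially over time.

This module provides

- :class:`StructuredTubeSurface` and its per-ring area/perimeter measures,
- centerline computation from a tube surface (:func:`compute_centerline`),
- extraction of cross-sectional area/perimeter time series at evenly spaced
  centerline stations (:func:`extract_cross_sections`),
- re-parameterization of raw tube meshes into consistent structured form
  (:func:`parameterize_consistent`), and
- structured tetrahedral volume meshing of the lumen for the quasi-steady
  flow solver (:func:`build_volume_mesh`).

All coordinates and lengths are in metres (SI).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

__all__ = [
    "StructuredTubeSurface",
    "CenterlineCurve",
    "TubeVolumeMesh",
    "ClosedLumenError",
    "compute_centerline",
    "extract_cross_sections",
    "parameterize_consistent",
    "build_volume_mesh",
    "plane_section",
]


class ClosedLumenError(RuntimeError):
    """Raised when a lumen is closed (or nearly closed) and cannot be meshed."""


# ---------------------------------------------------------------------------
# surface container
# ---------------------------------------------------------------------------


@dataclass
class StructuredTubeSurface:
    """Tube surface as an (n_rings, n_theta, 3) vertex grid.

    Ring index runs proximal (inlet, ventricle end) to distal (outlet,
    aortic-sac end); the angular index starts at the inner-curvature anchor
    direction and runs counter-clockwise about the local tangent.
    """

    vertices: np.ndarray
    layer: str = "lumen"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 3 or self.vertices.shape[2] != 3:
            raise ValueError("vertices must have shape (n_rings, n_theta, 3)")

    @property
    def n_rings(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_theta(self) -> int:
        return self.vertices.shape[1]

    def ring_centroids(self) -> np.ndarray:
        return self.vertices.mean(axis=1)

    def ring_areas(self) -> np.ndarray:
        """Enclosed planar area of each ring polygon (m^2).

        Half the norm of the summed cross products about the ring centroid;
        exact for planar polygons, and degrades gracefully to ~0 for
        slit-collapsed rings.
        """
        c = self.ring_centroids()[:, None, :]
        r = self.vertices - c
        cross = np.cross(r, np.roll(r, -1, axis=1)).sum(axis=1)
        return 0.5 * np.linalg.norm(cross, axis=1)

    def ring_perimeters(self) -> np.ndarray:
        d = np.roll(self.vertices, -1, axis=1) - self.vertices
        return np.linalg.norm(d, axis=2).sum(axis=1)

    def to_trimesh(self) -> trimesh.Trimesh:
        """Triangulated open tube (two triangles per structured quad)."""
        nr, nt = self.n_rings, self.n_theta
        idx = np.arange(nr * nt).reshape(nr, nt)
        a = idx[:-1, :]
        b = np.roll(idx[:-1, :], -1, axis=1)
        c = np.roll(idx[1:, :], -1, axis=1)
        d = idx[1:, :]
        tri1 = np.stack([a, b, c], axis=-1).reshape(-1, 3)
        tri2 = np.stack([a, c, d], axis=-1).reshape(-1, 3)
        faces = np.vstack([tri1, tri2])
        return trimesh.Trimesh(
            vertices=self.vertices.reshape(-1, 3), faces=faces, process=False
        )

    def save_ply(self, path) -> None:
        self.to_trimesh().export(str(path))

    def translated(self, offset) -> "StructuredTubeSurface":
        return StructuredTubeSurface(self.vertices + np.asarray(offset), self.layer)

    def transformed(self, rotation: np.ndarray, offset=(0.0, 0.0, 0.0)) -> "StructuredTubeSurface":
        v = self.vertices @ np.asarray(rotation).T + np.asarray(offset)
        return StructuredTubeSurface(v, self.layer)


# ---------------------------------------------------------------------------
# centerline
# ---------------------------------------------------------------------------


@dataclass
class CenterlineCurve:
    """Polyline centerline with arclength parameterization and unit tangents."""

    points: np.ndarray
    arclength: np.ndarray = None
    tangents: np.ndarray = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.arclength is None:
            seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
            self.arclength = np.concatenate([[0.0], np.cumsum(seg)])
        if not np.all(np.diff(self.arclength) > 0):
            raise ValueError("centerline arclength must be strictly increasing")
        if self.tangents is None:
            t = np.gradient(self.points, self.arclength, axis=0)
            self.tangents = t / np.linalg.norm(t, axis=1, keepdims=True)

    @property
    def length(self) -> float:
        return float(self.arclength[-1])

    def point_at(self, s) -> np.ndarray:
        s = np.atleast_1d(np.asarray(s, dtype=float))
        out = np.column_stack(
            [np.interp(s, self.arclength, self.points[:, d]) for d in range(3)]
        )
        return out[0] if out.shape[0] == 1 else out

    def tangent_at(self, s) -> np.ndarray:
        s = np.atleast_1d(np.asarray(s, dtype=float))
        t = np.column_stack(
            [np.interp(s, self.arclength, self.tangents[:, d]) for d in range(3)]
        )
        t = t / np.linalg.norm(t, axis=1, keepdims=True)
        return t[0] if t.shape[0] == 1 else t

    def curvature(self) -> float:
        """Curvature (1/m) of the best-fit circular arc through the points.

        Points are projected onto their best-fit plane and a Kasa algebraic
        circle fit is applied.  Returns 0 for (numerically) straight lines.
        """
        p = self.points - self.points.mean(axis=0)
        _, sv, vt = np.linalg.svd(p, full_matrices=False)
        xy = p @ vt[:2].T
        # straight line: second singular value negligible
        if sv[1] < 1e-9 * max(sv[0], 1e-300):
            return 0.0
        amat = np.column_stack([2 * xy[:, 0], 2 * xy[:, 1], np.ones(len(xy))])
        rhs = (xy**2).sum(axis=1)
        sol, *_ = np.linalg.lstsq(amat, rhs, rcond=None)
        r2 = sol[2] + sol[0] ** 2 + sol[1] ** 2
        if r2 <= 0:
            return 0.0
        radius = float(np.sqrt(r2))
        if radius > 1e6 * max(self.length, 1e-300):
            return 0.0
        return 1.0 / radius

    def curvature_normal(self) -> np.ndarray:
        """Mean unit vector from the curve toward its center of curvature.

        Used as the angular anchor (theta = 0 points toward the inner
        curvature).  Falls back to an arbitrary normal for straight lines.
        """
        d2 = np.gradient(self.tangents, self.arclength, axis=0)
        mean_t = self.tangents.mean(axis=0)
        mean_t /= np.linalg.norm(mean_t)
        n = d2.mean(axis=0)
        n = n - (n @ mean_t) * mean_t
        norm = np.linalg.norm(n)
        if norm < 1e-12 / max(self.length, 1e-300):
            # straight tube: pick any direction orthogonal to the axis
            trial = np.array([0.0, 0.0, 1.0])
            if abs(trial @ mean_t) > 0.9:
                trial = np.array([0.0, 1.0, 0.0])
            n = trial - (trial @ mean_t) * mean_t
            norm = np.linalg.norm(n)
        return n / norm

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "s_m": self.arclength,
                "x_m": self.points[:, 0],
                "y_m": self.points[:, 1],
                "z_m": self.points[:, 2],
            }
        ).to_csv(path, index=False)


def _smooth_polyline(points: np.ndarray, window: int) -> np.ndarray:
    """Moving-average smoothing with reflected ends (keeps endpoints stable)."""
    if window <= 1:
        return points
    pad = window // 2
    padded = np.concatenate(
        [
            2 * points[:1] - points[pad:0:-1],
            points,
            2 * points[-1:] - points[-2 : -pad - 2 : -1],
        ]
    )
    kernel = np.ones(window) / window
    out = np.column_stack(
        [np.convolve(padded[:, d], kernel, mode="valid") for d in range(3)]
    )
    return out[: len(points)]


def compute_centerline(
    surface: StructuredTubeSurface, smooth_window: int = 5
) -> CenterlineCurve:
    """Centerline of a tube surface as the smoothed polyline of ring centroids.

    The reference frame for analysis is the surface of the *most contracted*
    phase (chosen by the caller), whose myocardial tube is always open.
    """
    centroids = surface.ring_centroids()
    if len(centroids) < 2:
        raise ValueError("need at least two rings to define a centerline")
    pts = _smooth_polyline(centroids, min(smooth_window, len(centroids)))
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(seg <= 0):
        raise ValueError("degenerate (self-intersecting) tube centerline")
    return CenterlineCurve(pts)


def clamped_tangents(
    centerline: CenterlineCurve, stations: np.ndarray, max_angle: float = 0.2
) -> np.ndarray:
    """Section-plane normals: centerline tangents with tilt-rate clamping.

    Successive plane normals are limited to ``max_angle`` radians of relative
    tilt so that planes cannot intersect inside the tube near regions of high
    centerline curvature.
    """
    t = np.atleast_2d(centerline.tangent_at(stations))
    out = t.copy()
    for i in range(1, len(out)):
        prev, cur = out[i - 1], out[i]
        cosang = np.clip(prev @ cur, -1.0, 1.0)
        ang = np.arccos(cosang)
        if ang > max_angle:
            # rotate prev toward cur by max_angle (slerp)
            axis_w = (cur - cosang * prev) / np.sin(ang)
            out[i] = np.cos(max_angle) * prev + np.sin(max_angle) * axis_w
        out[i] /= np.linalg.norm(out[i])
    return out


# ---------------------------------------------------------------------------
# plane sections
# ---------------------------------------------------------------------------


def _section_loops(mesh: trimesh.Trimesh, origin, normal):
    """Ordered closed section polylines from raw plane/triangle segments.

    Avoids path-graph vertex merging (whose absolute tolerances are coarse at
    the sub-millimetre scale of embryonic geometry): segment endpoints are
    matched after rounding to 1e-12 m, so the result is exactly equivariant
    under rigid motions of the mesh.
    """
    segments = trimesh.intersections.mesh_plane(
        mesh, plane_normal=normal, plane_origin=origin
    )
    if len(segments) == 0:
        return []
    def key(p):
        return tuple(np.round(p, 12))

    adj: dict = {}
    for si, seg in enumerate(segments):
        for end in range(2):
            adj.setdefault(key(seg[end]), []).append((si, end))
    used = np.zeros(len(segments), dtype=bool)
    loops = []
    for start in range(len(segments)):
        if used[start]:
            continue
        used[start] = True
        pts = [segments[start][0], segments[start][1]]
        while True:
            k = key(pts[-1])
            nxt = None
            for si, end in adj.get(k, ()):
                if not used[si]:
                    nxt = (si, end)
                    break
            if nxt is None:
                break
            si, end = nxt
            used[si] = True
            pts.append(segments[si][1 - end])
        if len(pts) >= 4 and key(pts[0]) == key(pts[-1]):
            loops.append(np.asarray(pts))
    return loops


def plane_section(mesh: trimesh.Trimesh, origin, normal):
    """Intersect a surface mesh with a plane; return (area, perimeter, loop).

    ``loop`` is the ordered (n, 3) closed polyline of the largest section
    loop, or ``None`` when the plane misses the surface or the section is
    degenerate (closed slit); in those cases area and perimeter are 0.
    """
    origin = np.asarray(origin, dtype=float)
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    try:
        loops = _section_loops(mesh, origin, normal)
    except Exception:
        return 0.0, 0.0, None
    best = (0.0, 0.0, None)
    for loop in loops:
        loop = np.asarray(loop, dtype=float)
        if len(loop) < 3:
            continue
        # basis in the plane
        e1 = np.array([1.0, 0.0, 0.0])
        if abs(e1 @ normal) > 0.9:
            e1 = np.array([0.0, 1.0, 0.0])
        e1 = e1 - (e1 @ normal) * normal
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(normal, e1)
        rel = loop - origin
        x, y = rel @ e1, rel @ e2
        area = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
        closed = np.allclose(loop[0], loop[-1])
        seg = np.diff(loop, axis=0)
        perim = float(np.linalg.norm(seg, axis=1).sum())
        if not closed:
            perim += float(np.linalg.norm(loop[-1] - loop[0]))
        if area > best[0]:
            best = (float(area), perim, loop)
    return best


def structured_plane_section(
    surface: StructuredTubeSurface, origin, normal, hint_ring: float | None = None
):
    """Section a *structured* tube with a plane; returns (area, perimeter, loop).

    Exploits the ring structure: for each angular index the axial polyline is
    intersected with the plane, yielding one contour point per angular index,
    already ordered.  Robust for slit-collapsed (near-degenerate) rings where
    generic mesh sectioning fails.  ``hint_ring`` disambiguates multiple
    crossings on strongly curved tubes (expected fractional ring index).
    Returns (0, 0, None) when the plane misses the tube.
    """
    origin = np.asarray(origin, dtype=float)
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    v = surface.vertices
    nr, nt = surface.n_rings, surface.n_theta
    d = (v - origin) @ normal  # (nr, nt) signed distances
    pts = np.empty((nt, 3))
    for k in range(nt):
        dk = d[:, k]
        sign_change = np.flatnonzero(dk[:-1] * dk[1:] <= 0)
        # drop repeated touch points (both endpoints zero handled once)
        if sign_change.size == 0:
            return 0.0, 0.0, None
        if hint_ring is not None and sign_change.size > 1:
            i = sign_change[np.argmin(np.abs(sign_change + 0.5 - hint_ring))]
        else:
            i = sign_change[0]
        denom = dk[i] - dk[i + 1]
        t = 0.5 if denom == 0 else dk[i] / denom
        pts[k] = v[i, k] + t * (v[i + 1, k] - v[i, k])
    rel = pts - pts.mean(axis=0)
    cross = np.cross(rel, np.roll(rel, -1, axis=0)).sum(axis=0)
    area = 0.5 * float(np.linalg.norm(cross))
    perim = float(np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1).sum())
    return area, perim, pts


def extract_cross_sections(
    lumen_frames,
    myo_frames,
    centerline: CenterlineCurve,
    n_sections: int = 5,
    times=None,
    period: float | None = None,
):
    """Per-section lumen/myocardium area & perimeter traces over the cycle.

    Sections are centered at ``n_sections`` evenly spaced interior points of
    the centerline (normalized stations (i+1)/(n_sections+1)), with section
    planes perpendicular to the (tilt-clamped) centerline tangent.  Planes
    that miss the tube in a frame are reported as zero-area, not an error.

    Returns a list of :class:`oftflow.wallmotion.CrossSectionTrace`.
    """
    from .wallmotion import CrossSectionTrace  # deferred: avoids module cycle

    n_frames = len(lumen_frames)
    if myo_frames is not None and len(myo_frames) != n_frames:
        raise ValueError("lumen and myocardium frame counts differ")
    if times is None:
        times = np.arange(n_frames, dtype=float)
    stations_norm = (np.arange(n_sections) + 1.0) / (n_sections + 1.0)
    stations = stations_norm * centerline.length
    normals = clamped_tangents(centerline, stations)
    origins = np.atleast_2d(centerline.point_at(stations))

    traces = []
    for i in range(n_sections):
        a_lum = np.zeros(n_frames)
        c_lum = np.zeros(n_frames)
        a_myo = np.zeros(n_frames)
        c_myo = np.zeros(n_frames)
        hint = stations_norm[i] * (lumen_frames[0].n_rings - 1)
        for j in range(n_frames):
            a_lum[j], c_lum[j], _ = structured_plane_section(
                lumen_frames[j], origins[i], normals[i], hint_ring=hint
            )
            if myo_frames is not None:
                a_myo[j], c_myo[j], _ = structured_plane_section(
                    myo_frames[j], origins[i], normals[i], hint_ring=hint
                )
        traces.append(
            CrossSectionTrace(
                section_id=i + 1,
                station=float(stations_norm[i]),
                time=np.asarray(times, dtype=float),
                lumen_area=a_lum,
                lumen_perimeter=c_lum,
                myocardium_area=a_myo,
                myocardium_perimeter=c_myo,
                period=period,
            )
        )
    return traces


# ---------------------------------------------------------------------------
# consistent parameterization
# ---------------------------------------------------------------------------


def _estimate_centerline_from_mesh(mesh: trimesh.Trimesh, n_slabs: int = 32) -> CenterlineCurve:
    """Rough centerline of a raw tube mesh: PCA axis + slab centroids."""
    v = np.asarray(mesh.vertices, dtype=float)
    c0 = v.mean(axis=0)
    _, _, vt = np.linalg.svd(v - c0, full_matrices=False)
    axis = vt[0]
    proj = (v - c0) @ axis
    edges = np.linspace(proj.min(), proj.max(), n_slabs + 1)
    pts = []
    for k in range(n_slabs):
        mask = (proj >= edges[k]) & (proj <= edges[k + 1])
        if mask.sum() >= 3:
            pts.append(v[mask].mean(axis=0))
    pts = np.asarray(pts)
    return CenterlineCurve(_smooth_polyline(pts, 5))


def _resample_loop_by_angle(
    loop: np.ndarray, centroid: np.ndarray, e1: np.ndarray, e2: np.ndarray, n_theta: int
) -> np.ndarray:
    """Resample a closed planar loop at uniform polar angles about its centroid.

    Assumes the contour is star-shaped with respect to its centroid, which
    holds for the lumen/myocardium shapes handled here (ellipse-like with
    moderate cushion indentation).
    """
    rel = loop - centroid
    ang = np.arctan2(rel @ e2, rel @ e1)
    rad = np.hypot(rel @ e1, rel @ e2)
    order = np.argsort(ang)
    ang, rad = ang[order], rad[order]
    # de-duplicate angles for interpolation
    keep = np.concatenate([[True], np.diff(ang) > 1e-12])
    ang, rad = ang[keep], rad[keep]
    ang_ext = np.concatenate([ang - 2 * np.pi, ang, ang + 2 * np.pi])
    rad_ext = np.concatenate([rad, rad, rad])
    targets = np.arange(n_theta) * 2 * np.pi / n_theta
    targets = np.where(targets > np.pi, targets - 2 * np.pi, targets)
    r_t = np.interp(targets, ang_ext, rad_ext)
    return centroid + r_t[:, None] * (
        np.cos(targets)[:, None] * e1 + np.sin(targets)[:, None] * e2
    )


def parameterize_consistent(
    frames,
    n_rings: int = 40,
    n_theta: int = 32,
    anchor: np.ndarray | None = None,
    layer: str | None = None,
    end_inset: float = 0.01,
):
    """Re-parameterize a tube-surface sequence into consistent structured form.

    Rings are placed at uniform arclength along each frame's centerline and
    each ring contour is resampled at uniform angles starting from a fixed
    material anchor direction (the inner-curvature direction of the first
    frame unless ``anchor`` is given).  All output frames share the same
    (n_rings, n_theta) connectivity, enabling ring-wise comparison over time.

    ``frames`` may contain :class:`StructuredTubeSurface` or open-tube
    ``trimesh.Trimesh`` objects (genus-0, two open ends).  ``end_inset`` is
    the fraction of tube length by which the first/last ring planes are inset
    from the open ends to guarantee clean plane sections.
    """
    out = []
    anchor_vec = None if anchor is None else np.asarray(anchor, dtype=float)
    for frame in frames:
        if isinstance(frame, StructuredTubeSurface):
            mesh = frame.to_trimesh()
            cl = compute_centerline(frame)
            if layer is None:
                layer_tag = frame.layer
            else:
                layer_tag = layer
        elif isinstance(frame, trimesh.Trimesh):
            mesh = frame
            cl = _estimate_centerline_from_mesh(mesh)
            layer_tag = layer or "lumen"
        else:
            raise TypeError("frames must be StructuredTubeSurface or trimesh.Trimesh")
        if anchor_vec is None:
            anchor_vec = cl.curvature_normal()

        stations = np.linspace(
            end_inset * cl.length, (1.0 - end_inset) * cl.length, n_rings
        )
        normals = clamped_tangents(cl, stations)
        origins = np.atleast_2d(cl.point_at(stations))
        verts = np.empty((n_rings, n_theta, 3))
        for i in range(n_rings):
            area, _, loop = plane_section(mesh, origins[i], normals[i])
            if loop is None and i in (0, n_rings - 1):
                # near an open end a tilted plane can exit through the rim;
                # nudge the end station inward until the section closes
                sign = 1.0 if i == 0 else -1.0
                s_try = stations[i]
                for _ in range(4):
                    s_try += sign * 0.015 * cl.length
                    origin = cl.point_at(s_try)
                    normal = clamped_tangents(cl, np.array([s_try]))[0]
                    area, _, loop = plane_section(mesh, origin, normal)
                    if loop is not None:
                        origins[i], normals[i] = origin, normal
                        break
            if loop is None:
                raise ValueError(
                    f"non-tubular topology: no section loop at station {i}"
                )
            centroid = loop[:-1].mean(axis=0) if np.allclose(loop[0], loop[-1]) else loop.mean(axis=0)
            n = normals[i]
            e1 = anchor_vec - (anchor_vec @ n) * n
            nrm = np.linalg.norm(e1)
            if nrm < 1e-12:
                raise ValueError("anchor direction parallel to tube axis")
            e1 /= nrm
            e2 = np.cross(n, e1)
            verts[i] = _resample_loop_by_angle(loop, centroid, e1, e2, n_theta)
        out.append(StructuredTubeSurface(verts, layer_tag))
    return out


# ---------------------------------------------------------------------------
# volume meshing
# ---------------------------------------------------------------------------


def _disk_template(n_theta: int, n_radial: int):
    """2D reference triangulation of the unit disk boundary layers.

    Local node 0 is the ring centroid; node 1 + (j-1)*n_theta + k sits at
    radial fraction j/n_radial toward boundary vertex k.  Returns
    (radial fractions per node paired with boundary index, triangles).
    """
    tris = []
    # center fan
    for k in range(n_theta):
        k2 = (k + 1) % n_theta
        tris.append((0, 1 + k, 1 + k2))
    # annular layers
    for j in range(1, n_radial):
        base_in = 1 + (j - 1) * n_theta
        base_out = 1 + j * n_theta
        for k in range(n_theta):
            k2 = (k + 1) % n_theta
            a, b = base_in + k, base_in + k2
            c, d = base_out + k, base_out + k2
            tris.append((a, c, d))
            tris.append((a, d, b))
    return np.asarray(tris, dtype=np.int64)


_PRISM_ROTATIONS = [
    (0, 1, 2, 3, 4, 5),
    (1, 2, 0, 4, 5, 3),
    (2, 0, 1, 5, 3, 4),
    (3, 5, 4, 0, 2, 1),
    (4, 3, 5, 1, 0, 2),
    (5, 4, 3, 2, 1, 0),
]


def _split_prisms(prisms: np.ndarray) -> np.ndarray:
    """Split triangular prisms into 3 tetrahedra each, conformally.

    Uses the minimum-global-index rule (Dompierre et al.): each lateral quad's
    diagonal passes through its smallest-index vertex, so adjacent prisms
    always agree on shared faces.
    """
    tets = np.empty((len(prisms) * 3, 4), dtype=np.int64)
    for idx, pr in enumerate(prisms):
        amin = int(np.argmin(pr))
        rot = _PRISM_ROTATIONS[amin]
        v = pr[list(rot)]
        if min(v[1], v[5]) < min(v[2], v[4]):
            local = [(0, 1, 2, 5), (0, 1, 5, 4), (0, 4, 5, 3)]
        else:
            local = [(0, 1, 2, 4), (0, 4, 2, 5), (0, 4, 5, 3)]
        for t, loc in enumerate(local):
            tets[idx * 3 + t] = v[list(loc)]
    return tets


@dataclass
class TubeVolumeMesh:
    """Structured tetrahedral mesh of an open tube lumen.

    Boundary triangles are tagged inlet (first ring plane), outlet (last ring
    plane) and wall (lumen surface).  ``wall_node_grid[i, k]`` gives the node
    id of surface vertex (ring i, angle k), enabling unwrapped wall maps.
    """

    nodes: np.ndarray
    tets: np.ndarray
    inlet_faces: np.ndarray
    outlet_faces: np.ndarray
    wall_faces: np.ndarray
    wall_node_grid: np.ndarray
    n_rings: int
    n_theta: int
    n_radial: int
    section_tris: np.ndarray  # local 2D template triangles (per-section)

    @property
    def nodes_per_section(self) -> int:
        return 1 + self.n_radial * self.n_theta

    def section_nodes(self, i: int) -> np.ndarray:
        nps = self.nodes_per_section
        return np.arange(i * nps, (i + 1) * nps)

    def section_triangles(self, i: int) -> np.ndarray:
        return self.section_tris + i * self.nodes_per_section

    def tet_volumes(self) -> np.ndarray:
        p = self.nodes[self.tets]
        d1 = p[:, 1] - p[:, 0]
        d2 = p[:, 2] - p[:, 0]
        d3 = p[:, 3] - p[:, 0]
        return np.einsum("ij,ij->i", np.cross(d1, d2), d3) / 6.0

    @property
    def total_volume(self) -> float:
        return float(np.abs(self.tet_volumes()).sum())

    def boundary_faces(self) -> np.ndarray:
        return np.vstack([self.inlet_faces, self.outlet_faces, self.wall_faces])

    def wall_nodes(self) -> np.ndarray:
        return np.unique(self.wall_node_grid)

    def save_vtk(self, path, point_data=None) -> None:
        from .io import write_vtk_unstructured

        write_vtk_unstructured(path, self.nodes, self.tets, point_data or {})


def build_volume_mesh(
    lumen: StructuredTubeSurface,
    n_radial: int = 6,
    min_area: float = np.pi * (10e-6) ** 2,
) -> TubeVolumeMesh:
    """Fill a structured open lumen surface with a structured tet mesh.

    Each ring cross-section is filled by a centroid node plus ``n_radial``
    radial layers interpolated linearly between centroid and surface
    vertices; the triangulated layers of consecutive rings are joined by
    prisms, each split conformally into 3 tetrahedra.

    Raises :class:`ClosedLumenError` when any ring area is below ``min_area``
    (default: the area of a 10 µm-radius circle, below which the lumen is
    treated as effectively closed and the frame excluded from CFD).
    """
    areas = lumen.ring_areas()
    if np.any(areas < min_area):
        raise ClosedLumenError(
            f"lumen closed or nearly closed (min ring area {areas.min():.3e} m^2)"
        )
    nr, nt = lumen.n_rings, lumen.n_theta
    centroids = lumen.ring_centroids()
    fractions = np.arange(1, n_radial + 1) / n_radial  # radial node fractions

    nps = 1 + n_radial * nt
    nodes = np.empty((nr * nps, 3))
    for i in range(nr):
        base = i * nps
        nodes[base] = centroids[i]
        rel = lumen.vertices[i] - centroids[i]
        for j, f in enumerate(fractions):
            nodes[base + 1 + j * nt : base + 1 + (j + 1) * nt] = centroids[i] + f * rel

    tris2d = _disk_template(nt, n_radial)
    n_tri = len(tris2d)
    # prisms between consecutive sections
    prisms = np.empty(((nr - 1) * n_tri, 6), dtype=np.int64)
    for i in range(nr - 1):
        lo = tris2d + i * nps
        hi = tris2d + (i + 1) * nps
        prisms[i * n_tri : (i + 1) * n_tri, :3] = lo
        prisms[i * n_tri : (i + 1) * n_tri, 3:] = hi
    tets = _split_prisms(prisms)

    # fix orientation (positive volumes) by swapping last two vertices
    p = nodes[tets]
    vol6 = np.einsum(
        "ij,ij->i", np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), p[:, 3] - p[:, 0]
    )
    neg = vol6 < 0
    tets[neg, 2], tets[neg, 3] = tets[neg, 3].copy(), tets[neg, 2].copy()
    if np.any(
        np.abs(vol6) < 1e-6 * np.median(np.abs(vol6))
    ):
        raise ClosedLumenError("degenerate cells: lumen too close to collapse")

    # boundary faces by face counting
    faces = np.vstack(
        [
            tets[:, [0, 1, 2]],
            tets[:, [0, 1, 3]],
            tets[:, [0, 2, 3]],
            tets[:, [1, 2, 3]],
        ]
    )
    key = np.sort(faces, axis=1)
    _, first_idx, counts = np.unique(
        key, axis=0, return_index=True, return_counts=True
    )
    bfaces = faces[first_idx[counts == 1]]
    # classify: all three nodes in first / last section
    sec = bfaces // nps
    on_inlet = np.all(sec == 0, axis=1)
    on_outlet = np.all(sec == nr - 1, axis=1)
    wall = ~(on_inlet | on_outlet)

    wall_grid = np.empty((nr, nt), dtype=np.int64)
    for i in range(nr):
        wall_grid[i] = i * nps + 1 + (n_radial - 1) * nt + np.arange(nt)

    return TubeVolumeMesh(
        nodes=nodes,
        tets=tets,
        inlet_faces=bfaces[on_inlet],
        outlet_faces=bfaces[on_outlet],
        wall_faces=bfaces[wall],
        wall_node_grid=wall_grid,
        n_rings=nr,
        n_theta=nt,
        n_radial=n_radial,
        section_tris=tris2d,
    )
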