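"""Synthetic 4D outflow-tract generator with known ground truth.

Emulates the segmented geometry of the HH18 chick heart outflow tract (OFT):
a curved, tapered tube whose wall performs a peristaltic-like contraction /
expansion cycle.  Two opposed endocardial cushions (thickenings of the
cardiac jelly at the inner- and outer-curvature sides) protrude into the
lumen during contraction, so each lumen cross-section morphs circular ->
elliptical -> slit and closes completely for part of the cycle, acting as a
primitive valve.  An optional band reproduces the outflow-tract banding
intervention: a localized circumferential constriction near the OFT inlet
with locally suppressed wall motion.

The generator is analytic: every emitted quantity (per-section areas,
perimeters, cushion gaps, closure windows, the pressure-drop schedule used
to synthesize Doppler data) is also provided as exact ground truth, so
downstream wall-motion and CFD analyses can be validated end to end.

Geometry scale follows HH18 (tube length ~0.8 mm, lumen radii 100-150 µm,
heart rate 2.5 Hz).  The centerline is a planar arc in the x-z plane; the
scene z-axis is the OCT beam direction, and the inlet tangent is tilted so
axial flow always has a beam-direction component at the probe.
All lengths in metres, times in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .doppler import DopplerAcquisition, DopplerTrace, velocity_to_phase
from .geometry import StructuredTubeSurface

__all__ = [
    "OftShapeParams",
    "MotionParams",
    "BandParams",
    "GroundTruth",
    "generate_motion",
    "generate_mmode",
    "synthesize_doppler",
]


@dataclass(frozen=True)
class OftShapeParams:
    """Static OFT shape: tapered arc tube with two opposed cushions."""

    inlet_radius: float = 150e-6
    outlet_radius: float = 100e-6
    tube_length: float = 800e-6
    centerline_curvature: float = 900.0  # 1/m, planar arc
    cushion_amplitude: float = 0.25  # fraction of local radius
    cushion_angular_width: float = 0.9  # rad, half-width of each bulge
    n_cushions: int = 2  # fixed: two opposed cushions
    jelly_thickness: float = 30e-6  # lumen -> inner myocardium gap at expansion
    base_tilt: float = 0.35  # rad, inlet tangent tilt toward the beam axis

    def __post_init__(self) -> None:
        if self.inlet_radius <= 0 or self.outlet_radius <= 0:
            raise ValueError("radii must be positive")
        if self.outlet_radius >= self.inlet_radius:
            raise ValueError("outlet_radius must be < inlet_radius (tapering)")
        if not 0 <= self.cushion_amplitude < 1:
            raise ValueError("cushion_amplitude must be in [0, 1)")
        if self.tube_length <= 0:
            raise ValueError("tube_length must be positive")
        if self.n_cushions != 2:
            raise ValueError("exactly two opposed cushions are modeled")


@dataclass(frozen=True)
class MotionParams:
    """Peristaltic wall-motion cycle.

    Local cycle phase at normalized station s is the global phase minus
    ``wave_phase_lag * s`` (fraction of a cycle), producing a contraction
    wave traveling proximal -> distal; set the lag to 0 for the synchronous
    pattern seen in some banded hearts.  Each section's lumen is closed (slit
    of exactly zero area, or of ``residual_gap`` when nonzero) for
    ``closure_fraction`` of its local cycle.  ``dp_peak`` is the amplitude of
    the pressure-drop pulse driving flow while the whole tube is open.
    """

    period_T: float = 0.4  # s (heart rate 2.5 Hz)
    closure_fraction: float = 0.4
    wave_phase_lag: float = 0.15
    expansion_amplitude: float = 1.0
    n_frames: int = 56  # T / 56 = 7.14 ms, the 140 frames/s cadence
    slit_axis_ratio: float = 0.35  # contraction fraction of the slit axis
    myocardial_amplitude: float = 0.2  # myocardium contraction vs lumen
    residual_gap: float = 0.0  # m; >0 mimics the 10 µm resolution floor
    #: numerical half-gap floor (m) keeping closed-slit meshes non-degenerate;
    #: nanometre scale, 4 orders below the closure threshold, so closed frames
    #: still read as area ~0 while plane sections of the slit stay well posed
    slit_floor: float = 1e-9
    dp_peak: float = 20.0  # Pa

    def __post_init__(self) -> None:
        if self.period_T <= 0:
            raise ValueError("period_T must be positive")
        if not 0 <= self.closure_fraction < 1:
            raise ValueError("closure_fraction must be in [0, 1)")
        if self.n_frames < 8:
            raise ValueError("need at least 8 frames per cycle")
        if not 0 <= self.expansion_amplitude <= 1:
            raise ValueError("expansion_amplitude must be in [0, 1]")


@dataclass(frozen=True)
class BandParams:
    """Localized constriction (suture) near the OFT inlet."""

    position: float = 0.2  # normalized centerline coordinate
    tightness: float = 0.6  # remaining radius fraction at the band
    band_width: float = 100e-6  # m, half-width of the raised-cosine envelope
    motion_suppression: float = 0.8  # local wall-motion reduction

    def __post_init__(self) -> None:
        if not 0 < self.tightness <= 1:
            raise ValueError("tightness must be in (0, 1]")
        if not 0 <= self.position <= 1:
            raise ValueError("band position must be inside [0, 1]")
        if not 0 <= self.motion_suppression <= 1:
            raise ValueError("motion_suppression must be in [0, 1]")
        if self.band_width <= 0:
            raise ValueError("band_width must be positive")


@dataclass
class GroundTruth:
    """Prescribed quantities backing a generated sequence.

    All per-section arrays are evaluated at the 5 analysis stations
    (normalized centerline coordinates (i+1)/6) from the same analytic
    contours that produced the meshes, sampled at high angular resolution.
    """

    stations: np.ndarray  # (n_sections,)
    times: np.ndarray  # (n_frames,)
    period: float
    lumen_area: np.ndarray  # (n_sections, n_frames) m^2
    lumen_perimeter: np.ndarray
    myo_area: np.ndarray
    myo_perimeter: np.ndarray
    gap: np.ndarray  # cushion gap width (n_sections, n_frames) m
    closed: np.ndarray  # bool (n_sections, n_frames)
    closure_windows: list  # per section: (u_start, u_end) or None
    ring_areas_lumen: np.ndarray  # (n_rings, n_frames)
    ring_areas_myo: np.ndarray
    dp: np.ndarray  # (n_frames,) Pa
    no_flow: np.ndarray  # bool (n_frames,)
    probe_point: np.ndarray  # (3,)
    shape: OftShapeParams = None
    motion: MotionParams = None
    band: BandParams | None = None

    @property
    def total_closure_fraction(self) -> float:
        """Continuum union-closure fraction over the 5 analysis sections."""
        windows = [w for w in self.closure_windows if w is not None]
        if not windows:
            return 0.0
        grid = np.linspace(0.0, 1.0, 20001)[:-1]
        union = np.zeros(grid.size, dtype=bool)
        for u0, u1 in windows:
            union |= ((grid - u0) % 1.0) < (u1 - u0)
        return float(union.mean())

    def asf_lumen(self, section: int) -> float:
        a = self.lumen_area[section]
        return float((a.max() - a.min()) / a.max())

    def centerline(self, n_points: int = 200):
        """The exact generator centerline as a :class:`CenterlineCurve`.

        Useful for separating cross-section extraction error from centerline
        estimation error in validation studies.
        """
        from .geometry import CenterlineCurve

        model = _OftModel(self.shape, self.motion, self.band)
        s = np.linspace(0.0, self.shape.tube_length, n_points)
        return CenterlineCurve(model.centerline_point(s))

    def closed_fraction_at_threshold(
        self, section: int, gap_threshold: float, n_grid: int = 20000
    ) -> float:
        """Closed-time fraction a gap-resolution-limited instrument observes.

        The geometric closure window lasts ``closure_fraction`` of the local
        cycle, but any instrument with finite axial resolution also reads the
        sub-threshold approach/separation as closed; this evaluates the
        analytic cushion gap on a fine cycle grid and returns the fraction of
        time it is at or below ``gap_threshold``.
        """
        from . import synth as _synth  # self-module, for _OftModel

        model = _synth._OftModel(self.shape, self.motion, self.band)
        s = float(self.stations[section]) * self.shape.tube_length
        tt = np.linspace(0.0, self.period, n_grid, endpoint=False)
        gaps = np.array([model.gap_width(s, t) for t in tt])
        return float(np.mean(gaps <= gap_threshold))


class _OftModel:
    """Analytic kinematic model shared by mesh emission and ground truth."""

    def __init__(self, shape: OftShapeParams, motion: MotionParams, band):
        self.shape = shape
        self.motion = motion
        self.band = band

    # --- centerline frame -------------------------------------------------
    def centerline_point(self, s):
        sh = self.shape
        k = sh.centerline_curvature
        a0 = sh.base_tilt
        s = np.asarray(s, dtype=float)
        if abs(k) < 1e-9:
            return np.stack(
                [np.cos(a0) * s, np.zeros_like(s), np.sin(a0) * s], axis=-1
            )
        a = a0 + k * s
        return np.stack(
            [(np.sin(a) - np.sin(a0)) / k, np.zeros_like(s), -(np.cos(a) - np.cos(a0)) / k],
            axis=-1,
        )

    def frame_vectors(self, s):
        """(tangent, inner-curvature normal, binormal) at arclength s."""
        sh = self.shape
        a = sh.base_tilt + sh.centerline_curvature * np.asarray(s, dtype=float)
        tangent = np.stack([np.cos(a), np.zeros_like(a), np.sin(a)], axis=-1)
        normal = np.stack([-np.sin(a), np.zeros_like(a), np.cos(a)], axis=-1)
        binormal = np.broadcast_to(
            np.array([0.0, -1.0, 0.0]), tangent.shape
        ).copy()
        return tangent, normal, binormal

    # --- local modulation -------------------------------------------------
    def base_radius(self, s):
        sh = self.shape
        frac = np.asarray(s, dtype=float) / sh.tube_length
        return sh.inlet_radius + (sh.outlet_radius - sh.inlet_radius) * frac

    def band_envelope(self, s):
        if self.band is None:
            return np.zeros_like(np.asarray(s, dtype=float))
        s = np.asarray(s, dtype=float)
        sb = self.band.position * self.shape.tube_length
        w = self.band.band_width
        x = (s - sb) / w
        env = np.where(np.abs(x) < 1.0, np.cos(0.5 * np.pi * x) ** 2, 0.0)
        return env

    def local_radius_scale(self, s):
        if self.band is None:
            return np.ones_like(np.asarray(s, dtype=float))
        return 1.0 - (1.0 - self.band.tightness) * self.band_envelope(s)

    def local_amplitude(self, s):
        amp = self.motion.expansion_amplitude
        if self.band is None:
            return np.full_like(np.asarray(s, dtype=float), amp)
        return amp * (1.0 - self.band.motion_suppression * self.band_envelope(s))

    def local_phase(self, s, t):
        u = t / self.motion.period_T - self.motion.wave_phase_lag * (
            np.asarray(s, dtype=float) / self.shape.tube_length
        )
        return u % 1.0

    def openness(self, u):
        """(h_slit_axis, h_smooth): openness profiles on the local cycle.

        During the closed window both are 0; while open, the cushion
        apposition axis follows |sin| (linear approach to contact) and all
        smooth quantities follow sin^2.
        """
        u = np.asarray(u, dtype=float)
        zeta = self.motion.closure_fraction
        x = np.clip((u - zeta) / (1.0 - zeta), 0.0, 1.0)
        open_mask = u >= zeta
        h_a = np.where(open_mask, np.sin(np.pi * x), 0.0)
        h_b = np.where(open_mask, np.sin(np.pi * x) ** 2, 0.0)
        return h_a, h_b

    def lumen_axes(self, s, t):
        """Semi-axes (a: cushion apposition, b: slit axis) of the lumen."""
        r0 = self.base_radius(s) * self.local_radius_scale(s)
        amp = self.local_amplitude(s)
        h_a, h_b = self.openness(self.local_phase(s, t))
        a = r0 * (1.0 - amp * (1.0 - h_a))
        b = r0 * (1.0 - amp * self.motion.slit_axis_ratio * (1.0 - h_b))
        floor = max(0.5 * self.motion.residual_gap, self.motion.slit_floor)
        a = np.maximum(a, floor)
        return a, b, h_b

    def cushion_factor(self, theta, h_b, amp_loc=1.0):
        """Radial indentation of the two opposed cushions, in (0, 1].

        Grows during contraction in proportion to the local wall-motion
        amplitude, so a motionless (or band-suppressed) wall also has static
        cushions.
        """
        sh = self.shape
        w = sh.cushion_angular_width
        th = np.mod(np.asarray(theta, dtype=float) + np.pi / 2, np.pi) - np.pi / 2
        bump = np.where(np.abs(th) < w, np.cos(0.5 * np.pi * th / w) ** 2, 0.0)
        return 1.0 - sh.cushion_amplitude * amp_loc * (1.0 - h_b) * bump

    def lumen_contour_local(self, s, t, thetas):
        """(x, y) lumen contour in the (normal, binormal) ring plane."""
        a, b, h_b = self.lumen_axes(s, t)
        fc = self.cushion_factor(thetas, h_b, self.local_amplitude(s))
        x = fc * a * np.cos(thetas)
        y = fc * b * np.sin(thetas)
        return x, y

    def myo_contour_local(self, s, t, thetas):
        """Inner myocardium contour: near-circular, mildly contracting."""
        r0 = (self.base_radius(s) + self.shape.jelly_thickness) * self.local_radius_scale(s)
        amp = self.local_amplitude(s) * self.motion.myocardial_amplitude
        _, h_b = self.openness(self.local_phase(s, t))
        r = r0 * (1.0 - amp * (1.0 - h_b))
        return r * np.cos(thetas), r * np.sin(thetas)

    def contour_points(self, s, t, thetas, layer="lumen"):
        """3D contour points at arclength s, time t."""
        if layer == "lumen":
            x, y = self.lumen_contour_local(s, t, thetas)
        else:
            x, y = self.myo_contour_local(s, t, thetas)
        c = self.centerline_point(s)
        _, n, bvec = self.frame_vectors(s)
        return c + x[:, None] * n + y[:, None] * bvec

    def gap_width(self, s, t):
        """Cushion gap: lumen extent along the apposition axis (theta 0-pi)."""
        a, _, h_b = self.lumen_axes(s, t)
        fc0 = self.cushion_factor(0.0, h_b, self.local_amplitude(s))
        return 2.0 * float(a) * float(fc0)

    def dp_schedule(self, t):
        """Pressure-drop pulse: nonzero only while the whole tube is open."""
        m = self.motion
        u = (np.asarray(t, dtype=float) / m.period_T) % 1.0
        u0 = m.closure_fraction + m.wave_phase_lag
        w = 1.0 - u0
        if w <= 0:
            return np.zeros_like(u)
        x = (u - u0) / w
        return np.where((x >= 0) & (x < 1), m.dp_peak * np.sin(np.pi * x) ** 2, 0.0)

    def no_flow(self, t):
        m = self.motion
        u = (np.asarray(t, dtype=float) / m.period_T) % 1.0
        return u < (m.closure_fraction + m.wave_phase_lag)


def _polygon_area_perimeter(x: np.ndarray, y: np.ndarray):
    area = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    perim = float(
        np.sum(np.hypot(np.roll(x, -1) - x, np.roll(y, -1) - y))
    )
    return float(area), perim


def generate_motion(
    shape: OftShapeParams | None = None,
    motion: MotionParams | None = None,
    band: BandParams | None = None,
    seed: int = 0,
    n_rings: int = 40,
    n_theta: int = 32,
    n_sections: int = 5,
    jitter: float = 0.0,
    times: np.ndarray | None = None,
    gt_angular_resolution: int = 512,
):
    """Generate one synthetic cardiac cycle of OFT surfaces plus ground truth.

    Returns ``(lumen_frames, myo_frames, ground_truth)``; frames are
    :class:`StructuredTubeSurface` sequences with identical connectivity.
    Frames sample times ``j * T / n_frames`` (the acquisition cadence), and
    the underlying motion is exactly T-periodic.

    ``jitter`` adds seeded relative variation (uniform ±jitter) to radii,
    length, curvature and dp_peak, emulating inter-embryo variation; with
    the default ``jitter=0`` the output is fully deterministic.
    """
    shape = shape or OftShapeParams()
    motion = motion or MotionParams()
    if jitter > 0:
        rng = np.random.default_rng(seed)

        def jit():
            return 1.0 + jitter * rng.uniform(-1.0, 1.0)

        shape = replace(
            shape,
            inlet_radius=shape.inlet_radius * jit(),
            outlet_radius=shape.outlet_radius * jit(),
            tube_length=shape.tube_length * jit(),
            centerline_curvature=shape.centerline_curvature * jit(),
        )
        if shape.outlet_radius >= shape.inlet_radius:  # keep the taper invariant
            shape = replace(shape, outlet_radius=0.95 * shape.inlet_radius)
        motion = replace(motion, dp_peak=motion.dp_peak * jit())

    model = _OftModel(shape, motion, band)
    if times is None:
        times = np.arange(motion.n_frames) * motion.period_T / motion.n_frames
    times = np.asarray(times, dtype=float)
    n_frames = times.size

    s_rings = np.linspace(0.0, shape.tube_length, n_rings)
    thetas = np.arange(n_theta) * 2.0 * np.pi / n_theta

    lumen_frames, myo_frames = [], []
    for t in times:
        lum = np.empty((n_rings, n_theta, 3))
        myo = np.empty((n_rings, n_theta, 3))
        for i, s in enumerate(s_rings):
            lum[i] = model.contour_points(s, t, thetas, "lumen")
            myo[i] = model.contour_points(s, t, thetas, "myocardium")
        lumen_frames.append(StructuredTubeSurface(lum, "lumen"))
        myo_frames.append(StructuredTubeSurface(myo, "myocardium"))

    # ground truth at analysis stations, fine angular sampling
    stations = (np.arange(n_sections) + 1.0) / (n_sections + 1.0)
    th_fine = np.arange(gt_angular_resolution) * 2.0 * np.pi / gt_angular_resolution
    ns = len(stations)
    la = np.zeros((ns, n_frames))
    lp = np.zeros((ns, n_frames))
    ma = np.zeros((ns, n_frames))
    mp = np.zeros((ns, n_frames))
    gap = np.zeros((ns, n_frames))
    closed = np.zeros((ns, n_frames), dtype=bool)
    windows = []
    zeta = motion.closure_fraction
    for i, sn in enumerate(stations):
        s = sn * shape.tube_length
        amp_loc = float(model.local_amplitude(s))
        fully_closes = amp_loc >= 1.0 - 1e-12 and motion.residual_gap == 0.0
        if fully_closes and zeta > 0:
            u0 = (motion.wave_phase_lag * sn) % 1.0
            windows.append((u0, u0 + zeta))
        else:
            windows.append(None)
        for j, t in enumerate(times):
            x, y = model.lumen_contour_local(s, t, th_fine)
            la[i, j], lp[i, j] = _polygon_area_perimeter(x, y)
            x, y = model.myo_contour_local(s, t, th_fine)
            ma[i, j], mp[i, j] = _polygon_area_perimeter(x, y)
            gap[i, j] = model.gap_width(s, t)
            u_loc = float(model.local_phase(s, t))
            closed[i, j] = fully_closes and u_loc < zeta

    ring_a_lum = np.zeros((n_rings, n_frames))
    ring_a_myo = np.zeros((n_rings, n_frames))
    for i, s in enumerate(s_rings):
        for j, t in enumerate(times):
            x, y = model.lumen_contour_local(s, t, thetas)
            ring_a_lum[i, j], _ = _polygon_area_perimeter(x, y)
            x, y = model.myo_contour_local(s, t, thetas)
            ring_a_myo[i, j], _ = _polygon_area_perimeter(x, y)

    probe = model.centerline_point(0.5 * shape.tube_length)
    gt = GroundTruth(
        stations=stations,
        times=times,
        period=motion.period_T,
        lumen_area=la,
        lumen_perimeter=lp,
        myo_area=ma,
        myo_perimeter=mp,
        gap=gap,
        closed=closed,
        closure_windows=windows,
        ring_areas_lumen=ring_a_lum,
        ring_areas_myo=ring_a_myo,
        dp=np.asarray(model.dp_schedule(times), dtype=float),
        no_flow=np.asarray(model.no_flow(times), dtype=bool),
        probe_point=np.asarray(probe, dtype=float),
        shape=shape,
        motion=motion,
        band=band,
    )
    return lumen_frames, myo_frames, gt


# ---------------------------------------------------------------------------
# M-mode extraction
# ---------------------------------------------------------------------------


def generate_mmode(
    frames,
    station: float = 0.5,
    line=None,
    times=None,
    period: float | None = None,
):
    """Extract an M-mode gap trace along a line through the cushions.

    ``frames`` is a lumen surface sequence.  By default the scan line runs
    along the cushion apposition axis (the inner-curvature anchor direction)
    in the cross-section plane at the normalized ``station``; pass
    ``line=(point, direction)`` for an explicit probe line.  The gap is the
    chord length of the lumen section along that line; it is 0 while the
    lumen is closed there.

    Raises if the line misses the lumen in every frame.
    """
    import shapely.geometry as sg

    from .geometry import compute_centerline, structured_plane_section

    n_frames = len(frames)
    if times is None:
        times = np.arange(n_frames, dtype=float)

    # reference geometry: most expanded frame has a well-defined open tube
    areas_tot = [f.ring_areas().sum() for f in frames]
    ref = frames[int(np.argmax(areas_tot))]
    cl = compute_centerline(ref)
    if line is None:
        s = station * cl.length
        origin = cl.point_at(s)
        normal = cl.tangent_at(s)
        direction = cl.curvature_normal()
        direction = direction - (direction @ normal) * normal
        direction /= np.linalg.norm(direction)
    else:
        origin, direction = (np.asarray(v, dtype=float) for v in line)
        direction = direction / np.linalg.norm(direction)
        s = float(
            np.clip(
                cl.arclength[np.argmin(np.linalg.norm(cl.points - origin, axis=1))],
                0.0,
                cl.length,
            )
        )
        normal = cl.tangent_at(s)

    e1 = direction
    e2 = np.cross(normal, e1)
    gaps = np.zeros(n_frames)
    extent = 10.0 * max(np.linalg.norm(ref.vertices - origin, axis=-1).max(), 1e-6)
    scan = sg.LineString([(-extent, 0.0), (extent, 0.0)])
    hint = station * (frames[0].n_rings - 1)
    for j, frame in enumerate(frames):
        _, _, loop = structured_plane_section(frame, origin, normal, hint_ring=hint)
        if loop is None:
            gaps[j] = 0.0
            continue
        rel = loop - origin
        poly = sg.Polygon(np.column_stack([rel @ e1, rel @ e2]))
        if not poly.is_valid:
            poly = poly.buffer(0.0)
        if poly.is_empty or poly.area <= 0:
            gaps[j] = 0.0
            continue
        gaps[j] = float(poly.intersection(scan).length)
    if np.all(gaps == 0.0):
        raise ValueError("M-mode line misses the lumen in every frame")

    from .wallmotion import MModeTrace

    return MModeTrace(time=np.asarray(times, dtype=float), gap=gaps, period=period, station=station)


# ---------------------------------------------------------------------------
# Doppler synthesis
# ---------------------------------------------------------------------------


def synthesize_doppler(
    lumen_frames,
    dp_schedule,
    probe,
    times,
    acq: DopplerAcquisition | None = None,
    fluid=None,
    beam=None,
    n_radial: int = 5,
    min_area: float | None = None,
    phase_noise_sd: float = 0.0,
    seed: int = 0,
) -> DopplerTrace:
    """Synthesize a wrapped Doppler probe trace from a prescribed dp schedule.

    For each frame with nonzero pressure drop, the quasi-steady flow is
    solved on that frame's lumen, the velocity at the probe point projected
    onto the beam direction (scene vertical), and the resulting velocity
    encoded as a phase wrapped into (-pi, pi] — reproducing the
    single-component and wrapping limitations of Doppler OCT.  Closed-lumen
    frames are flagged no-flow.  Optional Gaussian phase noise (sd in
    radians) emulates measurement noise.
    """
    from .hemo import (
        BEAM_DIRECTION,
        FlowBoundaryCondition,
        FluidProperties,
        solve_quasi_steady,
    )
    from .geometry import ClosedLumenError, build_volume_mesh

    acq = acq or DopplerAcquisition()
    fluid = fluid or FluidProperties()
    beam_vec = BEAM_DIRECTION if beam is None else np.asarray(beam, dtype=float)
    beam_vec = beam_vec / np.linalg.norm(beam_vec)
    dp_schedule = np.asarray(dp_schedule, dtype=float)
    times = np.asarray(times, dtype=float)
    n = len(lumen_frames)
    if dp_schedule.size != n or times.size != n:
        raise ValueError("dp schedule, times and frames must be aligned")

    vz = np.zeros(n)
    no_flow = np.zeros(n, dtype=bool)
    kwargs = {} if min_area is None else {"min_area": min_area}
    for j in range(n):
        try:
            mesh = build_volume_mesh(lumen_frames[j], n_radial=n_radial, **kwargs)
        except ClosedLumenError:
            no_flow[j] = True
            continue
        if dp_schedule[j] == 0.0:
            continue
        sol = solve_quasi_steady(mesh, FlowBoundaryCondition(1.0), fluid)
        v_probe = sol.velocity_at(probe)  # raises if probe outside open lumen
        vz[j] = float(v_probe @ beam_vec) * dp_schedule[j]

    phase, wraps = velocity_to_phase(vz, acq)
    phase = np.atleast_1d(phase)
    wraps = np.atleast_1d(wraps)
    if phase_noise_sd > 0:
        rng = np.random.default_rng(seed)
        phase = phase + rng.normal(0.0, phase_noise_sd, size=phase.shape)
        phase = np.mod(phase + np.pi, 2.0 * np.pi) - np.pi
    measured_vz = np.asarray(
        phase * acq.wavelength_lambda
        / (4.0 * np.pi * acq.refractive_index_n * acq.line_interval_tau)
    )
    return DopplerTrace(
        time=times,
        phase_shift=phase,
        vz=measured_vz,
        acquisition=acq,
        no_flow=no_flow,
        wrapped=wraps != 0,
    )
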