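"""Doppler OCT phase-shift <-> velocity conversion with phase-wrap handling.

Doppler OCT measures, for every pixel, the phase shift ``delta_phi`` between
successive line scans.  The beam-direction (vertical) velocity component
follows from

    Vz = lambda * delta_phi / (4 * pi * n * tau)

where ``lambda`` is the source central wavelength, ``n`` the refractive index
of the medium and ``tau`` the inter-line-scan interval.  Because the measured
phase lives on the principal interval (-pi, pi], velocities of magnitude
beyond ``lambda / (4 n tau)`` alias (wrap) with a sign flip; this module
provides the forward conversion, the wrapping inverse used by the synthetic
generator, and temporal unwrapping of time-ordered traces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "DopplerAcquisition",
    "DopplerTrace",
    "phase_to_velocity",
    "velocity_to_phase",
    "unwrap_trace",
]


@dataclass(frozen=True)
class DopplerAcquisition:
    """Doppler OCT acquisition constants.

    Parameters
    ----------
    wavelength_lambda : float
        Central wavelength of the OCT source, in metres.
    refractive_index_n : float
        Refractive index of the imaged medium (dimensionless).
    line_interval_tau : float
        Time between two adjacent line scans (1 / A-scan rate), in seconds.
    """

    wavelength_lambda: float = 1310e-9
    refractive_index_n: float = 1.35
    line_interval_tau: float = 21e-6

    def __post_init__(self) -> None:
        for name in ("wavelength_lambda", "refractive_index_n", "line_interval_tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def aliasing_velocity(self) -> float:
        """Largest unambiguous |Vz| in m/s: lambda / (4 n tau).

        A phase of +/- pi maps to +/- this velocity; one full 2*pi wrap
        corresponds to twice this value.
        """
        return self.wavelength_lambda / (
            4.0 * self.refractive_index_n * self.line_interval_tau
        )


@dataclass
class DopplerTrace:
    """Time series of probe-point Doppler data.

    ``phase_shift`` is the (possibly wrapped) phase in (-pi, pi]; ``vz`` is the
    beam-direction velocity in m/s implied by that phase.  ``no_flow`` flags
    frames where the lumen was closed at the probe.  ``wrapped`` marks frames
    whose true velocity exceeded the aliasing velocity at synthesis time (set
    by the generator; unknown, hence False, for measured data).
    """

    time: np.ndarray
    phase_shift: np.ndarray
    vz: np.ndarray
    acquisition: DopplerAcquisition = field(default_factory=DopplerAcquisition)
    no_flow: np.ndarray | None = None
    wrapped: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.phase_shift = np.asarray(self.phase_shift, dtype=float)
        self.vz = np.asarray(self.vz, dtype=float)
        n = self.time.size
        if self.phase_shift.size != n or self.vz.size != n:
            raise ValueError("time, phase_shift and vz must have equal length")
        if self.no_flow is None:
            self.no_flow = np.zeros(n, dtype=bool)
        if self.wrapped is None:
            self.wrapped = np.zeros(n, dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "phase_shift_rad": self.phase_shift,
                "vz_m_per_s": self.vz,
                "no_flow": self.no_flow.astype(int),
                "wrapped": self.wrapped.astype(int),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, acquisition: DopplerAcquisition | None = None) -> "DopplerTrace":
        df = pd.read_csv(path)
        return cls(
            time=df["time_s"].to_numpy(),
            phase_shift=df["phase_shift_rad"].to_numpy(),
            vz=df["vz_m_per_s"].to_numpy(),
            acquisition=acquisition or DopplerAcquisition(),
            no_flow=df["no_flow"].to_numpy().astype(bool),
            wrapped=df["wrapped"].to_numpy().astype(bool),
        )


def phase_to_velocity(delta_phi, acq: DopplerAcquisition | None = None):
    """Convert an OCT phase shift (radians) to beam-direction velocity (m/s).

    Linear and odd in ``delta_phi``; a phase of pi maps to the aliasing
    velocity lambda / (4 n tau).
    """
    acq = acq or DopplerAcquisition()
    delta_phi = np.asarray(delta_phi, dtype=float)
    out = (
        acq.wavelength_lambda
        * delta_phi
        / (4.0 * np.pi * acq.refractive_index_n * acq.line_interval_tau)
    )
    return out if out.ndim else float(out)


def velocity_to_phase(vz, acq: DopplerAcquisition | None = None):
    """Convert velocity (m/s) to a wrapped phase in (-pi, pi] plus wrap count.

    Returns ``(phase, wraps)`` with ``phase + 2*pi*wraps`` the unwrapped phase,
    so ``phase_to_velocity(phase + 2*pi*wraps) == vz`` exactly.
    """
    acq = acq or DopplerAcquisition()
    vz = np.asarray(vz, dtype=float)
    true_phase = (
        4.0 * np.pi * acq.refractive_index_n * acq.line_interval_tau * vz
    ) / acq.wavelength_lambda
    # wrap into (-pi, pi]: shift so the boundary +pi maps to itself
    wraps = np.floor((np.pi - true_phase) / (2.0 * np.pi))
    phase = true_phase + 2.0 * np.pi * wraps
    wraps = -wraps
    if phase.ndim:
        return phase, wraps.astype(int)
    return float(phase), int(wraps)


def unwrap_trace(trace: DopplerTrace, jump_warn_fraction: float = 0.75) -> DopplerTrace:
    """Temporally unwrap a time-ordered Doppler trace.

    Successive phase jumps larger than pi are corrected by the nearest
    multiple of 2*pi (numpy.unwrap).  Idempotent on already-unwrapped traces.
    Frames flagged ``no_flow`` are pinned to zero phase and excluded from the
    jump accumulation so a closed-lumen gap cannot seed a spurious offset.

    Warns when any corrected inter-frame jump exceeds ``jump_warn_fraction``
    of pi: at that point the sampling is too sparse for the nearest-multiple
    correction to be unambiguous.
    """
    phase = trace.phase_shift.copy()
    open_idx = np.flatnonzero(~trace.no_flow)
    if open_idx.size:
        # unwrap contiguous open runs independently; closed gaps reset phase
        runs = np.split(open_idx, np.flatnonzero(np.diff(open_idx) > 1) + 1)
        for run in runs:
            seg = np.unwrap(phase[run])
            resid = np.abs(np.diff(seg))
            if resid.size and resid.max() > jump_warn_fraction * np.pi:
                warnings.warn(
                    "large inter-frame phase jump after unwrapping; sampling may "
                    "be too sparse to resolve wrap ambiguity",
                    stacklevel=2,
                )
            phase[run] = seg
    phase[trace.no_flow] = 0.0
    vz = phase_to_velocity(phase, trace.acquisition)
    return replace(
        trace,
        phase_shift=phase,
        vz=np.asarray(vz, dtype=float),
        no_flow=trace.no_flow.copy(),
        wrapped=np.zeros_like(trace.no_flow),
    )
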