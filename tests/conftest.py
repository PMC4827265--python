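"""Shared fixtures: analytic shapes and small, fast synthetic sequences."""

from __future__ import annotations

import numpy as np
import pytest

import oftflow as of


def cylinder_surface(radius=120e-6, length=600e-6, n_rings=25, n_theta=32, axis="x"):
    """Structured straight circular cylinder along +x."""
    s = np.linspace(0.0, length, n_rings)
    th = np.arange(n_theta) * 2 * np.pi / n_theta
    v = np.zeros((n_rings, n_theta, 3))
    v[:, :, 0] = s[:, None]
    v[:, :, 1] = radius * np.cos(th)[None, :]
    v[:, :, 2] = radius * np.sin(th)[None, :]
    return of.StructuredTubeSurface(v)


def tapered_surface(r_in=150e-6, r_out=100e-6, length=800e-6, n_rings=25, n_theta=32):
    s = np.linspace(0.0, length, n_rings)
    radii = r_in + (r_out - r_in) * s / length
    th = np.arange(n_theta) * 2 * np.pi / n_theta
    v = np.zeros((n_rings, n_theta, 3))
    v[:, :, 0] = s[:, None]
    v[:, :, 1] = radii[:, None] * np.cos(th)[None, :]
    v[:, :, 2] = radii[:, None] * np.sin(th)[None, :]
    return of.StructuredTubeSurface(v)


#: Generator settings for wall-motion tests: default axial resolution (the
#: band envelope needs ~20 µm ring spacing) with a lighter angular grid.
FAST_KW = dict(n_rings=40, n_theta=24)

#: Coarser settings for the CFD cycle fixtures, where each frame is a solve.
CFD_KW = dict(n_rings=20, n_theta=24)


def fast_motion(**over):
    base = dict(n_frames=32)
    base.update(over)
    return of.MotionParams(**base)


@pytest.fixture(scope="session")
def normal_sequence():
    """Default-scale normal embryo at reduced resolution (session-cached)."""
    lumen, myo, gt = of.generate_motion(motion=fast_motion(), **FAST_KW)
    return lumen, myo, gt


@pytest.fixture(scope="session")
def banded_sequence():
    lumen, myo, gt = of.generate_motion(
        motion=fast_motion(), band=of.BandParams(), **FAST_KW
    )
    return lumen, myo, gt


@pytest.fixture(scope="session")
def normal_cycle():
    """Doppler synthesis + quasi-steady cycle simulation, session-cached."""
    lumen, _, gt = of.generate_motion(motion=fast_motion(), **CFD_KW)
    trace = of.synthesize_doppler(lumen, gt.dp, gt.probe_point, gt.times, n_radial=4)
    sim = of.simulate_cycle(lumen, trace, gt.probe_point, n_radial=4)
    return lumen, gt, trace, sim


@pytest.fixture(scope="session")
def banded_cycle():
    lumen, _, gt = of.generate_motion(
        motion=fast_motion(), band=of.BandParams(), **CFD_KW
    )
    trace = of.synthesize_doppler(lumen, gt.dp, gt.probe_point, gt.times, n_radial=4)
    sim = of.simulate_cycle(lumen, trace, gt.probe_point, n_radial=4)
    return lumen, gt, trace, sim


@pytest.fixture(scope="session")
def normal_traces(normal_sequence):
    lumen, myo, gt = normal_sequence
    cl = of.compute_centerline(myo[int(np.argmin([f.ring_areas().sum() for f in lumen]))])
    return of.extract_cross_sections(lumen, myo, cl, times=gt.times, period=gt.period)
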