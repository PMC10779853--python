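"""Shared fixtures: preset phantoms run once per session through the full
pipeline, reused across the unit suites."""

from __future__ import annotations

import numpy as np
import pytest

import pulpsweep as ps


class Run:
    """A phantom + ground truth + pipeline result bundle."""

    def __init__(self, preset_name: str, seed: int = 0):
        self.name = preset_name
        self.spec = ps.preset(preset_name, seed)
        self.vol, self.gt = ps.build_phantom(self.spec)
        self.lms = ps.render_landmarks(self.gt)
        self.res = ps.run_pipeline(self.vol, self.lms, self.spec.arch, self.spec.side)


@pytest.fixture(scope="session")
def two_rooted():
    return Run("mand_two_rooted", 0)


@pytest.fixture(scope="session")
def radix():
    return Run("mand_radix", 0)


@pytest.fixture(scope="session")
def three_rooted():
    return Run("max_three_rooted", 0)


@pytest.fixture(scope="session")
def c_shape():
    return Run("max_c_shape", 0)


@pytest.fixture(scope="session")
def single_canal():
    """A single-rooted tooth: no furcation, orifice at the CEJ plane."""
    spec = ps.PhantomSpec(
        arch="maxillary", side="left",
        canals=(ps.CanalSpec("C1", (0.0, 0.0), (0.0, 0.0), 0.5, 0.3, 4.0),),
        plan=ps.Leaf(("C1",)), chamber_floor_depth=1.5,
        chamber_half_widths=(1.2, 1.2),
    )
    vol, gt = ps.build_phantom(spec)
    lms = ps.render_landmarks(gt)
    res = ps.run_pipeline(vol, lms, spec.arch, spec.side)
    r = Run.__new__(Run)
    r.name, r.spec, r.vol, r.gt, r.lms, r.res = "single_canal", spec, vol, gt, lms, res
    return r


def first_split_depth(run: Run) -> float:
    return min(e.depth for e in run.gt.split_events)


def angle_deg(u, v) -> float:
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    c = abs(u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
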