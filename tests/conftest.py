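"""Shared fixtures.

The expensive desk-scale FDTD cells (dx = 0.1 mm, 240 mm domain) are
computed lazily and memoized for the whole session, so every test that
needs the intact benchmark or a fractured model reuses one simulation per
(w, θ) cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pytest

from boneguide import (
    CrackSpec,
    ElasticPlate,
    ReceiverSpec,
    SourceSpec,
    attach_attenuation,
    build_layered_grid,
    carve_crack,
    default_layers,
    fundamental_branches,
    make_sim_config,
    measure_modes,
    plan_windows,
    run_simulation,
    toneburst_duration,
)
from boneguide.materials import CORTICAL_BONE


@pytest.fixture(scope="session")
def cortical_plate() -> ElasticPlate:
    return ElasticPlate(CORTICAL_BONE, 4.0)


@pytest.fixture(scope="session")
def branches(cortical_plate):
    """Traced S0/A0 fundamental branches up to 1 MHz·mm."""
    return fundamental_branches(cortical_plate, fh_max=1.0)


@dataclass
class DeskStudy:
    """Lazy per-(w, θ) desk-scale simulations of the reference model.

    Intact (w = 0) records the five distances z = 90…150 mm; fractured
    cells record z = 120 mm only. Measurements use the free-plate S0/A0
    group-velocity windows shifted by the source group delay. Runs are
    lossless: normalization to the intact model cancels absorption to
    first order, and suppressing the distance-dependent decay keeps the
    slow direct A0 packet dominant over faster multipath arrivals inside
    its window (see docs/methods.md).
    """

    dx: float = 0.1
    length_z: float = 240.0
    z1: float = 60.0
    _cache: dict = field(default_factory=dict)
    _vels: tuple | None = None

    def velocities(self) -> tuple[float, float]:
        if self._vels is None:
            plate = ElasticPlate(CORTICAL_BONE, 4.0)
            s0, a0 = fundamental_branches(plate, fh_max=0.6)
            self._vels = (s0.v_group_at(0.4), a0.v_group_at(0.4))
        return self._vels

    def cell(self, w: float, theta: float) -> dict:
        key = (w, theta) if w > 0 else (0.0, 0.0)
        if key in self._cache:
            return self._cache[key]
        base = build_layered_grid(default_layers(), length_z=self.length_z, dx=self.dx)
        source = SourceSpec(center_z=-self.z1)
        grid = carve_crack(base, CrackSpec(width_w=w, angle_theta=theta)) if w > 0 else base
        z2s = (30.0, 45.0, 60.0, 75.0, 90.0) if w == 0 else (60.0,)
        receivers = [ReceiverSpec(center_z=z2) for z2 in z2s]
        config = make_sim_config(grid, source, receivers, v_slowest=1.4)
        traces = run_simulation(config, grid)
        v_s0, v_a0 = self.velocities()
        pulse = toneburst_duration(source)
        modes = {}
        for r, z2 in enumerate(z2s):
            z = self.z1 + z2
            plan = plan_windows(z, v_s0, v_a0, pulse, t0=pulse / 2)
            modes[z] = measure_modes(traces.traces[r], traces.time, plan, z=z)
        result = dict(traces=traces, modes=modes, config=config)
        self._cache[key] = result
        return result

    def peaks(self, w: float, theta: float, z: float = 120.0):
        m = self.cell(w, theta)["modes"][z]
        return m.s0_peak, m.a0_peak

    def ratio_db(self, w: float, theta: float, z: float = 120.0) -> float:
        return self.cell(w, theta)["modes"][z].ratio_db


@pytest.fixture(scope="session")
def desk_study() -> DeskStudy:
    return DeskStudy()


@pytest.fixture(scope="session")
def pml_reflection_db() -> float:
    """Normal-incidence P reflection (dB) from the bottom PML, measured
    against a double-depth reference grid."""
    import math

    from boneguide.bone_model import LayerSpec
    from boneguide.fdtd import Simulator

    def run(depth: float) -> np.ndarray:
        g = build_layered_grid([LayerSpec("bone", depth, CORTICAL_BONE)], 40.0, 0.1)
        source = SourceSpec(center_z=0.0, aperture=28.0, f0=0.1, cycles=2)
        cfg = make_sim_config(g, source, [ReceiverSpec(center_z=0.0)], v_slowest=4.0,
                              extra_time=0.0)
        cfg.n_steps = int(40.0 / cfg.dt)
        sim = Simulator(g, cfg)
        probe = []
        j = int(20.0 / g.dx)
        i = g.nz // 2
        for n in range(cfg.n_steps):
            sim.step_once((n + 0.5) * cfg.dt)
            probe.append(sim.state.vy[i, j])
        return np.array(probe)

    near = run(32.0)
    ref = run(64.0)
    return 20 * math.log10(np.abs(near - ref).max() / np.abs(ref).max())


@pytest.fixture(scope="session")
def surface_wave_travel_time() -> dict:
    """Measured vs analytic receiver-to-receiver travel time of the
    dominant Rayleigh packet on a homogeneous bone block (the analytic
    speed is the closed-form Rayleigh-equation root)."""
    from boneguide.bone_model import LayerSpec
    from boneguide.dispersion import rayleigh_velocity
    from boneguide.signal_processing import envelope

    g = build_layered_grid([LayerSpec("bone", 24.0, CORTICAL_BONE)], 130.0, 0.2)
    source = SourceSpec(center_z=-45.0, aperture=2.0, f0=0.1, cycles=1)
    recs = [ReceiverSpec(center_z=z, aperture=2.0) for z in (0.0, 40.0)]
    cfg = make_sim_config(g, source, recs, v_slowest=1.6, extra_time=10.0)
    ts = run_simulation(cfg, g)

    def peak(trace):
        env = envelope(trace)
        return ts.time[np.argmax(env)]

    return dict(measured=peak(ts.traces[1]) - peak(ts.traces[0]),
                analytic=40.0 / rayleigh_velocity(CORTICAL_BONE))
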