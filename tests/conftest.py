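"""Shared fixtures.

The bundled two-sac comparison case is the workhorse battery case; it is
solved once per session (flow + wall maps + 5 age cycles) and shared by the
discriminant-ordering, slope, stagnation and mass-conservation tests.
"""

import numpy as np
import pytest

import aneuflow as af


@pytest.fixture(scope="session")
def twosac():
    """Full pipeline result for the bundled two-sac comparison case."""
    cfg = af.two_sac_comparison()
    report, flow, maps, ages = af.run_case(cfg)
    return {"config": cfg, "report": report, "flow": flow, "maps": maps,
            "ages": ages}


@pytest.fixture(scope="session")
def steady_channel_flows():
    """Steady (constant-inflow) straight-channel solves at two resolutions."""
    out = {}
    for h in (4e-4, 2e-4):
        geo = af.make_channel_aneurysm_geometry(4e-3, 1e-2, [], h)
        wf = af.make_inlet_waveform(271.7, 63, shape="steady")
        num = af.NumericsConfig(warmup_cycles=2, stored_cycles=1,
                                samples_per_cycle=50)
        out[h] = af.solve_unsteady_flow(geo, wf, af.RheologyParams.newtonian(),
                                        num)
    return out


@pytest.fixture()
def small_geometry():
    return af.make_channel_aneurysm_geometry(4e-3, 1.2e-2, [], 4e-4)


def poiseuille_profile(geo, q2d):
    """Analytic plane-Poiseuille nodal profile for a straight channel."""
    H = geo.inlet_width
    y = (np.arange(geo.ny) + 0.5) * geo.h
    return 6.0 * q2d / H**3 * y * (H - y)
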