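"""Analytic flow fixtures with known closed-form properties.

These serve as oracles for the post-processing chain: a plug flow is exactly
divergence-free with a flat profile, a plane Poiseuille field has wall shear
6 mu q / H^2, and a sealed cavity has no motion at all (so the age of fluid
grows exactly one second per second everywhere).
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigError
from .geometry import make_channel_aneurysm_geometry, make_sealed_box
from .solver import FlowSeries

__all__ = ["make_analytic_fixture"]


def make_analytic_fixture(kind: str, params: dict | None = None) -> FlowSeries:
    """Build a steady analytic flow series on a simple geometry.

    Parameters
    ----------
    kind : 'plug' | 'poiseuille' | 'sealed_cavity'
    params : dict with keys (all optional)
        width, length : channel dimensions, m (default 4 mm x 20 mm)
        grid_spacing : m (default 0.4 mm)
        u : plug speed, m/s (plug; default 0.1)
        flow_rate : per-unit-depth flow rate q, m^2/s (poiseuille;
            default 1e-4)
        mu : viscosity assigned to the stored viscosity field (default
            0.0035 kg/(m s))
        period, n_samples : stored time span and sample count
    """
    p = dict(params or {})
    width = p.get("width", 4e-3)
    length = p.get("length", 2e-2)
    h = p.get("grid_spacing", 4e-4)
    mu = p.get("mu", 3.5e-3)
    period = p.get("period", 1.0)
    n_samples = int(p.get("n_samples", 4))

    if kind == "sealed_cavity":
        geo = make_sealed_box(width, p.get("height", width), h)
    elif kind in ("plug", "poiseuille"):
        geo = make_channel_aneurysm_geometry(width, length, [], h)
    else:
        raise ConfigError(f"unknown fixture kind {kind!r}")

    nx, ny = geo.nx, geo.ny
    u = np.zeros((nx + 1, ny))
    v = np.zeros((nx, ny + 1))
    if kind == "plug":
        u[:, :] = float(p.get("u", 0.1))
    elif kind == "poiseuille":
        q = float(p.get("flow_rate", 1e-4))
        y = (np.arange(ny) + 0.5) * h
        u[:, :] = (6.0 * q / width**3) * y * (width - y)

    times = np.linspace(0.0, period, n_samples + 1)
    n_t = times.size
    us = np.broadcast_to(u, (n_t, *u.shape)).copy()
    vs = np.broadcast_to(v, (n_t, *v.shape)).copy()
    ps = np.zeros((n_t, nx, ny))
    viscs = np.full((n_t, nx, ny), mu)
    influx = np.full(n_t, float(np.sum(u[0, :]) * h))
    outflux = np.full((n_t, max(len(geo.outlets), 1)),
                      float(np.sum(u[-1, :]) * h))
    if not geo.outlets:
        outflux = np.zeros((n_t, 0))
    div = (u[1:, :] - u[:-1, :] + v[:, 1:] - v[:, :-1]) / h
    u_ref = max(float(np.max(np.abs(u))), 1e-30)
    divres = np.full(n_t, float(np.max(np.abs(div))) * h / u_ref)
    meta = {"fixture": kind, "u_reference": u_ref, "dt": period / n_samples,
            "samples_per_cycle": n_samples, "stored_cycles": 1,
            "warmup_cycles": 0, "n_fluid_cells": int(geo.fluid.sum())}
    return FlowSeries(geometry=geo, waveform=None, rheology=None,
                      times=times, u=us, v=vs, p=ps, visc=viscs,
                      div_residual=divres, inlet_flux=influx,
                      outlet_flux=outflux, metadata=meta)
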