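"""Unsteady incompressible flow with generalized-Newtonian viscosity.

A fractional-step (projection) method on a staggered (MAC) Cartesian grid:
explicit upwind advection, explicit variable-viscosity diffusion with the
apparent viscosity lagged one step (Picard), and a pressure Poisson solve by
a prefactorized sparse LU so the discrete divergence of every stored field is
at round-off level.

Boundary conditions follow the study protocol for cerebral-vessel CFD:

* inlet: quasi-steady parabolic profile scaled to the instantaneous
  waveform flow rate Q(t),
* outlets: zero-gradient outflow corrected additively so each outlet carries
  exactly its Murray-law share of the instantaneous inlet flux,
* walls: rigid, no-slip, stair-step approximated.

The printed volumetric flow rate (mL/min) is converted to a 2D flux per unit
depth through an equivalent circular lumen whose diameter equals the channel
width: U_mean(t) = Q(t) / (pi W^2 / 4), q2d(t) = U_mean(t) * W.  This keeps
the Reynolds and Womersley numbers of the planar model at the physiological
values implied by the printed flows.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import splu

from .errors import CFLError, GeometryError, SolverError
from .geometry import Geometry2D
from .rheology import RheologyParams, apparent_viscosity, strain_rate_magnitude
from .waveform import InletWaveform

__all__ = ["NumericsConfig", "FlowSeries", "solve_unsteady_flow",
           "check_continuity", "inlet_flux_2d"]


@dataclass(frozen=True)
class NumericsConfig:
    """Discretization controls for the unsteady solve.

    cfl : advective Courant bound used to pick the fixed time step
    visc_safety : fraction of the explicit viscous stability limit
    warmup_cycles : cardiac cycles run before any field is stored
    stored_cycles : cycles stored for post-processing
    samples_per_cycle : snapshots kept per stored cycle
    advection : 'upwind' (first-order, monotone) or 'upwind2' (second-order
        upwind with first-order fallback next to walls)
    div_tol : acceptance bound on the scaled divergence residual
    initial_condition : 'developed' (parabolic profile seeded along the
        channel, recommended) or 'rest'
    """

    cfl: float = 0.35
    visc_safety: float = 0.4
    warmup_cycles: int = 3
    stored_cycles: int = 1
    samples_per_cycle: int = 200
    advection: str = "upwind"
    div_tol: float = 1e-8
    min_steps_per_cycle: int = 200
    velocity_margin: float = 2.0
    initial_condition: str = "developed"


def inlet_flux_2d(waveform: InletWaveform, width: float):
    """Map Q(t) [mL/min] to a planar flux per unit depth q2d(t) [m^2/s]."""
    area = np.pi * width**2 / 4.0

    def q2d(t):
        return waveform.flow_rate_si(t) / area * width

    return q2d


@dataclass
class FlowSeries:
    """Velocity/pressure/viscosity fields stored over the final cycle(s)."""

    geometry: Geometry2D
    waveform: InletWaveform | None
    rheology: RheologyParams | None
    times: np.ndarray            # (n_t,) absolute times, s
    u: np.ndarray                # (n_t, nx+1, ny) x-velocity on vertical faces
    v: np.ndarray                # (n_t, nx, ny+1) y-velocity on horizontal faces
    p: np.ndarray                # (n_t, nx, ny) gauge pressure, Pa
    visc: np.ndarray             # (n_t, nx, ny) apparent viscosity
    div_residual: np.ndarray     # (n_t,) scaled max |div|
    inlet_flux: np.ndarray       # (n_t,) m^2/s per unit depth
    outlet_flux: np.ndarray      # (n_t, n_outlets)
    metadata: dict = dc_field(default_factory=dict)

    @property
    def n_times(self) -> int:
        return self.times.size

    @property
    def period(self) -> float:
        if self.waveform is not None:
            return self.waveform.period
        return float(self.times[-1] - self.times[0])

    def velocity_magnitude(self, k: int) -> np.ndarray:
        """Cell-centered speed |u| at stored sample k."""
        uc = 0.5 * (self.u[k, 1:, :] + self.u[k, :-1, :])
        vc = 0.5 * (self.v[k, :, 1:] + self.v[k, :, :-1])
        return np.hypot(uc, vc)


# ---------------------------------------------------------------------------
# face classification
# ---------------------------------------------------------------------------


class _Faces:
    """Active/prescribed face masks and the pressure-Poisson operator."""

    def __init__(self, geo: Geometry2D):
        fluid = geo.fluid
        nx, ny = fluid.shape
        self.nx, self.ny = nx, ny

        u_int = np.zeros((nx + 1, ny), dtype=bool)
        u_int[1:nx, :] = fluid[:-1, :] & fluid[1:, :]
        v_int = np.zeros((nx, ny + 1), dtype=bool)
        v_int[:, 1:ny] = fluid[:, :-1] & fluid[:, 1:]

        u_in = np.zeros_like(u_int)
        u_out = np.zeros_like(u_int)
        v_out = np.zeros_like(v_int)
        if not geo.closed:
            u_in[0, geo.inlet_rows] = True
            for o in geo.outlets:
                if o.orientation == "east":
                    u_out[nx, o.indices] = True
                elif o.orientation == "north":
                    v_out[o.indices, ny] = True
                else:  # pragma: no cover - constructor prevents this
                    raise GeometryError(f"unknown outlet orientation {o.orientation}")

        self.u_int, self.v_int = u_int, v_int
        self.u_in, self.u_out, self.v_out = u_in, u_out, v_out
        self.u_active = u_int | u_in | u_out
        self.v_active = v_int | v_out
        self.fluid = fluid

        # Poisson operator over fluid cells; Neumann at every non-interior face
        idx = -np.ones((nx, ny), dtype=np.int64)
        ii, jj = np.nonzero(fluid)
        idx[ii, jj] = np.arange(ii.size)
        self.cell_index = idx
        n = ii.size
        rows, cols, vals = [], [], []
        diag = np.zeros(n)

        def link(ci, cj, ni, nj):
            a, b = idx[ci, cj], idx[ni, nj]
            rows.append(a)
            cols.append(b)
            vals.append(-1.0)
            diag[a] += 1.0

        # east/west links through interior u-faces
        fe = u_int[1:nx, :] & fluid[:-1, :]
        ei, ej = np.nonzero(fe)
        for ci, cj in zip(ei, ej):
            link(ci, cj, ci + 1, cj)
            link(ci + 1, cj, ci, cj)
        fn = v_int[:, 1:ny] & fluid[:, :-1]
        ni_, nj_ = np.nonzero(fn)
        for ci, cj in zip(ni_, nj_):
            link(ci, cj, ci, cj + 1)
            link(ci, cj + 1, ci, cj)
        rows.extend(range(n))
        cols.extend(range(n))
        vals.extend(diag.tolist())
        A = coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
        # pin the first fluid cell to remove the Neumann null space
        A = A.tolil()
        A.rows[0], A.data[0] = [0], [1.0]
        self.lu = splu(A.tocsc())
        self.n_cells = n

        # wall-distance coefficients for the viscous terms: a missing
        # tangential neighbor means a wall half a cell away (ghost factor 2)
        self.u_north_wall = ~np.pad(self.u_active, ((0, 0), (0, 1)))[:, 1:]
        self.u_south_wall = ~np.pad(self.u_active, ((0, 0), (1, 0)))[:, :-1]
        self.v_east_wall = ~np.pad(self.v_active, ((0, 1), (0, 0)))[1:, :]
        self.v_west_wall = ~np.pad(self.v_active, ((1, 0), (0, 0)))[:-1, :]

    def divergence(self, u: np.ndarray, v: np.ndarray, h: float) -> np.ndarray:
        div = (u[1:, :] - u[:-1, :] + v[:, 1:] - v[:, :-1]) / h
        return np.where(self.fluid, div, 0.0)

    def project(self, u, v, h, dt):
        """Make (u, v) discretely divergence-free; return pressure phi*rho-free."""
        div = self.divergence(u, v, h)
        rhs = -(h * h / dt) * div[self.fluid]
        rhs[0] = 0.0
        phi = self.lu.solve(rhs)
        phig = np.zeros((self.nx, self.ny))
        phig[self.fluid] = phi
        gx = np.zeros_like(u)
        gx[1:-1, :] = (phig[1:, :] - phig[:-1, :]) / h
        gy = np.zeros_like(v)
        gy[:, 1:-1] = (phig[:, 1:] - phig[:, :-1]) / h
        u = u - dt * np.where(self.u_int, gx, 0.0)
        v = v - dt * np.where(self.v_int, gy, 0.0)
        return u, v, phig


# ---------------------------------------------------------------------------
# spatial operators
# ---------------------------------------------------------------------------


def _corner_viscosity(mu_c: np.ndarray, fluid: np.ndarray, mu_fill: float) -> np.ndarray:
    """Viscosity at grid corners: mean over the adjacent fluid cells."""
    m = np.where(fluid, mu_c, 0.0)
    w = fluid.astype(float)
    mp = np.pad(m, 1)
    wp = np.pad(w, 1)
    num = mp[:-1, :-1] + mp[1:, :-1] + mp[:-1, 1:] + mp[1:, 1:]
    den = wp[:-1, :-1] + wp[1:, :-1] + wp[:-1, 1:] + wp[1:, 1:]
    out = np.where(den > 0, num / np.maximum(den, 1.0), mu_fill)
    return out


def _upwind_derivative(q, vel, axis, h, order2=False):
    """Upwind first derivative of q along axis, with zero-value ghosts."""
    qp = np.pad(q, [(2, 2) if a == axis else (0, 0) for a in range(q.ndim)])

    def shift(k):
        s = [slice(None)] * q.ndim
        s[axis] = slice(2 + k, 2 + k + q.shape[axis])
        return qp[tuple(s)]

    back1 = (q - shift(-1)) / h
    fwd1 = (shift(1) - q) / h
    if not order2:
        return np.where(vel > 0, back1, fwd1)
    back2 = (3 * q - 4 * shift(-1) + shift(-2)) / (2 * h)
    fwd2 = (-3 * q + 4 * shift(1) - shift(2)) / (2 * h)
    return np.where(vel > 0, back2, fwd2)


def _viscous_u(u, mu_center, mu_corner, faces: _Faces, h):
    """div(mu grad u) at u-faces (interior faces only are meaningful)."""
    nx, ny = faces.nx, faces.ny
    # x-fluxes at cell centers flanking the face
    flux_e = np.zeros((nx + 1, ny))
    flux_w = np.zeros((nx + 1, ny))
    dudx = (u[1:, :] - u[:-1, :]) / h      # at cell centers
    flux_e[:-1, :] = mu_center * dudx      # flux at center i, used by face i
    flux_w[1:, :] = mu_center * dudx       # flux at center i-1, used by face i
    # y-fluxes at corners; walls half a cell away double the gradient
    un = np.pad(u, ((0, 0), (0, 1)))[:, 1:]
    us = np.pad(u, ((0, 0), (1, 0)))[:, :-1]
    dn = np.where(faces.u_north_wall, 2.0, 1.0)
    ds = np.where(faces.u_south_wall, 2.0, 1.0)
    mun = mu_corner[:, 1:]
    mus = mu_corner[:, :-1]
    flux_n = mun * dn * (np.where(faces.u_north_wall, 0.0, un) - u) / h
    flux_s = mus * ds * (u - np.where(faces.u_south_wall, 0.0, us)) / h
    return (flux_e - flux_w + flux_n - flux_s) / h


def _viscous_v(v, mu_center, mu_corner, faces: _Faces, h):
    nx, ny = faces.nx, faces.ny
    flux_n = np.zeros((nx, ny + 1))
    flux_s = np.zeros((nx, ny + 1))
    dvdy = (v[:, 1:] - v[:, :-1]) / h
    flux_n[:, :-1] = mu_center * dvdy
    flux_s[:, 1:] = mu_center * dvdy
    ve = np.pad(v, ((0, 1), (0, 0)))[1:, :]
    vw = np.pad(v, ((1, 0), (0, 0)))[:-1, :]
    de = np.where(faces.v_east_wall, 2.0, 1.0)
    dw = np.where(faces.v_west_wall, 2.0, 1.0)
    mue = mu_corner[1:, :]
    muw = mu_corner[:-1, :]
    flux_e = mue * de * (np.where(faces.v_east_wall, 0.0, ve) - v) / h
    flux_w = muw * dw * (v - np.where(faces.v_west_wall, 0.0, vw)) / h
    return (flux_n - flux_s + flux_e - flux_w) / h


# ---------------------------------------------------------------------------
# the solve
# ---------------------------------------------------------------------------


def solve_unsteady_flow(
    geometry: Geometry2D,
    waveform: InletWaveform,
    rheology: RheologyParams,
    numerics: NumericsConfig | None = None,
) -> FlowSeries:
    """March the pulsatile flow through warm-up cycles and store the last.

    Runs ``warmup_cycles`` full cardiac cycles to shed the initial transient
    (the protocol used throughout this package: 3 warm-up cycles, then the
    stored cycle feeds the wall-shear, washout and age analyses), then stores
    ``stored_cycles`` cycles at ``samples_per_cycle`` uniform snapshots.
    Deterministic: no random state anywhere.
    """
    num = numerics or NumericsConfig()
    geometry.validate()
    if geometry.closed:
        raise GeometryError("cannot drive flow through a sealed geometry")
    if num.advection not in ("upwind", "upwind2"):
        raise SolverError(f"unknown advection scheme {num.advection!r}")

    h = geometry.h
    fluid = geometry.fluid
    faces = _Faces(geometry)
    rho = rheology.rho
    T = waveform.period

    W = geometry.inlet_width
    q2d = inlet_flux_2d(waveform, W)
    tt = np.linspace(0, T, 2001)
    q2d_peak = float(np.max(q2d(tt)))

    # fixed time step: advective CFL plus explicit-viscous stability
    u_est = num.velocity_margin * q2d_peak / W
    dt_adv = num.cfl * h / u_est
    dt_visc = num.visc_safety * rho * h * h / (4.0 * rheology.mu_ceiling)
    dt0 = min(dt_adv, dt_visc)
    spc = num.samples_per_cycle
    n_per = int(np.ceil(T / dt0 / spc)) * spc
    n_per = max(n_per, max(num.min_steps_per_cycle, spc))
    dt = T / n_per
    stride = n_per // spc

    # inlet profile weights: parabolic, normalized to unit discrete flux
    n_in = geometry.inlet_rows.size
    yr = (np.arange(n_in) + 0.5) / n_in
    prof = yr * (1.0 - yr)
    prof = prof / (prof.sum() * h)

    east_rows = {o.name: o.indices for o in geometry.outlets
                 if o.orientation == "east"}
    north_cols = {o.name: o.indices for o in geometry.outlets
                  if o.orientation == "north"}

    u = np.zeros((faces.nx + 1, faces.ny))
    v = np.zeros((faces.nx, faces.ny + 1))
    if num.initial_condition == "developed":
        jch = geometry.inlet_rows
        u[:, jch] = (prof * q2d(0.0))[None, :]
        u[~faces.u_active] = 0.0
    _apply_boundary(u, v, geometry, faces, prof, q2d(0.0), h)
    u, v, _ = faces.project(u, v, h, dt)

    n_total = (num.warmup_cycles + num.stored_cycles) * n_per
    store_from = num.warmup_cycles * n_per
    n_snap = num.stored_cycles * spc + 1

    us = np.empty((n_snap, *u.shape))
    vs = np.empty((n_snap, *v.shape))
    ps = np.empty((n_snap, faces.nx, faces.ny))
    viscs = np.empty((n_snap, faces.nx, faces.ny))
    times = np.empty(n_snap)
    divres = np.empty(n_snap)
    influx = np.empty(n_snap)
    outflux = np.empty((n_snap, len(geometry.outlets)))

    u_ref = q2d_peak / W
    order2 = num.advection == "upwind2"
    cfl_seen = 0.0
    k_snap = 0
    phig = np.zeros((faces.nx, faces.ny))

    def snapshot(k, t, u, v, phig, mu_c):
        us[k] = u
        vs[k] = v
        ps[k] = rho * phig
        viscs[k] = np.where(fluid, mu_c, np.nan)
        times[k] = t
        d = faces.divergence(u, v, h)
        divres[k] = np.max(np.abs(d)) * h / u_ref
        influx[k] = np.sum(u[0, geometry.inlet_rows]) * h
        for m, o in enumerate(geometry.outlets):
            if o.orientation == "east":
                outflux[k, m] = np.sum(u[-1, o.indices]) * h
            else:
                outflux[k, m] = np.sum(v[o.indices, -1]) * h

    gdot = strain_rate_magnitude(u, v, h, fluid)
    mu_c = apparent_viscosity(gdot, rheology)
    if store_from == 0:
        snapshot(0, 0.0, u, v, phig, mu_c)
        k_snap = 1

    for step in range(n_total):
        t_new = (step + 1) * dt

        gdot = strain_rate_magnitude(u, v, h, fluid)
        mu_c = apparent_viscosity(gdot, rheology)          # lagged Picard
        mu_corner = _corner_viscosity(mu_c, fluid, rheology.mu)
        mu_fill = np.where(fluid, mu_c, rheology.mu)

        # advect u
        v_at_u = np.zeros_like(u)
        v_at_u[1:-1, :] = 0.25 * (v[:-1, :-1] + v[:-1, 1:]
                                  + v[1:, :-1] + v[1:, 1:])
        adv_u = (u * _upwind_derivative(u, u, 0, h, order2)
                 + v_at_u * _upwind_derivative(u, v_at_u, 1, h, order2))
        # advect v
        u_at_v = np.zeros_like(v)
        u_at_v[:, 1:-1] = 0.25 * (u[:-1, :-1] + u[1:, :-1]
                                  + u[:-1, 1:] + u[1:, 1:])
        adv_v = (u_at_v * _upwind_derivative(v, u_at_v, 0, h, order2)
                 + v * _upwind_derivative(v, v, 1, h, order2))

        visc_u = _viscous_u(u, mu_fill, mu_corner, faces, h)
        visc_v = _viscous_v(v, mu_fill, mu_corner, faces, h)

        u_star = u + dt * np.where(faces.u_int, -adv_u + visc_u / rho, 0.0)
        v_star = v + dt * np.where(faces.v_int, -adv_v + visc_v / rho, 0.0)

        _apply_boundary(u_star, v_star, geometry, faces, prof, q2d(t_new), h)
        u, v, phig = faces.project(u_star, v_star, h, dt)

        speed = max(np.max(np.abs(u)), np.max(np.abs(v)))
        cfl_now = speed * dt / h
        cfl_seen = max(cfl_seen, cfl_now)
        if cfl_now > 0.95:
            raise CFLError(
                f"advective CFL {cfl_now:.2f} at t = {t_new:.4f} s "
                f"(step {step + 1}); peak speed {speed:.3f} m/s exceeds the "
                f"sizing estimate {u_est:.3f} m/s"
            )
        if step % 200 == 0 and not np.isfinite(u).all():
            raise SolverError(f"non-finite velocity at step {step}, "
                              f"t = {t_new:.4f} s")

        if step + 1 >= store_from and (step + 1 - store_from) % stride == 0:
            snapshot(k_snap, t_new, u, v, phig, mu_c)
            k_snap += 1

    if np.max(divres) > num.div_tol:
        raise SolverError(
            f"scaled divergence residual {np.max(divres):.2e} exceeds the "
            f"tolerance {num.div_tol:.1e}"
        )

    meta = {
        "dt": dt, "steps_per_cycle": n_per, "warmup_cycles": num.warmup_cycles,
        "stored_cycles": num.stored_cycles, "samples_per_cycle": spc,
        "cfl_max": cfl_seen, "advection": num.advection,
        "scheme": "fractional-step projection, staggered Cartesian grid",
        "u_reference": u_ref, "n_fluid_cells": int(fluid.sum()),
    }
    return FlowSeries(geometry=geometry, waveform=waveform, rheology=rheology,
                      times=times, u=us, v=vs, p=ps, visc=viscs,
                      div_residual=divres, inlet_flux=influx,
                      outlet_flux=outflux, metadata=meta)


def _apply_boundary(u, v, geometry: Geometry2D, faces: _Faces,
                    prof, q2d_now, h):
    """Prescribe inlet profile and Murray-split outlet fluxes (in place)."""
    u[0, :] = 0.0
    u[0, geometry.inlet_rows] = prof * q2d_now
    q_in = np.sum(u[0, geometry.inlet_rows]) * h
    u[-1, :] = np.where(faces.u_out[-1, :], u[-1, :], 0.0)
    v[:, -1] = np.where(faces.v_out[:, -1], v[:, -1], 0.0)
    for o in geometry.outlets:
        target = o.fraction * q_in
        if o.orientation == "east":
            rows = o.indices
            u[-1, rows] = u[-2, rows]
            corr = (target - np.sum(u[-1, rows]) * h) / (rows.size * h)
            u[-1, rows] += corr
        else:
            cols = o.indices
            v[cols, -1] = v[cols, -2]
            corr = (target - np.sum(v[cols, -1]) * h) / (cols.size * h)
            v[cols, -1] += corr
    # zero every non-active face
    u[~faces.u_active] = 0.0
    v[~faces.v_active] = 0.0


def check_continuity(flow: FlowSeries, tol: float = 5e-3) -> dict:
    """Diagnostic report on mass conservation of a stored flow series.

    Returns the global and per-step scaled divergence maxima and verifies
    that the inlet flux matches both the waveform and the summed outlet
    fluxes within ``tol`` (default 0.5%) at every stored time.
    """
    if flow.n_times == 0:
        raise SolverError("empty flow series")
    h = flow.geometry.h
    faces = _Faces(flow.geometry)
    u_ref = flow.metadata.get("u_reference") or max(
        1e-30, float(np.max(np.abs(flow.u))))
    div_scaled = np.array([
        np.max(np.abs(faces.divergence(flow.u[k], flow.v[k], h))) * h / u_ref
        for k in range(flow.n_times)
    ])
    out_sum = flow.outlet_flux.sum(axis=1) if flow.outlet_flux.size else \
        np.zeros(flow.n_times)
    denom = np.maximum(np.abs(flow.inlet_flux), 1e-30)
    flux_err = np.abs(flow.inlet_flux - out_sum) / denom
    report = {
        "max_divergence_scaled": float(div_scaled.max()),
        "per_step_divergence": div_scaled,
        "max_flux_imbalance": float(flux_err.max()),
        "per_step_flux_imbalance": flux_err,
        "balanced": bool(flux_err.max() <= tol),
    }
    if flow.waveform is not None:
        q2d = inlet_flux_2d(flow.waveform, flow.geometry.inlet_width)
        wf_err = np.abs(flow.inlet_flux - q2d(flow.times)) / denom
        report["max_waveform_mismatch"] = float(wf_err.max())
        report["balanced"] = report["balanced"] and bool(wf_err.max() <= tol)
    return report
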