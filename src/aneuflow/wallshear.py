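"""Hemodynamic wall parameters: TAWSS, OSI and RRT on stair-step walls.

In 2D the wall shear stress reduces to a signed tangential scalar
tau_w = mu_wall * d(u_t)/dn, evaluated per wall face by a one-sided
difference that uses the no-slip condition (two fluid samples at n = h/2
and 3h/2 give a quadratic fit exact for parabolic profiles; a single sample
falls back to the linear form).  From the per-face time series over one
cardiac cycle:

* TAWSS  = (1/T) int |tau_w| dt                       (Pa)
* OSI    = 0.5 (1 - |int tau_w dt| / int |tau_w| dt)  (He-Ku form, in [0, 0.5])
* RRT    = 1 / ((1 - 2 OSI) * TAWSS)                  (Himburg form, 1/Pa)

RRT diverges where the mean shear vanishes; values beyond the cap 1/eps are
clamped and flagged so tabulated outputs stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError
from .geometry import AneurysmRegion, Geometry2D
from .solver import FlowSeries

__all__ = ["WallShearSeries", "WallParameterMaps", "wall_shear_vectors",
           "time_averaged_wss", "oscillatory_shear_index",
           "relative_residence_time", "aneurysm_wall_extrema",
           "compute_wall_maps"]

#: floor on (1 - 2 OSI) * TAWSS below which RRT is capped, Pa
RRT_EPS = 1e-6

_NORMALS = {"+x": (1, 0), "-x": (-1, 0), "+y": (0, 1), "-y": (0, -1)}


@dataclass
class WallShearSeries:
    """Signed tangential wall shear per wall face over one cycle."""

    geometry: Geometry2D
    cell_i: np.ndarray          # fluid cell owning each wall face
    cell_j: np.ndarray
    normal: np.ndarray          # strings '+x', '-x', '+y', '-y' (into fluid)
    x: np.ndarray               # wall-face center positions, m
    y: np.ndarray
    times: np.ndarray           # (n_t,) spanning exactly one period
    tau: np.ndarray             # (n_t, n_faces) signed wall shear, Pa
    period: float

    @property
    def n_faces(self) -> int:
        return self.cell_i.size


@dataclass
class WallParameterMaps:
    """Per-face TAWSS/OSI/RRT plus capping flags."""

    series: WallShearSeries
    tawss: np.ndarray
    osi: np.ndarray
    rrt: np.ndarray
    rrt_capped: np.ndarray      # bool flags

    def face_table(self):
        import pandas as pd
        s = self.series
        return pd.DataFrame({
            "face_id": np.arange(s.n_faces), "x_m": s.x, "y_m": s.y,
            "normal": s.normal, "tawss_pa": self.tawss, "osi": self.osi,
            "rrt_per_pa": self.rrt, "rrt_capped": self.rrt_capped,
        })


def _wall_faces(geometry: Geometry2D):
    """Enumerate wall faces as (cell_i, cell_j, normal-into-fluid)."""
    fluid = geometry.fluid
    nx, ny = fluid.shape
    solid_e = np.pad(~fluid, ((0, 1), (0, 0)), constant_values=True)[1:, :]
    solid_w = np.pad(~fluid, ((1, 0), (0, 0)), constant_values=True)[:-1, :]
    solid_n = np.pad(~fluid, ((0, 0), (0, 1)), constant_values=True)[:, 1:]
    solid_s = np.pad(~fluid, ((0, 0), (1, 0)), constant_values=True)[:, :-1]
    # open boundaries are not walls
    if not geometry.closed:
        solid_w[0, geometry.inlet_rows] = False
        for o in geometry.outlets:
            if o.orientation == "east":
                solid_e[nx - 1, o.indices] = False
            else:
                solid_n[o.indices, ny - 1] = False
    out = []
    for mask, normal in ((solid_e & fluid, "-x"), (solid_w & fluid, "+x"),
                         (solid_n & fluid, "-y"), (solid_s & fluid, "+y")):
        ii, jj = np.nonzero(mask)
        for i, j in zip(ii, jj):
            out.append((i, j, normal))
    if not out:
        raise GeometryError("geometry has no wall faces")
    return out


def wall_shear_vectors(flow: FlowSeries, geometry: Geometry2D | None = None,
                       rheology=None) -> WallShearSeries:
    """Signed tangential wall shear at every wall face and stored time.

    The wall-local apparent viscosity is taken from the stored viscosity
    field of the adjacent fluid cell; ``rheology`` is only used as a
    fallback when the flow series carries no viscosity (analytic fixtures).
    """
    geo = geometry or flow.geometry
    h = geo.h
    faces = _wall_faces(geo)
    n_f = len(faces)
    n_t = flow.n_times

    ci = np.array([f[0] for f in faces])
    cj = np.array([f[1] for f in faces])
    nrm = np.array([f[2] for f in faces])

    # face-center positions
    x = (ci + 0.5) * h
    y = (cj + 0.5) * h
    for k, (i, j, n) in enumerate(faces):
        dx, dy = _NORMALS[n]
        x[k] -= dx * h / 2
        y[k] -= dy * h / 2

    mu_fallback = None
    if rheology is not None:
        mu_fallback = rheology.mu
    elif flow.rheology is not None:
        mu_fallback = flow.rheology.mu

    tau = np.zeros((n_t, n_f))
    fluid = geo.fluid
    for t in range(n_t):
        u, v = flow.u[t], flow.v[t]
        uc = 0.5 * (u[1:, :] + u[:-1, :])
        vc = 0.5 * (v[:, 1:] + v[:, :-1])
        visc = flow.visc[t] if flow.visc.size else None
        for k, (i, j, n) in enumerate(faces):
            dx, dy = _NORMALS[n]
            ut = uc if dy != 0 else vc       # tangential component
            u0 = ut[i, j]
            i1, j1 = i + dx, j + dy
            if (0 <= i1 < geo.nx and 0 <= j1 < geo.ny and fluid[i1, j1]):
                u1 = ut[i1, j1]
                dudn = (9.0 * u0 - u1) / (3.0 * h)
            else:
                dudn = 2.0 * u0 / h
            if visc is not None and np.isfinite(visc[i, j]):
                mu_w = visc[i, j]
            else:
                mu_w = mu_fallback
            if mu_w is None:
                raise ValueError("no viscosity available for wall shear")
            tau[t, k] = mu_w * dudn
    return WallShearSeries(geometry=geo, cell_i=ci, cell_j=cj, normal=nrm,
                           x=x, y=y, times=flow.times.copy(), tau=tau,
                           period=flow.period)


def _cycle_trapz(y: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.trapezoid(y, t, axis=0)


def time_averaged_wss(ws: WallShearSeries) -> np.ndarray:
    """TAWSS: cycle average of |tau_w| per face (trapezoid rule), Pa."""
    T = ws.times[-1] - ws.times[0]
    return _cycle_trapz(np.abs(ws.tau), ws.times) / T


def oscillatory_shear_index(ws: WallShearSeries) -> np.ndarray:
    """OSI in [0, 0.5]; 0 where the shear never acts (zero denominator)."""
    T = ws.times[-1] - ws.times[0]
    mean_vec = np.abs(_cycle_trapz(ws.tau, ws.times)) / T
    mean_mag = _cycle_trapz(np.abs(ws.tau), ws.times) / T
    osi = np.zeros(ws.n_faces)
    nz = mean_mag > 0
    osi[nz] = 0.5 * (1.0 - mean_vec[nz] / mean_mag[nz])
    return np.clip(osi, 0.0, 0.5)


def relative_residence_time(tawss: np.ndarray, osi: np.ndarray,
                            eps: float = RRT_EPS):
    """RRT = 1 / ((1 - 2 OSI) TAWSS), capped at 1/eps with a flag."""
    denom = (1.0 - 2.0 * np.asarray(osi)) * np.asarray(tawss)
    capped = denom < eps
    rrt = 1.0 / np.maximum(denom, eps)
    return rrt, capped


def compute_wall_maps(ws: WallShearSeries, eps: float = RRT_EPS) -> WallParameterMaps:
    """Assemble the three wall-parameter maps from one shear series."""
    tawss = time_averaged_wss(ws)
    osi = oscillatory_shear_index(ws)
    rrt, capped = relative_residence_time(tawss, osi, eps)
    return WallParameterMaps(series=ws, tawss=tawss, osi=osi, rrt=rrt,
                             rrt_capped=capped)


def aneurysm_wall_extrema(maps: WallParameterMaps,
                          region: AneurysmRegion) -> dict:
    """Max RRT, min TAWSS and max OSI over the sac's own wall faces.

    The three extrema are searched independently (they generally occur at
    different faces); each is reported with the position of its face.
    """
    s = maps.series
    sel = region.mask[s.cell_i, s.cell_j]
    if not np.any(sel):
        raise GeometryError(f"region {region.name} has no wall faces")
    idx = np.nonzero(sel)[0]

    def at(k):
        return {"x_m": float(s.x[k]), "y_m": float(s.y[k]), "face_id": int(k)}

    k_rrt = idx[np.argmax(maps.rrt[idx])]
    k_wss = idx[np.argmin(maps.tawss[idx])]
    k_osi = idx[np.argmax(maps.osi[idx])]
    return {
        "max_rrt_per_pa": float(maps.rrt[k_rrt]),
        "max_rrt_location": at(k_rrt),
        "max_rrt_capped": bool(maps.rrt_capped[k_rrt]),
        "min_tawss_pa": float(maps.tawss[k_wss]),
        "min_tawss_location": at(k_wss),
        "max_osi": float(maps.osi[k_osi]),
        "max_osi_location": at(k_osi),
        "n_wall_faces": int(idx.size),
    }
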