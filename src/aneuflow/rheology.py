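"""Blood rheology: Newtonian and regularized Herschel-Bulkley viscosity.

The Herschel-Bulkley apparent viscosity

    mu(gdot) = k * gdot**(n - 1) + tau0 / gdot

captures shear thinning (n < 1) and yield stress (tau0 > 0) but diverges as
the strain rate gdot -> 0; it is regularized by flooring gdot at ``gdot_min``
and capping the result at ``mu_max``, which keeps the low-shear plateau
finite and the viscosity continuous in gdot.

The Herschel-Bulkley coefficient defaults below are literature-typical
stand-ins for whole blood and are meant to be overridden per case when
measured values are available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError

__all__ = ["RheologyParams", "apparent_viscosity", "strain_rate_magnitude"]


@dataclass(frozen=True)
class RheologyParams:
    """Constitutive parameters for one viscosity setting.

    model : "newtonian" or "herschel_bulkley"
    rho : density, kg/m^3
    mu : Newtonian viscosity, kg/(m s)
    k : consistency index, Pa s^n
    n : power-law index (dimensionless)
    tau0 : yield stress, Pa
    gdot_min : low-shear regularization floor on the strain rate, 1/s
    mu_max : viscosity cap, kg/(m s)
    """

    model: str = "newtonian"
    rho: float = 1050.0
    mu: float = 3.5e-3
    k: float = 8.9e-3
    n: float = 0.8
    tau0: float = 1.75e-2
    gdot_min: float = 0.1
    mu_max: float = 1.0

    def __post_init__(self):
        if self.model not in ("newtonian", "herschel_bulkley"):
            raise ConfigError(f"unknown rheology model {self.model!r}")
        if self.rho <= 0 or self.mu <= 0 or self.k <= 0 or self.n <= 0:
            raise ConfigError("rho, mu, k and n must all be positive")
        if self.tau0 < 0 or self.gdot_min <= 0:
            raise ConfigError("tau0 must be >= 0 and gdot_min > 0")
        if self.mu_max < self.mu:
            raise ConfigError("mu_max must be at least the Newtonian viscosity")

    @classmethod
    def newtonian(cls, mu: float = 3.5e-3, rho: float = 1050.0) -> "RheologyParams":
        return cls(model="newtonian", mu=mu, rho=rho)

    @classmethod
    def herschel_bulkley(cls, k: float = 8.9e-3, n: float = 0.8,
                         tau0: float = 1.75e-2, rho: float = 1050.0,
                         gdot_min: float = 0.1, mu_max: float = 1.0,
                         mu: float = 3.5e-3) -> "RheologyParams":
        return cls(model="herschel_bulkley", k=k, n=n, tau0=tau0, rho=rho,
                   gdot_min=gdot_min, mu_max=mu_max, mu=mu)

    @property
    def mu_ceiling(self) -> float:
        """Largest apparent viscosity the regularized law can produce."""
        if self.model == "newtonian":
            return self.mu
        if self.n > 1.0:          # shear thickening: unbounded, only the cap holds
            return float(self.mu_max)
        cap = self.k * self.gdot_min ** (self.n - 1.0) + self.tau0 / self.gdot_min
        return float(min(cap, self.mu_max))


def apparent_viscosity(strain_rate, params: RheologyParams) -> np.ndarray:
    """Apparent viscosity field (kg/(m s)) at the given strain rates (1/s)."""
    gdot = np.asarray(strain_rate, dtype=float)
    if np.any(gdot < 0):
        raise ValueError("strain rate must be non-negative (upstream bug?)")
    if params.model == "newtonian":
        return np.full_like(gdot, params.mu)
    g = np.maximum(gdot, params.gdot_min)
    mu = params.k * g ** (params.n - 1.0) + params.tau0 / g
    return np.minimum(mu, params.mu_max)


def strain_rate_magnitude(u: np.ndarray, v: np.ndarray, h: float,
                          fluid: np.ndarray | None = None) -> np.ndarray:
    """Strain-rate magnitude gdot = sqrt(2 D:D) at cell centers.

    Parameters
    ----------
    u : (nx+1, ny) face-normal x-velocity on vertical faces (MAC layout)
    v : (nx, ny+1) face-normal y-velocity on horizontal faces
    h : grid spacing, m
    fluid : optional (nx, ny) mask; solid cells are zeroed in the output

    Gradients use centered differences on center-interpolated fields, so a
    rigid translation gives exactly zero and simple shear u = (g y, 0) gives
    g in the interior.
    """
    dudx = (u[1:, :] - u[:-1, :]) / h              # natural at centers
    dvdy = (v[:, 1:] - v[:, :-1]) / h
    uc = 0.5 * (u[1:, :] + u[:-1, :])              # u at cell centers
    vc = 0.5 * (v[:, 1:] + v[:, :-1])
    dudy = np.gradient(uc, h, axis=1)
    dvdx = np.gradient(vc, h, axis=0)
    gdot = np.sqrt(2.0 * (dudx**2 + dvdy**2) + (dudy + dvdx) ** 2)
    if fluid is not None:
        gdot = np.where(fluid, gdot, 0.0)
    return gdot
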