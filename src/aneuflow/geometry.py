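"""Synthetic 2D vessel-plus-aneurysm geometries on uniform Cartesian grids.

The geometries generated here are desk-scale stand-ins for patient-specific
lumen reconstructions: a straight parent channel (optionally with one
bifurcating branch) carrying one or more sidewall aneurysm sacs.  Each sac is
a circular pocket opening onto a channel wall through a grid-aligned neck
plane; the neck is the chord where the sac circle meets the wall line, so the
only fluid connection between sac and parent vessel runs through the neck
faces.  Everything is defined on a uniform grid with stair-stepped walls.

Conventions
-----------
* x runs along the parent channel (inlet at x = 0, west), y across it.
* Cell (i, j) has its center at ((i + 1/2) h, (j + 1/2) h).
* 2D "volumes" are areas times a 1 mm unit depth, reported in mm^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import GeometryError

__all__ = [
    "SacSpec",
    "AneurysmRegion",
    "Outlet",
    "Geometry2D",
    "murray_outlet_fractions",
    "make_channel_aneurysm_geometry",
    "make_sealed_box",
]

#: depth (in mm) used to convert 2D areas into reported volumes
UNIT_DEPTH_MM = 1.0

#: minimum number of grid faces across any aneurysm neck
MIN_NECK_FACES = 8


def murray_outlet_fractions(diameters: Sequence[float]) -> list[float]:
    """Outlet flow fractions from the minimum-work (Murray cube-law) principle.

    fraction_k = d_k^3 / sum_j d_j^3.  Scale-invariant in the diameters.
    """
    d = np.asarray(list(diameters), dtype=float)
    if d.size == 0:
        raise GeometryError("Murray fractions need at least one outlet diameter")
    if np.any(d <= 0):
        raise GeometryError(f"outlet diameters must be positive, got {d.tolist()}")
    cubes = d**3
    return list(cubes / cubes.sum())


@dataclass(frozen=True)
class SacSpec:
    """Parameters of one sidewall aneurysm sac.

    diameter : sac (dome) diameter in m
    neck_width : chord length of the opening onto the channel wall, m;
        must be strictly smaller than the diameter
    position : x-coordinate of the neck center, m
    side : 'top' or 'bottom' channel wall
    name : label used in all reports (defaults to AN1, AN2, ... by order)
    """

    diameter: float
    neck_width: float
    position: float
    side: str = "top"
    name: str = ""


@dataclass
class AneurysmRegion:
    """A discretized sac: its cell mask, neck plane and volume."""

    name: str
    mask: np.ndarray                  # (nx, ny) bool, sac fluid cells
    neck_axis: str                    # 'y': neck faces are horizontal (v-faces)
    neck_face_j: int                  # v-face row index of the neck plane
    neck_face_i: np.ndarray           # column indices of the neck faces
    normal_sign: int                  # +1 if the into-sac normal points +y
    h: float                          # grid spacing, m

    @property
    def n_cells(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_mm3(self) -> float:
        """Sac area times the 1 mm unit depth, in mm^3."""
        h_mm = self.h * 1e3
        return self.n_cells * h_mm**2 * UNIT_DEPTH_MM

    @property
    def neck_width_faces(self) -> int:
        return int(self.neck_face_i.size)


@dataclass(frozen=True)
class Outlet:
    """One labeled outlet: a run of boundary faces plus its Murray data."""

    name: str
    orientation: str        # 'east' (u-faces at i = nx) or 'north' (v-faces at j = ny)
    indices: np.ndarray     # row indices (east) or column indices (north)
    diameter: float         # reference diameter for the Murray split, m
    fraction: float         # imposed share of the inlet flow


@dataclass
class Geometry2D:
    """Structured-grid fluid mask with labeled inlet, outlets and sacs."""

    h: float
    fluid: np.ndarray                     # (nx, ny) bool
    inlet_rows: np.ndarray                # j indices of inlet faces at i = 0
    outlets: list[Outlet]
    regions: list[AneurysmRegion] = field(default_factory=list)
    closed: bool = False                  # sealed cavity (no open boundary)

    @property
    def nx(self) -> int:
        return self.fluid.shape[0]

    @property
    def ny(self) -> int:
        return self.fluid.shape[1]

    @property
    def extents(self) -> tuple[float, float]:
        return (self.nx * self.h, self.ny * self.h)

    @property
    def inlet_width(self) -> float:
        return self.inlet_rows.size * self.h

    def region(self, name: str) -> AneurysmRegion:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(f"no aneurysm region named {name!r}")

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        """Check the structural invariants; raise GeometryError on failure."""
        if not self.closed:
            if self.inlet_rows.size == 0:
                raise GeometryError("geometry has no inlet faces")
            if not self.outlets:
                raise GeometryError("geometry has no outlets")
            if not np.all(self.fluid[0, self.inlet_rows]):
                raise GeometryError("inlet faces must border fluid cells")
            frac = sum(o.fraction for o in self.outlets)
            if abs(frac - 1.0) > 1e-12:
                raise GeometryError(f"outlet fractions sum to {frac}, not 1")
        # every fluid cell must connect to the inlet through fluid cells
        labels, _ = ndimage.label(self.fluid)
        if not self.closed:
            inlet_labels = set(labels[0, self.inlet_rows])
            reachable = np.isin(labels, list(inlet_labels)) & self.fluid
            if not np.array_equal(reachable, self.fluid):
                n_orphan = int(self.fluid.sum() - reachable.sum())
                raise GeometryError(
                    f"{n_orphan} fluid cells are not connected to the inlet"
                )
        for r in self.regions:
            if not np.all(self.fluid[r.mask]):
                raise GeometryError(f"sac {r.name}: mask contains solid cells")
            if r.n_cells == 0:
                raise GeometryError(f"sac {r.name}: empty region")
            if r.neck_width_faces < MIN_NECK_FACES:
                raise GeometryError(
                    f"sac {r.name}: neck resolved by {r.neck_width_faces} faces "
                    f"(< {MIN_NECK_FACES}); reduce grid_spacing below "
                    f"{r.neck_width_faces * self.h / MIN_NECK_FACES:.2e} m"
                )
            # removing the neck faces must disconnect the sac from the inlet
            if not self._neck_separates(r):
                raise GeometryError(
                    f"sac {r.name}: neck plane does not separate the sac "
                    "from the parent vessel"
                )

    def _neck_separates(self, r: AneurysmRegion) -> bool:
        """True if every sac cell sits on the sac side of the neck plane."""
        j_wall = r.neck_face_j  # v-face row index
        ii, jj = np.nonzero(r.mask)
        if r.normal_sign > 0:
            return bool(np.all(jj >= j_wall))
        return bool(np.all(jj < j_wall))


# ---------------------------------------------------------------------------
# constructors
# ---------------------------------------------------------------------------


def _as_sac_spec(s, k: int) -> SacSpec:
    if isinstance(s, SacSpec):
        spec = s
    else:
        spec = SacSpec(**dict(s))
    if not spec.name:
        spec = SacSpec(spec.diameter, spec.neck_width, spec.position,
                       spec.side, f"AN{k + 1}")
    return spec


def make_channel_aneurysm_geometry(
    channel_width: float,
    channel_length: float,
    sac_specs: Sequence[SacSpec | dict] = (),
    grid_spacing: float = 4e-4,
    outlet_spec: dict | None = None,
) -> Geometry2D:
    """Build a straight parent channel carrying sidewall aneurysm sacs.

    Parameters
    ----------
    channel_width, channel_length : m
        Parent channel dimensions.  The inlet spans the full width at x = 0.
    sac_specs : sequence of SacSpec or dict
        Sidewall pockets; see :class:`SacSpec`.
    grid_spacing : m
        Uniform cell size h.  Each neck must be resolved by >= 8 faces.
    outlet_spec : dict, optional
        Bifurcation description ``{"diameters": [d_main, d_branch],
        "branch_position": x_m, "branch_width": m (default d_branch)}``.
        The branch leaves the top wall and exits through the domain top;
        flow is split by Murray's law over the diameters.  Omitted: a single
        east outlet of reference diameter = channel width.
    """
    h = float(grid_spacing)
    if h <= 0:
        raise GeometryError("grid_spacing must be positive")
    n_w = int(round(channel_width / h))
    nx = int(round(channel_length / h))
    if n_w < 4 or nx < 4:
        raise GeometryError("channel must span at least 4 cells in each direction")

    specs = [_as_sac_spec(s, k) for k, s in enumerate(sac_specs)]
    for s in specs:
        if s.neck_width >= s.diameter:
            raise GeometryError(
                f"sac {s.name}: neck_width {s.neck_width} must be smaller than "
                f"the sac diameter {s.diameter}"
            )
        if s.neck_width <= 0 or s.diameter <= 0:
            raise GeometryError(f"sac {s.name}: non-positive dimensions")
        if s.side not in ("top", "bottom"):
            raise GeometryError(f"sac {s.name}: side must be 'top' or 'bottom'")
        if not (h <= s.position - s.neck_width / 2
                and s.position + s.neck_width / 2 <= channel_length - h):
            raise GeometryError(
                f"sac {s.name}: neck [{s.position - s.neck_width / 2:.4g}, "
                f"{s.position + s.neck_width / 2:.4g}] m does not fit inside "
                f"the channel (length {channel_length} m)"
            )
        if s.neck_width / h < MIN_NECK_FACES - 0.5:
            raise GeometryError(
                f"sac {s.name}: neck of {s.neck_width} m is resolved by about "
                f"{s.neck_width / h:.1f} faces at h = {h} m; need >= "
                f"{MIN_NECK_FACES} (use grid_spacing <= "
                f"{s.neck_width / MIN_NECK_FACES:.2e} m)"
            )

    def sac_extent(s: SacSpec) -> float:
        r = s.diameter / 2
        cy = np.sqrt(r**2 - (s.neck_width / 2) ** 2)
        return cy + r  # pocket depth beyond the wall line

    n_above = max((int(np.ceil(sac_extent(s) / h)) for s in specs
                   if s.side == "top"), default=0)
    n_below = max((int(np.ceil(sac_extent(s) / h)) for s in specs
                   if s.side == "bottom"), default=0)

    branch = None
    if outlet_spec:
        diam = list(outlet_spec["diameters"])
        if len(diam) != 2:
            raise GeometryError("outlet_spec expects exactly two diameters "
                                "[d_main, d_branch]")
        w_b = float(outlet_spec.get("branch_width", diam[1]))
        x_b = float(outlet_spec["branch_position"])
        i0 = int(round((x_b - w_b / 2) / h))
        i1 = int(round((x_b + w_b / 2) / h))
        if i0 < 1 or i1 > nx - 1 or i1 - i0 < 2:
            raise GeometryError("branch does not fit inside the channel length")
        branch = (i0, i1, diam)
        n_above = max(n_above, int(np.ceil(1.5 * w_b / h)))

    ny = n_below + n_w + n_above
    fluid = np.zeros((nx, ny), dtype=bool)
    j_lo, j_hi = n_below, n_below + n_w  # channel row band [j_lo, j_hi)
    fluid[:, j_lo:j_hi] = True

    if branch is not None:
        i0, i1, _ = branch
        fluid[i0:i1, j_hi:ny] = True

    xs = (np.arange(nx) + 0.5) * h
    ys = (np.arange(ny) + 0.5) * h
    XC, YC = np.meshgrid(xs, ys, indexing="ij")

    regions: list[AneurysmRegion] = []
    for s in specs:
        r = s.diameter / 2
        cy = float(np.sqrt(r**2 - (s.neck_width / 2) ** 2))
        if s.side == "top":
            y_wall = j_hi * h
            center = (s.position, y_wall + cy)
            mask = (YC > y_wall) & ((XC - center[0]) ** 2
                                    + (YC - center[1]) ** 2 < r**2)
            neck_face_j, normal_sign, j_first = j_hi, +1, j_hi
        else:
            y_wall = j_lo * h
            center = (s.position, y_wall - cy)
            mask = (YC < y_wall) & ((XC - center[0]) ** 2
                                    + (YC - center[1]) ** 2 < r**2)
            neck_face_j, normal_sign, j_first = j_lo, -1, j_lo - 1
        if branch is not None and np.any(mask[branch[0]:branch[1], :]):
            raise GeometryError(f"sac {s.name} overlaps the branch channel")
        for other in regions:
            if np.any(mask & other.mask):
                raise GeometryError(
                    f"sacs {other.name} and {s.name} overlap on the grid"
                )
        neck_face_i = np.nonzero(mask[:, j_first])[0]
        regions.append(AneurysmRegion(
            name=s.name, mask=mask, neck_axis="y", neck_face_j=neck_face_j,
            neck_face_i=neck_face_i, normal_sign=normal_sign, h=h,
        ))
        fluid |= mask

    inlet_rows = np.arange(j_lo, j_hi)
    if branch is None:
        outlets = [Outlet("outlet-1", "east", inlet_rows.copy(),
                          channel_width, 1.0)]
    else:
        i0, i1, diam = branch
        fr = murray_outlet_fractions(diam)
        outlets = [
            Outlet("outlet-1", "east", inlet_rows.copy(), diam[0], fr[0]),
            Outlet("outlet-2", "north", np.arange(i0, i1), diam[1], fr[1]),
        ]

    geo = Geometry2D(h=h, fluid=fluid, inlet_rows=inlet_rows,
                     outlets=outlets, regions=regions)
    geo.validate()
    return geo


def make_sealed_box(width: float, height: float, grid_spacing: float) -> Geometry2D:
    """A closed rectangular cavity with no open boundary (fixture geometry)."""
    h = float(grid_spacing)
    nx, ny = int(round(width / h)), int(round(height / h))
    if nx < 2 or ny < 2:
        raise GeometryError("sealed box must span at least 2 cells per side")
    geo = Geometry2D(h=h, fluid=np.ones((nx, ny), dtype=bool),
                     inlet_rows=np.empty(0, dtype=int), outlets=[],
                     regions=[], closed=True)
    geo.validate()
    return geo
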