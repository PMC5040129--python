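"""Artifact output: CSV tables, legacy-VTK snapshots, NPZ field bundles.

The VTK writer emits ASCII ``STRUCTURED_POINTS`` legacy files with cell
data, which every common viewer (ParaView, VisIt, pyvista) reads directly;
no VTK library is required for this trivial text format.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["write_vtk_structured", "write_case_outputs", "load_run"]


def write_vtk_structured(path, h: float, cell_fields: dict) -> None:
    """Write 2D cell-centered fields as a legacy ASCII VTK structured grid.

    cell_fields maps names to (nx, ny) arrays; NaNs are written as 0.
    """
    fields = {k: np.asarray(v, dtype=float) for k, v in cell_fields.items()}
    nx, ny = next(iter(fields.values())).shape
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write("aneuflow 2D cell fields\n")
        f.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {nx + 1} {ny + 1} 1\n")
        f.write("ORIGIN 0 0 0\n")
        f.write(f"SPACING {h} {h} {h}\n")
        f.write(f"CELL_DATA {nx * ny}\n")
        for name, arr in fields.items():
            if arr.shape != (nx, ny):
                raise ValueError(f"field {name}: shape {arr.shape} != "
                                 f"({nx}, {ny})")
            f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            flat = np.nan_to_num(arr).T.ravel()  # VTK is x-fastest
            np.savetxt(f, flat.reshape(-1, 1), fmt="%.8g")


def write_case_outputs(report, flow, maps, ages, outdir,
                       keep_fields: bool = True) -> None:
    """Write the full artifact set for one processed case."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    geo = flow.geometry
    h = geo.h

    report.table().to_csv(out / "metrics.csv", index=False)
    maps.face_table().to_csv(out / "wall_maps.csv", index=False)

    age_rows = {"time_s": ages.times}
    for k, name in enumerate(ages.region_names):
        age_rows[f"{name}_mean_age_s"] = ages.mean[k]
        age_rows[f"{name}_max_age_s"] = ages.max[k]
    pd.DataFrame(age_rows).to_csv(out / "age_series.csv", index=False)

    with open(out / "report.json", "w") as f:
        json.dump(report.to_json_dict(), f, indent=2)

    # final-snapshot fields for rendering
    k = flow.n_times - 1
    speed = flow.velocity_magnitude(k)
    region_id = np.zeros(geo.fluid.shape)
    for m, r in enumerate(geo.regions, start=1):
        region_id[r.mask] = m
    write_vtk_structured(out / "fields_final.vtk", h, {
        "fluid_mask": geo.fluid.astype(float),
        "region_id": region_id,
        "speed_m_s": np.where(geo.fluid, speed, 0.0),
        "pressure_pa": np.where(geo.fluid, flow.p[k], 0.0),
        "viscosity_pa_s": np.nan_to_num(flow.visc[k]),
        "age_s": ages.fields[-1],
    })

    if keep_fields:
        np.savez_compressed(
            out / "fields.npz", times=flow.times, u=flow.u, v=flow.v,
            p=flow.p, visc=flow.visc, fluid=geo.fluid,
            age_times=ages.times, age_fields=ages.fields, h=h,
        )

    manifest = pd.DataFrame({
        "time_s": flow.times,
        "divergence_residual": flow.div_residual,
        "inlet_flux_m2_s": flow.inlet_flux,
        **{f"outlet_{m + 1}_flux_m2_s": flow.outlet_flux[:, m]
           for m in range(flow.outlet_flux.shape[1])},
    })
    manifest.to_csv(out / "manifest.csv", index=False)


def load_run(rundir):
    """Load the field bundle and report of a previous run directory."""
    run = Path(rundir)
    with open(run / "report.json") as f:
        report = json.load(f)
    bundle = None
    if (run / "fields.npz").exists():
        bundle = np.load(run / "fields.npz")
    return report, bundle
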