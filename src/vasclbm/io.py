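"""Field snapshots: legacy-ASCII VTK export and HDF5 state files."""

from __future__ import annotations

import numpy as np

from .errors import GeometryError
from .geometry import VoxelDomain, _read_domain_group, _write_domain_group
from .solver import SolverInstance
from .units import UnitSystem

__all__ = ["write_vtk_image", "save_state", "load_state"]


def write_vtk_image(domain: VoxelDomain, fields: dict, path) -> None:
    """Write scalar/vector voxel fields as a legacy-ASCII VTK STRUCTURED_POINTS file.

    ``fields`` maps a name to an array of shape ``domain.shape`` (scalar)
    or ``(3,) + domain.shape`` (vector).  Readable by ParaView/VisIt.
    """
    nx, ny, nz = domain.shape
    lines = [
        "# vtk DataFile Version 3.0",
        "vasclbm field snapshot",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} {nz}",
        f"ORIGIN {domain.origin[0]} {domain.origin[1]} {domain.origin[2]}",
        f"SPACING {domain.dx} {domain.dx} {domain.dx}",
        f"POINT_DATA {nx * ny * nz}",
    ]
    for name, arr in fields.items():
        arr = np.asarray(arr)
        if arr.shape == domain.shape:
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            flat = arr.transpose(2, 1, 0).ravel()  # VTK is x-fastest
            lines.extend(f"{v:.7g}" for v in flat)
        elif arr.shape == (3,) + domain.shape:
            lines.append(f"VECTORS {name} float")
            flat = arr.transpose(0, 3, 2, 1).reshape(3, -1).T
            lines.extend(f"{v[0]:.7g} {v[1]:.7g} {v[2]:.7g}" for v in flat)
        else:
            raise GeometryError(
                f"field '{name}' shape {arr.shape} does not match domain"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def save_state(solver: SolverInstance, path) -> None:
    """Snapshot a solver instance (domain + populations + units) to HDF5."""
    import h5py

    with h5py.File(path, "w") as h5:
        h5.attrs["magic"] = "vasclbm-state"
        h5.attrs["step"] = solver.step_count
        h5.attrs["tau"] = solver.tau
        h5.attrs["name"] = solver.name
        u = solver.units
        h5.attrs["units"] = [u.dx, u.dt, u.rho_ref, u.nu_phys, u.v_max]
        _write_domain_group(solver.domain, h5.create_group("domain"))
        h5.create_dataset("f", data=solver.f, compression="gzip")


def load_state(path) -> SolverInstance:
    """Restore a solver instance saved with :func:`save_state`."""
    import h5py

    with h5py.File(path, "r") as h5:
        if h5.attrs.get("magic") != "vasclbm-state":
            raise GeometryError(f"{path} is not a vasclbm state snapshot")
        dom = _read_domain_group(h5["domain"])
        dx, dt, rho_ref, nu, v_max = h5.attrs["units"]
        units = UnitSystem(dx=dx, dt=dt, rho_ref=rho_ref, nu_phys=nu, v_max=v_max)
        inst = SolverInstance(
            dom, units=units, tau=float(h5.attrs["tau"]),
            name=str(h5.attrs["name"]),
        )
        inst.f = h5["f"][...]
        inst.step_count = int(h5.attrs["step"])
    return inst
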