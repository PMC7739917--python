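"""Inlet/outlet closures and the coupled-outlet dynamic-pressure force.

Velocity inlets and pressure outlets are realized as equilibrium-completion
closures: after streaming, every population at a patch site is replaced by
the equilibrium distribution for the target macroscopic state, with the
unconstrained quantity (density at velocity inlets, velocity at pressure
outlets) extrapolated from the nearest interior fluid site.  This closure
is simple, robust at low Mach number, and exactly achieves the imposed
moment at the patch sites; it is deliberately kept behind one narrow
interface so a different closure can be swapped in.

Coupled arterial outlets additionally receive an explicit body force based
on the local dynamic pressure (1/2 rho |u|^2), standing in for the unresolved
capillary bed between the coupled trees: a proportional controller scales
the dynamic-pressure magnitude by the mismatch between the patch mean
velocity and the exchanged target, pushing the mean toward the target.  The
force enters the collision step through the Guo scheme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, InvalidStateError, StabilityError
from .geometry import BoundaryPatch, VoxelDomain
from .lattice import D3Q19, LatticeDescriptor, equilibrium

__all__ = [
    "BoundaryCondition",
    "apply_velocity_inlet",
    "apply_pressure_outlet",
    "outlet_force_from_dynamic_pressure",
    "MACH_GUARD",
]

#: Lattice-velocity magnitude at which boundary targets are rejected.
MACH_GUARD = 0.1


@dataclass
class BoundaryCondition:
    """Boundary spec for one patch.

    kind: "velocity" | "pressure" | "coupled_velocity" | "coupled_force".
    value: target in physical units — m/s for the velocity kinds (and for
    the coupled-force target), Pa for "pressure".
    profile: "uniform" | "parabolic" (velocity kinds only); the parabolic
    profile peaks at 1.5x the patch mean.
    gain: proportional controller gain of the coupled-outlet force.
    """

    patch_id: int
    kind: str
    value: float
    profile: str = "uniform"
    gain: float = 10.0


def _interior_neighbours(patch: BoundaryPatch, domain: VoxelDomain) -> np.ndarray:
    nb = patch.sites + patch.normal.astype(int)
    shape = domain.shape
    ok = np.all((nb >= 0) & (nb < shape), axis=1)
    if not ok.all() or not domain.fluid_mask[tuple(nb[ok].T)].all():
        raise GeometryError(
            f"patch {patch.id}: interior neighbour along the normal is not fluid"
        )
    return nb


def _profile_factors(patch: BoundaryPatch, domain: VoxelDomain, profile: str) -> np.ndarray:
    if profile == "uniform":
        return np.ones(len(patch.sites))
    if profile != "parabolic":
        raise InvalidStateError(f"unknown velocity profile '{profile}'")
    # in-plane distance from the patch centroid, in site units
    pos = (patch.sites + 0.5) * domain.dx + domain.origin
    d = pos - patch.centroid
    d = d - np.outer(d @ patch.normal, patch.normal)  # project onto patch plane
    r = np.linalg.norm(d, axis=1)
    R = r.max() + 0.5 * domain.dx
    p = 1.5 * (1.0 - (r / R) ** 2)
    return p / p.mean()  # renormalize so the patch mean equals the target


def apply_velocity_inlet(
    f: np.ndarray,
    domain: VoxelDomain,
    patch: BoundaryPatch,
    v_target_lat: float,
    lat: LatticeDescriptor = D3Q19,
    profile: str = "uniform",
) -> None:
    """Impose a mean face-normal velocity at an inlet patch (in place).

    ``v_target_lat`` is the patch-mean speed in lattice units, directed
    along the inward normal.  Density is extrapolated from each site's
    interior neighbour.
    """
    if abs(v_target_lat) >= MACH_GUARD:
        raise StabilityError(
            f"inlet target |u|={abs(v_target_lat):.3f} (lattice) exceeds the "
            f"Mach guard {MACH_GUARD}"
        )
    sites = tuple(patch.sites.T)
    nb = _interior_neighbours(patch, domain)
    rho_nb = f[(slice(None),) + tuple(nb.T)].sum(axis=0)
    rho_nb = np.where(rho_nb > 0, rho_nb, 1.0)
    fac = _profile_factors(patch, domain, profile)
    u = patch.normal[:, None] * (v_target_lat * fac)[None, :]
    f[(slice(None),) + sites] = equilibrium(rho_nb, u, lat)


def apply_pressure_outlet(
    f: np.ndarray,
    domain: VoxelDomain,
    patch: BoundaryPatch,
    P_target_lat: float,
    lat: LatticeDescriptor = D3Q19,
) -> None:
    """Fix the density at an outlet patch to P/c_s2 (in place).

    Velocity is extrapolated from each site's interior neighbour and the
    populations completed with the corresponding equilibrium (an
    anti-bounce-back-style closure).
    """
    if P_target_lat <= 0:
        raise InvalidStateError(f"outlet pressure {P_target_lat} must be positive")
    sites = tuple(patch.sites.T)
    nb = _interior_neighbours(patch, domain)
    fnb = f[(slice(None),) + tuple(nb.T)]
    rho_nb = fnb.sum(axis=0)
    rho_nb = np.where(rho_nb > 0, rho_nb, 1.0)
    u_nb = np.tensordot(lat.velocities.astype(float), fnb, axes=([0], [0])) / rho_nb
    rho_t = P_target_lat / lat.c_s2
    f[(slice(None),) + sites] = equilibrium(np.full(rho_nb.shape, rho_t), u_nb, lat)


def outlet_force_from_dynamic_pressure(
    f: np.ndarray,
    domain: VoxelDomain,
    patch: BoundaryPatch,
    target_v_lat: float,
    gain: float = 10.0,
    lat: LatticeDescriptor = D3Q19,
) -> tuple:
    """Capillary-bed body force at a coupled outlet.

    Per-site force along the outflow direction (-normal) with magnitude

        F = gain * (target - mean_v)/v_ref * (1/2 rho |u|^2)

    where mean_v is the current patch-mean outflow speed and v_ref =
    max(|target|, |mean_v|).  The force vanishes when the fluid is at rest
    (zero dynamic pressure) and the controller correction vanishes at the
    fixed point mean_v == target; otherwise it pushes the patch mean toward
    the exchanged target.  Returned as ``(site_indices, force_vectors)``
    for accumulation into the collision-step force field.
    """
    sites = tuple(patch.sites.T)
    fp = f[(slice(None),) + sites]
    rho = fp.sum(axis=0)
    rho_safe = np.where(rho > 0, rho, 1.0)
    u = np.tensordot(lat.velocities.astype(float), fp, axes=([0], [0])) / rho_safe
    speed2 = (u**2).sum(axis=0)
    mean_v = float((u * patch.flow_dir[:, None]).sum(axis=0).mean())
    v_ref = max(abs(target_v_lat), abs(mean_v), 1e-12)
    q_dyn = 0.5 * rho_safe * speed2
    mag = gain * (target_v_lat - mean_v) / v_ref * q_dyn
    force = patch.flow_dir[:, None] * mag[None, :]
    return sites, force
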