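"""One lattice Boltzmann solver instance for a single vascular tree.

A :class:`SolverInstance` bundles a voxel domain, a unit system, the
distribution field and the per-patch boundary conditions, and advances them
with the collide-stream-boundary cycle.  Two instances (one arterial, one
venous tree) are run in lockstep and linked by the coupling machinery in
:mod:`vasclbm.coupling`.
"""

from __future__ import annotations

import numpy as np

from . import lattice as lb
from .boundaries import (
    BoundaryCondition,
    apply_pressure_outlet,
    apply_velocity_inlet,
    outlet_force_from_dynamic_pressure,
)
from .errors import DivergenceError, GeometryError
from .geometry import VoxelDomain
from .units import UnitSystem

__all__ = ["SolverInstance"]


class SolverInstance:
    """Distributions, macroscopic fields and unit system for one tree.

    Parameters
    ----------
    domain : VoxelDomain
    units : UnitSystem, optional
        Physical unit system; defaults to pure lattice units
        (dx = dt = rho_ref = 1) with the viscosity implied by ``tau``.
    tau : float, optional
        Relaxation time override (lattice).  If omitted it is derived from
        ``units``; one of the two must pin the viscosity.
    name : str
        Label used in logs and diagnostics.
    """

    def __init__(
        self,
        domain: VoxelDomain,
        units: UnitSystem | None = None,
        tau: float | None = None,
        name: str = "instance",
    ):
        if units is None:
            if tau is None:
                raise ValueError("provide units and/or tau")
            units = UnitSystem(
                dx=1.0, dt=1.0, rho_ref=1.0, nu_phys=(tau - 0.5) / 3.0
            )
        self.domain = domain
        self.units = units
        self.tau = float(tau if tau is not None else units.tau)
        self.name = name
        self.lat = lb.D3Q19
        self.fluid_mask = domain.fluid_mask
        self.f = lb.equilibrium(1.0, np.zeros(3), self.lat)[
            :, None, None, None
        ] * self.fluid_mask
        self.step_count = 0
        self.body_force = np.zeros((3,) + domain.shape)  # constant part, lattice
        self._has_body_force = False
        # two slots per patch: a population "closure" (velocity/pressure) and
        # an optional coupled "force" on top of it
        self.bcs: dict[int, dict] = {}
        # per-patch mean-velocity history (m/s), one float per step
        self.patch_history: dict[int, list] = {p.id: [] for p in domain.patches}
        self._record_patch_means()

    # -- configuration ----------------------------------------------------
    def set_bc(self, bc: BoundaryCondition) -> None:
        self.domain.patch(bc.patch_id)  # validates the id
        slot = "force" if bc.kind == "coupled_force" else "closure"
        self.bcs.setdefault(bc.patch_id, {})[slot] = bc

    def set_uniform_body_force(self, F_lat) -> None:
        """Constant body force density (lattice units) on all fluid sites."""
        F_lat = np.asarray(F_lat, float)
        self.body_force = F_lat[:, None, None, None] * self.fluid_mask
        self._has_body_force = np.any(F_lat != 0)

    # -- measurement ------------------------------------------------------
    def macroscopic(self) -> lb.MacroFields:
        return lb.macroscopic(
            self.f, self._assemble_force(), self.lat,
            fluid_mask=self.fluid_mask, step=self.step_count,
        )

    def patch_mean_v(self, pid: int) -> float:
        """Instantaneous patch-mean forward-flow speed in m/s."""
        p = self.domain.patch(pid)
        fp = self.f[(slice(None),) + tuple(p.sites.T)]
        rho = fp.sum(axis=0)
        rho = np.where(rho > 0, rho, 1.0)
        u = np.tensordot(self.lat.velocities.astype(float), fp, axes=([0], [0])) / rho
        v_lat = float((u * p.flow_dir[:, None]).sum(axis=0).mean())
        return self.units.velocity_to_physical(v_lat)

    def patch_mass_flux(self, pid: int) -> float:
        """Mass flux through a patch along its forward-flow direction (kg/s).

        Unlike ``area * mean_v`` this weights by the local density, so at
        steady state inflow and outflow fluxes balance exactly even in the
        presence of the (weakly compressible) axial density gradient.  The
        flux is evaluated one layer inside the fluid (the patch sites
        themselves hold the imposed closure, whose momentum is reset every
        step and is not the transported flux).
        """
        p = self.domain.patch(pid)
        interior = p.sites + p.normal.astype(int)
        fp = self.f[(slice(None),) + tuple(interior.T)]
        mom = np.tensordot(self.lat.velocities.astype(float), fp, axes=([0], [0]))
        flux_lat = float((mom * p.flow_dir[:, None]).sum())
        u = self.units
        return flux_lat * u.rho_ref * u.dx**3 / u.dt

    def patch_mean_P(self, pid: int) -> float:
        """Instantaneous patch-mean pressure in Pa."""
        p = self.domain.patch(pid)
        fp = self.f[(slice(None),) + tuple(p.sites.T)]
        rho = fp.sum(axis=0)
        return self.units.pressure_to_physical(self.lat.c_s2 * float(rho.mean()))

    def windowed_mean_v(self, pid: int, window: int) -> float:
        """Mean of the last ``window`` recorded patch means (m/s)."""
        h = self.patch_history[pid]
        if not h:
            return 0.0
        return float(np.mean(h[-window:]))

    def _record_patch_means(self) -> None:
        for p in self.domain.patches:
            v = self.patch_mean_v(p.id)
            self.patch_history[p.id].append(v)
            p.mean_v = v
            p.mean_P = self.patch_mean_P(p.id)

    def total_mass(self) -> float:
        return float(self.f.sum())

    # -- time stepping -----------------------------------------------------
    def _assemble_force(self) -> np.ndarray | None:
        """Force field for this step, or None when no force acts anywhere."""
        coupled = [
            slots["force"] for slots in self.bcs.values() if "force" in slots
        ]
        if not coupled:
            return self.body_force if self._has_body_force else None
        F = self.body_force
        if coupled:
            F = F.copy()
            for bc in coupled:
                p = self.domain.patch(bc.patch_id)
                target_lat = self.units.velocity_to_lattice(bc.value)
                sites, force = outlet_force_from_dynamic_pressure(
                    self.f, self.domain, p, target_lat, gain=bc.gain, lat=self.lat
                )
                F[(slice(None),) + sites] += force
        return F

    def _apply_bcs(self) -> None:
        for slots in self.bcs.values():
            bc = slots.get("closure")
            if bc is None:
                continue
            p = self.domain.patch(bc.patch_id)
            if bc.kind in ("velocity", "coupled_velocity"):
                if p.kind != "inlet":
                    raise GeometryError(
                        f"velocity condition on non-inlet patch {p.id}"
                    )
                v_lat = self.units.velocity_to_lattice(bc.value)
                apply_velocity_inlet(
                    self.f, self.domain, p, v_lat, self.lat, profile=bc.profile
                )
            elif bc.kind == "pressure":
                # typically an outlet closure, but valid on either patch kind
                P_lat = self.units.pressure_to_lattice(bc.value)
                apply_pressure_outlet(self.f, self.domain, p, P_lat, self.lat)
            else:
                raise ValueError(f"unknown boundary kind '{bc.kind}'")

    def step(self, n: int = 1) -> None:
        """Advance n collide-stream-boundary cycles."""
        for _ in range(n):
            F = self._assemble_force()
            self.f = lb.collide(
                self.f, self.tau, F, self.lat,
                fluid_mask=self.fluid_mask, step=self.step_count,
            )
            self.f = lb.stream(self.f, self.fluid_mask, self.lat)
            self._apply_bcs()
            self.step_count += 1
            self._record_patch_means()
            if self.step_count % 100 == 0 and not np.isfinite(self.f).all():
                raise DivergenceError(
                    f"{self.name}: non-finite populations at step {self.step_count}"
                )
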