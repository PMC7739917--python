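"""Canned validation experiments on synthetic vascular geometries.

These are the package's verification workloads, shared by the test suite,
the CLI and the acceptance script:

* :func:`coupled_one_to_n_experiment` — the 1:3 (generally 1:N) coupled
  arterial-venous run checking that imposed velocity scale factors are
  achieved between coupled boundaries at steady state;
* :func:`poiseuille_experiment` — body-force-driven flow in a periodic
  voxel cylinder against the parabolic closed form;
* :func:`tree_flow_experiment` — steady flow through a bifurcating
  arterial tree for the velocity-versus-vessel-area analysis.

All run in pure lattice units (dx = dt = rho_ref = 1) unless a unit system
is supplied; the coupling logic itself is unit-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import analysis, geometry
from .boundaries import BoundaryCondition
from .coupling import (
    CouplingMap,
    build_coupling_map,
    run_coupled,
    sample_pressure_factors,
    velocity_factors,
)
from .solver import SolverInstance

__all__ = [
    "coupled_one_to_n_experiment",
    "poiseuille_experiment",
    "tree_flow_experiment",
]


@dataclass
class CoupledResult:
    """Outcome of a coupled 1:N verification run."""

    cmap: CouplingMap
    arterial: SolverInstance
    venous: SolverInstance
    log: pd.DataFrame
    imposed_factors: np.ndarray  # v_i/v0 per link, group order
    achieved_ratios: np.ndarray  # measured <v_i>/<v0> at the end
    v0: float  # arterial outlet mean velocity at the end
    steady_step: int | None


def coupled_one_to_n_experiment(
    n: int = 3,
    dp_fracs=None,
    seed: int = 0,
    n_steps: int = 4000,
    exchange_period: int = 10,
    tau: float = 0.8,
    v_in: float = 0.02,
    gain: float = 10.0,
    measure_window: int = 100,
    steady_tol: float = 1e-3,
    steady_window: int = 500,
) -> CoupledResult:
    """Run the 1:N coupled verification experiment.

    Builds the synthetic 1:N geometry pair, wires the coupling map from
    the fixture's own measured centroid distances, imposes the capillary
    pressure-drop fractions (``dp_fracs`` explicitly, else sampled
    uniformly from [0.3, 0.7] with ``seed``), computes the velocity scale
    factors, and advances both trees in lockstep with alternating
    exchanges.  The arterial tree is driven by a fixed inlet velocity
    ``v_in`` (lattice units); both trees have reference-pressure outlets.

    The quantity of interest is the achieved ratio of venous-inlet to
    arterial-outlet mean velocity per link, which should equal the imposed
    factor once steady state is reached.
    """
    art_dom, ven_dom = geometry.make_one_to_n_domain(n)
    art = SolverInstance(art_dom, tau=tau, name="arterial")
    ven = SolverInstance(ven_dom, tau=tau, name="venous")

    art_in = art_dom.patches_of_kind("inlet")[0]
    art_out = art_dom.patches_of_kind("outlet")[0]
    ven_out = ven_dom.patches_of_kind("outlet")[0]
    P_ref = art.units.reference_pressure()
    art.set_bc(BoundaryCondition(art_in.id, "velocity", v_in))
    art.set_bc(BoundaryCondition(art_out.id, "pressure", P_ref))
    ven.set_bc(BoundaryCondition(ven_out.id, "pressure", P_ref))
    for p in ven_dom.patches_of_kind("inlet"):
        ven.set_bc(BoundaryCondition(p.id, "coupled_velocity", 0.0))

    cmap = build_coupling_map(
        [art_out], ven_dom.patches_of_kind("inlet"),
        exchange_period=exchange_period, P0_ref=P_ref,
    )
    group = cmap.groups[0]
    if dp_fracs is not None:
        if len(dp_fracs) != len(group.links):
            raise ValueError(
                f"{len(dp_fracs)} pressure fractions for {len(group.links)} links"
            )
        for lk, dp in zip(group.links, dp_fracs):
            lk.dP_frac = float(dp)
    else:
        sample_pressure_factors(cmap, seed)
    velocity_factors(group)

    log = run_coupled(art, ven, cmap, n_steps, gain=gain)

    v0 = art.windowed_mean_v(art_out.id, measure_window)
    achieved = np.array(
        [
            ven.windowed_mean_v(lk.inlet.id, measure_window) / v0
            if v0 != 0.0
            else np.nan
            for lk in group.links
        ]
    )
    imposed = np.array([lk.v_factor for lk in group.links])
    history = {
        f"art_out": art.patch_history[art_out.id],
        **{
            f"ven_in_{lk.inlet.id}": ven.patch_history[lk.inlet.id]
            for lk in group.links
        },
    }
    steady = analysis.steady_state(history, window=steady_window, tol=steady_tol)
    return CoupledResult(
        cmap=cmap, arterial=art, venous=ven, log=log,
        imposed_factors=imposed, achieved_ratios=achieved,
        v0=v0, steady_step=steady,
    )


#: "Magic" relaxation time (tau - 1/2)^2 = 3/16, at which the bounce-back
#: wall of SRT channel flow sits exactly halfway between fluid and solid.
TAU_MAGIC = 0.5 + np.sqrt(3.0 / 16.0)


def poiseuille_experiment(
    radius: int = 10,
    tau: float = TAU_MAGIC,
    G: float = 2e-4,
    n_steps: int = 3000,
) -> dict:
    """Body-force-driven Poiseuille flow in a periodic voxel cylinder.

    Compares the steady axial velocity profile with the closed form
    u(r) = G (R^2 - r^2) / (4 rho nu), R = radius + 1/2 (the tube lumen
    holds voxel centres within R of the axis, and the halfway bounce-back
    wall sits half a spacing beyond the last fluid voxel).  The default
    relaxation time is the "magic" SRT value at which the bounce-back wall
    location is exact for channel flow.

    Returns the relative L2 profile error, the peak velocities, and the
    mass drift over the run.
    """
    dom = geometry.make_tube(radius, max(2 * radius, 4), periodic=True)
    # shorten the periodic axis: the flow is axially invariant
    dom = geometry.VoxelDomain(site_class=dom.site_class[:, :, :4], dx=dom.dx)
    inst = SolverInstance(dom, tau=tau, name="poiseuille")
    inst.set_uniform_body_force((0.0, 0.0, G))
    mass0 = inst.total_mass()
    inst.step(n_steps)
    mass_drift = abs(inst.total_mass() - mass0) / mass0

    nu = (tau - 0.5) / 3.0
    R = radius + 0.5
    mac = inst.macroscopic()
    uz = mac.u[2, :, :, 1]
    fluid = dom.fluid_mask[:, :, 1]
    c = radius + 1
    ii, jj = np.meshgrid(
        np.arange(dom.shape[0]), np.arange(dom.shape[1]), indexing="ij"
    )
    r = np.sqrt((ii - c) ** 2 + (jj - c) ** 2)[fluid]
    u_num = uz[fluid]
    u_ref = G * (R**2 - r**2) / (4.0 * nu)  # rho = 1
    l2 = float(np.linalg.norm(u_num - u_ref) / np.linalg.norm(u_ref))
    return {
        "l2_error": l2,
        "u_max_numeric": float(u_num.max()),
        "u_max_analytic": float(G * R**2 / (4 * nu)),
        "mass_drift": float(mass_drift),
        "n_sites": int(dom.n_fluid),
    }


def tree_flow_experiment(
    tau: float = 0.8,
    v_in: float = 0.02,
    n_steps: int = 3000,
    fractions=analysis.DEFAULT_FRACTIONS,
) -> dict:
    """Steady flow through the bifurcating arterial tree.

    Drives the root inlet at ``v_in`` (lattice units) with
    reference-pressure leaf outlets, then extracts per-vessel
    cross-sections at the given length fractions.  Because total lumen
    area grows distally, mass conservation forces the mean speed to fall
    from root to leaves: the table should show speed decreasing with
    generation and a positive area-speed association.
    """
    dom = geometry.make_bifurcating_tree()
    inst = SolverInstance(dom, tau=tau, name="tree")
    P_ref = inst.units.reference_pressure()
    inlet = dom.patches_of_kind("inlet")[0]
    inst.set_bc(BoundaryCondition(inlet.id, "velocity", v_in))
    for p in dom.patches_of_kind("outlet"):
        inst.set_bc(BoundaryCondition(p.id, "pressure", P_ref))
    inst.step(n_steps)

    sections = analysis.extract_cross_sections(
        dom, inst, fractions=fractions, tree="arterial"
    )
    table = analysis.velocity_area_table(sections)
    per_plane = (
        table.groupby("fraction")["mean_speed"].mean().sort_index()
    )
    from scipy.stats import spearmanr

    rho_s = float(
        spearmanr(-table["area"], table["mean_speed"]).statistic
    )  # un-negate the arterial presentation sign
    return {
        "solver": inst,
        "domain": dom,
        "table": table,
        "mean_speed_by_plane": per_plane,
        "spearman_area_speed": rho_s,
    }
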