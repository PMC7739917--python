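"""Artery-vein self-coupling: 1:N maps, scale factors, alternating exchange.

Two solver instances — an arterial tree whose outlets feed an unresolved
capillary bed, and a venous tree whose inlets drain it — are linked by a
coupling map.  Each arterial outlet heads one group of links to venous
inlets (a 1:N unit); every venous inlet belongs to exactly one link.

Per link i the map stores the centroid-centroid distance L_i, a sampled
capillary pressure-drop fraction dP_i = DeltaP_i / P_0 in [0.3, 0.7], and a
velocity scale factor v_i / v_0.  The factor comes from modelling the
capillary bed between the pair as a linear resistance — the pressure drop
proportional to flow rate times path length, DeltaP_i = k_i q_i L_i with
k_i inversely proportional to the inlet area — combined with mass
conservation q_0 = sum_i q_i across the group.  Writing w_i =
DeltaP_i A_i / L_i this gives

    v_i / v_0 = (A_0 / A_i) * w_i / sum_j w_j,

which satisfies the exact mass-conservation identity
sum_i (A_i/A_0) (v_i/v_0) = 1.

During a coupled run the two instances advance in lockstep and swap only
patch-averaged values, alternating direction at every swap: "forward"
(arterial to venous) scales the arterial-outlet mean velocity by each
link's factor to produce venous inlet velocity targets; "reverse" (venous
to arterial) averages the factor-descaled venous inlet means into a target
for the arterial outlet's capillary-bed force.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DivergenceError, ExchangeError, MappingError
from .geometry import BoundaryPatch
from .solver import SolverInstance

__all__ = [
    "CouplingLink",
    "CouplingGroup",
    "CouplingMap",
    "build_coupling_map",
    "sample_pressure_factors",
    "velocity_factors",
    "forward_exchange",
    "reverse_exchange",
    "run_coupled",
]


@dataclass
class CouplingLink:
    """One arterial-outlet / venous-inlet pairing."""

    outlet: BoundaryPatch
    inlet: BoundaryPatch
    L: float  # centroid-centroid distance, m
    dP_frac: float = np.nan  # DeltaP_i / P0, sampled in [0.3, 0.7]
    v_factor: float = np.nan  # v_i / v0


@dataclass
class CouplingGroup:
    """All links sharing one arterial outlet (the 1:N unit)."""

    outlet: BoundaryPatch
    links: list = field(default_factory=list)

    def mass_identity(self) -> float:
        """sum_i (A_i/A_0) v_factor_i; equals 1 for consistent factors."""
        A0 = self.outlet.area
        return float(
            sum((lk.inlet.area / A0) * lk.v_factor for lk in self.links)
        )


@dataclass
class CouplingMap:
    """The full 1:N wiring plus exchange bookkeeping."""

    groups: list
    exchange_period: int = 10
    direction_state: str = "forward"
    P0_ref: float = 1.0  # arterial-outlet reference pressure, Pa

    @property
    def links(self) -> list:
        return [lk for g in self.groups for lk in g.links]

    def group_for_outlet(self, pid: int) -> CouplingGroup:
        for g in self.groups:
            if g.outlet.id == pid:
                return g
        raise MappingError(f"no coupling group for outlet {pid}")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "outlet_id": lk.outlet.id,
                "inlet_id": lk.inlet.id,
                "L": lk.L,
                "dP_frac": lk.dP_frac,
                "v_factor": lk.v_factor,
            }
            for lk in self.links
        ]
        return pd.DataFrame(rows)


def _nearest(target: np.ndarray, candidates: list) -> BoundaryPatch:
    """Closest patch by Euclidean centroid distance; ties -> lowest id."""
    best = min(
        candidates,
        key=lambda p: (float(np.linalg.norm(p.centroid - target)), p.id),
    )
    return best


def build_coupling_map(outlets: list, inlets: list, **kwargs) -> CouplingMap:
    """Two-pass nearest-neighbour construction of the 1:N map.

    Pass 1 guarantees coverage of every arterial outlet: outlets are
    visited in ascending patch-id order and each claims its nearest
    still-unassigned venous inlet.  Pass 2 assigns every remaining inlet to
    the group of its nearest outlet.  Distances are Euclidean between patch
    centroids (world frame); equidistant candidates resolve to the lowest
    patch id.  Each link records its centroid distance L for the later
    scale-factor computation.
    """
    if not outlets:
        raise MappingError("need at least one arterial outlet")
    if len(inlets) < len(outlets):
        raise MappingError(
            f"{len(inlets)} venous inlets cannot cover "
            f"{len(outlets)} arterial outlets"
        )
    groups = {}
    remaining = sorted(inlets, key=lambda p: p.id)
    for o in sorted(outlets, key=lambda p: p.id):
        chosen = _nearest(o.centroid, remaining)
        remaining.remove(chosen)
        dist = float(np.linalg.norm(chosen.centroid - o.centroid))
        groups[o.id] = CouplingGroup(
            outlet=o, links=[CouplingLink(outlet=o, inlet=chosen, L=dist)]
        )
    outlet_list = sorted(outlets, key=lambda p: p.id)
    for inlet in remaining:
        o = _nearest(inlet.centroid, outlet_list)
        dist = float(np.linalg.norm(inlet.centroid - o.centroid))
        groups[o.id].links.append(CouplingLink(outlet=o, inlet=inlet, L=dist))
    return CouplingMap(groups=[groups[k] for k in sorted(groups)], **kwargs)


def sample_pressure_factors(
    cmap: CouplingMap, rng_seed: int, lo: float = 0.3, hi: float = 0.7
) -> CouplingMap:
    """Draw each link's capillary pressure-drop fraction from U(lo, hi).

    Draws are i.i.d. from a generator seeded with ``rng_seed``, visiting
    groups in order and links in creation order, so identical seeds give
    identical maps.
    """
    rng = np.random.default_rng(rng_seed)
    for g in cmap.groups:
        for lk in g.links:
            lk.dP_frac = float(rng.uniform(lo, hi))
    return cmap


def velocity_factors(group: CouplingGroup) -> CouplingGroup:
    """Set v_i/v_0 for every link in a group from (dP_frac, L, areas).

    v_factor_i = (A_0/A_i) * w_i / sum_j w_j  with  w_i = dP_i A_i / L_i.
    The group then satisfies sum_i (A_i/A_0) v_factor_i = 1 exactly, so the
    imposed venous inflow carries the whole arterial outflow.
    """
    for lk in group.links:
        if lk.L <= 0 or lk.inlet.area <= 0 or group.outlet.area <= 0:
            raise MappingError(
                f"degenerate link outlet={lk.outlet.id} inlet={lk.inlet.id}: "
                "zero length or area"
            )
        if not np.isfinite(lk.dP_frac):
            raise ExchangeError("pressure factors must be sampled first")
    w = np.array([lk.dP_frac * lk.inlet.area / lk.L for lk in group.links])
    A0 = group.outlet.area
    for lk, wi in zip(group.links, w):
        lk.v_factor = float((A0 / lk.inlet.area) * wi / w.sum())
    return group


def _require_factors(cmap: CouplingMap) -> None:
    for lk in cmap.links:
        if not np.isfinite(lk.v_factor):
            raise ExchangeError(
                "velocity factors are unset; call velocity_factors() per group"
            )


def forward_exchange(arterial: SolverInstance, cmap: CouplingMap) -> dict:
    """Arterial-to-venous swap of averaged boundary values.

    For each link, the venous inlet's velocity target becomes
    v_factor_i * <v_0>, where <v_0> is the arterial outlet's patch-mean
    forward velocity averaged over the steps since the last swap; the
    inlet pressure bookkeeping value is (1 - dP_frac) * P0.  Flips the
    direction state to "reverse".

    Returns ``{inlet_patch_id: (v_target_m_per_s, P_target_pa)}``.
    """
    if cmap.direction_state != "forward":
        raise ExchangeError("map is in the reverse phase")
    _require_factors(cmap)
    out = {}
    for g in cmap.groups:
        v0 = arterial.windowed_mean_v(g.outlet.id, cmap.exchange_period)
        for lk in g.links:
            out[lk.inlet.id] = (
                lk.v_factor * v0,
                (1.0 - lk.dP_frac) * cmap.P0_ref,
            )
    cmap.direction_state = "reverse"
    return out


def reverse_exchange(venous: SolverInstance, cmap: CouplingMap) -> dict:
    """Venous-to-arterial swap: force-controller targets for the outlets.

    Each group's arterial outlet target is the mean over its links of the
    factor-descaled venous inlet patch-mean velocity, <v_i>/v_factor_i —
    the venous tree's consensus estimate of v_0.  Flips the direction state
    to "forward".

    Returns ``{outlet_patch_id: v_target_m_per_s}``.
    """
    if cmap.direction_state != "reverse":
        raise ExchangeError("map is in the forward phase")
    _require_factors(cmap)
    out = {}
    for g in cmap.groups:
        ests = [
            venous.windowed_mean_v(lk.inlet.id, cmap.exchange_period)
            / lk.v_factor
            for lk in g.links
        ]
        out[g.outlet.id] = float(np.mean(ests))
    cmap.direction_state = "forward"
    return out


def run_coupled(
    arterial: SolverInstance,
    venous: SolverInstance,
    cmap: CouplingMap,
    n_steps: int,
    gain: float = 10.0,
) -> pd.DataFrame:
    """Advance both instances in lockstep with alternating exchanges.

    Every ``cmap.exchange_period`` steps one exchange occurs, alternating
    forward/reverse; exchanged values are installed as coupled boundary
    conditions on the receiving instance.  Returns the exchange log (one
    row per link per exchange).  Aborts with a diagnostic on instability.
    """
    from .boundaries import BoundaryCondition

    log = []
    for k in range(1, n_steps + 1):
        try:
            arterial.step()
            venous.step()
        except DivergenceError as err:
            raise DivergenceError(
                f"coupled run aborted at step {k}: {err}; "
                f"arterial mass={arterial.total_mass():.4g}, "
                f"venous mass={venous.total_mass():.4g}"
            ) from err
        if k % cmap.exchange_period != 0:
            continue
        direction = cmap.direction_state
        if direction == "forward":
            targets = forward_exchange(arterial, cmap)
            for pid, (v_t, P_t) in targets.items():
                venous.set_bc(
                    BoundaryCondition(patch_id=pid, kind="coupled_velocity", value=v_t)
                )
                for lk in cmap.links:
                    if lk.inlet.id == pid:
                        log.append(
                            {
                                "step": k,
                                "direction": "forward",
                                "outlet_id": lk.outlet.id,
                                "inlet_id": pid,
                                "value": v_t,
                                "pressure": P_t,
                            }
                        )
        else:
            targets = reverse_exchange(venous, cmap)
            for pid, v_t in targets.items():
                arterial.set_bc(
                    BoundaryCondition(
                        patch_id=pid, kind="coupled_force", value=v_t, gain=gain
                    )
                )
                for lk in cmap.group_for_outlet(pid).links:
                    log.append(
                        {
                            "step": k,
                            "direction": "reverse",
                            "outlet_id": pid,
                            "inlet_id": lk.inlet.id,
                            "value": v_t,
                            "pressure": np.nan,
                        }
                    )
    return pd.DataFrame(
        log,
        columns=["step", "direction", "outlet_id", "inlet_id", "value", "pressure"],
    )
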