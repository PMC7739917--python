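"""Physical <-> lattice unit conversion and stability/validity checks.

Two relations govern the accuracy and stability of single-relaxation-time
lattice Boltzmann runs:

* viscosity:  nu = (1/3) (tau - 1/2) dx^2 / dt
* computational Mach number:  Ma = 3 v_max dt / dx, required < 0.1

with the relaxation time preferred in (0.5, 1].  These pull in opposite
directions: refining dt at fixed dx lowers Ma but drives tau toward the
unstable 0.5 limit, which is why physiological resolutions (25 um, 1 us,
~1 m/s aortic peak) sit at the edge of the feasible window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "UnitSystem",
    "tau_from_physical",
    "nu_from_tau",
    "mach_number",
    "validate_stability",
    "StabilityReport",
]

#: Conventional kinematic viscosity of blood (m^2/s), config-overridable.
BLOOD_NU = 3.3e-6
#: Reference blood density (kg/m^3).
BLOOD_RHO = 1050.0

MACH_LIMIT = 0.1
TAU_MIN = 0.5
TAU_PREF_MAX = 1.0


def tau_from_physical(nu_phys: float, dx: float, dt: float) -> float:
    """Relaxation time for a target kinematic viscosity.

    Inverts nu = (1/3)(tau - 1/2) dx^2/dt:  tau = 3 nu dt / dx^2 + 1/2.
    """
    return 3.0 * nu_phys * dt / dx**2 + 0.5


def nu_from_tau(tau: float, dx: float, dt: float) -> float:
    """Kinematic viscosity implied by a relaxation time (m^2/s)."""
    return (tau - 0.5) * dx**2 / (3.0 * dt)


def mach_number(v_max: float, dx: float, dt: float) -> float:
    """Computational Mach number, 3 v_max dt / dx."""
    return 3.0 * v_max * dt / dx


@dataclass
class UnitSystem:
    """Lattice <-> physical conversion for one solver instance.

    Parameters
    ----------
    dx : lattice spacing (m)
    dt : time step (s)
    rho_ref : reference density (kg/m^3); maps to lattice density 1
    nu_phys : kinematic viscosity (m^2/s)
    v_max : expected peak speed (m/s), used for the Mach check
    """

    dx: float
    dt: float
    rho_ref: float = BLOOD_RHO
    nu_phys: float = BLOOD_NU
    v_max: float = 0.0

    @property
    def tau(self) -> float:
        return tau_from_physical(self.nu_phys, self.dx, self.dt)

    @property
    def Ma(self) -> float:
        return mach_number(self.v_max, self.dx, self.dt)

    # conversions ---------------------------------------------------------
    def velocity_to_lattice(self, v: float) -> float:
        return v * self.dt / self.dx

    def velocity_to_physical(self, v_lat: float) -> float:
        return v_lat * self.dx / self.dt

    def pressure_to_lattice(self, P: float) -> float:
        return P * self.dt**2 / (self.rho_ref * self.dx**2)

    def pressure_to_physical(self, P_lat: float) -> float:
        return P_lat * self.rho_ref * self.dx**2 / self.dt**2

    def force_density_to_physical(self, F_lat: float) -> float:
        return F_lat * self.rho_ref * self.dx / self.dt**2

    def reference_pressure(self) -> float:
        """Physical pressure (Pa) of the lattice rest state (rho=1, P=c_s2)."""
        return self.pressure_to_physical(1.0 / 3.0)


@dataclass
class StabilityReport:
    """Outcome of the tau/Mach guardrail checks."""

    status: str  # "pass" | "warn" | "fail"
    tau: float
    Ma: float
    messages: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.status != "fail"

    def __str__(self) -> str:
        lines = [f"stability: {self.status} (tau={self.tau:.4f}, Ma={self.Ma:.4f})"]
        lines += [f"  - {m}" for m in self.messages]
        return "\n".join(lines)


def validate_stability(units: UnitSystem) -> StabilityReport:
    """Check a unit system against the stability guardrails.

    fail: tau <= 0.5 (negative/zero viscosity) or Ma >= 0.1;
    warn: tau > 1 (accuracy preference tau in (0.5, 1]);
    pass otherwise.  Report-only: never raises.
    """
    tau, Ma = units.tau, units.Ma
    msgs = []
    status = "pass"
    if tau <= TAU_MIN:
        status = "fail"
        msgs.append(f"tau={tau:.4f} <= 0.5: unstable (non-positive viscosity)")
    if Ma >= MACH_LIMIT:
        status = "fail"
        msgs.append(
            f"Ma={Ma:.4f} >= {MACH_LIMIT}: computational Mach bound violated"
        )
    if status == "pass" and tau > TAU_PREF_MAX:
        status = "warn"
        msgs.append(f"tau={tau:.4f} > 1: accuracy degrades; prefer tau in (0.5, 1]")
    return StabilityReport(status=status, tau=tau, Ma=Ma, messages=msgs)
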