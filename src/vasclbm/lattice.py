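"""D3Q19 single-relaxation-time lattice Boltzmann kernel.

The solver evolves 19 particle populations per fluid voxel under the BGK
(single relaxation time) collision operator with the second-order Guo body
force scheme, followed by propagation with halfway bounce-back at rigid
walls.  All quantities in this module are in lattice units: dx = dt = 1 and
the reference density is 1; conversion to physical units lives in
:mod:`vasclbm.units`.

Populations are stored densely as an array of shape ``(19, nx, ny, nz)``
over the bounding box of the domain; solid voxels simply carry zeros.  At
desk scale (<= a few 1e5 sites) the dense layout with vectorized numpy is
both simpler and faster than indexed sparse storage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .errors import DivergenceError, InvalidStateError, StabilityError

__all__ = [
    "LatticeDescriptor",
    "build_d3q19",
    "D3Q19",
    "equilibrium",
    "macroscopic",
    "collide",
    "stream",
]


@dataclass(frozen=True)
class LatticeDescriptor:
    """The D3Q19 stencil: discrete velocities, quadrature weights, opposites.

    Attributes
    ----------
    velocities : (19, 3) int array
        Discrete velocity vectors e_i: one rest vector, 6 face vectors
        (|e| = 1) and 12 edge vectors (|e| = sqrt(2)).
    weights : (19,) float array
        Quadrature weights w_i (1/3 rest, 1/18 face, 1/36 edge); sum to 1.
    weights_exact : tuple of Fraction
        The same weights as exact rationals, for identity checks.
    opposite : (19,) int array
        Index map with velocities[opposite[i]] == -velocities[i].
    c_s2 : float
        Squared lattice sound speed, 1/3.
    """

    velocities: np.ndarray
    weights: np.ndarray
    weights_exact: tuple
    opposite: np.ndarray
    c_s2: float = 1.0 / 3.0


def build_d3q19() -> LatticeDescriptor:
    """Construct the D3Q19 lattice descriptor.

    The velocity set is every integer 3-vector with squared norm 0, 1 or 2;
    ordering is rest vector first, then faces, then edges, each block in
    lexicographic order.
    """
    all_vecs = [
        (x, y, z)
        for x in (-1, 0, 1)
        for y in (-1, 0, 1)
        for z in (-1, 0, 1)
        if x * x + y * y + z * z <= 2
    ]
    rest = [v for v in all_vecs if sum(c * c for c in v) == 0]
    faces = sorted(v for v in all_vecs if sum(c * c for c in v) == 1)
    edges = sorted(v for v in all_vecs if sum(c * c for c in v) == 2)
    velocities = np.array(rest + faces + edges, dtype=np.int64)
    assert velocities.shape == (19, 3)

    norms2 = (velocities**2).sum(axis=1)
    w_exact = tuple(
        Fraction(1, 3) if n == 0 else Fraction(1, 18) if n == 1 else Fraction(1, 36)
        for n in norms2
    )
    weights = np.array([float(w) for w in w_exact])

    opposite = np.empty(19, dtype=np.int64)
    for i, e in enumerate(velocities):
        (j,) = np.nonzero((velocities == -e).all(axis=1))[0]
        opposite[i] = j

    return LatticeDescriptor(
        velocities=velocities,
        weights=weights,
        weights_exact=w_exact,
        opposite=opposite,
    )


#: Shared default descriptor; the stencil is immutable so one instance serves.
D3Q19 = build_d3q19()


@dataclass
class DistributionField:
    """Per-site populations plus a step counter.

    ``f`` has shape (19, nx, ny, nz); entries at solid voxels are zero.
    """

    f: np.ndarray
    step: int = 0

    def total_mass(self, fluid_mask: np.ndarray | None = None) -> float:
        if fluid_mask is None:
            return float(self.f.sum())
        return float(self.f[:, fluid_mask].sum())


@dataclass
class MacroFields:
    """Macroscopic moments on the lattice: density, velocity, pressure, force."""

    rho: np.ndarray
    u: np.ndarray  # shape (3, nx, ny, nz)
    P: np.ndarray
    F: np.ndarray  # shape (3, nx, ny, nz)


def equilibrium(rho, u, lat: LatticeDescriptor = D3Q19) -> np.ndarray:
    """Second-order Maxwell-Boltzmann equilibrium populations.

    f_eq_i = w_i rho [1 + (e_i.u)/c_s2 + (e_i.u)^2/(2 c_s2^2) - u^2/(2 c_s2)]

    Parameters
    ----------
    rho : scalar or (nx, ny, nz) array, must be positive
    u : (3,) vector or (3, nx, ny, nz) array

    Returns
    -------
    (19, ...) array with Sum_i f_eq = rho and Sum_i f_eq e_i = rho u exactly
    (to round-off).
    """
    rho = np.asarray(rho, dtype=float)
    u = np.asarray(u, dtype=float)
    if np.any(rho <= 0):
        raise InvalidStateError("equilibrium requires rho > 0 everywhere")
    cs2 = lat.c_s2
    # eu[i] = e_i . u  with broadcasting over trailing spatial axes
    eu = np.tensordot(lat.velocities.astype(float), u, axes=([1], [0]))
    u2 = (u**2).sum(axis=0)
    w = lat.weights.reshape((19,) + (1,) * u2.ndim)
    return w * rho * (1.0 + eu / cs2 + eu**2 / (2 * cs2**2) - u2 / (2 * cs2))


def macroscopic(
    f: np.ndarray,
    F: np.ndarray | None = None,
    lat: LatticeDescriptor = D3Q19,
    fluid_mask: np.ndarray | None = None,
    step: int | None = None,
) -> MacroFields:
    """Density, velocity and pressure moments of the populations.

    rho = Sum_i f_i;  u = (Sum_i f_i e_i + F/2) / rho;  P = c_s2 rho.

    The half-force shift in the velocity is the Guo-scheme convention: with
    it, the recovered momentum is second-order accurate in the presence of a
    body force.

    Raises
    ------
    DivergenceError
        If rho <= 0 at any fluid site (names the worst site and the step).
    """
    rho = f.sum(axis=0)
    mom = np.tensordot(lat.velocities.astype(float), f, axes=([0], [0]))
    if F is not None:
        mom = mom + 0.5 * F
    if fluid_mask is None:
        bad = rho <= 0
    else:
        bad = (rho <= 0) & fluid_mask
    if np.any(bad):
        site = tuple(int(c) for c in np.argwhere(bad)[0])
        raise DivergenceError(
            f"non-positive density at site {site}"
            + (f" at step {step}" if step is not None else "")
        )
    safe = np.where(rho > 0, rho, 1.0)
    u = mom / safe
    if fluid_mask is not None:
        u = u * fluid_mask
    return MacroFields(rho=rho, u=u, P=lat.c_s2 * rho, F=F)


def guo_source(u: np.ndarray, F: np.ndarray, tau: float, lat: LatticeDescriptor = D3Q19) -> np.ndarray:
    """Second-order Guo forcing term S_i.

    S_i = (1 - 1/(2 tau)) w_i [ (e_i - u)/c_s2 + (e_i.u) e_i / c_s2^2 ] . F
    """
    cs2 = lat.c_s2
    e = lat.velocities.astype(float)
    eu = np.tensordot(e, u, axes=([1], [0]))  # (19, ...)
    eF = np.tensordot(e, F, axes=([1], [0]))
    uF = (u * F).sum(axis=0)
    w = lat.weights.reshape((19,) + (1,) * uF.ndim)
    return (1.0 - 0.5 / tau) * w * ((eF - uF) / cs2 + eu * eF / cs2**2)


def collide(
    f: np.ndarray,
    tau: float,
    F: np.ndarray | None = None,
    lat: LatticeDescriptor = D3Q19,
    fluid_mask: np.ndarray | None = None,
    step: int | None = None,
) -> np.ndarray:
    """BGK collision with optional Guo body force.

    f' = f - (f - f_eq(rho, u)) / tau + S_i, where u includes the half-step
    force correction.  Requires tau > 0.5 for linear stability.
    """
    if tau <= 0.5:
        raise StabilityError(f"relaxation time tau={tau} must exceed 0.5")
    mac = macroscopic(f, F, lat, fluid_mask=fluid_mask, step=step)
    rho = np.where(mac.rho > 0, mac.rho, 1.0)
    feq = equilibrium(rho, mac.u, lat)
    out = f - (f - feq) / tau
    if F is not None:
        out = out + guo_source(mac.u, F, tau, lat)
    if fluid_mask is not None:
        out = out * fluid_mask
    return out


def stream(f: np.ndarray, fluid_mask: np.ndarray, lat: LatticeDescriptor = D3Q19) -> np.ndarray:
    """Propagation with halfway bounce-back at solid voxels.

    Population i arriving at x comes from x - e_i when that source voxel is
    fluid; when the source is solid, the population that left x toward the
    solid returns reversed (halfway bounce-back), giving a rigid no-slip
    wall located half a lattice spacing beyond the last fluid voxel.

    Array edges wrap periodically (np.roll); domains that are not meant to
    be periodic carry a solid shell or boundary patches on their faces, so
    wrapped values are either bounced or overwritten by boundary closures.

    Mass is conserved exactly in closed domains.
    """
    out = np.empty_like(f)
    shift_axes = (0, 1, 2)
    for i, e in enumerate(lat.velocities):
        sh = tuple(int(c) for c in e)
        src = np.roll(f[i], shift=sh, axis=shift_axes)
        src_fluid = np.roll(fluid_mask, shift=sh, axis=shift_axes)
        out[i] = np.where(src_fluid, src, f[lat.opposite[i]])
    out *= fluid_mask
    return out
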