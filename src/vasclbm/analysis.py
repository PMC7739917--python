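"""Observables: cross-section extraction, hull areas, steady-state detection.

The velocity-versus-vessel-area study slices the domain with measurement
planes (by default at one-quarter, one-half and three-quarters of the
domain length), splits each plane's fluid sites into per-vessel connected
components, and tabulates each vessel's convex-hull cross-sectional area
against its mean velocity magnitude.  Arterial rows carry a negated area —
a plotting convention that keeps arterial and venous points on opposite
sides of the area axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from .geometry import VoxelDomain
from .solver import SolverInstance

__all__ = [
    "VesselCrossSection",
    "extract_cross_sections",
    "hull_area",
    "velocity_area_table",
    "steady_state",
    "DEFAULT_FRACTIONS",
]

DEFAULT_FRACTIONS = (0.25, 0.5, 0.75)

# 8-connectivity within a plane
_CONN8 = np.ones((3, 3), dtype=bool)


@dataclass
class VesselCrossSection:
    """One vessel's intersection with a measurement plane."""

    axis: int  # plane normal axis (0, 1, 2)
    index: int  # plane position, voxel index along the axis
    fraction: float  # position as a fraction of domain length
    component: int  # vessel component id within the plane
    sites: np.ndarray  # (n, 2) in-plane voxel indices
    area_hull: float  # m^2, convex hull of site centres
    mean_speed: float  # m/s, mean of per-site |u|
    tree: str = "arterial"  # "arterial" | "venous"


def hull_area(sites: np.ndarray, dx: float) -> float:
    """2D convex-hull area of in-plane site centres, in m^2.

    Degenerate inputs (< 3 sites or collinear) fall back to face counting
    (n_sites * dx^2) with a warning, since a hull is undefined there.
    """
    pts = np.asarray(sites, float) * dx
    if len(pts) >= 3:
        try:
            return float(ConvexHull(pts).volume)  # 2D "volume" is the area
        except QhullError:
            pass
    warnings.warn(
        "degenerate cross-section (<3 non-collinear sites); "
        "falling back to voxel-face area",
        stacklevel=2,
    )
    return len(pts) * dx**2


def extract_cross_sections(
    domain: VoxelDomain,
    solver: SolverInstance,
    fractions=DEFAULT_FRACTIONS,
    axis: int = 2,
    tree: str = "arterial",
) -> list:
    """Slice the domain with measurement planes and split into vessels.

    Each plane at ``round(frac * (n-1))`` along ``axis`` is decomposed into
    8-connected in-plane components of fluid sites; per component the mean
    of per-site velocity magnitudes and the convex-hull area are computed.
    Planes that contain no fluid yield nothing (with a warning).
    """
    mac = solver.macroscopic()
    speed_lat = np.sqrt((mac.u**2).sum(axis=0))
    out = []
    n = domain.shape[axis]
    for frac in fractions:
        if not 0 < frac < 1:
            raise ValueError(f"plane fraction {frac} must lie in (0, 1)")
        idx = int(round(frac * (n - 1)))
        sl = [slice(None)] * 3
        sl[axis] = idx
        plane_fluid = domain.fluid_mask[tuple(sl)]
        if not plane_fluid.any():
            warnings.warn(f"plane at fraction {frac} contains no fluid sites")
            continue
        plane_speed = speed_lat[tuple(sl)]
        labels, ncomp = ndimage.label(plane_fluid, structure=_CONN8)
        for comp in range(1, ncomp + 1):
            sites2d = np.argwhere(labels == comp)
            speeds = plane_speed[tuple(sites2d.T)]
            out.append(
                VesselCrossSection(
                    axis=axis,
                    index=idx,
                    fraction=frac,
                    component=comp,
                    sites=sites2d,
                    area_hull=hull_area(sites2d, domain.dx),
                    mean_speed=solver.units.velocity_to_physical(
                        float(speeds.mean())
                    ),
                    tree=tree,
                )
            )
    return out


def velocity_area_table(sections: list) -> pd.DataFrame:
    """Tabulate (signed area, mean speed, tree) for a list of cross-sections.

    Arterial areas are negated so arterial and venous populations separate
    along the area axis when plotted.
    """
    rows = [
        {
            "fraction": s.fraction,
            "component": s.component,
            "tree": s.tree,
            "area": -s.area_hull if s.tree == "arterial" else s.area_hull,
            "mean_speed": s.mean_speed,
        }
        for s in sections
    ]
    return pd.DataFrame(
        rows, columns=["fraction", "component", "tree", "area", "mean_speed"]
    )


def steady_state(history, window: int, tol: float) -> int | None:
    """First step at which all monitored series have settled.

    ``history`` maps a label to a per-step sequence of patch means.  A step
    t qualifies when, for every series, the peak-to-peak variation over the
    trailing ``window`` steps is below ``tol`` times the series' scale
    (max |value| in the window, floored at machine-tiny to handle all-zero
    series).  Returns the earliest qualifying step, or None if never
    reached.
    """
    series = [np.asarray(h, float) for h in history.values()]
    if not series:
        return None
    n = min(len(s) for s in series)
    if n < window:
        return None
    for t in range(window, n + 1):
        ok = True
        for s in series:
            win = s[t - window : t]
            scale = max(np.abs(win).max(), 1e-300)
            if (win.max() - win.min()) / scale >= tol:
                ok = False
                break
        if ok:
            return t
    return None
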